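"""SNP selection by PLS-DA and classification by nearest shrunken centroids.

This is the comparison baseline built on a reduced SNP panel. It runs on
genotypes that already passed the major-genotypic-frequency filter and
reference-anchored standardization (see :mod:`grmclassify.io`):

1. *PLS-DA selection* — a partial least squares regression of one-hot
   breed indicators on the standardized genotypes. The number of latent
   components (1..50) is chosen by 10-fold cross-validated classification
   accuracy (assign to the breed with the largest predicted response);
   after a full-data refit, a SNP enters the panel when the absolute value
   of its regression coefficient exceeds ``mean(|coef|) + 3 * SD(|coef|)``
   for at least one breed.

2. *Nearest shrunken centroids (NSC)* — per-class centroids are expressed
   as standardized offsets from the overall centroid,

       d_kj = (xbar_kj - xbar_j) / (m_k * (s_j + s0)),

   with ``s_j`` the pooled within-class SD, ``s0`` the median of the
   ``s_j`` and ``m_k = sqrt(1/n_k - 1/n)``; the offsets are soft-thresholded
   at shrinkage level delta, ``d'_kj = sign(d) * max(|d| - delta, 0)``, and
   delta is chosen from a grid by 10-fold CV accuracy (ties -> largest
   delta, the most parsimonious model). Class posterior probabilities come
   from the penalized distances
   ``delta_k(x) = sum_j (x_j - xbar'_kj)^2 / (s_j + s0)^2 - 2 log pi_k``
   via ``p_k ∝ exp(-delta_k / 2)``.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold

from .assign import AssignmentResult, _argmax_assign

logger = logging.getLogger(__name__)

DEFAULT_DELTA_GRID: tuple[float, ...] = (0.01, 0.05, 0.10, 0.25, 0.50, 1.0)


@dataclasses.dataclass(frozen=True)
class PLSSelection:
    """Outcome of the PLS-DA coefficient-threshold SNP selection."""

    n_components_chosen: int
    coefficients: np.ndarray  # (n_breeds, n_snps)
    breeds: tuple[str, ...]
    snp_ids: tuple[str, ...]
    per_breed_threshold: dict[str, float]
    selected_snps: tuple[str, ...]
    cv_accuracy: float


def _one_hot(y: np.ndarray, breeds: Sequence[str]) -> np.ndarray:
    return np.stack([(y == b).astype(float) for b in breeds], axis=1)


def pls_da_select_snps(
    standardized_genotypes: np.ndarray,
    labels: Sequence[str],
    snp_ids: Sequence[str],
    max_components: int = 50,
    folds: int = 10,
    seed: int = 0,
) -> PLSSelection:
    """Choose a reduced SNP panel from PLS-DA regression coefficients.

    ``standardized_genotypes`` holds the reference animals only (rows
    aligned with ``labels``). Component counts exceeding what the data can
    support are clipped with a warning. Deterministic given ``seed``.
    """
    x = np.asarray(standardized_genotypes, dtype=float)
    y = np.asarray(labels)
    breeds = tuple(sorted(set(y.tolist())))
    if len(breeds) < 2:
        raise ValueError("PLS-DA selection needs at least two breeds")
    n, p = x.shape
    limit = min(n - max(2, n // folds) - 1, p)
    if max_components > limit:
        logger.warning("max_components=%d clipped to %d for %d animals x %d SNP", max_components, limit, n, p)
        max_components = max(1, limit)
    yd = _one_hot(y, breeds)

    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_splits = list(cv.split(x, y))
    best_ncomp, best_acc = 1, -np.inf
    with warnings.catch_warnings():
        # scanning past the useful rank triggers a constant-residual note
        warnings.filterwarnings("ignore", message=".*residual is constant.*")
        for ncomp in range(1, max_components + 1):
            hits = 0
            for train, test in fold_splits:
                model = PLSRegression(n_components=ncomp, scale=False)
                model.fit(x[train], yd[train])
                pred = model.predict(x[test])
                hits += int((pred.argmax(axis=1) == yd[test].argmax(axis=1)).sum())
            acc = hits / n
            if acc > best_acc + 1e-12:  # ties keep the fewest components
                best_ncomp, best_acc = ncomp, acc

    final = PLSRegression(n_components=best_ncomp, scale=False)
    final.fit(x, yd)
    coef = np.asarray(final.coef_)  # (n_breeds, n_snps)
    if coef.shape != (len(breeds), p):  # pragma: no cover - sklearn<1.1 layout
        coef = coef.T

    abs_coef = np.abs(coef)
    thresholds = {
        b: float(abs_coef[k].mean() + 3.0 * abs_coef[k].std(ddof=1)) for k, b in enumerate(breeds)
    }
    exceeds = np.zeros(p, dtype=bool)
    for k, b in enumerate(breeds):
        exceeds |= abs_coef[k] > thresholds[b]
    if not exceeds.any():
        raise ValueError(
            "no SNP coefficient exceeds the mean + 3*SD threshold for any breed; "
            "inputs may be degenerate (e.g. constant coefficient magnitudes)"
        )
    selected = tuple(s for s, keep in zip(snp_ids, exceeds) if keep)
    return PLSSelection(
        n_components_chosen=best_ncomp,
        coefficients=coef,
        breeds=breeds,
        snp_ids=tuple(snp_ids),
        per_breed_threshold=thresholds,
        selected_snps=selected,
        cv_accuracy=float(best_acc),
    )


@dataclasses.dataclass(frozen=True)
class NSCModel:
    """Fitted nearest-shrunken-centroid classifier over a fixed SNP set."""

    breeds: tuple[str, ...]
    snp_ids: tuple[str, ...]
    overall_centroid: np.ndarray  # (p,)
    class_centroids: np.ndarray  # (K, p) raw centroids
    shrunken_centroids: np.ndarray  # (K, p)
    shrunken_offsets: np.ndarray  # (K, p) d'_kj
    pooled_sd: np.ndarray  # (p,) s_j
    s0: float
    delta: float
    priors: np.ndarray  # (K,)
    cv_accuracy: float


def _nsc_statistics(x: np.ndarray, y: np.ndarray, breeds: Sequence[str]):
    n, p = x.shape
    k = len(breeds)
    class_centroids = np.stack([x[y == b].mean(axis=0) for b in breeds])
    overall = x.mean(axis=0)
    within_ss = np.zeros(p)
    n_k = np.array([(y == b).sum() for b in breeds], dtype=float)
    for i, b in enumerate(breeds):
        within_ss += ((x[y == b] - class_centroids[i]) ** 2).sum(axis=0)
    pooled_sd = np.sqrt(within_ss / (n - k))
    s0 = float(np.median(pooled_sd))
    m_k = np.sqrt(1.0 / n_k - 1.0 / n)
    d = (class_centroids - overall) / (m_k[:, None] * (pooled_sd + s0))
    return class_centroids, overall, pooled_sd, s0, m_k, n_k, d


def _fit_nsc_at_delta(
    x: np.ndarray, y: np.ndarray, breeds: Sequence[str], delta: float, cv_accuracy: float, snp_ids: Sequence[str]
) -> NSCModel:
    class_centroids, overall, pooled_sd, s0, m_k, n_k, d = _nsc_statistics(x, y, breeds)
    d_shrunk = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    shrunken = overall + m_k[:, None] * (pooled_sd + s0) * d_shrunk
    return NSCModel(
        breeds=tuple(breeds),
        snp_ids=tuple(snp_ids),
        overall_centroid=overall,
        class_centroids=class_centroids,
        shrunken_centroids=shrunken,
        shrunken_offsets=d_shrunk,
        pooled_sd=pooled_sd,
        s0=s0,
        delta=float(delta),
        priors=n_k / n_k.sum(),
        cv_accuracy=float(cv_accuracy),
    )


def _nsc_discriminants(model: NSCModel, x: np.ndarray) -> np.ndarray:
    scale = (model.pooled_sd + model.s0) ** 2
    dist = ((x[:, None, :] - model.shrunken_centroids[None, :, :]) ** 2 / scale).sum(axis=2)
    return dist - 2.0 * np.log(model.priors)


def train_nsc(
    genotypes: np.ndarray,
    labels: Sequence[str],
    snp_ids: Sequence[str],
    delta_grid: Sequence[float] = DEFAULT_DELTA_GRID,
    folds: int = 10,
    seed: int = 0,
) -> NSCModel:
    """Fit NSC on the selected-SNP genotypes, choosing delta by 10-fold CV.

    Ties in CV accuracy resolve to the *largest* delta (heaviest shrinkage,
    most parsimonious centroids). ``delta_grid`` may contain 0 to disable
    shrinkage entirely, which reduces NSC to nearest (standardized)
    centroid classification.
    """
    if len(delta_grid) == 0:
        raise ValueError("empty delta grid")
    x = np.asarray(genotypes, dtype=float)
    y = np.asarray(labels)
    breeds = tuple(sorted(set(y.tolist())))
    if len(breeds) < 2:
        raise ValueError("NSC needs at least two breeds")
    if min((y == b).sum() for b in breeds) < 2:
        raise ValueError("every breed needs at least two training animals")

    if len(delta_grid) == 1:
        best_delta, best_acc = float(delta_grid[0]), float("nan")
    else:
        folds_eff = min(folds, min(int((y == b).sum()) for b in breeds))
        cv = StratifiedKFold(n_splits=folds_eff, shuffle=True, random_state=seed)
        fold_splits = list(cv.split(x, y))
        best_delta, best_acc = -np.inf, -np.inf
        for delta in delta_grid:
            hits = 0
            for train, test in fold_splits:
                sub = _fit_nsc_at_delta(x[train], y[train], breeds, delta, np.nan, snp_ids)
                pred = np.asarray(sub.breeds)[_nsc_discriminants(sub, x[test]).argmin(axis=1)]
                hits += int((pred == y[test]).sum())
            acc = hits / len(y)
            # ties keep the largest delta (heaviest shrinkage)
            if acc > best_acc + 1e-12 or (abs(acc - best_acc) <= 1e-12 and delta > best_delta):
                best_delta, best_acc = float(delta), float(acc)
    return _fit_nsc_at_delta(x, y, breeds, best_delta, best_acc, snp_ids)


def predict_nsc(
    model: NSCModel, genotypes: np.ndarray, animal_ids: Sequence[str], snp_ids: Sequence[str] | None = None
) -> list[AssignmentResult]:
    """Assign each animal to the class with the highest NSC posterior."""
    x = np.asarray(genotypes, dtype=float)
    if snp_ids is not None and tuple(snp_ids) != model.snp_ids:
        raise ValueError("SNP set does not match the fitted NSC model")
    if x.shape[1] != len(model.snp_ids):
        raise ValueError(f"expected {len(model.snp_ids)} SNPs, got {x.shape[1]}")
    disc = _nsc_discriminants(model, x)
    log_p = -disc / 2.0
    log_p -= log_p.max(axis=1, keepdims=True)
    probs = np.exp(log_p)
    probs /= probs.sum(axis=1, keepdims=True)
    return [
        _argmax_assign(a, "PLS_NSC", model.breeds, probs[i]) for i, a in enumerate(animal_ids)
    ]
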