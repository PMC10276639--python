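"""VanRaden method-1 genomic relationship matrix and relatedness summaries.

Workflow: allele frequencies are computed per breed on the reference set
and averaged *unweighted* across breeds — pooling over animals instead
would let the largest breed dominate the centring when reference sizes are
imbalanced. The GRM over reference + validation animals is then

    Z = M - 2P,      G = Z Z' / (2 * sum_j p_j (1 - p_j))

with M the dosage matrix and P the averaged frequencies broadcast over
rows. Because both centring and scaling depend only on the reference set,
a validation animal's relationships to the reference animals — and hence
its assignment — do not change when other validation animals are added to
or removed from the matrix.

Each animal is summarized by its mean and standard deviation of
relatedness to every breed's reference animals (2K features for K breeds;
the "six variables" when K = 3). Self-relationships are excluded whenever
the summarized animal is itself part of a breed's reference set.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import GenotypePanel


@dataclasses.dataclass(frozen=True)
class AlleleFrequencySet:
    """Per-breed and across-breed-averaged reference allele frequencies."""

    per_breed: dict[str, np.ndarray]
    averaged: np.ndarray
    source_ids: tuple[str, ...]
    snp_ids: tuple[str, ...]


@dataclasses.dataclass(frozen=True)
class GenomicRelationshipMatrix:
    """Symmetric relationship matrix plus the frequencies that scaled it."""

    ids: tuple[str, ...]
    values: np.ndarray
    frequencies_used: AlleleFrequencySet
    denominator: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "_index", {a: i for i, a in enumerate(self.ids)})

    def loc(self, animal_id: str) -> int:
        return self._index[animal_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def write_tsv(self, path) -> None:
        """Square tab-separated matrix with animal IDs as first row/column."""
        self.to_frame().to_csv(path, sep="\t")


@dataclasses.dataclass(frozen=True)
class RelatednessFeatures:
    """Mean/SD of relationships of each target animal to each breed's reference.

    ``means`` and ``sds`` are (n_targets, n_breeds) arrays over ``breeds``
    in sorted order; SDs use the sample (n-1) convention.
    """

    animal_ids: tuple[str, ...]
    breeds: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    self_excluded: bool = True

    def feature_matrix(self) -> np.ndarray:
        """(n_targets, 2K) matrix: all breed means then all breed SDs."""
        return np.hstack([self.means, self.sds])

    def feature_names(self) -> list[str]:
        return [f"mean_{b}" for b in self.breeds] + [f"sd_{b}" for b in self.breeds]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.feature_matrix(), index=list(self.animal_ids), columns=self.feature_names()
        )

    def write_tsv(self, path) -> None:
        frame = self.to_frame()
        frame.index.name = "animal_id"
        frame.to_csv(path, sep="\t")


def compute_allele_frequencies(
    panel: GenotypePanel, reference_ids: Iterable[str]
) -> AlleleFrequencySet:
    """Per-breed reference allele frequencies and their unweighted average.

    Per breed and SNP, AF = (sum of dosages) / (2 x non-missing count).
    The averaged frequency is the plain mean over breeds — NOT the pooled
    frequency over animals — so every breed contributes equally no matter
    its reference size.
    """
    ref = list(reference_ids)
    if not ref:
        raise ValueError("empty reference set")
    unlabelled = [a for a in ref if a not in panel.breed_labels]
    if unlabelled:
        raise ValueError(f"reference animals without breed labels: {unlabelled[:5]}")
    per_breed: dict[str, np.ndarray] = {}
    breeds = sorted({panel.breed_labels[a] for a in ref})
    for breed in breeds:
        members = [a for a in ref if panel.breed_labels[a] == breed]
        block = panel.dosages[panel.rows(members)]
        n_called = np.isfinite(block).sum(axis=0)
        if np.any(n_called == 0):
            snp = panel.snp_ids[int(np.flatnonzero(n_called == 0)[0])]
            raise ValueError(f"breed {breed!r} has no non-missing calls at SNP {snp!r}")
        per_breed[breed] = np.nansum(block, axis=0) / (2.0 * n_called)
    averaged = np.mean(np.stack([per_breed[b] for b in breeds]), axis=0)
    return AlleleFrequencySet(
        per_breed=per_breed,
        averaged=averaged,
        source_ids=tuple(ref),
        snp_ids=tuple(panel.snp_ids),
    )


def build_grm(
    panel: GenotypePanel,
    ids: Iterable[str],
    frequencies: AlleleFrequencySet | np.ndarray,
) -> GenomicRelationshipMatrix:
    """VanRaden method-1 GRM over ``ids`` with the given centring frequencies.

    ``frequencies`` is an :class:`AlleleFrequencySet` (its averaged
    frequencies are used) or a bare per-SNP frequency vector. Missing
    dosages are imputed with twice the centring frequency, i.e. they are
    relationship-neutral (zero after centring).
    """
    ids = tuple(ids)
    if isinstance(frequencies, AlleleFrequencySet):
        if tuple(panel.snp_ids) != frequencies.snp_ids:
            raise ValueError("frequency set was computed for different SNPs")
        p = frequencies.averaged
        freq_set = frequencies
    else:
        p = np.asarray(frequencies, dtype=float)
        if p.shape != (panel.n_snps,):
            raise ValueError(f"expected {panel.n_snps} frequencies, got shape {p.shape}")
        freq_set = AlleleFrequencySet(
            per_breed={}, averaged=p, source_ids=(), snp_ids=tuple(panel.snp_ids)
        )
    denominator = float(2.0 * np.sum(p * (1.0 - p)))
    if denominator <= 0:
        raise ValueError("all SNPs fixed in the frequency set; GRM denominator is zero")
    m = panel.dosages[panel.rows(ids)]
    m = np.where(np.isfinite(m), m, 2.0 * p)  # missing -> relationship-neutral
    z = m - 2.0 * p
    g = (z @ z.T) / denominator
    return GenomicRelationshipMatrix(ids=ids, values=g, frequencies_used=freq_set, denominator=denominator)


def relatedness_summaries(
    grm: GenomicRelationshipMatrix,
    reference_labels: Mapping[str, str],
    target_ids: Iterable[str],
) -> RelatednessFeatures:
    """Mean and SD of each target's relationships to each breed's reference.

    For target ``t`` and breed ``b`` the statistics run over
    ``{G(t, r) : r reference animal of b, r != t}`` — the self-relationship
    ``G(t, t)`` is excluded whenever ``t`` is itself a reference animal of
    ``b``, for reference targets and validation targets alike. SDs use the
    sample (n-1) convention; a target left with a single usable
    relationship to a breed gets a defined mean but a NaN SD, and zero
    usable relationships is an error.
    """
    targets = tuple(target_ids)
    breeds = tuple(sorted(set(reference_labels.values())))
    by_breed = {
        b: np.array([grm.loc(a) for a in grm.ids if reference_labels.get(a) == b], dtype=int)
        for b in breeds
    }
    for b, idx in by_breed.items():
        missing = [a for a, lbl in reference_labels.items() if lbl == b and a not in grm._index]
        if missing:
            raise ValueError(f"reference animals of breed {b!r} not in GRM: {missing[:5]}")
        if idx.size < 2:
            raise ValueError(f"breed {b!r} has {idx.size} reference animal(s) in the GRM; need >= 2")
    means = np.empty((len(targets), len(breeds)))
    sds = np.empty_like(means)
    for i, t in enumerate(targets):
        ti = grm.loc(t)
        for k, b in enumerate(breeds):
            idx = by_breed[b]
            rels = grm.values[ti, idx[idx != ti]]
            if rels.size == 0:
                raise ValueError(f"target {t!r} has no usable relationships to breed {b!r}")
            means[i, k] = rels.mean()
            sds[i, k] = rels.std(ddof=1) if rels.size >= 2 else np.nan
    return RelatednessFeatures(animal_ids=targets, breeds=breeds, means=means, sds=sds)
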