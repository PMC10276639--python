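"""Assignment metrics and inference over repeated reference/validation splits.

Metrics per repetition: global accuracy (percent correct over all
validation animals), per-breed sensitivity (percent correct within one
breed) and per-breed specificity (percent of other-breed animals NOT
assigned to that breed).

Because the repeated splits reuse the same animals, per-repetition metric
differences between two methods are not independent and the naive paired
t-test is anti-conservative. The variance-corrected resampled paired
t-test inflates the variance term instead:

    t = xbar / sqrt((1/n + n2/n1) * sigma^2),   df = n - 1

with n the number of repetitions, xbar and sigma^2 the sample mean and
variance of the differences, n1 the calibration (reference) count and n2
the validation count relevant to the metric. Since |t_corrected| <=
|t_naive| always, the correction can only lose power, never inflate the
type-I error.

Six pairwise method comparisons are Bonferroni-guarded with the banded
thresholds 0.0083 (0.05/6), 0.0017 (0.01/6), 0.00017 (0.001/6) and
0.000017 (0.0001/6). Percentile bootstrap CIs of the mean metric
complement the tests where the correction is under-powered.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

BONFERRONI_BANDS: tuple[tuple[float, str], ...] = (
    (0.000017, "extremely significant"),
    (0.00017, "highly significant"),
    (0.0017, "very significant"),
    (0.0083, "significant"),
)


@dataclasses.dataclass(frozen=True)
class AssignmentMetrics:
    """Confusion table and the derived percentage metrics for one repetition."""

    breeds: tuple[str, ...]
    confusion: np.ndarray  # rows = true breed, columns = predicted
    global_accuracy: float
    per_breed_sensitivity: dict[str, float]
    per_breed_specificity: dict[str, float | None]  # None when undefined
    n_validation: int


def confusion_metrics(
    predictions: Mapping[str, str], truth: Mapping[str, str]
) -> AssignmentMetrics:
    """Score predicted against true breeds.

    Specificity of a breed with no other-breed animals in the truth set is
    undefined and reported as ``None``, never coerced to a number.
    """
    if not truth:
        raise ValueError("empty truth mapping")
    extra = set(predictions) - set(truth)
    if extra:
        raise ValueError(f"predictions for animals without truth: {sorted(extra)[:5]}")
    missing = set(truth) - set(predictions)
    if missing:
        raise ValueError(f"animals without predictions: {sorted(missing)[:5]}")
    breeds = tuple(sorted(set(truth.values()) | set(predictions.values())))
    index = {b: i for i, b in enumerate(breeds)}
    confusion = np.zeros((len(breeds), len(breeds)), dtype=int)
    for animal, true_breed in truth.items():
        confusion[index[true_breed], index[predictions[animal]]] += 1
    total = confusion.sum()
    sensitivity: dict[str, float] = {}
    specificity: dict[str, float | None] = {}
    for b, i in index.items():
        row = confusion[i].sum()
        sensitivity[b] = 100.0 * confusion[i, i] / row if row else float("nan")
        others = total - row
        if others == 0:
            specificity[b] = None
        else:
            assigned_b = confusion[:, i].sum() - confusion[i, i]
            specificity[b] = 100.0 * (others - assigned_b) / others
    return AssignmentMetrics(
        breeds=breeds,
        confusion=confusion,
        global_accuracy=100.0 * np.trace(confusion) / total,
        per_breed_sensitivity=sensitivity,
        per_breed_specificity=specificity,
        n_validation=int(total),
    )


@dataclasses.dataclass(frozen=True)
class CorrectedTTestResult:
    """Variance-corrected resampled paired t-test outcome."""

    n: int
    mean_diff: float
    variance: float
    n1: int
    n2: int
    t_value: float
    p_value: float
    df: int


def corrected_paired_ttest(
    differences: Sequence[float], n1: int, n2: int
) -> CorrectedTTestResult:
    """Corrected paired t-test on per-repetition metric differences.

    Degenerate zero-variance inputs: a nonzero mean yields an infinite-t
    sentinel with p = 0; an all-zero difference vector yields t = 0, p = 1.
    """
    x = np.asarray(differences, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least two repetitions")
    if n1 < 1 or n2 < 1:
        raise ValueError("n1 and n2 must be >= 1")
    mean = float(x.mean())
    var = float(x.var(ddof=1))
    df = n - 1
    if var == 0:
        t = 0.0 if mean == 0 else math.copysign(math.inf, mean)
        p = 1.0 if mean == 0 else 0.0
    else:
        t = mean / math.sqrt((1.0 / n + n2 / n1) * var)
        p = 2.0 * sps.t.sf(abs(t), df)
    return CorrectedTTestResult(
        n=n, mean_diff=mean, variance=var, n1=n1, n2=n2, t_value=t, p_value=p, df=df
    )


def naive_paired_ttest_statistic(differences: Sequence[float]) -> float:
    """Ordinary one-sample t statistic of the differences (for comparison)."""
    x = np.asarray(differences, dtype=float)
    var = x.var(ddof=1)
    if var == 0:
        return 0.0 if x.mean() == 0 else math.copysign(math.inf, x.mean())
    return float(x.mean() / math.sqrt(var / x.size))


def bonferroni_band(p: float) -> str:
    """Significance label of a p-value under the six-comparison Bonferroni bands."""
    if not 0 <= p <= 1:
        raise ValueError(f"p must be in [0, 1], got {p}")
    label = "not significant"
    for threshold, name in sorted(BONFERRONI_BANDS, reverse=True):
        if p < threshold:
            label = name
    return label


def bootstrap_percentile_ci(
    values: Sequence[float], n_boot: int = 10000, seed: int = 0
) -> tuple[float, float]:
    """95% percentile bootstrap CI (P2.5, P97.5) of the mean of ``values``."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    means = rng.choice(x, size=(n_boot, x.size), replace=True).mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(lo), float(hi)
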