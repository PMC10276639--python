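"""Genotype panel container, file formats, pre-model filters and splits.

The central data structure is :class:`GenotypePanel`: an animals x SNP
matrix of allele dosages (0/1/2, ``NaN`` for missing calls) together with
animal identifiers, SNP identifiers and an optional breed label per animal.
Two on-disk dialects are supported:

* *tabular* — tab-separated, first column the animal ID, one column per SNP
  with a header row of SNP IDs; missing calls written as ``NA``;
* *plink_raw* — the whitespace-separated PLINK ``--recode A`` export with
  the six leading ``FID IID PAT MAT SEX PHENOTYPE`` columns and SNP columns
  suffixed by the counted allele (``snp1_A``).

This module also houses the two pre-model transformations applied before
the PLS-DA baseline (the 0.95 major-genotypic-frequency filter and
reference-anchored standardization) and the repeated reference/validation
split designs RS1 (reference = the half not drawn for validation) and RS2
(reference capped at a fixed count per breed).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

MISSING_TOKEN = "NA"
_VALID_DOSAGES = (0.0, 1.0, 2.0)


class GenotypeParseError(ValueError):
    """A genotype file contains a token outside {0, 1, 2, NA}."""


class PanelValidationError(ValueError):
    """A panel violates a structural invariant (duplicate IDs, bad shape)."""


class SplitError(ValueError):
    """A reference/validation split cannot be formed."""


@dataclasses.dataclass
class GenotypePanel:
    """Animals x SNP dosage matrix with IDs and optional breed labels.

    Parameters
    ----------
    animal_ids
        Unique animal identifiers, one per matrix row.
    snp_ids
        Unique SNP identifiers, one per matrix column.
    dosages
        Float matrix with entries in {0, 1, 2} or ``NaN`` for missing.
    breed_labels
        Mapping animal ID -> breed name. May omit animals whose breed is
        unknown (the to-be-assigned animals).
    """

    animal_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray
    breed_labels: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.animal_ids = [str(a) for a in self.animal_ids]
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.dosages = np.asarray(self.dosages, dtype=float)
        if len(set(self.animal_ids)) != len(self.animal_ids):
            raise PanelValidationError("duplicate animal IDs")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise PanelValidationError("duplicate SNP IDs")
        if self.dosages.shape != (len(self.animal_ids), len(self.snp_ids)):
            raise PanelValidationError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.animal_ids)} animals x {len(self.snp_ids)} SNP"
            )
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and not np.isin(finite, _VALID_DOSAGES).all():
            bad = finite[~np.isin(finite, _VALID_DOSAGES)][0]
            raise PanelValidationError(f"dosage value {bad!r} outside {{0,1,2}}")
        unknown = set(self.breed_labels) - set(self.animal_ids)
        if unknown:
            raise PanelValidationError(f"breed labels for unknown animals: {sorted(unknown)[:5]}")
        self._row_index = {a: i for i, a in enumerate(self.animal_ids)}

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def rows(self, animal_ids: Iterable[str]) -> np.ndarray:
        """Row indices of the given animals, in the given order."""
        try:
            return np.array([self._row_index[a] for a in animal_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"unknown animal ID {exc.args[0]!r}") from None

    def breeds(self) -> list[str]:
        """Sorted list of distinct breed names among labelled animals."""
        return sorted(set(self.breed_labels.values()))

    def animals_of_breed(self, breed: str) -> list[str]:
        """Labelled animals of one breed, in panel row order."""
        return [a for a in self.animal_ids if self.breed_labels.get(a) == breed]

    def subset(self, animal_ids: Iterable[str]) -> "GenotypePanel":
        """New panel restricted to the given animals (order preserved)."""
        ids = list(animal_ids)
        idx = self.rows(ids)
        return GenotypePanel(
            animal_ids=ids,
            snp_ids=list(self.snp_ids),
            dosages=self.dosages[idx].copy(),
            breed_labels={a: self.breed_labels[a] for a in ids if a in self.breed_labels},
        )


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------

def _coerce_dosages(frame: pd.DataFrame, path: str) -> np.ndarray:
    values = frame.to_numpy(dtype=object)
    out = np.empty(values.shape, dtype=float)
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            tok = values[i, j]
            if tok is None or (isinstance(tok, float) and np.isnan(tok)) or str(tok) == MISSING_TOKEN:
                out[i, j] = np.nan
                continue
            try:
                val = float(tok)
            except (TypeError, ValueError):
                val = -1.0
            if val not in _VALID_DOSAGES:
                raise GenotypeParseError(
                    f"{path}: invalid dosage token {tok!r} at animal row {i + 1}, "
                    f"SNP column {frame.columns[j]!r}"
                )
            out[i, j] = val
    return out


def read_genotype_panel(
    path: str | Path,
    format: Literal["tabular", "plink_raw"] = "tabular",
    breed_labels: Mapping[str, str] | str | Path | None = None,
) -> GenotypePanel:
    """Read a genotype panel from disk.

    ``breed_labels`` may be a mapping, a path to a two-column TSV
    (animal ID, breed), or ``None``.
    """
    path = Path(path)
    if format == "tabular":
        frame = pd.read_csv(path, sep="\t", dtype=str, index_col=0, keep_default_na=False)
        animal_ids = [str(a) for a in frame.index]
        snp_ids = [str(c) for c in frame.columns]
    elif format == "plink_raw":
        frame = pd.read_csv(path, sep=r"\s+", dtype=str, keep_default_na=False)
        lead = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        missing_cols = [c for c in lead if c not in frame.columns]
        if missing_cols:
            raise GenotypeParseError(f"{path}: not a PLINK .raw file (missing {missing_cols})")
        animal_ids = [str(a) for a in frame["IID"]]
        snp_cols = [c for c in frame.columns if c not in lead]
        # strip the counted-allele suffix PLINK appends ("snp1_A" -> "snp1")
        snp_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
        frame = frame[snp_cols]
        frame.index = animal_ids
    else:
        raise ValueError(f"unknown format {format!r}")

    dosages = _coerce_dosages(frame, str(path))
    labels: dict[str, str] = {}
    if breed_labels is not None:
        if isinstance(breed_labels, (str, Path)):
            labels = read_breed_labels(breed_labels)
        else:
            labels = dict(breed_labels)
        labels = {a: b for a, b in labels.items() if a in set(animal_ids)}
    return GenotypePanel(animal_ids, snp_ids, dosages, labels)


def write_genotype_panel(
    panel: GenotypePanel,
    path: str | Path,
    format: Literal["tabular", "plink_raw"] = "tabular",
) -> None:
    """Write a panel (dosages as integers, NA missing) in either dialect.

    The plink_raw dialect writes the six PLINK lead columns with FID equal
    to the breed label (or 0) and a ``_N`` counted-allele suffix on SNP
    names, which :func:`read_genotype_panel` strips again.
    """
    tokens = np.where(
        np.isfinite(panel.dosages),
        panel.dosages.astype(object),
        None,
    )
    frame = pd.DataFrame(tokens, index=panel.animal_ids, columns=panel.snp_ids)
    frame = frame.map(lambda v: MISSING_TOKEN if v is None else str(int(v)))
    if format == "tabular":
        frame.index.name = "animal_id"
        frame.to_csv(path, sep="\t")
    elif format == "plink_raw":
        frame.columns = [f"{s}_N" for s in panel.snp_ids]
        frame.insert(0, "FID", [panel.breed_labels.get(a, "0") for a in panel.animal_ids])
        frame.insert(1, "IID", panel.animal_ids)
        for i, col in enumerate(("PAT", "MAT", "SEX", "PHENOTYPE")):
            frame.insert(2 + i, col, "0" if col != "PHENOTYPE" else "-9")
        frame.to_csv(path, sep=" ", index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_breed_labels(path: str | Path) -> dict[str, str]:
    frame = pd.read_csv(path, sep="\t", dtype=str, header=None, names=["animal_id", "breed"])
    if frame["animal_id"].duplicated().any():
        dup = frame.loc[frame["animal_id"].duplicated(), "animal_id"].iloc[0]
        raise PanelValidationError(f"duplicate animal ID {dup!r} in breed-label file")
    return dict(zip(frame["animal_id"], frame["breed"]))


def write_breed_labels(labels: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(sorted(labels.items())).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Pre-model filters and standardization
# ---------------------------------------------------------------------------

def major_genotype_frequency_filter(
    panel: GenotypePanel,
    reference_ids: Iterable[str],
    threshold: float = 0.95,
) -> list[str]:
    """SNPs whose most common genotype class is rarer than ``threshold``.

    The frequency of the modal genotype class (0, 1 or 2) is computed over
    the non-missing calls of the reference animals only; a SNP is retained
    iff that frequency is strictly below ``threshold``. This removes
    (almost) monomorphic SNPs ahead of PLS-DA, which cannot handle
    near-constant predictors.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    ref = list(reference_ids)
    if not ref:
        raise ValueError("empty reference set")
    block = panel.dosages[panel.rows(ref)]
    counts = np.stack([(block == g).sum(axis=0) for g in (0.0, 1.0, 2.0)])
    n_called = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        major = np.where(n_called > 0, counts.max(axis=0) / n_called, 1.0)
    return [s for s, f in zip(panel.snp_ids, major) if f < threshold]


def standardize_genotypes(
    panel: GenotypePanel,
    reference_ids: Iterable[str],
    snp_ids: Iterable[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center and scale dosages by reference-set per-SNP mean and SD.

    Centers and scales are computed from the reference animals only
    (population-SD convention, i.e. divide by n) and applied to every
    animal in the panel, so validation animals are expressed on the
    reference scale. Missing calls are mean-imputed (they standardize to
    zero). Returns ``(standardized matrix over all panel animals, centers,
    scales)`` with columns restricted to ``snp_ids`` when given.

    Raises
    ------
    ValueError
        If any SNP is constant over the reference set (zero SD); run
        :func:`major_genotype_frequency_filter` first.
    """
    ref = list(reference_ids)
    if not ref:
        raise ValueError("empty reference set")
    if snp_ids is None:
        cols = np.arange(panel.n_snps)
        names = panel.snp_ids
    else:
        names = list(snp_ids)
        pos = {s: j for j, s in enumerate(panel.snp_ids)}
        cols = np.array([pos[s] for s in names], dtype=int)
    block = panel.dosages[np.ix_(panel.rows(ref), cols)]
    centers = np.nanmean(block, axis=0)
    scales = np.nanstd(block, axis=0)  # population SD (ddof=0)
    zero = np.flatnonzero(scales == 0)
    if zero.size:
        raise ValueError(
            f"zero reference SD at SNP {names[zero[0]]!r}; "
            "apply the major-genotype-frequency filter first"
        )
    full = panel.dosages[:, cols]
    full = np.where(np.isfinite(full), full, centers)  # mean-impute -> standardizes to 0
    return (full - centers) / scales, centers, scales


# ---------------------------------------------------------------------------
# Reference / validation splits
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SplitPlan:
    """One reference/validation partition of a labelled panel."""

    validation_ids: tuple[str, ...]
    reference_ids: tuple[str, ...]
    mode: Literal["RS1", "RS2"]
    per_breed_cap: int | None
    seed: int

    def __post_init__(self) -> None:
        if set(self.validation_ids) & set(self.reference_ids):
            raise SplitError("validation and reference sets overlap")


def make_split(
    panel: GenotypePanel,
    mode: Literal["RS1", "RS2"],
    seed: int,
    per_breed_cap: int = 50,
) -> SplitPlan:
    """Draw one repetition's reference/validation split.

    Per breed, floor(n/2) animals are drawn without replacement into the
    validation set. Under RS1 the reference set is everything that remains;
    under RS2 it is ``per_breed_cap`` animals per breed sampled from the
    remainder (all of them when fewer are available). Deterministic given
    ``seed``; the RS2 reference of a seed is always a subset of the RS1
    reference of the same seed.
    """
    if mode not in ("RS1", "RS2"):
        raise ValueError(f"mode must be RS1 or RS2, got {mode!r}")
    unlabelled = [a for a in panel.animal_ids if a not in panel.breed_labels]
    if unlabelled:
        raise SplitError(f"unlabelled animals cannot be split: {unlabelled[:5]}")
    validation: list[str] = []
    reference: list[str] = []
    # one substream per breed so the validation draw is identical between
    # RS1 and RS2 at the same seed, and the RS2 reference nests in RS1's
    for k, breed in enumerate(panel.breeds()):
        members = panel.animals_of_breed(breed)
        if len(members) < 2:
            raise SplitError(f"breed {breed!r} has {len(members)} animal(s); need >= 2")
        perm = np.random.default_rng([seed, k]).permutation(len(members))
        n_val = len(members) // 2
        val = [members[i] for i in perm[:n_val]]
        rest = [members[i] for i in perm[n_val:]]
        if mode == "RS2" and len(rest) > per_breed_cap:
            keep = np.random.default_rng([seed, k, 1]).choice(
                len(rest), size=per_breed_cap, replace=False
            )
            rest = [rest[i] for i in sorted(keep)]
        validation.extend(val)
        reference.extend(rest)
    return SplitPlan(
        validation_ids=tuple(validation),
        reference_ids=tuple(reference),
        mode=mode,
        per_breed_cap=per_breed_cap if mode == "RS2" else None,
        seed=seed,
    )
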