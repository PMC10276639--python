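"""Multi-breed SNP genotype simulation under a Balding-Nichols drift model.

The real populations the assignment methods target are closely related
sister breeds drifted from a common ancestral gene pool. The generator
mirrors that structure with the standard Balding-Nichols parameterization:
each breed's allele frequency at a SNP is drawn from a Beta distribution
with mean equal to the ancestral frequency ``p`` and variance
``fst * p * (1 - p)``, and genotypes are then Binomial(2, breed frequency)
within each breed. ``fst`` is the single difficulty knob — 0 makes breeds
indistinguishable, larger values push them apart.

Deliberately NOT modelled: linkage disequilibrium, pedigree/family
structure within breeds, mutation, and admixture. Relationship variance in
simulated panels therefore arises from drift alone.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import GenotypePanel


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated multi-breed panel.

    ``n_per_breed`` may be a single integer (same size for every breed) or
    one integer per breed. ``fst`` in [0, 1) controls drift; the ancestral
    allele frequency of each SNP is drawn uniformly on
    ``ancestral_af_range`` so no SNP is near-monomorphic ancestrally
    (breeds may still drift to fixation).
    """

    n_breeds: int
    n_per_breed: int | tuple[int, ...]
    n_snps: int
    fst: float
    ancestral_af_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_breeds < 1 or self.n_snps < 1:
            raise ValueError("n_breeds and n_snps must be >= 1")
        if not 0 <= self.fst < 1:
            raise ValueError(f"fst must be in [0, 1), got {self.fst}")
        lo, hi = self.ancestral_af_range
        if not (0 < lo <= hi < 1):
            raise ValueError(f"ancestral_af_range must lie within (0, 1), got {self.ancestral_af_range}")
        sizes = self.breed_sizes
        if len(sizes) != self.n_breeds or any(n < 1 for n in sizes):
            raise ValueError("need one positive size per breed")

    @property
    def breed_sizes(self) -> tuple[int, ...]:
        if isinstance(self.n_per_breed, int):
            return (self.n_per_breed,) * self.n_breeds
        return tuple(self.n_per_breed)

    @property
    def breed_names(self) -> tuple[str, ...]:
        return tuple(f"breed{k + 1}" for k in range(self.n_breeds))


@dataclasses.dataclass(frozen=True)
class SimulatedPopulation:
    """A simulated panel plus the true frequencies that generated it."""

    panel: GenotypePanel
    ancestral_af: np.ndarray  # (n_snps,)
    breed_af_true: np.ndarray  # (n_breeds, n_snps)
    config: SimulationConfig


def draw_breed_frequencies(
    ancestral_af: np.ndarray,
    fst: float,
    n_breeds: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-breed allele frequencies drifted from the ancestral pool.

    For ``fst > 0`` each breed/SNP frequency is Beta(a, b) with
    ``a = p (1 - fst) / fst`` and ``b = (1 - p)(1 - fst) / fst``, which has
    mean ``p`` and variance ``fst * p * (1 - p)``. ``fst = 0`` copies the
    ancestral frequencies exactly (the Beta parameters diverge).

    Returns an ``(n_breeds, n_snps)`` array.
    """
    p = np.asarray(ancestral_af, dtype=float)
    if not 0 <= fst < 1:
        raise ValueError(f"fst must be in [0, 1), got {fst}")
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("ancestral frequencies must be strictly inside (0, 1)")
    if fst == 0:
        return np.tile(p, (n_breeds, 1))
    scale = (1 - fst) / fst
    return rng.beta(p * scale, (1 - p) * scale, size=(n_breeds, p.size))


def simulate_genotypes(config: SimulationConfig) -> SimulatedPopulation:
    """Simulate a labelled genotype panel under ``config``.

    Genotypes are Binomial(2, breed frequency), independent across animals
    and SNPs; bit-identical given the same config and seed.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.ancestral_af_range
    ancestral = rng.uniform(lo, hi, size=config.n_snps)
    breed_af = draw_breed_frequencies(ancestral, config.fst, config.n_breeds, rng)

    sizes = config.breed_sizes
    names = config.breed_names
    dosages = np.vstack(
        [rng.binomial(2, breed_af[k], size=(sizes[k], config.n_snps)) for k in range(config.n_breeds)]
    ).astype(float)
    animal_ids: list[str] = []
    labels: dict[str, str] = {}
    for k, (name, size) in enumerate(zip(names, sizes)):
        for i in range(size):
            aid = f"{name}_a{i + 1:04d}"
            animal_ids.append(aid)
            labels[aid] = name
    panel = GenotypePanel(
        animal_ids=animal_ids,
        snp_ids=[f"snp{j + 1}" for j in range(config.n_snps)],
        dosages=dosages,
        breed_labels=labels,
    )
    return SimulatedPopulation(panel=panel, ancestral_af=ancestral, breed_af_true=breed_af, config=config)


def hudson_fst(panel: GenotypePanel, breed_a: str, breed_b: str) -> float:
    """Hudson FST estimate between two breeds, ratio-of-averages form.

    Used to validate that simulated panels carry the configured level of
    differentiation. Per SNP the numerator is
    ``(p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)`` and the denominator
    ``p1(1-p2) + p2(1-p1)``, with ``n`` the number of sampled allele copies;
    sums are taken over SNPs before the ratio. Can be slightly negative for
    undifferentiated breeds.
    """
    freqs = []
    ns = []
    for breed in (breed_a, breed_b):
        members = panel.animals_of_breed(breed)
        if len(members) < 2:
            raise KeyError(f"breed {breed!r} absent or has fewer than 2 animals")
        block = panel.dosages[panel.rows(members)]
        n_alleles = 2 * np.isfinite(block).sum(axis=0)
        freqs.append(np.nansum(block, axis=0) / n_alleles)
        ns.append(n_alleles)
    p1, p2 = freqs
    n1, n2 = ns
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    keep = den > 0
    return float(num[keep].sum() / den[keep].sum())
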