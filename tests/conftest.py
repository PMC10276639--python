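import numpy as np
import pytest

from grmclassify import (
    GenotypePanel,
    SimulationConfig,
    build_grm,
    compute_allele_frequencies,
    make_split,
    relatedness_summaries,
    simulate_genotypes,
)


@pytest.fixture(scope="session")
def three_breed_population():
    """Moderately drifted 3-breed panel shared across tests."""
    config = SimulationConfig(n_breeds=3, n_per_breed=100, n_snps=800, fst=0.05, seed=11)
    return simulate_genotypes(config)


@pytest.fixture(scope="session")
def three_breed_panel(three_breed_population):
    return three_breed_population.panel


@pytest.fixture
def tiny_panel():
    """Hand-sized 4-animal, 3-SNP labelled panel."""
    return GenotypePanel(
        animal_ids=["a1", "a2", "b1", "b2"],
        snp_ids=["s1", "s2", "s3"],
        dosages=np.array(
            [[0, 1, 2], [1, 1, 2], [2, 0, 0], [2, 1, 0]], dtype=float
        ),
        breed_labels={"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
    )


@pytest.fixture(scope="session")
def split_features(three_breed_panel):
    """One RS1 split with its GRM-derived features, shared across tests."""
    panel = three_breed_panel
    plan = make_split(panel, "RS1", seed=5)
    ref, val = list(plan.reference_ids), list(plan.validation_ids)
    freqs = compute_allele_frequencies(panel, ref)
    grm = build_grm(panel, ref + val, freqs)
    ref_labels = {a: panel.breed_labels[a] for a in ref}
    return {
        "panel": panel,
        "plan": plan,
        "grm": grm,
        "ref_labels": ref_labels,
        "ref_features": relatedness_summaries(grm, ref_labels, ref),
        "val_features": relatedness_summaries(grm, ref_labels, val),
        "truth": {a: panel.breed_labels[a] for a in val},
    }
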