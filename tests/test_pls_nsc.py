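"""PLS-DA SNP selection and nearest-shrunken-centroid classification."""

import numpy as np
import pytest

from grmclassify import (
    SimulationConfig,
    major_genotype_frequency_filter,
    pls_da_select_snps,
    predict_nsc,
    simulate_genotypes,
    standardize_genotypes,
    train_nsc,
)
from grmclassify.pls_nsc import _fit_nsc_at_delta, _nsc_statistics


@pytest.fixture(scope="module")
def spiked_panel():
    """2 breeds, 2,000 weakly drifted background SNPs + 20 strongly drifted ones."""
    background = simulate_genotypes(
        SimulationConfig(n_breeds=2, n_per_breed=60, n_snps=2000, fst=0.01, seed=30)
    )
    spikes = simulate_genotypes(
        SimulationConfig(n_breeds=2, n_per_breed=60, n_snps=20, fst=0.4, seed=31)
    )
    dosages = np.hstack([background.panel.dosages, spikes.panel.dosages])
    snp_ids = [f"bg{j}" for j in range(2000)] + [f"spike{j}" for j in range(20)]
    from grmclassify import GenotypePanel

    panel = GenotypePanel(
        animal_ids=background.panel.animal_ids,
        snp_ids=snp_ids,
        dosages=dosages,
        breed_labels=background.panel.breed_labels,
    )
    return panel


class TestPlsDaSelection:
    def test_spiked_snps_enriched_far_beyond_chance(self, spiked_panel):
        panel = spiked_panel
        ref = panel.animal_ids
        kept = major_genotype_frequency_filter(panel, ref)
        std, _, _ = standardize_genotypes(panel, ref, snp_ids=kept)
        labels = [panel.breed_labels[a] for a in ref]
        sel = pls_da_select_snps(std, labels, kept, max_components=5, seed=0)
        n_spiked_selected = sum(s.startswith("spike") for s in sel.selected_snps)
        n_spiked_total = sum(s.startswith("spike") for s in kept)
        # chance overlap if selection ignored SNP identity
        expected = len(sel.selected_snps) * n_spiked_total / len(kept)
        assert n_spiked_selected > 10 * expected
        assert len(sel.selected_snps) < len(kept) / 4  # real dimensionality cut

    def test_deterministic_given_seed(self, spiked_panel):
        panel = spiked_panel
        kept = major_genotype_frequency_filter(panel, panel.animal_ids)
        std, _, _ = standardize_genotypes(panel, panel.animal_ids, snp_ids=kept)
        labels = [panel.breed_labels[a] for a in panel.animal_ids]
        a = pls_da_select_snps(std, labels, kept, max_components=3, seed=7)
        b = pls_da_select_snps(std, labels, kept, max_components=3, seed=7)
        assert a.n_components_chosen == b.n_components_chosen
        assert a.selected_snps == b.selected_snps

    def test_component_cap_clipped_with_warning(self, caplog):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(30, 40))
        x[:15, :2] += 6.0  # two strongly discriminative SNPs among noise
        labels = ["A"] * 15 + ["B"] * 15
        with caplog.at_level("WARNING"):
            sel = pls_da_select_snps(x, labels, [f"s{j}" for j in range(40)],
                                     max_components=50, seed=0)
        assert "clipped" in caplog.text
        assert 1 <= sel.n_components_chosen <= 30
        assert set(sel.selected_snps) == {"s0", "s1"}

    def test_single_breed_rejected(self):
        with pytest.raises(ValueError):
            pls_da_select_snps(np.zeros((10, 4)), ["A"] * 10, list("abcd"), seed=0)

    def test_degenerate_equal_coefficients_rejected(self, monkeypatch):
        # if every |coefficient| is identical the mean + 3*SD threshold
        # excludes everything — surfaced as an error, not an empty panel
        import grmclassify.pls_nsc as mod

        class FakePLS:
            def __init__(self, n_components, scale):
                self.coef_ = None

            def fit(self, x, y):
                self.coef_ = np.ones((y.shape[1], x.shape[1]))
                return self

            def predict(self, x):
                return np.tile([1.0, 0.0], (x.shape[0], 1))

        monkeypatch.setattr(mod, "PLSRegression", FakePLS)
        x = np.random.default_rng(0).normal(size=(20, 6))
        labels = ["A"] * 10 + ["B"] * 10
        with pytest.raises(ValueError, match="threshold"):
            mod.pls_da_select_snps(x, labels, [f"s{j}" for j in range(6)],
                                   max_components=2, seed=0)


@pytest.fixture(scope="module")
def two_class_data():
    rng = np.random.default_rng(5)
    x = np.vstack([rng.normal(-2, 1, (30, 8)), rng.normal(2, 1, (30, 8))])
    y = ["A"] * 30 + ["B"] * 30
    return x, y


class TestNsc:
    def test_zero_delta_is_plain_nearest_centroid(self, two_class_data):
        x, y = two_class_data
        model = _fit_nsc_at_delta(x, np.asarray(y), ("A", "B"), 0.0, np.nan, range(8))
        np.testing.assert_allclose(model.shrunken_centroids, model.class_centroids)

    def test_full_shrinkage_collapses_to_priors(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(30, 5))
        y = np.array(["A"] * 20 + ["B"] * 10)
        stats = _nsc_statistics(x, y, ("A", "B"))
        dmax = np.abs(stats[-1]).max()
        model = _fit_nsc_at_delta(x, y, ("A", "B"), dmax + 1.0, np.nan, range(5))
        assert (model.shrunken_offsets == 0).all()
        np.testing.assert_allclose(
            model.shrunken_centroids, np.tile(model.overall_centroid, (2, 1))
        )
        res = predict_nsc(model, x[:3], ["q1", "q2", "q3"])
        for r in res:
            assert r.scores["A"] == pytest.approx(20 / 30)
            assert r.scores["B"] == pytest.approx(10 / 30)

    def test_shrinkage_is_monotone_in_delta(self, two_class_data):
        x, y = two_class_data
        prev = None
        for delta in (0.01, 0.05, 0.10, 0.25, 0.50, 1.0):
            model = _fit_nsc_at_delta(x, np.asarray(y), ("A", "B"), delta, np.nan, range(8))
            mags = np.abs(model.shrunken_offsets)
            if prev is not None:
                assert (mags <= prev + 1e-12).all()
            prev = mags

    def test_well_separated_classes_tie_to_largest_delta(self, two_class_data):
        x, y = two_class_data
        model = train_nsc(x, y, [f"s{j}" for j in range(8)], seed=0)
        assert model.cv_accuracy == 1.0
        assert model.delta == 1.0  # every grid delta ties at 100%

    def test_symmetric_two_snp_closed_form(self):
        # centroids at +-1 with (s_j + s0) = 1 and equal priors: a query at
        # the origin is equidistant, so probabilities are exactly (1/2, 1/2)
        from grmclassify.pls_nsc import NSCModel

        model = NSCModel(
            breeds=("A", "B"),
            snp_ids=("s1", "s2"),
            overall_centroid=np.zeros(2),
            class_centroids=np.array([[-1.0, -1.0], [1.0, 1.0]]),
            shrunken_centroids=np.array([[-1.0, -1.0], [1.0, 1.0]]),
            shrunken_offsets=np.array([[-1.0, -1.0], [1.0, 1.0]]),
            pooled_sd=np.full(2, 0.5),
            s0=0.5,
            delta=0.0,
            priors=np.array([0.5, 0.5]),
            cv_accuracy=float("nan"),
        )
        res = predict_nsc(model, np.zeros((1, 2)), ["origin"])[0]
        assert res.scores["A"] == pytest.approx(0.5)
        assert res.scores["B"] == pytest.approx(0.5)
        assert res.tie_flag

    def test_centroid_self_classification_and_normalization(self, two_class_data):
        x, y = two_class_data
        model = train_nsc(x, y, [f"s{j}" for j in range(8)], seed=0)
        res = predict_nsc(model, model.shrunken_centroids, ["atA", "atB"])
        assert res[0].predicted_breed == "A"
        assert res[1].predicted_breed == "B"
        rng = np.random.default_rng(1)
        rand = predict_nsc(model, rng.normal(size=(10, 8)), [f"r{i}" for i in range(10)])
        for r in rand:
            assert sum(r.scores.values()) == pytest.approx(1.0, abs=1e-9)

    def test_mismatched_snp_set_rejected(self, two_class_data):
        x, y = two_class_data
        model = train_nsc(x, y, [f"s{j}" for j in range(8)], seed=0)
        with pytest.raises(ValueError, match="SNP"):
            predict_nsc(model, x[:, :5], ["q"], snp_ids=[f"s{j}" for j in range(5)])

    def test_empty_delta_grid_rejected(self, two_class_data):
        x, y = two_class_data
        with pytest.raises(ValueError, match="delta"):
            train_nsc(x, y, [f"s{j}" for j in range(8)], delta_grid=[], seed=0)


class TestPipelineAgreementWithGrm:
    def test_pls_nsc_tracks_mean_grm_accuracy(self):
        # reduced-panel baseline and the all-SNP mean-relatedness rule land
        # within a few accuracy points of each other on drifted panels
        from grmclassify import ExperimentConfig, run_experiment

        config = ExperimentConfig(
            simulation=SimulationConfig(n_breeds=3, n_per_breed=60, n_snps=2000, fst=0.05, seed=17),
            n_repetitions=3,
            rs_modes=("RS1",),
            methods=("mean_GRM", "PLS_NSC"),
            base_seed=90,
            pls_max_components=10,
            n_boot=500,
        )
        report = run_experiment(config)
        assert not report.failures
        acc = report.summaries[report.summaries["metric"] == "global_accuracy"]
        means = acc.set_index("method")["mean"]
        assert abs(means["PLS_NSC"] - means["mean_GRM"]) <= 5.0
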