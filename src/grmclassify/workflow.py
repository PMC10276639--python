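"""End-to-end repeated-split comparison of the four assignment methods.

One *experiment* repeats, ``n_repetitions`` times: draw a validation half
per breed, form the RS1 (remaining half) and/or RS2 (capped per-breed)
reference sets, compute reference allele frequencies, build one GRM over
reference + validation animals, derive relatedness features, run every
requested method on the identical split (a paired design — required for
the corrected paired t-test to be meaningful), and score against the true
labels. Per-repetition metrics are then summarized (min/mean/max/SD and a
percentile-bootstrap CI per method) and every unordered method pair is
compared with the variance-corrected paired t-test and Bonferroni bands.

Per-repetition seeds are ``base_seed + repetition`` so any single
repetition can be reproduced in isolation; RS1 and RS2 of a repetition
share the same validation draw and the RS2 reference nests inside RS1's.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import assign as assign_mod
from . import pls_nsc as pls_mod
from .grm import build_grm, compute_allele_frequencies, relatedness_summaries
from .io import GenotypePanel, major_genotype_frequency_filter, make_split, standardize_genotypes
from .simulate import SimulationConfig, simulate_genotypes
from .stats import (
    bonferroni_band,
    bootstrap_percentile_ci,
    confusion_metrics,
    corrected_paired_ttest,
)

logger = logging.getLogger(__name__)

METHODS = ("PLS_NSC", "mean_GRM", "SD_GRM", "GRM_SVM")
_ALIASES = {m.lower(): m for m in METHODS}


def canonical_method(name: str) -> str:
    try:
        return _ALIASES[name.lower()]
    except KeyError:
        raise ValueError(f"unknown method {name!r}; choose from {METHODS}") from None


@dataclasses.dataclass
class ExperimentConfig:
    """Configuration of one repeated-split comparison experiment."""

    panel: GenotypePanel | None = None
    simulation: SimulationConfig | None = None
    n_repetitions: int = 200
    rs_modes: tuple[str, ...] = ("RS1", "RS2")
    methods: tuple[str, ...] = METHODS
    base_seed: int = 0
    rs2_cap: int = 50
    svm_cost_grid: tuple[float, ...] = assign_mod.DEFAULT_COST_GRID
    nsc_delta_grid: tuple[float, ...] = pls_mod.DEFAULT_DELTA_GRID
    pls_max_components: int = 50
    cv_folds: int = 10
    n_boot: int = 10000
    output_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        self.methods = tuple(canonical_method(m) for m in self.methods)
        if not self.methods or not self.rs_modes:
            raise ValueError("need at least one method and one reference-set mode")
        for mode in self.rs_modes:
            if mode not in ("RS1", "RS2"):
                raise ValueError(f"unknown reference-set mode {mode!r}")
        if self.panel is None and self.simulation is None:
            raise ValueError("provide a panel or a simulation config")

    def resolve_panel(self) -> GenotypePanel:
        if self.panel is not None:
            return self.panel
        return simulate_genotypes(self.simulation).panel


@dataclasses.dataclass
class ComparisonReport:
    """Per-repetition metrics, pairwise tests and per-method summaries."""

    per_repetition: pd.DataFrame  # mode, method, repetition, metric, value
    comparisons: pd.DataFrame  # mode, metric, method_a, method_b, t, p, df, band
    summaries: pd.DataFrame  # mode, metric, method, min, mean, max, sd, ci_low, ci_high
    failures: list[dict]
    config_echo: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config_echo,
                "per_repetition": self.per_repetition.to_dict(orient="records"),
                "comparisons": self.comparisons.to_dict(orient="records"),
                "summaries": self.summaries.to_dict(orient="records"),
                "failures": self.failures,
            },
            indent=1,
            default=str,
        )

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_repetition.to_csv(out / "per_repetition.tsv", sep="\t", index=False)
        self.comparisons.to_csv(out / "comparisons.tsv", sep="\t", index=False)
        self.summaries.to_csv(out / "summaries.tsv", sep="\t", index=False)
        (out / "report.json").write_text(self.to_json())


def _assign_one_mode(
    panel: GenotypePanel,
    reference_ids: Sequence[str],
    validation_ids: Sequence[str],
    methods: Sequence[str],
    config: ExperimentConfig,
    seed: int,
) -> dict[str, dict[str, str]]:
    """Predictions {method: {animal: breed}} for one (repetition, mode)."""
    ref = list(reference_ids)
    val = list(validation_ids)
    ref_labels = {a: panel.breed_labels[a] for a in ref}
    predictions: dict[str, dict[str, str]] = {}

    grm_methods = [m for m in methods if m in ("mean_GRM", "SD_GRM", "GRM_SVM")]
    if grm_methods:
        freqs = compute_allele_frequencies(panel, ref)
        grm = build_grm(panel, ref + val, freqs)
        val_features = relatedness_summaries(grm, ref_labels, val)
        if "mean_GRM" in grm_methods:
            predictions["mean_GRM"] = {
                r.animal_id: r.predicted_breed for r in assign_mod.assign_by_mean(val_features)
            }
        if "SD_GRM" in grm_methods:
            predictions["SD_GRM"] = {
                r.animal_id: r.predicted_breed for r in assign_mod.assign_by_sd(val_features)
            }
        if "GRM_SVM" in grm_methods:
            ref_features = relatedness_summaries(grm, ref_labels, ref)
            model = assign_mod.train_grm_svm(
                ref_features, ref_labels, cost_grid=config.svm_cost_grid,
                folds=config.cv_folds, seed=seed,
            )
            predictions["GRM_SVM"] = {
                r.animal_id: r.predicted_breed
                for r in assign_mod.predict_grm_svm(model, val_features)
            }

    if "PLS_NSC" in methods:
        kept = major_genotype_frequency_filter(panel, ref, threshold=0.95)
        std, _, _ = standardize_genotypes(panel, ref, snp_ids=kept)
        ref_rows = panel.rows(ref)
        val_rows = panel.rows(val)
        labels = [ref_labels[a] for a in ref]
        selection = pls_mod.pls_da_select_snps(
            std[ref_rows], labels, kept,
            max_components=config.pls_max_components, folds=config.cv_folds, seed=seed,
        )
        sel_cols = [kept.index(s) for s in selection.selected_snps]
        nsc = pls_mod.train_nsc(
            std[np.ix_(ref_rows, sel_cols)], labels, selection.selected_snps,
            delta_grid=config.nsc_delta_grid, folds=config.cv_folds, seed=seed,
        )
        predictions["PLS_NSC"] = {
            r.animal_id: r.predicted_breed
            for r in pls_mod.predict_nsc(nsc, std[np.ix_(val_rows, sel_cols)], val)
        }
    return predictions


def _metric_rows(metrics, mode: str, method: str, repetition: int) -> list[dict]:
    rows = [
        {
            "mode": mode, "method": method, "repetition": repetition,
            "metric": "global_accuracy", "value": metrics.global_accuracy,
        }
    ]
    for b in metrics.breeds:
        rows.append(
            {"mode": mode, "method": method, "repetition": repetition,
             "metric": f"sensitivity_{b}", "value": metrics.per_breed_sensitivity[b]}
        )
        spec = metrics.per_breed_specificity[b]
        if spec is not None:
            rows.append(
                {"mode": mode, "method": method, "repetition": repetition,
                 "metric": f"specificity_{b}", "value": spec}
            )
    return rows


def _test_counts(panel: GenotypePanel, mode: str, cap: int, metric: str) -> tuple[int, int]:
    """(n1, n2) for the corrected t-test: calibration and validation counts.

    Totals for global accuracy; one breed's counts for its sensitivity; the
    other breeds' counts for its specificity. Counts follow the fixed split
    design (floor-halving, RS2 cap), which does not vary by repetition.
    """
    val = {b: len(panel.animals_of_breed(b)) // 2 for b in panel.breeds()}
    ref = {b: len(panel.animals_of_breed(b)) - val[b] for b in panel.breeds()}
    if mode == "RS2":
        ref = {b: min(cap, n) for b, n in ref.items()}
    if metric == "global_accuracy":
        return sum(ref.values()), sum(val.values())
    kind, breed = metric.split("_", 1)
    if kind == "sensitivity":
        return ref[breed], val[breed]
    return (
        sum(n for b, n in ref.items() if b != breed),
        sum(n for b, n in val.items() if b != breed),
    )


def run_experiment(config: ExperimentConfig) -> ComparisonReport:
    """Run the full repeated-split comparison described by ``config``."""
    panel = config.resolve_panel()
    rows: list[dict] = []
    failures: list[dict] = []
    for rep in range(config.n_repetitions):
        seed = config.base_seed + rep
        for mode in config.rs_modes:
            plan = make_split(panel, mode, seed, per_breed_cap=config.rs2_cap)
            truth = {a: panel.breed_labels[a] for a in plan.validation_ids}
            try:
                predictions = _assign_one_mode(
                    panel, plan.reference_ids, plan.validation_ids,
                    config.methods, config, seed,
                )
            except Exception as exc:  # record, keep sweeping
                logger.exception("repetition %d mode %s failed", rep, mode)
                failures.append({"repetition": rep, "mode": mode, "method": "*", "error": str(exc)})
                continue
            for method in config.methods:
                if method not in predictions:
                    failures.append(
                        {"repetition": rep, "mode": mode, "method": method, "error": "no predictions"}
                    )
                    continue
                rows.extend(
                    _metric_rows(confusion_metrics(predictions[method], truth), mode, method, rep)
                )
    per_repetition = pd.DataFrame(rows)
    comparisons, summaries = _analyze(per_repetition, panel, config)
    report = ComparisonReport(
        per_repetition=per_repetition,
        comparisons=comparisons,
        summaries=summaries,
        failures=failures,
        config_echo={
            "n_repetitions": config.n_repetitions,
            "rs_modes": list(config.rs_modes),
            "methods": list(config.methods),
            "base_seed": config.base_seed,
            "rs2_cap": config.rs2_cap,
            "n_animals": panel.n_animals,
            "n_snps": panel.n_snps,
        },
    )
    if config.output_dir is not None:
        report.write(config.output_dir)
    return report


def _analyze(
    per_repetition: pd.DataFrame, panel: GenotypePanel, config: ExperimentConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    comparisons: list[dict] = []
    summaries: list[dict] = []
    if per_repetition.empty:
        return pd.DataFrame(), pd.DataFrame()
    for (mode, metric), block in per_repetition.groupby(["mode", "metric"]):
        wide = block.pivot(index="repetition", columns="method", values="value")
        n1, n2 = _test_counts(panel, mode, config.rs2_cap, metric)
        for method in wide.columns:
            vals = wide[method].dropna().to_numpy()
            if vals.size == 0:
                continue
            if vals.size == 1:  # degenerate single-repetition summary
                lo = hi = float(vals[0])
                sd = 0.0
            else:
                lo, hi = bootstrap_percentile_ci(vals, n_boot=config.n_boot, seed=config.base_seed)
                sd = vals.std(ddof=1)
            summaries.append(
                {"mode": mode, "metric": metric, "method": method,
                 "min": vals.min(), "mean": vals.mean(), "max": vals.max(),
                 "sd": sd, "ci_low": lo, "ci_high": hi, "n": vals.size}
            )
        for ma, mb in itertools.combinations(sorted(wide.columns), 2):
            pair = wide[[ma, mb]].dropna()
            if len(pair) < 2:
                continue
            res = corrected_paired_ttest((pair[ma] - pair[mb]).to_numpy(), n1=n1, n2=n2)
            comparisons.append(
                {"mode": mode, "metric": metric, "method_a": ma, "method_b": mb,
                 "mean_diff": res.mean_diff, "t": res.t_value, "p": res.p_value,
                 "df": res.df, "band": bonferroni_band(res.p_value)}
            )
    return pd.DataFrame(comparisons), pd.DataFrame(summaries)


def summarize(report: ComparisonReport) -> pd.DataFrame:
    """Wide summary table: min/mean/max/SD per (mode, method), global accuracy."""
    block = report.summaries[report.summaries["metric"] == "global_accuracy"]
    return block.set_index(["mode", "method"])[["min", "mean", "max", "sd", "ci_low", "ci_high"]]
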