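"""Breed assignment from relatedness summaries.

Three classifiers share the :class:`~grmclassify.grm.RelatednessFeatures`
input:

* ``mean_GRM`` — assign to the breed with the highest mean relatedness.
  Rationale: an animal's genomic relationships to members of its own breed
  are on average higher than to members of other breeds.
* ``SD_GRM`` — assign to the breed with the highest SD of relatedness.
  Rationale: relationships within a breed (close family through distant
  cousins) vary more than the uniformly low relationships to another breed.
* ``GRM_SVM`` — a linear support vector machine on the standardized mean
  and SD features (2K variables for K breeds), with the cost parameter C
  chosen by stratified 10-fold cross-validation and decision scores mapped
  to probabilities by Platt's logistic scaling.

Ties are broken by lexicographic breed order with ``tie_flag`` set, so all
assignments are deterministic and order-invariant.
"""

from __future__ import annotations

import contextlib
import dataclasses
import warnings
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .grm import RelatednessFeatures

DEFAULT_COST_GRID: tuple[float, ...] = (0.001, 0.01, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)

_TIE_RTOL = 1e-12


@dataclasses.dataclass(frozen=True)
class AssignmentResult:
    """One animal's predicted breed with per-breed scores."""

    animal_id: str
    method: str
    predicted_breed: str
    scores: dict[str, float]
    tie_flag: bool


def _argmax_assign(animal_id: str, method: str, breeds: Sequence[str], values: np.ndarray) -> AssignmentResult:
    # scan breeds in lexicographic order keeping strict improvements, so
    # exact ties resolve to the lexicographically first breed
    best_k = None
    for k in sorted(range(len(breeds)), key=lambda k: breeds[k]):
        if best_k is None or values[k] > values[best_k]:
            best_k = k
    top = values[best_k]
    tol = _TIE_RTOL * max(1.0, abs(top))
    tie = sum(abs(values[k] - top) <= tol for k in range(len(breeds))) > 1
    return AssignmentResult(
        animal_id=animal_id,
        method=method,
        predicted_breed=breeds[best_k],
        scores={b: float(values[k]) for k, b in enumerate(breeds)},
        tie_flag=bool(tie),
    )


def assign_by_mean(features: RelatednessFeatures) -> list[AssignmentResult]:
    """Assign each animal to the breed with the highest mean relatedness."""
    if not features.breeds:
        raise ValueError("features contain no breeds")
    return [
        _argmax_assign(a, "mean_GRM", features.breeds, features.means[i])
        for i, a in enumerate(features.animal_ids)
    ]


def assign_by_sd(features: RelatednessFeatures) -> list[AssignmentResult]:
    """Assign each animal to the breed with the highest SD of relatedness."""
    if not features.breeds:
        raise ValueError("features contain no breeds")
    return [
        _argmax_assign(a, "SD_GRM", features.breeds, features.sds[i])
        for i, a in enumerate(features.animal_ids)
    ]


@dataclasses.dataclass
class LinearSVMModel:
    """Fitted linear SVM over standardized relatedness features."""

    pipeline: Pipeline
    breeds: tuple[str, ...]
    feature_names: tuple[str, ...]
    chosen_cost: float
    cv_accuracy: float


def train_grm_svm(
    training_features: RelatednessFeatures,
    labels: dict[str, str],
    cost_grid: Sequence[float] = DEFAULT_COST_GRID,
    folds: int = 10,
    seed: int = 0,
) -> LinearSVMModel:
    """Tune and fit the linear SVM on reference-animal relatedness features.

    The 2K features are standardized by their training mean/SD; C is chosen
    as the cost with the highest stratified ``folds``-fold CV accuracy
    (ties -> largest C, which keeps the Platt sigmoid away from its
    uniform-probability degeneracy), then the model is refit on all training animals
    with Platt-scaled probability outputs (one-vs-one with pairwise
    coupling for K > 2). Deterministic given ``seed``.
    """
    if not cost_grid:
        raise ValueError("empty cost grid")
    x = training_features.feature_matrix()
    y = np.array([labels[a] for a in training_features.animal_ids])
    breeds = tuple(sorted(set(y)))
    if len(breeds) < 2:
        raise ValueError("need at least two breeds to train the SVM")
    if np.any(x.std(axis=0) == 0):
        j = int(np.flatnonzero(x.std(axis=0) == 0)[0])
        raise ValueError(f"constant training feature {training_features.feature_names()[j]!r}")

    @contextlib.contextmanager
    def quiet_platt():
        # SVC(probability=True) is the wanted one-vs-one Platt coupling;
        # newer sklearn warns about it at every fit
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*probability.*", category=FutureWarning)
            yield

    def make_pipeline(c: float) -> Pipeline:
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("svm", SVC(kernel="linear", C=c, probability=True, random_state=seed)),
            ]
        )

    if len(cost_grid) == 1:
        chosen, cv_acc = float(cost_grid[0]), float("nan")
    else:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        chosen, cv_acc = None, -np.inf
        with quiet_platt():
            for c in cost_grid:
                acc = cross_val_score(make_pipeline(float(c)), x, y, cv=cv, scoring="accuracy").mean()
                # ties keep the largest C: with heavy regularization the
                # decision values compress and the Platt sigmoid degenerates
                # toward uniform probabilities, breaking the probability argmax
                if acc >= cv_acc - 1e-12:
                    chosen, cv_acc = float(c), max(float(acc), cv_acc)
    pipeline = make_pipeline(chosen)
    with quiet_platt():
        pipeline.fit(x, y)
    return LinearSVMModel(
        pipeline=pipeline,
        breeds=breeds,
        feature_names=tuple(training_features.feature_names()),
        chosen_cost=chosen,
        cv_accuracy=float(cv_acc),
    )


def predict_grm_svm(model: LinearSVMModel, features: RelatednessFeatures) -> list[AssignmentResult]:
    """Assign each animal to the breed with the highest Platt probability."""
    if tuple(features.feature_names()) != model.feature_names:
        raise ValueError(
            f"feature mismatch: model expects {model.feature_names}, "
            f"got {tuple(features.feature_names())}"
        )
    probs = model.pipeline.predict_proba(features.feature_matrix())
    classes = tuple(model.pipeline.named_steps["svm"].classes_)
    order = [classes.index(b) for b in model.breeds]
    results = []
    for i, a in enumerate(features.animal_ids):
        results.append(_argmax_assign(a, "GRM_SVM", model.breeds, probs[i, order]))
    return results
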