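"""Classifier specifications, fitting, scoring, and randomized tuning.

Two families are supported: logistic regression and random forest, each with
a "default" configuration (the underlying scikit-learn defaults, recorded
explicitly) and a "tuned" configuration:

* logistic regression — C=11.29, max_iter=2500, solver="saga"
* random forest — max_features="sqrt", n_estimators=1000

Scores are positive-class probabilities: the fitted sigmoid output for LR,
the fraction of trees voting positive for RF. Hard labels are produced
downstream by thresholding at 0.5.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .encoders import FeatureMatrix
from .errors import (
    DimensionError,
    InvalidFeatureError,
    MissingClassError,
    SearchFailedError,
    UnknownModelError,
)

LOGISTIC_REGRESSION = "logistic_regression"
RANDOM_FOREST = "random_forest"
FAMILIES = (LOGISTIC_REGRESSION, RANDOM_FOREST)

# scikit-learn defaults, recorded explicitly so specs are self-describing
DEFAULT_HYPERPARAMETERS = {
    LOGISTIC_REGRESSION: {"C": 1.0, "max_iter": 100, "solver": "lbfgs"},
    RANDOM_FOREST: {"n_estimators": 100, "max_features": "sqrt"},
}

TUNED_HYPERPARAMETERS = {
    LOGISTIC_REGRESSION: {"C": 11.29, "max_iter": 2500, "solver": "saga"},
    RANDOM_FOREST: {"n_estimators": 1000, "max_features": "sqrt"},
}

# randomized-search sampling space (paper's winning points are members)
SEARCH_SPACE = {
    LOGISTIC_REGRESSION: {
        "C": ("loguniform", 1e-2, 1e3),
        "max_iter": ("choice", (500, 1000, 2500, 5000)),
        "solver": ("choice", ("saga", "lbfgs")),
    },
    RANDOM_FOREST: {
        "n_estimators": ("choice", (100, 250, 500, 1000)),
        "max_features": ("choice", ("sqrt", "log2", 0.5)),
    },
}


@dataclass(frozen=True)
class ModelSpec:
    """Classifier family plus a fully-materialized hyperparameter map."""

    family: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    tuned: bool = False

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise UnknownModelError(f"unknown model family {self.family!r}")
        hp = self.hyperparameters
        if "C" in hp and hp["C"] <= 0:
            raise ValueError("C must be > 0")
        if "max_iter" in hp and hp["max_iter"] < 1:
            raise ValueError("max_iter must be >= 1")
        if "n_estimators" in hp and hp["n_estimators"] < 1:
            raise ValueError("n_estimators must be >= 1")

    def as_dict(self) -> dict:
        return {
            "family": self.family,
            "hyperparameters": dict(self.hyperparameters),
            "seed": self.seed,
            "tuned": self.tuned,
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        d = json.loads(text)
        return cls(
            family=d["family"],
            hyperparameters=d["hyperparameters"],
            seed=d["seed"],
            tuned=d.get("tuned", False),
        )


@dataclass
class FittedModel:
    """A trained classifier bound to its spec and expected feature count."""

    spec: ModelSpec
    estimator: Any
    n_features_expected: int

    def save(self, path: str | Path) -> None:
        """Persist the estimator (joblib) with a spec JSON alongside."""
        joblib.dump(self.estimator, path)
        Path(f"{path}.spec.json").write_text(self.spec.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "FittedModel":
        estimator = joblib.load(path)
        spec = ModelSpec.from_json(Path(f"{path}.spec.json").read_text())
        return cls(spec=spec, estimator=estimator, n_features_expected=estimator.n_features_in_)


def make_spec(family: str, tuned: bool = False, seed: int = 0) -> ModelSpec:
    """Build a spec with either the library-default or the tuned configuration."""
    if family not in FAMILIES:
        raise UnknownModelError(f"unknown model family {family!r}")
    table = TUNED_HYPERPARAMETERS if tuned else DEFAULT_HYPERPARAMETERS
    return ModelSpec(
        family=family, hyperparameters=dict(table[family]), seed=seed, tuned=tuned
    )


def _build_estimator(spec: ModelSpec):
    hp = spec.hyperparameters
    if spec.family == LOGISTIC_REGRESSION:
        return LogisticRegression(
            C=hp.get("C", 1.0),
            max_iter=hp.get("max_iter", 100),
            solver=hp.get("solver", "lbfgs"),
            random_state=spec.seed,
        )
    max_features = hp.get("max_features", "sqrt")
    if max_features == "all":
        max_features = None
    return RandomForestClassifier(
        n_estimators=hp.get("n_estimators", 100),
        max_features=max_features,
        random_state=spec.seed,
    )


def fit(spec: ModelSpec, X: FeatureMatrix) -> FittedModel:
    """Train one classifier; deterministic for a fixed (spec.seed, X)."""
    if X.n_records < 2:
        raise MissingClassError("need at least 2 records to fit")
    classes = set(int(v) for v in X.labels)
    if classes != {0, 1}:
        raise MissingClassError(f"training set must contain both classes, got {sorted(classes)}")
    if not np.all(np.isfinite(X.values)):
        raise InvalidFeatureError("feature matrix contains non-finite values")
    estimator = _build_estimator(spec)
    with warnings.catch_warnings():
        # default LR (max_iter=100) may stop early on wide matrices; that is
        # part of the "library defaults" contract, not an error
        warnings.simplefilter("ignore", ConvergenceWarning)
        estimator.fit(X.values, X.labels)
    return FittedModel(spec=spec, estimator=estimator, n_features_expected=X.n_features)


def predict_scores(model: FittedModel, X: FeatureMatrix) -> np.ndarray:
    """Positive-class probability per record, in [0, 1]."""
    if X.n_features != model.n_features_expected:
        raise DimensionError(
            f"model expects {model.n_features_expected} features, got {X.n_features}"
        )
    proba = model.estimator.predict_proba(X.values)
    pos_col = list(model.estimator.classes_).index(1)
    return proba[:, pos_col]


def _sample_point(space: dict, rng: np.random.Generator) -> dict[str, Any]:
    point = {}
    for name, (kind, *args) in space.items():
        if kind == "loguniform":
            lo, hi = args
            point[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            choices = args[0]
            point[name] = choices[int(rng.integers(len(choices)))]
    return point


def randomized_search(
    family: str,
    X: FeatureMatrix,
    n_iter: int = 25,
    seed: int = 0,
    folds: int = 5,
) -> tuple[ModelSpec, list[dict]]:
    """Random hyperparameter search scored by mean cross-validated accuracy.

    Samples ``n_iter`` points from the documented search space, evaluates
    each by stratified ``folds``-fold CV accuracy on ``X``, and returns the
    best spec plus the full (point, score) table. Deterministic given seed.
    """
    from . import evaluation  # local import: evaluation depends on this module

    if family not in FAMILIES:
        raise UnknownModelError(f"unknown model family {family!r}")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    table: list[dict] = []
    best: tuple[float, ModelSpec] | None = None
    for i in range(n_iter):
        point = _sample_point(SEARCH_SPACE[family], rng)
        spec = ModelSpec(family=family, hyperparameters=point, seed=seed, tuned=False)
        try:
            report = evaluation.cross_validate_matrix(X, spec, k=folds, seed=seed)
            score = report.aggregate["acc"]
            table.append({"point": point, "score": score, "error": None})
        except Exception as exc:  # noqa: BLE001 - per-point failures are recorded
            table.append({"point": point, "score": None, "error": str(exc)})
            continue
        if best is None or score > best[0]:
            best = (score, spec)
    if best is None:
        raise SearchFailedError("all sampled hyperparameter points failed")
    return best[1], table
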