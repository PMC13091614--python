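"""The three recaller families and their tuning machinery.

Families:

* ``rmlr`` — regularized multinomial logistic regression (scikit-learn,
  saga solver; supports l1/l2/elastic-net penalties);
* ``gbt``  — gradient-boosted trees (XGBoost, multiclass softmax
  cross-entropy objective, probability output);
* ``nn``   — a three-hidden-layer multilayer perceptron (scikit-learn
  MLPClassifier; ReLU hidden activations, softmax output, Adam).

Hyperparameters are tuned by grid search under group-wise cross-validation:
folds group records by individual, so no individual ever appears in both a
training and a validation fold, and grid points are scored by mean
multiclass log loss (lower is better; ties broken by grid order).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import GroupKFold, ParameterGrid
from sklearn.neural_network import MLPClassifier
from xgboost import XGBClassifier

from .features import Normalizer
from .genotypes import GENOTYPES

PROB_COLUMNS = ["p_aa", "p_ab", "p_bb"]

#: allowed hyperparameter names per family
PARAM_REGISTRY = {
    "rmlr": {"C", "penalty", "l1_ratio", "max_iter"},
    "gbt": {"n_estimators", "learning_rate", "max_depth", "gamma",
            "min_child_weight", "subsample"},
    "nn": {"hidden_layer_sizes", "learning_rate_init", "epochs"},
}

DEFAULT_PARAMS = {
    "rmlr": {"C": 1.0, "penalty": "l2", "max_iter": 200},
    "gbt": {"n_estimators": 200, "learning_rate": 0.1, "max_depth": 6,
            "gamma": 0.0, "min_child_weight": 1, "subsample": 0.8},
    # third hidden layer mirrors the first; epochs fixed, no early stopping
    "nn": {"hidden_layer_sizes": (50, 100, 50), "learning_rate_init": 0.01,
           "epochs": 50},
}


@dataclass
class ModelSpec:
    family: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in PARAM_REGISTRY:
            raise ValueError(f"unknown model family {self.family!r}")
        bad = set(self.params) - PARAM_REGISTRY[self.family]
        if bad:
            raise ValueError(
                f"invalid {self.family} hyperparameters: {sorted(bad)}")

    def resolved(self) -> dict:
        p = dict(DEFAULT_PARAMS[self.family])
        p.update(self.params)
        return p


@dataclass
class TrainedModel:
    spec: ModelSpec
    estimator: object
    feature_names: list[str]
    normalizer: Normalizer | None = None
    metadata: dict = field(default_factory=dict)


def _build_estimator(spec: ModelSpec):
    p = spec.resolved()
    if spec.family == "rmlr":
        kwargs = dict(C=p["C"], penalty=p["penalty"], solver="saga",
                      max_iter=p["max_iter"], random_state=spec.seed)
        if p["penalty"] == "elasticnet":
            kwargs["l1_ratio"] = p.get("l1_ratio", 0.5)
        return LogisticRegression(**kwargs)
    if spec.family == "gbt":
        return XGBClassifier(
            objective="multi:softprob", eval_metric="mlogloss",
            n_estimators=p["n_estimators"], learning_rate=p["learning_rate"],
            max_depth=p["max_depth"], gamma=p["gamma"],
            min_child_weight=p["min_child_weight"], subsample=p["subsample"],
            tree_method="hist", n_jobs=1, random_state=spec.seed)
    return MLPClassifier(
        hidden_layer_sizes=tuple(p["hidden_layer_sizes"]), activation="relu",
        solver="adam", learning_rate_init=p["learning_rate_init"],
        max_iter=p["epochs"], random_state=spec.seed)


def _data_hash(X: pd.DataFrame, y) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X.to_numpy(dtype=float)).tobytes())
    h.update("".join(map(str, y)).encode())
    return h.hexdigest()[:16]


def train(spec: ModelSpec, X: pd.DataFrame, y,
          class_weight: dict[str, float] | None = None) -> TrainedModel:
    """Fit one model on z-scored features X and genotype labels y.

    ``class_weight`` maps genotype -> weight (see labeling.class_weights);
    rmlr and gbt apply it exactly, the nn family cannot and ignores it with
    a warning.
    """
    y = pd.Series(y).reset_index(drop=True)
    present = set(y.unique())
    if not set(GENOTYPES) <= present:
        raise ValueError(f"training labels miss classes: {sorted(set(GENOTYPES) - present)}")
    est = _build_estimator(spec)
    codes = y.map({g: i for i, g in enumerate(GENOTYPES)}).to_numpy()

    if spec.family == "gbt":
        sw = None
        if class_weight:
            sw = y.map(class_weight).to_numpy(dtype=float)
        est.fit(X.to_numpy(dtype=float), codes, sample_weight=sw)
    elif spec.family == "rmlr":
        if class_weight:
            est.set_params(class_weight={i: class_weight[g]
                                         for i, g in enumerate(GENOTYPES)})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # saga convergence chatter
            est.fit(X.to_numpy(dtype=float), codes)
    else:
        if class_weight:
            warnings.warn("nn family does not support class weights; ignoring",
                          stacklevel=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X.to_numpy(dtype=float), codes)

    meta = {"data_hash": _data_hash(X, y), "seed": spec.seed,
            "n_examples": len(y)}
    return TrainedModel(spec, est, list(X.columns), metadata=meta)


def predict_proba(model: TrainedModel, X: pd.DataFrame) -> pd.DataFrame:
    """Posterior genotype probabilities, argmax call and Phred quality per row.

    Ties in the argmax resolve to the first class in AA < AB < BB order.
    """
    if list(X.columns) != model.feature_names:
        raise ValueError(
            f"feature mismatch: model expects {model.feature_names}, "
            f"got {list(X.columns)}")
    P = model.estimator.predict_proba(X.to_numpy(dtype=float))
    # estimator classes are the codes 0,1,2; reorder defensively
    order = np.argsort(model.estimator.classes_)
    P = P[:, order]
    out = pd.DataFrame(P, columns=PROB_COLUMNS, index=X.index)
    out["call"] = np.array(GENOTYPES, dtype=object)[P.argmax(axis=1)]
    from .filters import phred_quality
    out["q"] = phred_quality(P)
    return out


def group_folds(groups, n_folds: int):
    """Leave-individuals-out CV folds: (train_idx, val_idx) pairs in which the
    individuals of the two sides are disjoint."""
    groups = pd.Series(groups).reset_index(drop=True)
    n_groups = groups.nunique()
    if n_folds > n_groups:
        raise ValueError(f"n_folds={n_folds} exceeds {n_groups} individuals")
    cv = GroupKFold(n_splits=n_folds)
    dummy = np.zeros(len(groups))
    return list(cv.split(dummy, dummy, groups))


def grid_search(family: str, grid: dict[str, list], X: pd.DataFrame, y,
                groups, n_folds: int, seed: int = 0,
                class_weight: dict[str, float] | None = None
                ) -> tuple[ModelSpec, pd.DataFrame]:
    """Exhaustive grid search scored by mean multiclass log loss under
    leave-individuals-out cross-validation.

    ``groups`` are individual IDs aligned with X/y rows; each CV fold holds
    out whole individuals.  Returns the winning spec (lowest mean log loss,
    ties to the earlier grid point) and the per-fold score table.
    """
    y = pd.Series(y).reset_index(drop=True)
    folds = group_folds(groups, n_folds)
    Xa = X.reset_index(drop=True)

    rows = []
    best_spec, best_score = None, np.inf
    for gi, params in enumerate(ParameterGrid(grid)):
        spec = ModelSpec(family, dict(params), seed=seed)
        fold_losses = []
        for fold, (tr, va) in enumerate(folds):
            m = train(spec, Xa.iloc[tr], y.iloc[tr], class_weight=class_weight)
            P = predict_proba(m, Xa.iloc[va])[PROB_COLUMNS].to_numpy()
            loss = log_loss(y.iloc[va], P, labels=list(GENOTYPES))
            fold_losses.append(loss)
            rows.append({"grid_index": gi, "fold": fold, "log_loss": loss,
                         **params})
        mean_loss = float(np.mean(fold_losses))
        if mean_loss < best_score:
            best_score, best_spec = mean_loss, spec
    scores = pd.DataFrame(rows)
    return best_spec, scores


def fit_final(family: str, best: ModelSpec, X: pd.DataFrame, y,
              class_weight: dict[str, float] | None) -> TrainedModel:
    """Refit the winning spec on the full training partition with class
    reweighting (no down-sampling)."""
    spec = ModelSpec(family, dict(best.params), seed=best.seed)
    return train(spec, X, y, class_weight=class_weight)


# ---------------------------------------------------------------------------
# model artifact persistence

def save_model(model: TrainedModel, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    joblib.dump(model.estimator, outdir / "estimator.joblib")
    if model.normalizer is not None:
        model.normalizer.to_json(outdir / "normalizer.json")
    manifest = {
        "family": model.spec.family, "params": _jsonable(model.spec.params),
        "seed": model.spec.seed, "feature_names": model.feature_names,
        "metadata": model.metadata,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_model(outdir: str | Path) -> TrainedModel:
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    est = joblib.load(outdir / "estimator.joblib")
    norm = None
    if (outdir / "normalizer.json").exists():
        norm = Normalizer.from_json(outdir / "normalizer.json")
    spec = ModelSpec(manifest["family"], manifest["params"], manifest["seed"])
    return TrainedModel(spec, est, manifest["feature_names"], norm,
                        manifest["metadata"])


def _jsonable(params: dict) -> dict:
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in params.items()}
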