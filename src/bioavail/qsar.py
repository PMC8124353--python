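"""Trainable QSAR endpoint models over signature descriptors.

Nine ADME endpoints feed the PBPK integration: passive fraction absorbed
(f_abs_p), in vivo intrinsic hepatic clearance (CL_int), CYP3A4 substrate
specificity, plasma unbound fraction (f_u), dissolution potential (f_diss),
MDR-1 and BCRP efflux substrate specificity, biliary clearance (CL_bile) and
the blood-to-plasma concentration ratio (cbl_cpl).  Permeability, clearance
and CYP3A4 endpoints use RBF-kernel support vector machines tuned by an
exhaustive (gamma, cost) grid search under 10-fold cross-validation; the
remaining endpoints use PLS regression or PLS-DA with a fixed number of
latent components.

scikit-learn performs the fits; prediction is re-implemented here from the
extracted parameter arrays so that a persisted model bundle reproduces its
predictions bit-identically after reload.
"""
from __future__ import annotations

import json
import math
import warnings as _warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC, SVR

from .chemstruct import AlertFlags, Compound, DescriptorVector, compute_signatures, detect_alerts

SCHEMA_VERSION = 1

#: Logit clipping for bounded (fraction) endpoints.
LOGIT_EPS = 0.005
#: Floor (in natural units) before a log10 transform of clearances/ratios.
LOG10_FLOOR = 1e-3

#: Default (gamma, cost) grid: powers of two, 2^-10 .. 2^10 in steps of 2^2.
DEFAULT_GRID = {
    "gamma": [2.0**e for e in range(-10, 11, 2)],
    "cost": [2.0**e for e in range(-10, 11, 2)],
}


class TrainingError(ValueError):
    """Degenerate training data (constant response, impossible components...)."""


class ConfigurationError(RuntimeError):
    """Missing or inconsistent model configuration."""


@dataclass(frozen=True)
class EndpointSpec:
    name: str
    task: str  # "regression" | "classification"
    learner: str  # "svm" | "pls" | "pls_da"
    transform: str = "identity"  # "identity" | "log10" | "logit"
    n_components: int | None = None  # PLS only
    value_range: tuple = (-math.inf, math.inf)  # clip range in natural units

    def __post_init__(self):
        if self.task not in ("regression", "classification"):
            raise ValueError(f"bad task {self.task!r}")
        if self.learner not in ("svm", "pls", "pls_da"):
            raise ValueError(f"bad learner {self.learner!r}")
        if self.learner in ("pls", "pls_da"):
            if self.n_components is None or not 4 <= self.n_components <= 8:
                raise ValueError("PLS endpoints need n_components in [4, 8]")


#: The nine endpoints: learner/task/transform/latent-component assignments.
ENDPOINTS: dict[str, EndpointSpec] = {
    "f_abs_p": EndpointSpec("f_abs_p", "regression", "svm", "logit", None, (0.0, 1.0)),
    "CL_int": EndpointSpec("CL_int", "regression", "svm", "log10", None, (0.0, math.inf)),
    "cyp3a4": EndpointSpec("cyp3a4", "classification", "svm"),
    "f_u": EndpointSpec("f_u", "regression", "pls", "logit", 7, (LOGIT_EPS, 1.0)),
    "f_diss": EndpointSpec("f_diss", "regression", "pls", "logit", 5, (0.0, 1.0)),
    "mdr1": EndpointSpec("mdr1", "classification", "pls_da", n_components=4),
    "bcrp": EndpointSpec("bcrp", "classification", "pls_da", n_components=5),
    "CL_bile": EndpointSpec("CL_bile", "regression", "pls", "log10", 6, (0.0, math.inf)),
    "cbl_cpl": EndpointSpec("cbl_cpl", "regression", "pls", "log10", 8, (LOG10_FLOOR, math.inf)),
}


def transform_forward(y: np.ndarray, transform: str) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if transform == "identity":
        return y
    if transform == "log10":
        return np.log10(np.maximum(y, LOG10_FLOOR))
    if transform == "logit":
        p = np.clip(y, LOGIT_EPS, 1.0 - LOGIT_EPS)
        return np.log(p / (1.0 - p))
    raise ValueError(f"unknown transform {transform!r}")


def transform_inverse(z: np.ndarray, transform: str) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if transform == "identity":
        return z
    if transform == "log10":
        return np.power(10.0, z)
    if transform == "logit":
        return 1.0 / (1.0 + np.exp(-z))
    raise ValueError(f"unknown transform {transform!r}")


@dataclass(frozen=True)
class CVReport:
    folds: int
    per_fold_scores: tuple
    aggregate: float  # pooled Q2 (regression) or accuracy (classification)
    seed: int

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class TrainedModel:
    spec: EndpointSpec
    feature_index: tuple  # frozen signature vocabulary, column order
    parameters: dict  # learner-specific numeric arrays
    cv_report: CVReport
    training_meta: dict

    # ---- featurization -------------------------------------------------
    def _vector(self, d: DescriptorVector) -> np.ndarray:
        x = np.zeros(len(self.feature_index), dtype=float)
        entries = d.entries
        for j, key in enumerate(self.feature_index):
            v = entries.get(key)
            if v:
                x[j] = float(v)
        return (x - np.asarray(self.parameters["x_mean"])) / np.asarray(self.parameters["x_scale"])

    # ---- prediction (independent of sklearn objects) -------------------
    def decision(self, d: DescriptorVector) -> float:
        """Raw decision value on the model's internal (transformed) scale."""
        x = self._vector(d)
        p = self.parameters
        if self.spec.learner == "svm":
            sv = np.asarray(p["support_vectors"])
            dual = np.asarray(p["dual_coef"])
            gamma = float(p["gamma"])
            diff = sv - x[None, :]
            k = np.exp(-gamma * np.einsum("ij,ij->i", diff, diff))
            return float(dual @ k + float(p["intercept"]))
        coef = np.asarray(p["coef"])
        return float(x @ coef + float(p["intercept"]))

    def predict(self, d: DescriptorVector):
        """Natural-units value (regression) or ``(bool, score)`` (classification).

        Signatures absent from the frozen vocabulary contribute zero; an
        all-zero descriptor yields the intercept prediction. Regression output
        is inverse-transformed and clipped into the endpoint's valid range.
        """
        raw = self.decision(d)
        if self.spec.task == "classification":
            if self.spec.learner == "pls_da":
                # coded response in [0,1]; threshold 0.5, ties -> non-substrate
                return raw > 0.5, raw
            return raw > 0.0, raw
        value = float(transform_inverse(raw, self.spec.transform))
        lo, hi = self.spec.value_range
        if value < lo or value > hi:
            _warnings.warn(
                f"{self.spec.name}: prediction {value:.4g} clipped into [{lo:g}, {hi:g}]",
                stacklevel=2,
            )
            value = min(max(value, lo), hi)
        return value


# ---------------------------------------------------------------------------
# feature matrices and cross-validation folds
# ---------------------------------------------------------------------------

def build_feature_matrix(
    descriptors: Sequence[DescriptorVector], vocabulary: Sequence[str] | None = None
):
    """Dense count matrix over a (sorted) signature vocabulary."""
    if vocabulary is None:
        vocab: set = set()
        for d in descriptors:
            vocab.update(d.entries)
        vocabulary = sorted(vocab)
    index = {k: j for j, k in enumerate(vocabulary)}
    X = np.zeros((len(descriptors), len(vocabulary)), dtype=float)
    for i, d in enumerate(descriptors):
        for k, v in d.entries.items():
            j = index.get(k)
            if j is not None:
                X[i, j] = float(v)
    return X, tuple(vocabulary)


def _standardize_fit(X: np.ndarray):
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0.0] = 1.0
    return mean, scale


def make_folds(y: np.ndarray, task: str, folds: int, seed: int):
    """Seeded fold assignment: stratified by class, or by response quartile
    (rank-based, ties broken by position) for regression."""
    y = np.asarray(y)
    n = len(y)
    if folds < 2 or folds > n:
        raise TrainingError(f"need 2 <= folds <= n, got folds={folds}, n={n}")
    if task == "classification":
        strata = y.astype(int)
    else:
        order = np.argsort(y, kind="stable")
        rank = np.empty(n, dtype=int)
        rank[order] = np.arange(n)
        strata = (rank * 4) // n
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(n), strata))


def _pooled_score(y_true, y_pred, task: str) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if task == "classification":
        return float(np.mean(y_true == y_pred))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


def _cross_validate(fit_predict, X, y, splits, task):
    """Out-of-fold predictions for every sample exactly once."""
    oof = np.empty(len(y), dtype=float)
    per_fold = []
    for train_idx, test_idx in splits:
        pred = fit_predict(X[train_idx], y[train_idx], X[test_idx])
        oof[test_idx] = pred
        per_fold.append(_pooled_score(y[test_idx], pred, task))
    return oof, per_fold


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _check_targets(y: np.ndarray, task: str):
    if task == "classification":
        if len(np.unique(y)) < 2:
            raise TrainingError("single-class response: nothing to fit")
    elif float(np.std(y)) == 0.0:
        raise TrainingError("zero-variance response: nothing to fit")


def train_svm(
    spec: EndpointSpec,
    X: np.ndarray,
    y: np.ndarray,
    grid: Mapping[str, Sequence[float]] | None = None,
    folds: int = 10,
    seed: int = 0,
    epsilon: float = 0.1,
) -> TrainedModel:
    """Exhaustive RBF (gamma, cost) grid search under seeded k-fold CV.

    Classification selects by CV accuracy, regression by CV Q2 (pooled
    out-of-fold predictive accuracy); ties go to the first grid point in
    (gamma, cost) iteration order. The winner is refit on all data.
    """
    if spec.learner != "svm":
        raise ConfigurationError(f"{spec.name} is not an SVM endpoint")
    grid = grid or DEFAULT_GRID
    gammas, costs = list(grid["gamma"]), list(grid["cost"])
    if not gammas or not costs:
        raise TrainingError("empty hyperparameter grid")
    X = np.asarray(X, dtype=float)
    y_nat = np.asarray(y, dtype=float)
    if X.shape[0] != len(y_nat):
        raise TrainingError("X and y row counts differ")
    if spec.task == "classification":
        yt = y_nat.astype(int).astype(float)
    else:
        yt = transform_forward(y_nat, spec.transform)
    _check_targets(yt, spec.task)
    x_mean, x_scale = _standardize_fit(X)
    Xs = (X - x_mean) / x_scale
    splits = make_folds(yt, spec.task, folds, seed)

    def _fit(gamma, cost):
        if spec.task == "classification":
            return SVC(kernel="rbf", gamma=gamma, C=cost)
        return SVR(kernel="rbf", gamma=gamma, C=cost, epsilon=epsilon)

    best = None
    for gamma in gammas:
        for cost in costs:
            def fp(Xtr, ytr, Xte, gamma=gamma, cost=cost):
                est = _fit(gamma, cost)
                est.fit(Xtr, ytr)
                return est.predict(Xte)

            oof, per_fold = _cross_validate(fp, Xs, yt, splits, spec.task)
            score = _pooled_score(yt, oof, spec.task)
            if best is None or score > best[0]:
                best = (score, gamma, cost, per_fold)
    score, gamma, cost, per_fold = best
    est = _fit(gamma, cost)
    est.fit(Xs, yt)
    if spec.task == "classification":
        # fold decision_function sign into a +/-1 dual-coef convention so the
        # reimplemented decision() maps >0 to the positive class
        dual = est.dual_coef_[0].astype(float)
        intercept = float(est.intercept_[0])
        if est.classes_[1] != 1:  # pragma: no cover - classes are {0,1} coded
            dual, intercept = -dual, -intercept
    else:
        dual = est.dual_coef_[0].astype(float)
        intercept = float(est.intercept_[0])
    return TrainedModel(
        spec=spec,
        feature_index=(),  # filled by train_endpoint when descriptors are known
        parameters={
            "kind": "svm",
            "support_vectors": est.support_vectors_.astype(float),
            "dual_coef": dual,
            "intercept": intercept,
            "gamma": float(gamma),
            "cost": float(cost),
            "epsilon": float(epsilon),
            "x_mean": x_mean,
            "x_scale": x_scale,
        },
        cv_report=CVReport(folds=folds, per_fold_scores=tuple(per_fold), aggregate=score, seed=seed),
        training_meta={"n": int(X.shape[0]), "seed": seed,
                       "grid": {"gamma": [float(g) for g in gammas], "cost": [float(c) for c in costs]}},
    )


def train_pls(
    spec: EndpointSpec,
    X: np.ndarray,
    y: np.ndarray,
    n_components: int | None = None,
    folds: int = 10,
    seed: int = 0,
) -> TrainedModel:
    """PLS regression / PLS-DA with a fixed number of latent components."""
    if spec.learner not in ("pls", "pls_da"):
        raise ConfigurationError(f"{spec.name} is not a PLS endpoint")
    n_components = n_components or spec.n_components
    X = np.asarray(X, dtype=float)
    y_nat = np.asarray(y, dtype=float)
    if X.shape[0] != len(y_nat):
        raise TrainingError("X and y row counts differ")
    n, p = X.shape
    max_comp = min(n - math.ceil(n / folds), p)
    if n_components > max_comp:
        raise TrainingError(
            f"n_components={n_components} exceeds what n={n}, p={p}, folds={folds} permit ({max_comp})"
        )
    if spec.task == "classification":
        yt = y_nat.astype(int).astype(float)  # coded 0/1 response
    else:
        yt = transform_forward(y_nat, spec.transform)
    _check_targets(yt, spec.task)
    x_mean, x_scale = _standardize_fit(X)
    Xs = (X - x_mean) / x_scale
    splits = make_folds(yt, spec.task, folds, seed)

    def fp(Xtr, ytr, Xte):
        pls = PLSRegression(n_components=n_components, scale=False)
        pls.fit(Xtr, ytr)
        pred = (Xte @ pls.coef_.T + pls.intercept_).ravel()
        if spec.task == "classification":
            pred = (pred > 0.5).astype(float)
        return pred

    oof, per_fold = _cross_validate(fp, Xs, yt, splits, spec.task)
    aggregate = _pooled_score(yt, oof, spec.task)
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Xs, yt)
    return TrainedModel(
        spec=spec,
        feature_index=(),
        parameters={
            "kind": "pls",
            "coef": pls.coef_.ravel().astype(float),
            "intercept": float(np.asarray(pls.intercept_).ravel()[0]),
            "n_components": int(n_components),
            "x_mean": x_mean,
            "x_scale": x_scale,
        },
        cv_report=CVReport(folds=folds, per_fold_scores=tuple(per_fold), aggregate=aggregate, seed=seed),
        training_meta={"n": int(n), "seed": seed, "grid": None},
    )


def train_endpoint(
    name: str,
    descriptors: Sequence[DescriptorVector],
    y: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    grid: Mapping[str, Sequence[float]] | None = None,
    max_height: int | None = None,
) -> TrainedModel:
    """Featurize + train one named endpoint; freezes the signature vocabulary."""
    if name not in ENDPOINTS:
        raise ConfigurationError(f"unknown endpoint {name!r}")
    spec = ENDPOINTS[name]
    X, vocab = build_feature_matrix(descriptors)
    if spec.learner == "svm":
        model = train_svm(spec, X, y, grid=grid, folds=folds, seed=seed)
    else:
        model = train_pls(spec, X, y, folds=folds, seed=seed)
    model.feature_index = vocab
    if max_height is None:
        max_height = max(d.max_height for d in descriptors)
    model.training_meta["max_height"] = int(max_height)
    return model


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ADMEProfile:
    """The nine endpoint values/classes plus alert flags for one compound."""

    f_abs_p: float
    f_diss: float
    CL_int: float  # mL/min, in vivo whole-liver intrinsic clearance
    f_u: float
    cbl_cpl: float  # blood-to-plasma concentration ratio
    CL_bile: float  # mL/min
    cyp3a4: bool
    mdr1: bool
    bcrp: bool
    alerts: AlertFlags = AlertFlags()

    def __post_init__(self):
        for name in ("f_abs_p", "f_diss"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if not 0.0 < self.f_u <= 1.0:
            raise ValueError(f"f_u={self.f_u} outside (0,1]")
        if self.CL_int < 0 or self.CL_bile < 0:
            raise ValueError("clearances must be >= 0")
        if self.cbl_cpl <= 0:
            raise ValueError("cbl_cpl must be > 0")


def predict_endpoint(model: TrainedModel, d: DescriptorVector):
    """Apply one trained endpoint model to a descriptor vector."""
    return model.predict(d)


def predict_profile(
    registry: Mapping[str, TrainedModel],
    compound: Compound,
    patterns: dict | None = None,
) -> ADMEProfile:
    """Run all nine endpoint models plus the structural alerts."""
    missing = [e for e in ENDPOINTS if e not in registry]
    if missing:
        raise ConfigurationError(f"{missing[0]} model absent (missing: {missing})")
    cache: dict[int, DescriptorVector] = {}
    values: dict = {}
    for name, model in ((e, registry[e]) for e in ENDPOINTS):
        h = int(model.training_meta.get("max_height", 3))
        if h not in cache:
            cache[h] = compute_signatures(compound, h)
        out = model.predict(cache[h])
        values[name] = out[0] if model.spec.task == "classification" else out
    return ADMEProfile(alerts=detect_alerts(compound, patterns), **values)


# ---------------------------------------------------------------------------
# persistence: JSON bundle, bit-identical round trip
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path) -> None:
    params = {}
    for k, v in model.parameters.items():
        params[k] = v.tolist() if isinstance(v, np.ndarray) else v
    doc = {
        "schema_version": SCHEMA_VERSION,
        "spec": {
            "name": model.spec.name,
            "task": model.spec.task,
            "learner": model.spec.learner,
            "transform": model.spec.transform,
            "n_components": model.spec.n_components,
            "value_range": [
                None if math.isinf(b) else b for b in model.spec.value_range
            ],
        },
        "feature_index": list(model.feature_index),
        "parameters": params,
        "cv_report": {
            "folds": model.cv_report.folds,
            "per_fold_scores": list(model.cv_report.per_fold_scores),
            "aggregate": model.cv_report.aggregate,
            "seed": model.cv_report.seed,
        },
        "training_meta": model.training_meta,
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1) + "\n")


def load_model(path) -> TrainedModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ConfigurationError(f"unsupported bundle schema in {path}")
    s = doc["spec"]
    lo, hi = s["value_range"]
    spec = EndpointSpec(
        name=s["name"],
        task=s["task"],
        learner=s["learner"],
        transform=s["transform"],
        n_components=s["n_components"],
        value_range=(-math.inf if lo is None else lo, math.inf if hi is None else hi),
    )
    params = {}
    for k, v in doc["parameters"].items():
        params[k] = np.asarray(v, dtype=float) if isinstance(v, list) else v
    cv = doc["cv_report"]
    return TrainedModel(
        spec=spec,
        feature_index=tuple(doc["feature_index"]),
        parameters=params,
        cv_report=CVReport(
            folds=cv["folds"],
            per_fold_scores=tuple(cv["per_fold_scores"]),
            aggregate=cv["aggregate"],
            seed=cv["seed"],
        ),
        training_meta=doc["training_meta"],
    )
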