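"""Endpoint model training, prediction, persistence and profiles."""
import json
import math

import numpy as np
import pytest

from bioavail import chemstruct, synthetic
from bioavail import qsar
from bioavail.qsar import (
    ENDPOINTS,
    ConfigurationError,
    EndpointSpec,
    TrainingError,
    build_feature_matrix,
    load_model,
    make_folds,
    predict_profile,
    save_model,
    train_pls,
    train_svm,
    transform_forward,
    transform_inverse,
)

from conftest import TINY_GRID

IDENTITY_PLS = EndpointSpec("f_diss", "regression", "pls", "identity", 6)


def test_transform_roundtrip():
    y = np.array([0.01, 0.2, 0.5, 0.9, 0.99])
    for t in ("identity", "logit"):
        assert transform_inverse(transform_forward(y, t), t) == pytest.approx(y, abs=1e-9)
    cl = np.array([0.5, 5.0, 500.0, 5e4])
    assert transform_inverse(transform_forward(cl, "log10"), "log10") == pytest.approx(cl)


def test_endpoint_registry_learner_task_pairings():
    svm = {n for n, s in ENDPOINTS.items() if s.learner == "svm"}
    pls = {n for n, s in ENDPOINTS.items() if s.learner == "pls"}
    pls_da = {n for n, s in ENDPOINTS.items() if s.learner == "pls_da"}
    assert svm == {"f_abs_p", "CL_int", "cyp3a4"}
    assert pls == {"f_u", "f_diss", "CL_bile", "cbl_cpl"}
    assert pls_da == {"mdr1", "bcrp"}
    for spec in ENDPOINTS.values():
        if spec.learner != "svm":
            assert 4 <= spec.n_components <= 8


def test_fold_partition_covers_each_sample_once():
    y = np.random.default_rng(0).normal(size=57)
    splits = make_folds(y, "regression", 10, seed=3)
    seen = np.concatenate([test for _, test in splits])
    assert sorted(seen) == list(range(57))
    y_cls = np.array([0] * 30 + [1] * 27)
    for _, test in make_folds(y_cls, "classification", 3, seed=3):
        frac = y_cls[test].mean()
        assert 0.3 < frac < 0.65  # stratification keeps the class mix


# ---------------------------------------------------------------------------
# SVM training
# ---------------------------------------------------------------------------

def _separable_xy(n=120, seed=5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 6))
    y = (X[:, 0] + X[:, 1] > 0.0).astype(int)
    keep = np.abs(X[:, 0] + X[:, 1]) > 0.4
    return X[keep], y[keep]


def test_svm_separable_classes_high_cv_accuracy():
    X, y = _separable_xy()
    m = train_svm(ENDPOINTS["cyp3a4"], X, y, grid=TINY_GRID, folds=10, seed=1)
    assert m.cv_report.aggregate >= 0.95
    assert len(m.cv_report.per_fold_scores) == 10


def test_svm_grid_search_reproducible():
    X, y = _separable_xy()
    a = train_svm(ENDPOINTS["cyp3a4"], X, y, grid=TINY_GRID, folds=5, seed=9)
    b = train_svm(ENDPOINTS["cyp3a4"], X, y, grid=TINY_GRID, folds=5, seed=9)
    assert (a.parameters["gamma"], a.parameters["cost"]) == (b.parameters["gamma"], b.parameters["cost"])
    assert a.cv_report == b.cv_report


def test_svm_constant_response_errors():
    X = np.random.default_rng(0).normal(size=(30, 4))
    with pytest.raises(TrainingError):
        train_svm(ENDPOINTS["cyp3a4"], X, np.ones(30), grid=TINY_GRID, folds=5, seed=0)
    with pytest.raises(TrainingError):
        train_svm(ENDPOINTS["f_abs_p"], X, np.full(30, 0.5), grid=TINY_GRID, folds=5, seed=0)


def test_svm_conflicting_labels_bounded_by_majority():
    # identical rows, 60/40 label split: no model can beat the majority class
    X = np.ones((30, 3))
    y = np.array([1] * 18 + [0] * 12)
    m = train_svm(ENDPOINTS["cyp3a4"], X, y, grid=TINY_GRID, folds=5, seed=2)
    assert m.cv_report.aggregate <= 18 / 30 + 1e-12


# ---------------------------------------------------------------------------
# PLS training
# ---------------------------------------------------------------------------

def test_pls_exact_recovery_of_noiseless_linear_response():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(60, 6))
    y = X @ rng.normal(size=6) + 1.7
    m = train_pls(IDENTITY_PLS, X, y, n_components=6, folds=5, seed=0)
    x_mean, x_scale = np.asarray(m.parameters["x_mean"]), np.asarray(m.parameters["x_scale"])
    Xs = (X - x_mean) / x_scale
    fitted = Xs @ np.asarray(m.parameters["coef"]) + m.parameters["intercept"]
    q2_train = 1 - np.sum((fitted - y) ** 2) / np.sum((y - y.mean()) ** 2)
    assert q2_train == pytest.approx(1.0, abs=1e-9)


def test_pls_permuted_response_has_no_predictive_power():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(200, 10))
    y = X @ rng.normal(size=10)
    y_perm = rng.permutation(y)
    m = train_pls(IDENTITY_PLS, X, y_perm, n_components=4, folds=10, seed=1)
    assert m.cv_report.aggregate <= 0.1


def test_pls_da_separable_classes():
    X, y = _separable_xy(n=200, seed=6)
    m = train_pls(ENDPOINTS["mdr1"], X, y, n_components=4, folds=10, seed=1)
    assert m.cv_report.aggregate >= 0.95


def test_pls_component_budget_enforced():
    X = np.random.default_rng(0).normal(size=(12, 40))
    y = X[:, 0]
    with pytest.raises(TrainingError, match="n_components"):
        train_pls(IDENTITY_PLS, X, y, n_components=8, folds=2, seed=0)


# ---------------------------------------------------------------------------
# prediction and persistence
# ---------------------------------------------------------------------------

def test_training_set_prediction_bit_identical_after_reload(tmp_path, registry):
    ds = synthetic.generate_endpoint_dataset("f_u", 30, noise_sd=0.05, seed=12, max_height=1)
    model = registry["f_u"]
    path = tmp_path / "f_u.json"
    save_model(model, path)
    reloaded = load_model(path)
    assert reloaded.feature_index == tuple(model.feature_index)
    for d in ds.descriptors[:10]:
        assert reloaded.predict(d) == model.predict(d)  # bit-identical
    save_model(reloaded, tmp_path / "again.json")
    assert (tmp_path / "again.json").read_bytes() == path.read_bytes()


def test_unknown_signatures_fall_back_to_baseline(registry):
    model = registry["f_u"]
    strange = chemstruct.DescriptorVector(entries={"h0|Xx": 3}, max_height=0)
    empty = chemstruct.DescriptorVector(entries={}, max_height=0)
    assert model.predict(strange) == model.predict(empty)


def test_regression_output_clipped_into_valid_range_with_warning():
    spec = EndpointSpec("f_u", "regression", "pls", "identity", 4, (0.0, 1.0))
    model = qsar.TrainedModel(
        spec=spec,
        feature_index=("h0|C",),
        parameters={"kind": "pls", "coef": np.array([0.0]), "intercept": 1.3,
                    "x_mean": np.array([0.0]), "x_scale": np.array([1.0])},
        cv_report=qsar.CVReport(folds=2, per_fold_scores=(0.0, 0.0), aggregate=0.0, seed=0),
        training_meta={},
    )
    d = chemstruct.DescriptorVector(entries={"h0|C": 1}, max_height=0)
    with pytest.warns(UserWarning, match="clipped"):
        assert model.predict(d) == 1.0


def test_profile_runs_all_endpoints_and_propagates_alerts(registry, paracetamol):
    profile = predict_profile(registry, paracetamol)
    assert profile.alerts.phenol
    assert 0.0 <= profile.f_abs_p <= 1.0
    assert 0.0 <= profile.f_diss <= 1.0
    assert 0.0 < profile.f_u <= 1.0
    assert profile.CL_int >= 0.0 and profile.CL_bile >= 0.0
    assert profile.cbl_cpl > 0.0
    for flag in (profile.cyp3a4, profile.mdr1, profile.bcrp):
        assert isinstance(flag, (bool, np.bool_))


def test_profile_missing_endpoint_names_it(registry, paracetamol):
    partial = {k: v for k, v in registry.items() if k != "CL_bile"}
    with pytest.raises(ConfigurationError, match="CL_bile"):
        predict_profile(partial, paracetamol)


def test_profile_invariants_enforced():
    with pytest.raises(ValueError):
        qsar.ADMEProfile(f_abs_p=1.2, f_diss=1.0, CL_int=0.0, f_u=0.5, cbl_cpl=1.0,
                         CL_bile=0.0, cyp3a4=False, mdr1=False, bcrp=False)
    with pytest.raises(ValueError):
        qsar.ADMEProfile(f_abs_p=0.5, f_diss=1.0, CL_int=-1.0, f_u=0.5, cbl_cpl=1.0,
                         CL_bile=0.0, cyp3a4=False, mdr1=False, bcrp=False)
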