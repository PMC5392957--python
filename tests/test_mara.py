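"""Activity fitting: oracle equivalence, gauge, recovery, ridge behavior."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import maranet as mn
from maranet import pipeline

from conftest import SMALL


def brute_force_ridge(expr: pd.DataFrame, sitecounts: pd.DataFrame, lam: float) -> np.ndarray:
    """Independent route: augmented least squares per sample on the
    doubly-centered data (no normal-equations solve)."""
    e = expr.to_numpy(dtype=float)
    ecc = e - e.mean(axis=0) - e.mean(axis=1, keepdims=True) + e.mean()
    x = sitecounts.to_numpy(dtype=float).T
    xc = x - x.mean(axis=0)
    n_motifs = xc.shape[1]
    aug = np.vstack([xc, np.sqrt(lam) * np.eye(n_motifs)])
    a = np.empty((n_motifs, e.shape[1]))
    for s in range(e.shape[1]):
        rhs = np.concatenate([ecc[:, s], np.zeros(n_motifs)])
        a[:, s] = np.linalg.lstsq(aug, rhs, rcond=None)[0]
    return a


@pytest.fixture(scope="module")
def oracle_case():
    rng = np.random.default_rng(42)
    motifs = [f"m{i}" for i in range(5)]
    promoters = [f"p{i}" for i in range(10)]
    samples = [f"s{i}" for i in range(4)]
    counts = pd.DataFrame(
        rng.poisson(1.0, size=(5, 10)).astype(float), index=motifs, columns=promoters
    )
    expr = pd.DataFrame(rng.normal(5.0, 1.0, size=(10, 4)), index=promoters, columns=samples)
    return expr, counts


def test_fit_matches_brute_force_solution(oracle_case):
    expr, counts = oracle_case
    for lam in (0.5, 1.0, 4.0):
        model = mn.fit_mara(expr, counts, ridge_lambda=lam)
        oracle = brute_force_ridge(expr, counts, lam)
        oracle -= oracle.mean(axis=1, keepdims=True)
        assert np.abs(model.activities.to_numpy() - oracle).max() < 1e-8


def test_single_motif_closed_form():
    # 3 promoters x 2 samples x 1 motif: A_s = x'e_s / (x'x + lambda)
    expr = pd.DataFrame(
        [[1.0, 3.0], [2.0, 2.0], [6.0, 1.0]], index=["p1", "p2", "p3"], columns=["s1", "s2"]
    )
    counts = pd.DataFrame([[1.0, 0.0, 2.0]], index=["m1"], columns=["p1", "p2", "p3"])
    lam = 0.7
    e = expr.to_numpy()
    ecc = e - e.mean(axis=0) - e.mean(axis=1, keepdims=True) + e.mean()
    x = counts.to_numpy().ravel()
    xc = x - x.mean()
    expected = xc @ ecc / (xc @ xc + lam)
    model = mn.fit_mara(expr, counts, ridge_lambda=lam)
    assert np.abs(model.activities.to_numpy().ravel() - expected).max() < 1e-8


def test_zero_sitecounts_give_zero_activities(oracle_case):
    expr, counts = oracle_case
    zeros = pd.DataFrame(0.0, index=counts.index, columns=counts.columns)
    model = mn.fit_mara(expr, zeros, ridge_lambda=1.0)
    assert (model.activities.to_numpy() == 0).all()
    assert (model.activity_errors.to_numpy() > 0).all()
    assert np.isfinite(model.activity_errors.to_numpy()).all()
    np.testing.assert_allclose(model.sample_means, expr.mean(axis=0))
    centered = expr - expr.mean(axis=0)
    np.testing.assert_allclose(model.promoter_baselines, centered.mean(axis=1))
    assert model.inestimable == list(counts.index)


def test_noiseless_fit_recovers_planted_activities():
    cfg = dataclasses.replace(SMALL, noise_sd=0.0)
    bundle = mn.generate_bundle(cfg)
    model = mn.fit_mara(bundle.expression["D0"], bundle.sitecounts, ridge_lambda=1e-8)
    true = bundle.truth.true_activities["D0"].to_numpy()
    true = true - true.mean(axis=1, keepdims=True)  # zero-sum gauge
    assert np.abs(model.activities.to_numpy() - true).max() < 1e-6


def test_zero_sum_gauge_holds_to_machine_precision(small_models):
    for model in small_models.values():
        scale = np.abs(model.activities.to_numpy()).max()
        assert np.abs(model.activities.sum(axis=1)).max() <= 1e-12 * max(scale, 1.0)


def test_ridge_monotonically_shrinks_activities(oracle_case):
    expr, counts = oracle_case
    norms = [
        np.linalg.norm(mn.fit_mara(expr, counts, ridge_lambda=lam).activities)
        for lam in (0.1, 1.0, 10.0, 100.0)
    ]
    assert all(a > b for a, b in zip(norms, norms[1:]))


def test_singular_system_requires_positive_lambda():
    expr = pd.DataFrame(
        np.arange(8, dtype=float).reshape(4, 2), index=list("abcd"), columns=["s1", "s2"]
    )
    counts = pd.DataFrame(
        [[1.0, 2.0, 0.0, 1.0], [1.0, 2.0, 0.0, 1.0]],  # duplicated motif row
        index=["m1", "m2"],
        columns=list("abcd"),
    )
    with pytest.raises(np.linalg.LinAlgError, match="ridge_lambda"):
        mn.fit_mara(expr, counts, ridge_lambda=0.0)


def test_prediction_reproduces_noiseless_input():
    cfg = dataclasses.replace(SMALL, noise_sd=0.0)
    bundle = mn.generate_bundle(cfg)
    expr = bundle.expression["D1"]
    model = mn.fit_mara(expr, bundle.sitecounts, ridge_lambda=1e-8)
    pred = mn.predict_expression(model, bundle.sitecounts)
    assert np.abs((pred - expr).to_numpy()).max() < 1e-6


def test_prediction_with_zero_activities_is_additive(oracle_case):
    expr, counts = oracle_case
    zeros = pd.DataFrame(0.0, index=counts.index, columns=counts.columns)
    model = mn.fit_mara(expr, zeros, ridge_lambda=1.0)
    pred = mn.predict_expression(model, counts)
    expected = np.add.outer(
        model.promoter_baselines.to_numpy(), model.sample_means.to_numpy()
    )
    np.testing.assert_allclose(pred.to_numpy(), expected)


def test_fit_residuals_have_zero_mean_per_sample(small_bundle, small_models):
    model = small_models["D0"]
    pred = mn.predict_expression(model, small_bundle.sitecounts)
    resid = small_bundle.expression["D0"] - pred
    assert np.abs(resid.mean(axis=0)).max() < 1e-10


def test_activity_profile_shape_and_step(small_bundle, small_models):
    model = small_models["D0"]
    motif = small_bundle.truth.active_motifs[0]
    prof = mn.activity_profile(model, motif)
    assert list(prof.columns) == ["sample_id", "activity", "error"]
    assert list(prof["sample_id"]) == model.sample_ids
    # planted condition step: a-samples and b-samples sit on opposite sides
    cond = small_bundle.manifest.set_index("sample_id")["condition"]
    signs = np.sign(prof.set_index("sample_id")["activity"])
    by_cond = signs.groupby(cond.reindex(signs.index)).nunique()
    assert (by_cond == 1).all()
    sign = small_bundle.truth.motif_signs[motif]
    b_mean = prof.set_index("sample_id")["activity"][cond == "b"].mean()
    assert np.sign(b_mean) == sign

    with pytest.raises(KeyError, match="nonexistent"):
        mn.activity_profile(model, "nonexistent")


def test_activity_errors_shrink_with_noise():
    quiet = dataclasses.replace(SMALL, noise_sd=0.05)
    loud = dataclasses.replace(SMALL, noise_sd=0.4)
    errs = {}
    for cfg in (quiet, loud):
        bundle = mn.generate_bundle(cfg)
        model = mn.fit_mara(bundle.expression["D0"], bundle.sitecounts)
        errs[cfg.noise_sd] = model.activity_errors.to_numpy().mean()
    assert errs[0.05] < errs[0.4]


def test_activity_recovery_on_default_fixture(default_bundle):
    models = pipeline.fit_all(default_bundle.expression, default_bundle.sitecounts)
    for ds, model in models.items():
        true = default_bundle.truth.true_activities[ds].to_numpy().ravel()
        fitted = model.activities.to_numpy().ravel()
        r = np.corrcoef(true, fitted)[0, 1]
        assert r >= 0.9


def test_cross_validated_lambda_is_from_grid(small_bundle):
    expr = small_bundle.expression["D0"].iloc[:60]
    counts = small_bundle.sitecounts[expr.index]
    lam = mn.choose_lambda_cv(expr, counts, lambdas=(0.3, 1.0, 3.0), n_folds=3, seed=1)
    assert lam in (0.3, 1.0, 3.0)
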