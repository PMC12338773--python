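"""Group-contribution fitting, prediction, and condition-transform tests."""

import math

import numpy as np
import pytest

from retrostoic.thermo import (
    GibbsEstimate,
    R_KJ,
    RankDeficiencyError,
    T_STANDARD,
    adjust_concentrations,
    fit_group_contribution,
    predict_reaction_dg,
    transform_conditions,
)

KEYS = [f"k{i}" for i in range(6)]


def _random_training(rng, beta, n, noise_sd=0.0):
    rows = []
    for _ in range(n):
        delta = {
            k: int(v)
            for k, v in zip(KEYS, rng.integers(-3, 4, len(KEYS)))
            if v
        }
        y = sum(beta[k] * v for k, v in delta.items())
        rows.append((delta, y + rng.normal(0.0, noise_sd)))
    return rows


def test_noiseless_recovery_matches_normal_equations():
    """With a full-rank design and lambda -> 0, beta solves X'Xb = X'y exactly."""
    rng = np.random.default_rng(7)
    beta_true = {k: float(b) for k, b in zip(KEYS, rng.normal(0, 30, len(KEYS)))}
    training = _random_training(rng, beta_true, 25)
    model = fit_group_contribution(training, ridge_lambda=1e-12)
    # independent closed-form oracle
    X = np.array([[d.get(k, 0) for k in model.keys] for d, _ in training], float)
    y = np.array([v for _, v in training])
    beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
    np.testing.assert_allclose(
        [model.beta[k] for k in model.keys], beta_oracle, atol=1e-6
    )
    np.testing.assert_allclose(
        [model.beta[k] for k in KEYS], [beta_true[k] for k in KEYS], atol=1e-6
    )


def test_zero_delta_rows_and_prediction():
    rng = np.random.default_rng(3)
    beta_true = {k: float(b) for k, b in zip(KEYS, rng.normal(0, 10, len(KEYS)))}
    training = _random_training(rng, beta_true, 20) + [({}, 0.0)]
    model = fit_group_contribution(training, ridge_lambda=1e-10)
    est = predict_reaction_dg({}, model)
    assert est.mean == 0.0 and est.sd == 0.0


def test_duplicate_rows_equal_double_weight():
    """Duplicating a training row is the same as doubling its weight at lambda=0."""
    rng = np.random.default_rng(11)
    beta_true = {k: float(b) for k, b in zip(KEYS, rng.normal(0, 10, len(KEYS)))}
    base = _random_training(rng, beta_true, 12, noise_sd=2.0)
    dup = base + [base[0]]
    model_dup = fit_group_contribution(dup, ridge_lambda=0.0)
    # weighted least-squares oracle with weight 2 on row 0
    X = np.array([[d.get(k, 0) for k in model_dup.keys] for d, _ in base], float)
    y = np.array([v for _, v in base])
    w = np.ones(len(base)); w[0] = 2.0
    beta_w = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y))
    np.testing.assert_allclose(
        [model_dup.beta[k] for k in model_dup.keys], beta_w, atol=1e-8
    )


def test_rank_deficiency_requires_ridge():
    rows = [({"a": 1, "b": 1}, 5.0), ({"a": 2, "b": 2}, 10.0)]
    with pytest.raises(RankDeficiencyError, match="ridge_lambda"):
        fit_group_contribution(rows, ridge_lambda=0.0)
    model = fit_group_contribution(rows, ridge_lambda=1e-6)  # regularized: fine
    assert model.training_n == 2


def test_prediction_linearity_and_antisymmetry():
    rng = np.random.default_rng(5)
    beta_true = {k: float(b) for k, b in zip(KEYS, rng.normal(0, 20, len(KEYS)))}
    model = fit_group_contribution(_random_training(rng, beta_true, 30), 1e-9)
    d1 = {"k0": 1, "k2": -2}
    d2 = {"k2": 1, "k4": 3}
    p1, p2 = predict_reaction_dg(d1, model), predict_reaction_dg(d2, model)
    combined = predict_reaction_dg(
        {k: d1.get(k, 0) + d2.get(k, 0) for k in set(d1) | set(d2)}, model
    )
    assert combined.mean == pytest.approx(p1.mean + p2.mean, abs=1e-9)
    reverse = predict_reaction_dg({k: -v for k, v in d1.items()}, model)
    assert reverse.mean == pytest.approx(-p1.mean, abs=1e-9)
    assert reverse.sd == pytest.approx(p1.sd, abs=1e-9)
    # independent dot-product oracle
    assert p1.mean == pytest.approx(
        sum(model.beta[k] * v for k, v in d1.items()), abs=1e-9
    )


def test_unseen_moiety_flagged_with_penalty():
    model = fit_group_contribution([({"a": 1}, -3.0), ({"a": 2}, -6.0)], 1e-9)
    est = predict_reaction_dg({"a": 1, "zz": 2}, model, unseen_penalty=10.0)
    assert any("zz" in f for f in est.flags)
    base = predict_reaction_dg({"a": 1}, model)
    assert est.sd == pytest.approx(base.sd + 20.0)
    assert est.mean == pytest.approx(base.mean)


def test_parameter_recovery_under_noise():
    """50 synthetic reactions over 10 moieties, 1 kJ/mol noise: RMSE(beta) < 1."""
    rng = np.random.default_rng(42)
    keys = [f"m{i}" for i in range(10)]
    beta_true = {k: float(b) for k, b in zip(keys, rng.normal(0, 30, 10))}
    rows = []
    for _ in range(50):
        delta = {k: int(v) for k, v in zip(keys, rng.integers(-3, 4, 10)) if v}
        y = sum(beta_true[k] * v for k, v in delta.items()) + rng.normal(0, 1.0)
        rows.append((delta, y))
    model = fit_group_contribution(rows, ridge_lambda=1e-6)
    rmse = math.sqrt(
        np.mean([(model.beta[k] - beta_true[k]) ** 2 for k in keys])
    )
    assert rmse < 1.0


# ---------------------------------------------------------------------------
# Condition transforms

def test_ph_shift_adds_rt_ln10_per_proton():
    est = GibbsEstimate(mean=-10.0, sd=1.0, conditions=(7.0, 0.0, T_STANDARD))
    moved = transform_conditions(est, delta_nH=1, delta_z2=0, pH=8.0, ionic_strength=0.0)
    assert moved.mean - est.mean == pytest.approx(5.708, abs=1e-3)
    assert moved.sd == est.sd


def test_zero_ionic_strength_no_debye_huckel():
    est = GibbsEstimate(mean=2.0, sd=0.5, conditions=(7.0, 0.0, T_STANDARD))
    same_ph = transform_conditions(est, delta_nH=3, delta_z2=-2, pH=7.0, ionic_strength=0.0)
    assert same_ph.mean == pytest.approx(est.mean)


def test_identity_transform_unchanged():
    est = GibbsEstimate(mean=-4.2, sd=0.7, conditions=(6.5, 0.1, T_STANDARD))
    out = transform_conditions(est, delta_nH=2, delta_z2=1, pH=6.5, ionic_strength=0.1)
    assert out.mean == pytest.approx(est.mean) and out.sd == est.sd


def test_transform_argument_errors_and_warning():
    est = GibbsEstimate(mean=0.0, sd=0.0)
    with pytest.raises(ValueError):
        transform_conditions(est, 1, 0, pH=15.0, ionic_strength=0.0)
    with pytest.raises(ValueError):
        transform_conditions(est, 1, 0, pH=7.0, ionic_strength=-0.1)
    with pytest.warns(UserWarning, match="298.15"):
        transform_conditions(est, 1, 0, pH=7.0, ionic_strength=0.0, temperature=310.0)


# ---------------------------------------------------------------------------
# Concentration adjustment

def test_standard_concentrations_unchanged():
    est = GibbsEstimate(mean=3.3, sd=0.2)
    out = adjust_concentrations(est, {"a": -1, "b": 1}, {"a": 1.0, "b": 1.0})
    assert out.mean == pytest.approx(est.mean)


def test_single_product_millimolar_shift():
    est = GibbsEstimate(mean=0.0, sd=0.0)
    out = adjust_concentrations(est, {"p": 1}, {"p": 1e-3})
    assert out.mean == pytest.approx(R_KJ * T_STANDARD * math.log(1e-3), abs=1e-6)
    assert out.mean == pytest.approx(-17.12, abs=0.01)


def test_concentration_window_tilts_positive_step_negative():
    """A +5 kJ/mol step becomes favorable with 10 mM substrate / 0.1 mM product."""
    est = GibbsEstimate(mean=5.0, sd=1.0)
    out = adjust_concentrations(
        est, {"s": -1, "p": 1}, {"s": 1e-2, "p": 1e-4}
    )
    assert out.mean < 0


def test_water_and_proton_excluded_and_errors():
    est = GibbsEstimate(mean=1.0, sd=0.0)
    out = adjust_concentrations(
        est, {"h2o": -1, "h": 1, "x": 1}, {"h2o": 1e-3, "h": 1e-7, "x": 1.0}
    )
    assert out.mean == pytest.approx(est.mean)
    with pytest.raises(ValueError):
        adjust_concentrations(est, {"x": 1}, {"x": 0.0})
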