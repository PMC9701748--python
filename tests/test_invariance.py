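"""Logistic fit, residuals and the Welch invariance test against oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import icpbin as icp


def make_dataset(x: np.ndarray | None, y: np.ndarray, env: np.ndarray | None = None):
    n = len(y)
    X = pd.DataFrame({"x": x}) if x is not None else pd.DataFrame(index=range(n))
    if x is None:
        X = pd.DataFrame({"x": np.zeros(n)})
    env = env if env is not None else np.zeros(n)
    return icp.Dataset(
        X=X,
        y=pd.Series(np.asarray(y, dtype=float)),
        env=pd.DataFrame({"env": np.asarray(env, dtype=float)}),
    )


def welch_oracle(a, b):
    """From-scratch Welch formula: statistic, Welch-Satterthwaite dof, p."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    v0, v1 = a.var(ddof=1), b.var(ddof=1)
    se2 = v0 / a.size + v1 / b.size
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    dof = se2**2 / ((v0 / a.size) ** 2 / (a.size - 1) + (v1 / b.size) ** 2 / (b.size - 1))
    p = 2.0 * stats.t.sf(abs(t), dof)
    return t, dof, p


class TestFitLogistic:
    def test_empty_subset_closed_form(self):
        y = np.r_[np.ones(25), np.zeros(75)]
        ds = make_dataset(None, y)
        fit = icp.fit_logistic(ds, ())
        assert fit.intercept == pytest.approx(np.log(0.25 / 0.75))
        np.testing.assert_allclose(fit.fitted_probs, 0.25)

    def test_two_by_two_log_odds_ratio(self):
        # events: 10/100 at x=0, 30/100 at x=1 -> slope log((30/70)/(10/90))
        x = np.r_[np.zeros(100), np.ones(100)]
        y = np.r_[np.ones(10), np.zeros(90), np.ones(30), np.zeros(70)]
        fit = icp.fit_logistic(make_dataset(x, y), ("x",))
        assert fit.slopes[0] == pytest.approx(np.log((30 / 70) / (10 / 90)), abs=1e-8)
        assert fit.intercept == pytest.approx(np.log(10 / 90), abs=1e-8)
        assert fit.converged and fit.regularization_used == "none"

    def test_matches_independent_glm_fit(self):
        statsmodels = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        x = rng.normal(size=400)
        y = (rng.random(400) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(float)
        fit = icp.fit_logistic(make_dataset(x, y), ("x",))
        ref = statsmodels.GLM(
            y, statsmodels.add_constant(x), family=statsmodels.families.Binomial()
        ).fit()
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-8)

    def test_perfect_separation_triggers_tiny_ridge(self):
        x = np.r_[np.linspace(-2, -0.1, 10), np.linspace(0.1, 2, 10)]
        y = np.r_[np.zeros(10), np.ones(10)]
        fit = icp.fit_logistic(make_dataset(x, y), ("x",))
        assert fit.regularization_used == "tiny-ridge"
        assert np.isfinite(fit.coefficients).all()
        assert ((fit.fitted_probs > 0) & (fit.fitted_probs < 1)).all()

    def test_single_class_outcome_raises(self):
        with pytest.raises(icp.DegenerateOutcomeError):
            icp.fit_logistic(make_dataset(np.arange(10.0), np.zeros(10)), ("x",))

    def test_unknown_predictor_raises(self, scm_dataset):
        with pytest.raises(icp.DataError):
            icp.fit_logistic(scm_dataset, ("nope",))


class TestResiduals:
    def test_intercept_only_two_values(self):
        y = np.r_[np.ones(1), np.zeros(3)]
        fit = icp.fit_logistic(make_dataset(None, y), ())
        r = icp.residuals(fit, y)
        assert set(np.round(r, 12)) == {-0.25, 0.75}

    def test_response_residuals_sum_to_zero(self, scm_dataset):
        fit = icp.fit_logistic(scm_dataset, ("X1", "X3"))
        r = icp.residuals(fit, scm_dataset.y.to_numpy())
        assert abs(r.sum()) < 1e-8

    def test_pearson_and_deviance_available(self, scm_dataset):
        fit = icp.fit_logistic(scm_dataset, ("X1",))
        y = scm_dataset.y.to_numpy()
        resp = icp.residuals(fit, y, kind="response")
        pear = icp.residuals(fit, y, kind="pearson")
        dev = icp.residuals(fit, y, kind="deviance")
        np.testing.assert_allclose(
            pear, resp / np.sqrt(fit.fitted_probs * (1 - fit.fitted_probs))
        )
        assert np.sign(dev).tolist() == np.sign(resp).tolist()

    def test_length_mismatch_raises(self, scm_dataset):
        fit = icp.fit_logistic(scm_dataset, ("X1",))
        with pytest.raises(icp.DataError):
            icp.residuals(fit, np.zeros(3))


class TestWelch:
    def test_identical_samples_accept_everywhere(self):
        r = np.r_[np.tile([1.0, -1.0], 2), np.tile([1.0, -1.0], 2)]
        env = np.r_[np.zeros(4), np.ones(4)]
        res = icp.invariance_test(r, env, alpha=0.5)
        assert res.t_statistic == 0.0 and res.p_value == 1.0 and res.accepted

    def test_hand_computed_example(self):
        res = icp.invariance_test(
            np.array([0.1, 0.2, 0.3, 1.1, 1.2, 1.3]),
            np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0]),
            alpha=0.01,
        )
        assert res.t_statistic == pytest.approx(-12.247, abs=1e-3)
        assert res.p_value < 0.001 and not res.accepted
        assert res.dof == pytest.approx(4.0)

    def test_oracle_equivalence_on_random_inputs(self):
        # 1,000 random small samples against the from-scratch Welch formula
        rng = np.random.default_rng(123)
        worst = 0.0
        for _ in range(1000):
            n0, n1 = rng.integers(2, 30, size=2)
            a = rng.normal(rng.uniform(-1, 1), rng.uniform(0.1, 3), size=n0)
            b = rng.normal(rng.uniform(-1, 1), rng.uniform(0.1, 3), size=n1)
            t, dof, p = icp.welch_test(a, b)
            t0, dof0, p0 = welch_oracle(a, b)
            worst = max(worst, abs(t - t0), abs(dof - dof0), abs(p - p0))
        assert worst < 1e-10

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_label_swap_flips_t_and_keeps_p(self, seed):
        rng = np.random.default_rng(seed)
        r = rng.normal(size=24)
        env = rng.permutation(np.r_[np.zeros(12), np.ones(12)])
        fwd = icp.invariance_test(r, env, alpha=0.05)
        rev = icp.invariance_test(r, 1.0 - env, alpha=0.05)
        assert fwd.t_statistic == pytest.approx(-rev.t_statistic)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_tiny_environment_level_raises(self):
        with pytest.raises(icp.UntestableEnvironmentError):
            icp.invariance_test(
                np.array([0.1, 0.2, 0.3]), np.array([0.0, 0.0, 1.0]), alpha=0.05
            )

    def test_acceptance_monotone_in_alpha(self, scm_dataset):
        res = icp.test_subset(scm_dataset, ("X1",), "env", alpha=0.0)
        p = res.p_value
        for lo, hi in [(0.01, 0.05), (0.05, 0.1)]:
            accept_hi = p >= hi
            accept_lo = p >= lo
            assert accept_lo or not accept_hi  # accepted at hi implies at lo


class TestTestSubset:
    def test_collider_child_rejected_in_majority(self, collider_spec):
        # the intervened child of the parent opens a non-invariant path
        rejected = 0
        for seed in range(20):
            ds = icp.simulate_scm(collider_spec, n_per_env=2000, seed=seed)
            res = icp.test_subset(ds, ("X2",), "env", alpha=0.1)
            rejected += not res.accepted
        assert rejected > 10

    def test_superset_of_parents_accepted(self, strong_spec):
        accepted = 0
        for seed in range(20):
            ds = icp.simulate_scm(strong_spec, n_per_env=2000, seed=100 + seed)
            res = icp.test_subset(
                ds, ("X1", "X2", "X3", "X4", "X5"), "env", alpha=0.05
            )
            accepted += res.accepted
        assert accepted >= 18

    def test_type_one_error_controlled(self, null_calibration_spec):
        rejections = 0
        n_reps = 500
        for seed in range(n_reps):
            ds = icp.simulate_scm(null_calibration_spec, n_per_env=250, seed=seed)
            res = icp.test_subset(ds, ("X1", "X2"), "env", alpha=0.05)
            rejections += not res.accepted
        se = np.sqrt(0.05 * 0.95 / n_reps)
        assert rejections / n_reps <= 0.05 + 2 * se

    def test_reversed_direction_flag(self, scm_dataset):
        std = icp.test_subset(scm_dataset, ("X1",), "env", alpha=0.05)
        rev = icp.test_subset(
            scm_dataset, ("X1",), "env", alpha=0.05, reject_direction="reversed"
        )
        assert std.accepted != rev.accepted

    def test_missing_env_rows_excluded(self, strong_spec):
        ds = icp.simulate_scm(strong_spec, n_per_env=500, seed=2)
        env = ds.env.copy()
        env.loc[:49, "env"] = np.nan
        masked = icp.Dataset(X=ds.X, y=ds.y, env=env)
        res = icp.test_subset(masked, ("X1",), "env", alpha=0.05)
        assert sum(res.n_per_env) == ds.n - 50
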