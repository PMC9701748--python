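"""Subset enumeration, lasso screening and the intersection estimator."""

import numpy as np
import pytest

import icpbin as icp
from icpbin.model import n_subsets


class TestEnumerate:
    def test_three_predictors_all_subsets_in_order(self):
        subs = list(icp.enumerate_subsets(["a", "b", "c"]))
        assert len(subs) == 8
        assert subs[0] == ()
        assert subs[-1] == ("a", "b", "c")
        sizes = [len(s) for s in subs]
        assert sizes == sorted(sizes)

    def test_counts(self):
        assert sum(1 for _ in icp.enumerate_subsets(list("abcdefghijklmnopqr"), 0)) == 1
        assert n_subsets(18) == 262_144
        assert len(list(icp.enumerate_subsets(list("abcde"), max_size=2))) == 16
        assert n_subsets(5, 2) == 16

    def test_duplicates_rejected(self):
        with pytest.raises(icp.ConfigError):
            list(icp.enumerate_subsets(["a", "a"]))


class TestIntersection:
    def test_plain_intersection(self):
        est, status = icp.intersect_accepted([{"A", "B"}, {"B", "C"}])
        assert est == ("B",) and status == "ok"

    def test_no_accepted_sets_is_model_rejected(self):
        est, status = icp.intersect_accepted([])
        assert est == () and status == "model_rejected"

    def test_empty_set_absorbs(self):
        est, status = icp.intersect_accepted([set(), {"A"}])
        assert est == () and status == "empty_by_intersection"


class TestLassoScreen:
    def test_truncates_to_k_max(self):
        spec = icp.planted_signal_spec(10)
        ds = icp.simulate_scm(spec, n_per_env=1500, seed=0)
        one = icp.lasso_screen(ds, k_max=1, seed=0)
        assert len(one) == 1

    def test_deterministic_given_seed(self):
        spec = icp.planted_signal_spec(10)
        ds = icp.simulate_scm(spec, n_per_env=1500, seed=1)
        assert icp.lasso_screen(ds, k_max=5, seed=3) == icp.lasso_screen(
            ds, k_max=5, seed=3
        )

    def test_retains_planted_parents(self):
        spec = icp.planted_signal_spec(18)
        hits = 0
        for seed in range(10):
            ds = icp.simulate_scm(spec, n_per_env=2500, seed=seed)
            kept = icp.lasso_screen(ds, k_max=8, seed=seed)
            hits += {"X1", "X2"} <= set(kept)
        assert hits >= 9


class TestRunICP:
    def test_independent_environment_accepts_everything(self):
        # environment unrelated to anything: no invariance violation exists,
        # the empty subset is accepted, and the estimate is empty
        spec = icp.planted_signal_spec(4, parent_weights=(1.0,))
        ds = icp.simulate_scm(spec, n_per_env=400, seed=6)  # no interventions
        res = icp.run_icp(ds, "env", alpha=0.05, method="full")
        assert res.n_subsets_tested == 16
        assert res.status == "empty_by_intersection"
        assert res.estimated_set == ()
        assert len(res.accepted_sets) > 14  # essentially everything

    def test_identifiable_design_recovers_parents(self, identifiable_spec):
        hits = 0
        for seed in range(10):
            ds = icp.simulate_scm(identifiable_spec, n_per_env=2000, seed=seed)
            res = icp.run_icp(ds, "env", alpha=0.05, method="full")
            hits += res.estimated_set == ("X1", "X2")
        assert hits >= 9

    def test_estimate_within_accepted_sets(self, strong_spec):
        ds = icp.simulate_scm(strong_spec, n_per_env=800, seed=3)
        res = icp.run_icp(ds, "env", alpha=0.1, method="full")
        for accepted in res.accepted_sets:
            assert set(res.estimated_set) <= set(accepted)

    def test_alpha_monotonicity_every_dataset(self, strong_spec):
        # where the estimate is defined (model not rejected), stricter
        # levels can only shrink it
        for seed in range(15):
            ds = icp.simulate_scm(strong_spec, n_per_env=300, seed=seed)
            model = icp.InvariantCausalPrediction(ds, "env")
            grid = model.fit_alphas([0.1, 0.05, 0.01])
            assert icp.estimate_chain_monotone(grid)

    def test_chain_monotone_skips_model_rejected_levels(self):
        def cell(alpha, estimated, status):
            return icp.ICPResults(
                env_name="e", alpha=alpha, method="full",
                screened_predictors=("a", "b"), accepted_sets=[],
                estimated_set=estimated, status=status, n_subsets_tested=4,
            )

        # rejection at the widest level does not contradict a defined,
        # nonempty estimate at a stricter level
        ok_grid = {
            0.1: cell(0.1, (), "model_rejected"),
            0.05: cell(0.05, ("a",), "ok"),
            0.01: cell(0.01, (), "empty_by_intersection"),
        }
        assert icp.estimate_chain_monotone(ok_grid)
        # a genuine growth from wider to stricter level is a violation
        bad_grid = {
            0.1: cell(0.1, (), "empty_by_intersection"),
            0.05: cell(0.05, ("a",), "ok"),
        }
        assert not icp.estimate_chain_monotone(bad_grid)

    def test_fit_alphas_matches_separate_fits(self, strong_spec):
        ds = icp.simulate_scm(strong_spec, n_per_env=400, seed=9)
        model = icp.InvariantCausalPrediction(ds, "env")
        joint = model.fit_alphas([0.1, 0.01])
        for alpha in (0.1, 0.01):
            single = model.fit(alpha=alpha)
            assert single.estimated_set == joint[alpha].estimated_set
            assert single.accepted_sets == joint[alpha].accepted_sets

    def test_max_size_caps_enumeration(self, strong_spec):
        ds = icp.simulate_scm(strong_spec, n_per_env=300, seed=4)
        res = icp.run_icp(ds, "env", alpha=0.05, method="full", max_size=2)
        assert res.n_subsets_tested == n_subsets(5, 2)

    def test_lasso_method_tests_screened_pool_only(self):
        spec = icp.planted_signal_spec(12)
        ds = icp.simulate_scm(spec, n_per_env=1500, seed=5)
        res = icp.run_icp(ds, "env", alpha=0.05, method="lasso", k_max=4, seed=5)
        assert len(res.screened_predictors) <= 4
        assert res.n_subsets_tested == 2 ** len(res.screened_predictors)

    def test_summary_mentions_estimate(self, identifiable_spec):
        ds = icp.simulate_scm(identifiable_spec, n_per_env=2000, seed=0)
        res = icp.run_icp(ds, "env", alpha=0.05)
        text = res.summary()
        assert "X1" in text and "Estimated parents" in text

    def test_from_dataframe_constructor(self, identifiable_spec):
        ds = icp.simulate_scm(identifiable_spec, n_per_env=1000, seed=1)
        model = icp.InvariantCausalPrediction.from_dataframe(ds.to_frame(), env="env")
        res = model.fit(alpha=0.05)
        assert set(res.estimated_set) <= {"X1", "X2"}
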