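"""Inverse-variance pooling, heterogeneity, multiple testing, leave-one-out."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ewasmeta.meta import (
    bh_adjust,
    bonferroni_threshold,
    heterogeneity,
    ivw_pool,
    leave_one_out,
    rescale_per10pct,
    run_meta,
)


def naive_ivw(estimates):
    """Independent reference implementation of fixed-effects pooling."""
    num = den = 0.0
    for b, s in estimates:
        num += b / s**2
        den += 1.0 / s**2
    pooled = num / den
    se = den**-0.5
    z = pooled / se
    return pooled, se, z, 2 * stats.norm.sf(abs(z))


def bh_oracle(p):
    """Brute-force step-up: adjusted_i = min_{j>=i} p_(j)*m/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.empty(m)
    for rank, idx in enumerate(order):
        candidates = [p[order[j]] * m / (j + 1) for j in range(rank, m)]
        adj_sorted[rank] = min(1.0, min(candidates))
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestIvwPool:
    def test_single_study_identity(self):
        pooled, se, _, _ = ivw_pool([(0.5, 0.1)])
        assert (pooled, se) == (pytest.approx(0.5), pytest.approx(0.1))

    def test_hand_computed_two_studies(self):
        # weights 100 and 25 -> pooled (100*0.5 + 25*1.0)/125 = 0.6
        pooled, se, _, _ = ivw_pool([(0.5, 0.1), (1.0, 0.2)])
        assert pooled == pytest.approx(0.6, rel=1e-12)
        assert se == pytest.approx(125**-0.5, rel=1e-9)  # ~0.089443

    def test_reported_scale_pvalue(self):
        # effect 0.96288, SE 0.16871 per 10% methylation -> P ~ 1.15e-8
        _, _, _, p = ivw_pool([(0.96288, 0.16871)])
        assert p == pytest.approx(1.15e-8, rel=5e-3)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError, match="entry 1"):
            ivw_pool([(0.5, 0.1), (0.3, 0.0)])

    def test_matches_naive_oracle_on_random_probes(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            k = rng.integers(2, 8)
            est = [(rng.normal(), rng.uniform(0.05, 0.5)) for _ in range(k)]
            got = ivw_pool(est)
            want = naive_ivw(est)
            np.testing.assert_allclose(got, want, rtol=1e-10, atol=1e-12)

    def test_pooled_within_range_and_se_below_min(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            est = [(rng.normal(), rng.uniform(0.05, 0.5)) for _ in range(4)]
            pooled, se, _, _ = ivw_pool(est)
            betas = [b for b, _ in est]
            assert min(betas) - 1e-12 <= pooled <= max(betas) + 1e-12
            assert se <= min(s for _, s in est)

    def test_associative_pooling_of_pools(self):
        est = [(0.2, 0.1), (0.5, 0.2), (-0.1, 0.15), (0.3, 0.05)]
        all_at_once = ivw_pool(est)
        p1, s1, _, _ = ivw_pool(est[:2])
        p2, s2, _, _ = ivw_pool(est[2:])
        staged = ivw_pool([(p1, s1), (p2, s2)])
        np.testing.assert_allclose(all_at_once, staged, rtol=1e-12)


class TestHeterogeneity:
    def test_identical_estimates(self):
        Q, i2 = heterogeneity([(0.4, 0.1), (0.4, 0.2)], 0.4)
        assert Q == 0.0 and i2 == 0.0

    def test_hand_computed_example(self):
        # weights 100, 25; pooled 0.6: Q = 100*0.01 + 25*0.16 = 5; I2 = 80
        Q, i2 = heterogeneity([(0.5, 0.1), (1.0, 0.2)], 0.6)
        assert Q == pytest.approx(5.0, rel=1e-12)
        assert i2 == pytest.approx(80.0, rel=1e-12)

    def test_i2_exactly_fifty_not_flagged(self):
        # (0,1) and (2,1): pooled 1, Q = 2, I2 = 50 -> strictly-greater rule
        Q, i2 = heterogeneity([(0.0, 1.0), (2.0, 1.0)], 1.0)
        assert i2 == pytest.approx(50.0)
        assert not (i2 > 50)

    def test_single_study_i2_missing(self):
        _, i2 = heterogeneity([(0.4, 0.1)], 0.4)
        assert np.isnan(i2)

    def test_i2_invariant_to_common_rescaling(self):
        est = [(0.5, 0.1), (1.0, 0.2), (0.2, 0.15)]
        pooled = ivw_pool(est)[0]
        _, i2 = heterogeneity(est, pooled)
        scaled = [(10 * b, 10 * s) for b, s in est]
        _, i2s = heterogeneity(scaled, 10 * pooled)
        assert i2 == pytest.approx(i2s, rel=1e-12)


class TestBonferroni:
    def test_printed_threshold(self):
        t = bonferroni_threshold(429_959)
        assert float(f"{t:.2e}") == pytest.approx(1.16e-7)

    def test_single_test(self):
        assert bonferroni_threshold(1) == 0.05

    def test_definition(self):
        assert bonferroni_threshold(428_967) == pytest.approx(0.05 / 428_967, rel=1e-15)

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)


class TestBHAdjust:
    def test_uniform_grid_collapses(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_all_equal(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 6), 0.2)

    @given(
        st.lists(st.floats(1e-12, 1.0, exclude_min=False), min_size=1, max_size=40)
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), rtol=1e-12)

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(1e-8, 1, 500)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])


class TestRescale:
    def test_per_unit_to_per_10pct(self):
        b, s = rescale_per10pct(9.6288, 1.6871)
        assert (float(b), float(s)) == (pytest.approx(0.96288), pytest.approx(0.16871))

    def test_zero_effect(self):
        b, s = rescale_per10pct(0.0, 0.3)
        assert float(b) == 0.0 and float(s) == pytest.approx(0.03)

    def test_z_statistic_invariant(self):
        b, s = rescale_per10pct(2.0, 0.5)
        assert float(b) / float(s) == pytest.approx(2.0 / 0.5, rel=1e-15)


def make_cohort_results(rng, n_probes=30, cohorts=("c1", "c2", "c3")):
    out = {}
    for c in cohorts:
        out[c] = pd.DataFrame(
            {
                "cpg_id": [f"cg{i:03d}" for i in range(n_probes)],
                "beta": rng.normal(0, 1, n_probes),
                "se": rng.uniform(0.1, 0.5, n_probes),
                "n": 100,
                "converged": True,
            }
        )
    return out


class TestRunMeta:
    def test_two_identical_cohorts_halve_variance(self):
        rng = np.random.default_rng(14)
        single = make_cohort_results(rng, cohorts=("c1",))["c1"]
        res = run_meta({"c1": single, "c2": single.copy()})
        one = single.set_index("cpg_id")
        merged = res.set_index("cpg_id")
        for cpg in merged.index:
            assert merged.loc[cpg, "pooled_beta_per10pct"] == pytest.approx(
                0.1 * one.loc[cpg, "beta"], rel=1e-9
            )
            assert merged.loc[cpg, "pooled_se_per10pct"] == pytest.approx(
                0.1 * one.loc[cpg, "se"] / np.sqrt(2), rel=1e-9
            )

    def test_subset_rule_equals_leave_one_out(self):
        rng = np.random.default_rng(15)
        cres = make_cohort_results(rng)
        info = pd.DataFrame(
            {
                "cohort_id": ["c1", "c2", "c3"],
                "ancestry_label": ["European", "European", "African"],
                "overweight_fraction": [0.2, 0.2, 0.2],
                "selection_flag": [False, False, False],
            }
        )
        sub = run_meta(cres, subset_rule="europeans_only", cohort_info=info)
        loo = leave_one_out(cres, min_studies=2)
        loo_c3 = loo[loo["left_out"] == "c3"].drop(columns="left_out").reset_index(drop=True)
        pd.testing.assert_frame_equal(
            sub.reset_index(drop=True), loo_c3, check_like=True, atol=1e-12
        )

    def test_sorted_by_p_with_cpg_tiebreak(self):
        rng = np.random.default_rng(16)
        res = run_meta(make_cohort_results(rng))
        p = res["p"].to_numpy()
        assert np.all(np.diff(p) >= 0)

    def test_direction_string_order(self):
        cres = {
            "b_cohort": pd.DataFrame(
                {"cpg_id": ["cg1"], "beta": [-0.5], "se": [0.1], "n": [50], "converged": [True]}
            ),
            "a_cohort": pd.DataFrame(
                {"cpg_id": ["cg1"], "beta": [0.5], "se": [0.1], "n": [50], "converged": [True]}
            ),
        }
        res = run_meta(cres)
        assert res.loc[0, "direction"] == "+-"  # a_cohort first (sorted)

    def test_probe_missing_from_one_cohort_direction_question_mark(self):
        cres = {
            "a": pd.DataFrame(
                {"cpg_id": ["cg1", "cg2"], "beta": [0.5, 0.2], "se": [0.1, 0.1],
                 "n": [50, 50], "converged": [True, True]}
            ),
            "b": pd.DataFrame(
                {"cpg_id": ["cg1"], "beta": [0.4], "se": [0.1], "n": [50], "converged": [True]}
            ),
        }
        res = run_meta(cres, min_studies=1).set_index("cpg_id")
        assert res.loc["cg2", "direction"] == "+?"


class TestLeaveOneOut:
    def test_two_cohorts_each_loo_equals_other(self):
        cres = {
            "a": pd.DataFrame(
                {"cpg_id": ["cg1"], "beta": [0.5], "se": [0.1], "n": [50], "converged": [True]}
            ),
            "b": pd.DataFrame(
                {"cpg_id": ["cg1"], "beta": [1.0], "se": [0.2], "n": [60], "converged": [True]}
            ),
        }
        loo = leave_one_out(cres)
        drop_b = loo[loo["left_out"] == "b"].iloc[0]
        assert drop_b["pooled_beta_per10pct"] == pytest.approx(0.05, rel=1e-12)
        drop_a = loo[loo["left_out"] == "a"].iloc[0]
        assert drop_a["pooled_beta_per10pct"] == pytest.approx(0.10, rel=1e-12)

    def test_duplicate_cohort_exchangeable(self):
        base = pd.DataFrame(
            {"cpg_id": ["cg1"], "beta": [0.5], "se": [0.1], "n": [50], "converged": [True]}
        )
        three = {"a": base, "b": base.copy(), "c": base.copy()}
        loo = leave_one_out(three)
        two = run_meta({"a": base, "b": base.copy()})
        drop_c = loo[loo["left_out"] == "c"].iloc[0]
        assert drop_c["pooled_se_per10pct"] == pytest.approx(
            two.loc[0, "pooled_se_per10pct"], rel=1e-12
        )

    def test_single_cohort_warns_empty(self):
        base = {"a": pd.DataFrame(
            {"cpg_id": ["cg1"], "beta": [0.5], "se": [0.1], "n": [50], "converged": [True]}
        )}
        with pytest.warns(UserWarning):
            assert leave_one_out(base).empty
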