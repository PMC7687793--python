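"""Prior-set look-up, hypergeometric enrichment, correlation comparisons."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ewasmeta.priors import (
    PriorCpGSet,
    compare_correlations,
    correlation_pvalue,
    effect_correlation,
    enrichment_report,
    hypergeom_enrichment,
    lookup_replication,
    overlap_chi2,
    top_list,
)


def meta_frame(p_values, effects=None):
    m = len(p_values)
    return pd.DataFrame(
        {
            "cpg_id": [f"cg{i:05d}" for i in range(m)],
            "p": p_values,
            "pooled_beta_per10pct": effects if effects is not None else np.zeros(m),
        }
    )


class TestLookupReplication:
    def test_per_study_bonferroni_cutoff(self):
        prior = PriorCpGSet("s", tuple(f"cg{i:05d}" for i in range(8)),
                            n_cpgs_tested_in_source=8)
        table = lookup_replication(prior, meta_frame([0.5] * 10))
        assert table["cutoff"].iloc[0] == pytest.approx(0.00625)

    def test_absent_cpg_untested_not_failed(self):
        prior = PriorCpGSet("s", ("cg00001", "cgZZZZZ"), n_cpgs_tested_in_source=2)
        table = lookup_replication(prior, meta_frame([0.5] * 5)).set_index("cpg_id")
        assert not table.loc["cgZZZZZ", "tested"]
        assert not table.loc["cgZZZZZ", "replicated"]

    def test_single_cpg_prior_replicates_at_nominal(self):
        prior = PriorCpGSet("s", ("cg00000",), n_cpgs_tested_in_source=1)
        table = lookup_replication(prior, meta_frame([0.049, 0.9]))
        assert table["replicated"].iloc[0]

    def test_empty_prior_rejected(self):
        with pytest.raises(ValueError):
            lookup_replication(PriorCpGSet("s", ()), meta_frame([0.5]))


def hypergeom_brute(K, n, N, k):
    """Exact enumeration oracle for small N."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, min(K, n) + 1)
    ) / total


class TestHypergeomEnrichment:
    def test_zero_overlap_is_one(self):
        assert hypergeom_enrichment(10, 20, 100, 0) == 1.0

    @pytest.mark.parametrize(
        "K,n,N,k,expected",
        [
            (187, 37_074, 429_957, 61, 1.97e-20),
            (187, 25_292, 428_967, 77, 1.68e-44),
            (187, 26, 428_967, 3, 2.10e-7),
        ],
    )
    def test_published_scale_tuples(self, K, n, N, k, expected):
        assert hypergeom_enrichment(K, n, N, k) == pytest.approx(expected, rel=5e-3)

    def test_matches_enumeration_for_small_universes(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            N = int(rng.integers(2, 61))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            got = hypergeom_enrichment(K, n, N, k)
            want = hypergeom_brute(K, n, N, k)
            assert got == pytest.approx(want, rel=1e-9, abs=1e-300)

    def test_strictly_decreasing_in_k(self):
        vals = [hypergeom_enrichment(20, 30, 200, k) for k in range(0, 15)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_symmetric_in_K_and_n(self):
        assert hypergeom_enrichment(15, 40, 300, 6) == pytest.approx(
            hypergeom_enrichment(40, 15, 300, 6), rel=1e-12
        )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(10, 20, 100, 15)


class TestTopList:
    def test_uniform_null_count(self):
        m = 10_000
        p = (np.arange(m) + 0.5) / m
        top = top_list(meta_frame(p), 0.05)
        assert abs(len(top) - 500) <= 3 * np.sqrt(m * 0.05 * 0.95)

    def test_cutoff_below_minimum_empty(self):
        assert top_list(meta_frame([0.1, 0.2]), 1e-6) == set()

    def test_boundary_strictly_below(self):
        top = top_list(meta_frame([0.05, 0.049]), 0.05)
        assert len(top) == 1


class TestEffectCorrelation:
    def test_matches_scipy_pearsonr(self):
        rng = np.random.default_rng(18)
        x = rng.normal(size=60)
        y = 0.5 * x + rng.normal(size=60)
        r, n, p = effect_correlation(x, y)
        sr, sp = stats.pearsonr(x, y)
        assert r == pytest.approx(sr, rel=1e-12)
        assert p == pytest.approx(sp, rel=1e-9)

    def test_permutation_oracle_small_n(self):
        rng = np.random.default_rng(19)
        x = rng.normal(size=30)
        y = 0.6 * x + rng.normal(size=30) * 0.9
        r, n, p = effect_correlation(x, y)
        perms = 10_000
        robs = abs(r)
        count = 0
        for _ in range(perms):
            rp = np.corrcoef(x, rng.permutation(y))[0, 1]
            count += abs(rp) >= robs
        p_perm = (count + 1) / (perms + 1)
        mc_sd = np.sqrt(max(p_perm, 1e-4) * (1 - p_perm) / perms)
        assert abs(p - p_perm) < 4 * mc_sd + 1e-4

    def test_identical_vectors_r_one(self):
        x = np.arange(10.0)
        r, n, p = effect_correlation(x, x)
        assert r == pytest.approx(1.0)
        assert p > 0  # degenerate p reported as smallest positive float

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            effect_correlation(np.ones(10), np.arange(10.0))


class TestCompareCorrelations:
    def test_equal_correlations_p_one(self):
        _, p = compare_correlations(0.3, 100, 0.3, 200)
        assert p == pytest.approx(1.0)

    def test_reported_scale_weak_pair(self):
        # r = -0.186 vs -0.013 at n = 187 each -> P ~ 0.09
        _, p = compare_correlations(-0.186, 187, -0.013, 187)
        assert p == pytest.approx(0.09, abs=0.005)

    def test_reported_scale_strong_pair(self):
        _, p = compare_correlations(0.604, 187, 0.816, 187)
        assert p < 0.01

    def test_degenerate_r_rejected(self):
        with pytest.raises(ValueError):
            compare_correlations(1.0, 50, 0.5, 50)


class TestOverlapChi2:
    def test_identical_sets_strongly_associated(self):
        u = {f"cg{i}" for i in range(200)}
        s = {f"cg{i}" for i in range(30)}
        chi2, p = overlap_chi2(s, s, u)
        assert p < 1e-30

    def test_disjoint_cover_is_maximal_negative(self):
        u = {f"cg{i}" for i in range(40)}
        s1 = {f"cg{i}" for i in range(20)}
        s2 = u - s1
        chi2, _ = overlap_chi2(s1, s2, u)
        assert chi2 == pytest.approx(len(u), rel=1e-12)

    def test_degenerate_margins_rejected(self):
        u = {"a", "b", "c"}
        with pytest.raises(ValueError):
            overlap_chi2(set(), {"a"}, u)
        with pytest.raises(ValueError):
            overlap_chi2(u, {"a"}, u)

    def test_independent_sets_p_uniform(self):
        rng = np.random.default_rng(20)
        universe = np.arange(400)
        pvals = []
        for _ in range(300):
            s1 = set(rng.choice(universe, 80, replace=False))
            s2 = set(rng.choice(universe, 80, replace=False))
            pvals.append(overlap_chi2(s1, s2, set(universe))[1])
        # the 2x2 statistic is discrete, so compare tail rates rather than
        # the full distribution against continuous uniformity
        pvals = np.asarray(pvals)
        assert 0.02 <= (pvals < 0.05).mean() <= 0.09
        assert 0.35 <= (pvals < 0.5).mean() <= 0.65


class TestEnrichmentReport:
    def test_report_counts_and_tail(self):
        m = 1000
        p = np.linspace(1e-8, 1, m)
        prior = PriorCpGSet("toy", tuple(f"cg{i:05d}" for i in range(50)))
        rep = enrichment_report(meta_frame(p), [prior], cutoffs=(0.05,))
        row = rep.iloc[0]
        top = top_list(meta_frame(p), 0.05)
        assert row["k"] == len(top & set(prior.cpg_ids))
        assert row["N"] == m
        assert row["p_upper"] == pytest.approx(
            hypergeom_enrichment(50, len(top), m, row["k"]), rel=1e-12
        )


def test_prior_csv_round_trip(tmp_path):
    path = tmp_path / "prior.csv"
    pd.DataFrame(
        {
            "cpg_id": ["cg1", "cg2"],
            "effect": [0.3, -0.2],
            "source": ["adultstudy", "adultstudy"],
            "n_cpgs_tested": [187, 187],
        }
    ).to_csv(path, index=False)
    prior = PriorCpGSet.from_csv(path)
    assert prior.source_label == "adultstudy"
    assert prior.effects == (0.3, -0.2)
    assert prior.n_cpgs_tested_in_source == 187
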