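import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from mircontext import (
    ValidationError,
    breadth_count,
    coexpression_randomization,
    compare_correlations,
    correlate,
    enrichment_fisher,
    expression_divergence,
    fisher_exact_p,
    host_age_randomization,
    kaks_compare,
    rank_match_statistic,
    target_counts,
    tau,
)


def brute_force_tau(values):
    x = [math.log2(v + 1) for v in values]
    m = max(x)
    return sum(1 - xi / m for xi in x) / (len(x) - 1)


class TestTau:
    def test_uniform_profile_is_zero(self):
        assert tau([4, 4, 4]).tau == 0.0

    def test_single_tissue_is_one(self):
        assert tau([7, 0, 0, 0]).tau == 1.0

    def test_hand_evaluated_example(self):
        # [3,1,0] -> log2(v+1) = [2,1,0] -> normalized [1,.5,0] -> tau .75
        assert tau([3, 1, 0]).tau == pytest.approx(0.75, abs=1e-12)

    def test_matches_brute_force_on_random_profiles(self, rng):
        for _ in range(300):
            n = int(rng.integers(2, 15))
            v = rng.lognormal(1, 2, size=n)
            v[rng.random(n) < 0.3] = 0.0
            if v.max() == 0:
                v[0] = 1.0
            assert tau(v).tau == pytest.approx(brute_force_tau(v), abs=1e-12)

    @given(st.lists(st.floats(0, 1e6, allow_nan=False), min_size=2, max_size=16))
    @settings(max_examples=100, deadline=None)
    def test_bounded_in_unit_interval(self, values):
        if math.log2(max(values) + 1) <= 0:
            return  # indistinguishable from all-zero on the log scale
        t = tau(values).tau
        assert -1e-12 <= t <= 1 + 1e-12

    def test_all_zero_profile_rejected(self):
        with pytest.raises(ValidationError):
            tau([0, 0, 0])
        with pytest.raises(ValidationError):
            tau([5])


class TestBreadthCount:
    @pytest.mark.parametrize("values,thr,expected", [
        ([2, 0.5, 1.0], 1, 2),
        ([0.2, 0.3], 1, 0),
        ([1.0, 0.99], 1.0, 1),  # equality counted, below not
    ])
    def test_threshold_rule(self, values, thr, expected):
        assert breadth_count(values, thr) == expected

    def test_positive_threshold_required(self):
        with pytest.raises(ValidationError):
            breadth_count([1], 0)


class TestHostAgeRandomization:
    def test_pool_entirely_old_gives_p_one(self, rng):
        res = host_age_randomization([1] * 10, [5] * 10, [1] * 50, n_draws=200, rng=rng)
        assert res.observed_statistic == 1.0
        assert np.all(res.null_values == 1.0)
        assert res.empirical_p == 1.0

    def test_planted_excess_detected(self):
        rng = np.random.default_rng(11)
        pool = np.concatenate([np.ones(600, int), np.full(400, 2, int)])
        ages = rng.integers(2, 13, 200)
        hosts = np.where(rng.random(200) < 0.85, 1, 2)
        res = host_age_randomization(hosts, ages, pool, n_draws=2_000, rng=rng)
        assert res.empirical_p < 0.01
        assert res.chi2_p is not None and res.chi2_p < 0.01

    def test_observed_below_null_mean_gives_large_p(self):
        rng = np.random.default_rng(12)
        pool = np.concatenate([np.ones(600, int), np.full(400, 2, int)])
        ages = rng.integers(2, 13, 200)
        hosts = np.where(rng.random(200) < 0.30, 1, 2)  # depleted old hosts
        res = host_age_randomization(hosts, ages, pool, n_draws=2_000, rng=rng)
        assert res.empirical_p > 0.95

    def test_missing_eligible_pool_names_age(self, rng):
        with pytest.raises(ValidationError, match="age 2"):
            host_age_randomization([5], [2], [5, 6, 7], n_draws=10, rng=rng)

    def test_empirical_p_never_zero(self, rng):
        res = host_age_randomization([1] * 50, [12] * 50, [1] * 5 + [12] * 95,
                                     n_draws=100, rng=rng)
        assert res.empirical_p >= 1 / 101


class TestRankMatch:
    def test_identical_profiles_match_fully(self):
        v = [5.0, 4.0, 3.0, 2.0, 1.0]
        assert rank_match_statistic(v, v) == 1.0

    def test_reversed_profile_matches_only_middle(self):
        assert rank_match_statistic([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]) == pytest.approx(0.2)

    def test_constant_profile_rejected(self):
        with pytest.raises(ValidationError):
            rank_match_statistic([1, 1, 1], [3, 2, 1])

    def test_statistic_one_iff_orderings_identical(self, rng):
        for _ in range(50):
            m = rng.lognormal(0, 1, 6)
            h = rng.lognormal(0, 1, 6)
            s = rank_match_statistic(m, h)
            same = np.array_equal(np.argsort(-m, kind="stable"), np.argsort(-h, kind="stable"))
            assert (s == 1.0) == same

    def test_randomization_p_small_for_copied_profiles(self):
        rng = np.random.default_rng(3)
        m = np.array([50.0, 20.0, 10.0, 5.0, 1.0, 30.0, 2.0, 8.0])
        res = coexpression_randomization(m, m, n_shuffles=500, rng=rng)
        assert res.observed_statistic == 1.0
        assert res.empirical_p < 0.01


class TestDivergence:
    def test_identical_profiles_zero(self):
        a = pd.Series([3.0, 2.0, 5.0], index=["t1", "t2", "t3"])
        assert expression_divergence(a, a).euclidean_distance == 0.0

    def test_single_tissue_log_difference(self):
        a = pd.Series([3.0, 1.0], index=["t1", "t2"])
        b = pd.Series([15.0, 1.0], index=["t1", "t2"])  # log2 16 - log2 4 = 2
        assert expression_divergence(a, b).euclidean_distance == pytest.approx(2.0)

    def test_low_expression_pair_excluded(self):
        a = pd.Series([0.5, 0.2], index=["t1", "t2"])
        b = pd.Series([10.0, 1.0], index=["t1", "t2"])
        res = expression_divergence(a, b, min_cpm=1.0)
        assert res.excluded and res.euclidean_distance is None

    def test_panel_mismatch_rejected(self):
        a = pd.Series([1.0, 2.0], index=["t1", "t2"])
        b = pd.Series([1.0, 2.0], index=["t1", "t3"])
        with pytest.raises(ValidationError):
            expression_divergence(a, b)

    def test_metric_axioms_on_random_triples(self, rng):
        tissues = [f"t{i}" for i in range(5)]
        for _ in range(200):
            x, y, z = (pd.Series(rng.lognormal(1, 1, 5) + 1.0, index=tissues) for _ in range(3))
            dxy = expression_divergence(x, y).euclidean_distance
            dyx = expression_divergence(y, x).euclidean_distance
            dxz = expression_divergence(x, z).euclidean_distance
            dzy = expression_divergence(z, y).euclidean_distance
            assert dxy == pytest.approx(dyx)
            assert dxy >= 0
            assert dxz + dzy >= dxy - 1e-9


class TestCorrelations:
    def test_perfect_rank_correlation(self):
        res = correlate([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert res.rho == pytest.approx(1.0)

    def test_equal_correlations_give_z_zero(self):
        cmp = compare_correlations(0.5, 40, 0.5, 40)
        assert cmp.z == 0.0 and cmp.one_tailed_p == pytest.approx(0.5)

    def test_fisher_z_closed_form(self):
        cmp = compare_correlations(0.83, 60, 0.68, 40)
        z = (math.atanh(0.83) - math.atanh(0.68)) / math.sqrt(1 / 57 + 1 / 37)
        assert cmp.z == pytest.approx(z, abs=1e-12)
        assert 0 < cmp.one_tailed_p < 0.5
        assert cmp.one_tailed_p == pytest.approx(sps.norm.sf(z), abs=1e-12)

    def test_small_samples_rejected(self):
        with pytest.raises(ValidationError):
            correlate([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValidationError):
            compare_correlations(0.5, 3, 0.5, 40)


def fisher_oracle(a, b, c, d):
    """Exact-integer hypergeometric enumeration of the two-sided P."""
    r, cc, N = a + b, a + c, a + b + c + d
    lo, hi = max(0, r + cc - N), min(r, cc)
    w = {k: math.comb(r, k) * math.comb(N - r, cc - k) for k in range(lo, hi + 1)}
    return sum(v for v in w.values() if v <= w[a]) / sum(w.values())


class TestFisher:
    def test_balanced_table(self):
        res = enrichment_fisher([[10, 10], [10, 10]])
        assert res.odds_ratio == 1.0 and res.p == pytest.approx(1.0)

    def test_worked_example(self):
        res = enrichment_fisher([[8, 2], [2, 8]])
        assert res.odds_ratio == pytest.approx(16.0)
        assert res.p == pytest.approx(fisher_oracle(8, 2, 2, 8), abs=1e-12)
        assert res.p == pytest.approx(0.023, abs=5e-4)

    def test_zero_cell_odds_ratio(self):
        res = enrichment_fisher([[0, 5], [5, 0]])
        assert res.odds_ratio == 0.0
        assert res.p == pytest.approx(fisher_oracle(0, 5, 5, 0), abs=1e-12)

    def test_zero_margin_flagged_undefined(self):
        res = enrichment_fisher([[0, 0], [3, 4]])
        assert res.undefined and math.isnan(res.odds_ratio)

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, 4))
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            mine = fisher_exact_p(a, b, c, d)
            ref = sps.fisher_exact([[a, b], [c, d]]).pvalue
            assert mine == pytest.approx(ref, abs=1e-10)

    def test_one_sided_tail(self):
        assert fisher_exact_p(8, 2, 2, 8, alternative="greater") == pytest.approx(
            sps.fisher_exact([[8, 2], [2, 8]], alternative="greater").pvalue, abs=1e-12
        )


class TestKaKs:
    def test_identical_samples(self):
        d, p = kaks_compare([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_values_above_one_discarded(self):
        d1, _ = kaks_compare([0.1, 0.2, 1.2], [0.1, 0.2])
        d2, _ = kaks_compare([0.1, 0.2], [0.1, 0.2])
        assert d1 == d2
        with pytest.raises(ValidationError):
            kaks_compare([1.2, 1.5], [0.1, 0.2])

    def test_disjoint_supports(self):
        d, _ = kaks_compare([0.1, 0.15, 0.2], [0.7, 0.8, 0.9])
        assert d == 1.0


class TestTargetCounts:
    TABLE = pd.DataFrame(
        [
            ("mirA", "g1", "8mer", -0.30),
            ("mirA", "g1", "7mer-m8", -0.40),  # same gene: counted once
            ("mirA", "g2", "7mer-1a", -0.40),  # wrong site type
            ("mirA", "g3", "8mer", -0.10),     # weak context score
            ("mirB", "g1", "7mer-m8", -0.26),
        ],
        columns=["mirna_id", "gene_id", "site_type", "context_score"],
    )

    def test_filtering_and_distinct_count(self):
        counts = target_counts(self.TABLE)
        assert counts.to_dict() == {"mirA": 1, "mirB": 1}

    def test_unknown_site_type_warns_and_excluded(self):
        bad = pd.concat(
            [self.TABLE, pd.DataFrame([("mirC", "g9", "9mer", -0.9)], columns=self.TABLE.columns)],
            ignore_index=True,
        )
        with pytest.warns(UserWarning, match="9mer"):
            counts = target_counts(bad)
        assert "mirC" not in counts.index

    def test_boundary_score_excluded(self):
        t = pd.DataFrame([("m", "g", "8mer", -0.25)], columns=self.TABLE.columns)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            assert len(target_counts(t)) == 0
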