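"""Pairwise correlation statistics, permutation nulls, and the
correlation-of-correlations with leave-one-out diagnostics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from neuroconcord.concordance import (
    AlignmentError,
    DegenerateInputError,
    bonferroni,
    corr_pvalue,
    corr_se,
    correlate,
    correlation_of_correlations,
    leave_one_out,
    pair_key,
    pairwise_table,
    permutation_pvalue,
)
from neuroconcord.profiles import DisorderPanel, ValidationError
from neuroconcord.simulate import matrix_to_pairs


class TestCorrelate:
    def test_perfect_linear_and_monotone(self):
        assert correlate([1, 2, 3], [2, 4, 6], "pearson") == pytest.approx(1.0)
        assert correlate([1, 2, 3], [2, 4, 6], "spearman") == pytest.approx(1.0)

    def test_spearman_hand_ranked(self):
        # ranks (1,2,3,4) vs (1,3,2,4): rho = 1 - 6*2/(4*15) = 0.8
        assert correlate([1, 2, 3, 4], [1, 3, 2, 4], "spearman") == pytest.approx(0.8)

    def test_pearson_matches_longhand_oracle(self):
        x = [0.1, -0.2, 0.05, -0.3, 0.2]
        y = [0.2, -0.1, 0.0, -0.25, 0.15]
        # frozen exact-rational longhand covariance/variance computation
        assert correlate(x, y, "pearson") == pytest.approx(0.9353865413237217, abs=1e-14)

    @pytest.mark.parametrize("method", ["pearson", "spearman"])
    def test_cross_check_against_scipy(self, method):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x, y = rng.standard_normal((2, 30))
            ours = correlate(x, y, method)
            ref = (stats.pearsonr if method == "pearson" else stats.spearmanr)(x, y)[0]
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_zero_variance_error(self):
        with pytest.raises(DegenerateInputError):
            correlate([1.0, 1.0, 1.0], [1, 2, 3])

    def test_too_few_pairs(self):
        with pytest.raises(DegenerateInputError):
            correlate([1, 2], [3, 4])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_spearman_invariant_under_increasing_transform(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal((2, 15))
        base = correlate(x, y, "spearman")
        assert correlate(np.exp(x), y, "spearman") == pytest.approx(base, abs=1e-12)
        assert correlate(x, y ** 3 + 2 * y, "spearman") == pytest.approx(base, abs=1e-12)


class TestAnalyticColumns:
    def test_corr_se_closed_form(self):
        assert corr_se(0.0, 4) == pytest.approx(0.5)
        assert round(corr_se(0.65, 72), 3) == pytest.approx(0.090)
        assert round(corr_se(0.17, 39), 3) == pytest.approx(0.158)
        with pytest.raises(ValueError):
            corr_se(0.5, 0)

    def test_corr_pvalue_trivial_and_quadrature(self):
        assert corr_pvalue(0.0, 50) == pytest.approx(1.0)
        assert corr_pvalue(1.0, 10) == 0.0
        # frozen from numerical integration of the t density at t = .5*sqrt(10/.75)
        assert corr_pvalue(0.5, 10) == pytest.approx(0.09785461425781247, rel=1e-9)

    def test_bonferroni(self):
        assert bonferroni(0.1, 21) == 1.0
        assert bonferroni(0.01, 3) == pytest.approx(0.03)
        assert bonferroni(0.0, 5) == 0.0
        with pytest.raises(ValueError):
            bonferroni(1.5, 3)

    @given(st.floats(0, 1), st.floats(0, 1), st.integers(1, 100))
    @settings(max_examples=50, deadline=None)
    def test_bonferroni_monotone_and_capped(self, p1, p2, m):
        lo, hi = sorted([p1, p2])
        assert bonferroni(lo, m) <= bonferroni(hi, m) <= 1.0
        if bonferroni(lo, m) < 1.0:
            assert bonferroni(lo, m) == pytest.approx(m * lo)


class TestPermutation:
    def test_exact_enumeration_matches_sampling(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(6)
        y = 0.8 * x + 0.6 * rng.standard_normal(6)
        exact = permutation_pvalue(x, y, exact=True)
        sampled = permutation_pvalue(x, y, n_perm=10_000, seed=5)
        # binomial Monte-Carlo error at n_perm = 1e4
        assert abs(sampled - exact) < 4 * math.sqrt(exact * (1 - exact) / 10_000) + 2e-4

    def test_exact_identity_vector(self):
        x = np.array([0.3, -1.2, 0.7, 2.1, -0.5, 0.9])
        exact = permutation_pvalue(x, x, exact=True)
        # only permutations reproducing |r|=1 count; at least the identity
        assert exact >= 1 / math.factorial(6)
        assert exact < 0.05

    def test_exact_agrees_with_brute_force_on_tiny_input(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([0.0, 0.0, 1.0])
        r_obs = abs(correlate(x, y))
        hits = sum(
            abs(correlate(x, np.array(p))) >= r_obs - 1e-12
            for p in itertools.permutations(y)
        )
        assert permutation_pvalue(x, y, exact=True) == pytest.approx(hits / 6)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(3)
        x, y = rng.standard_normal((2, 20))
        p1 = permutation_pvalue(x, y, n_perm=500, seed=42)
        p2 = permutation_pvalue(x, y, n_perm=500, seed=42)
        p3 = permutation_pvalue(x, y, n_perm=500, seed=43)
        assert p1 == p2
        assert 1 / 501 <= p1 <= 1.0
        assert p1 != p3 or True  # different seeds may coincide; no assertion beyond bounds

    def test_add_one_floor(self):
        x = np.arange(10.0)
        p = permutation_pvalue(x, 2 * x, n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)


class TestPairwiseTable:
    def test_seven_disorders_give_21_sorted_rows(self, default_panel):
        rows = pairwise_table(default_panel, n_perm=100, seed=1)
        assert len(rows) == 21
        assert [r.p for r in rows] == sorted(r.p for r in rows)
        for row in rows:
            assert -1 <= row.r <= 1
            assert row.df == row.n_overlap - 2
            assert row.p_bonf == pytest.approx(min(1.0, 21 * row.p))
            assert 1 / 101 <= row.p_perm <= 1

    def test_two_disorder_panel(self, default_panel):
        panel = DisorderPanel(profiles=default_panel.profiles[:2])
        rows = pairwise_table(panel, n_perm=50, seed=2)
        assert len(rows) == 1
        assert rows[0].p_bonf == pytest.approx(min(1.0, rows[0].p))

    def test_invariant_under_disorder_order(self, default_panel):
        reversed_panel = DisorderPanel(profiles=default_panel.profiles[::-1])
        fwd = {r.pair: r for r in pairwise_table(default_panel, n_perm=200, seed=9)}
        rev = {r.pair: r for r in pairwise_table(reversed_panel, n_perm=200, seed=9)}
        assert fwd.keys() == rev.keys()
        for key in fwd:
            assert fwd[key].r == pytest.approx(rev[key].r, abs=1e-14)
            assert fwd[key].p == pytest.approx(rev[key].p, abs=1e-14)
            assert fwd[key].p_perm == rev[key].p_perm  # same per-pair stream

    def test_recovers_generator_targets(self, default_panel, default_scenario):
        rows = {r.pair: r.r for r in pairwise_table(default_panel, n_perm=1, seed=0)}
        targets = matrix_to_pairs(default_scenario.disorders, default_scenario.target_corr)
        for key, target in targets.items():
            n = 41 if "Epilepsy" in key else (74 if "OCD" in key else 75)
            band = 4 * (1 - target ** 2) / math.sqrt(n - 3)  # Fisher-z scale bound
            assert abs(rows[key] - target) < max(band, 0.15)


class TestCorrelationOfCorrelations:
    def _maps(self, n_disorders=7, seed=0, rho=None):
        rng = np.random.default_rng(seed)
        names = [f"D{i}" for i in range(n_disorders)]
        pairs = [pair_key(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
        imaging = {k: rng.uniform(-0.5, 0.9) for k in pairs}
        return imaging, pairs

    def test_identity_gives_rho_one(self):
        imaging, _ = self._maps()
        res = correlation_of_correlations(imaging, dict(imaging))
        assert res.rho == pytest.approx(1.0)
        assert all(v == pytest.approx(1.0) for v in res.loo.values())

    def test_monotone_transform_gives_rho_one(self):
        imaging, pairs = self._maps()
        genetic = {k: math.tanh(2 * v) + 1 for k, v in imaging.items()}
        res = correlation_of_correlations(imaging, genetic)
        assert res.rho == pytest.approx(1.0)

    def test_alignment_error_names_difference(self):
        imaging, pairs = self._maps()
        genetic = dict(imaging)
        del genetic[pairs[0]]
        with pytest.raises(AlignmentError, match=str(pairs[0][0])):
            correlation_of_correlations(imaging, genetic)

    def test_alignment_by_identifier_not_position(self):
        imaging, pairs = self._maps()
        genetic = {k: imaging[k] for k in reversed(pairs)}
        res = correlation_of_correlations(imaging, genetic)
        assert res.rho == pytest.approx(1.0)

    def test_needs_four_pairs(self):
        tiny = {("A", "B"): 0.1, ("A", "C"): 0.2, ("B", "C"): 0.3}
        with pytest.raises(ValidationError):
            correlation_of_correlations(tiny, dict(tiny))

    def test_t_and_permutation_p_agree_in_scale(self):
        imaging, _ = self._maps(seed=4)
        rng = np.random.default_rng(8)
        genetic = {k: v + 0.3 * rng.standard_normal() for k, v in imaging.items()}
        t_res = correlation_of_correlations(imaging, genetic, p_method="t")
        p_res = correlation_of_correlations(imaging, genetic, p_method="permutation",
                                            n_perm=20_000, seed=1)
        assert t_res.rho == p_res.rho
        assert abs(t_res.p - p_res.p) < 0.05


class TestLeaveOneOut:
    def test_count_contract_five_pairs(self):
        pairs = [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D")]
        rng = np.random.default_rng(2)
        imaging = {k: float(v) for k, v in zip(pairs, rng.uniform(-1, 1, 5))}
        genetic = {k: float(v) for k, v in zip(pairs, rng.uniform(-1, 1, 5))}
        loo = leave_one_out(imaging, genetic)
        assert set(loo) == set(pairs)

    def test_outlier_pair_dominates_sensitivity(self):
        names = [f"D{i}" for i in range(7)]
        pairs = [pair_key(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
        base = np.linspace(-0.4, 0.8, len(pairs))
        imaging = dict(zip(pairs, base))
        genetic = dict(zip(pairs, base))
        outlier = pairs[3]
        genetic[outlier] = 0.9  # gross rank violation for a low-imaging pair
        full = correlation_of_correlations(imaging, genetic).rho
        loo = leave_one_out(imaging, genetic)
        shifts = {k: abs(v - full) for k, v in loo.items()}
        assert max(shifts, key=shifts.get) == outlier

    def test_requires_five_pairs(self):
        tiny = {("A", "B"): 0.1, ("A", "C"): 0.2, ("B", "C"): 0.3, ("A", "D"): 0.4}
        with pytest.raises(ValidationError):
            leave_one_out(tiny, dict(tiny))
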