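"""Exact 2x2 inference against independent oracles.

The rational-arithmetic enumeration oracle used throughout recomputes
hypergeometric tail sums with exact integer weights, independently of the
log-space implementation under test.
"""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact

from carrierscan.exact import (
    ContingencyTable2x2,
    bh_fdr,
    exact_table_test,
    fisher_two_sided,
    hypergeom_pmf,
    or_conditional_mle,
    or_exact_ci,
)
from conftest import random_table


def oracle_minlike_p(a, b, c, d):
    """Minimum-likelihood two-sided p by exact integer enumeration."""
    N, K, n = a + b + c + d, a + c, a + b
    ks = range(max(0, n + K - N), min(n, K) + 1)
    w = {k: comb(K, k) * comb(N - K, n - k) for k in ks}
    tot = sum(w.values())
    # same tie rule as the implementation (w_k / w_a <= 1 + 1e-7), exactly
    num = sum(wk for wk in w.values() if wk * 10**7 <= w[a] * (10**7 + 1))
    return Fraction(num, tot)


class TestHypergeomPmf:
    def test_exact_rational_value(self):
        # oracle: C(5,4) * C(240,33) / C(245,37) reduced with Fraction
        frac = Fraction(comb(5, 4) * comb(240, 33), comb(245, 37))
        assert frac == Fraction(13737360, 7060140549)
        assert hypergeom_pmf(4, 245, 5, 37) == pytest.approx(float(frac), rel=1e-12)

    def test_degenerate_margin(self):
        assert hypergeom_pmf(0, 10, 0, 5) == 1.0

    def test_outside_support_is_zero(self):
        assert hypergeom_pmf(6, 10, 5, 6) == 0.0
        assert hypergeom_pmf(0, 10, 5, 6) == 0.0  # below support min 1

    def test_inconsistent_margins_raise(self):
        with pytest.raises(ValueError):
            hypergeom_pmf(1, 10, 12, 5)

    def test_sums_to_one_over_support(self, rng):
        for _ in range(200):
            N = int(rng.integers(1, 80))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            s = sum(
                hypergeom_pmf(k, N, K, n)
                for k in range(max(0, n + K - N), min(n, K) + 1)
            )
            assert s == pytest.approx(1.0, abs=1e-12)


class TestFisherTwoSided:
    @pytest.mark.parametrize(
        "table,expected,digits",
        [
            ((4, 33, 1, 207), 0.002, 3),      # top-gene carrier table
            ((16, 717, 6, 784), 0.029, 3),    # N- vs C-terminal clustering
        ],
    )
    def test_reference_tables(self, table, expected, digits):
        p = fisher_two_sided(ContingencyTable2x2(*table))
        assert round(p, digits) == expected

    def test_no_carriers_anywhere(self):
        assert fisher_two_sided(ContingencyTable2x2(0, 10, 0, 20)) == 1.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(500):
            a, b, c, d = random_table(rng)
            p = fisher_two_sided(ContingencyTable2x2(a, b, c, d))
            assert p == pytest.approx(float(oracle_minlike_p(a, b, c, d)), rel=1e-10)

    def test_matches_scipy(self, rng):
        # independent library cross-check (scipy uses the same two-sided rule)
        for _ in range(200):
            a, b, c, d = random_table(rng)
            p = fisher_two_sided(ContingencyTable2x2(a, b, c, d))
            assert p == pytest.approx(fisher_exact([[a, b], [c, d]]).pvalue, rel=1e-6)

    def test_doubling_method(self):
        t = ContingencyTable2x2(4, 33, 1, 207)
        p_min = fisher_two_sided(t)
        p_dbl = fisher_two_sided(t, method="doubling")
        assert p_dbl >= p_min  # doubling is never smaller here
        assert p_dbl <= 1.0


class TestConditionalMle:
    def test_top_gene_value(self):
        t = ContingencyTable2x2(4, 33, 1, 207)
        assert or_conditional_mle(t) == pytest.approx(24.52, rel=5e-3)
        # literature-compatible mode reproduces R's printed digits
        assert round(or_conditional_mle(t, method="r-compat"), 2) == 24.52

    def test_symmetric_table_is_one(self):
        assert or_conditional_mle(ContingencyTable2x2(5, 5, 5, 5)) == pytest.approx(1.0, abs=1e-7)

    def test_clustering_table(self):
        t = ContingencyTable2x2(16, 717, 6, 784)
        assert or_conditional_mle(t) == pytest.approx(2.92, abs=0.02)

    def test_boundaries(self):
        assert or_conditional_mle(ContingencyTable2x2(0, 10, 5, 15)) == 0.0
        assert or_conditional_mle(ContingencyTable2x2(5, 5, 0, 20)) == np.inf

    def test_monotone_in_a_with_margins_fixed(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 20))
            m = int(rng.integers(4, 20))
            K = int(rng.integers(2, min(n, m)))
            prev = -1.0
            for a in range(0, K + 1):
                est = or_conditional_mle(ContingencyTable2x2(a, n - a, K - a, m - K + a))
                assert est > prev or (est == np.inf and prev < np.inf)
                prev = est

    def test_attenuation_below_sample_or(self, rng):
        # conditional MLE never exceeds the cross-product ratio when ad > bc
        checked = 0
        for _ in range(300):
            a, b, c, d = random_table(rng)
            if a * d > b * c and b * c > 0:
                t = ContingencyTable2x2(a, b, c, d)
                assert or_conditional_mle(t) <= t.sample_odds_ratio + 1e-9
                checked += 1
        assert checked > 50


class TestExactCi:
    def test_top_gene_interval_r_compat(self):
        t = ContingencyTable2x2(4, 33, 1, 207)
        lo, hi = or_exact_ci(t, method="r-compat")
        assert lo == pytest.approx(2.34, rel=5e-3)
        assert hi == pytest.approx(1231.61, rel=5e-3)

    def test_top_gene_interval_precise(self):
        # the tightly converged tail-inversion roots
        t = ContingencyTable2x2(4, 33, 1, 207)
        lo, hi = or_exact_ci(t)
        assert lo == pytest.approx(2.33639, rel=1e-4)
        assert hi == pytest.approx(1241.206, rel=1e-4)

    def test_interval_contains_estimate(self, rng):
        for _ in range(100):
            a, b, c, d = random_table(rng)
            t = ContingencyTable2x2(a, b, c, d)
            lo, hi = or_exact_ci(t)
            est = or_conditional_mle(t)
            assert lo <= est <= hi or (est == np.inf and hi == np.inf)

    def test_boundary_counts(self):
        lo, hi = or_exact_ci(ContingencyTable2x2(0, 10, 5, 15))
        assert lo == 0.0 and np.isfinite(hi)
        lo, hi = or_exact_ci(ContingencyTable2x2(5, 5, 0, 20))
        assert hi == np.inf and lo > 0.0

    def test_tail_equations_hold_at_bounds(self, rng):
        # verify the defining equations with exact rational weights
        for _ in range(50):
            a, b, c, d = random_table(rng, max_margin=20)
            N, K, n = a + b + c + d, a + c, a + b
            ks = list(range(max(0, n + K - N), min(n, K) + 1))
            if a == ks[0] or a == ks[-1]:
                continue
            w = {k: comb(K, k) * comb(N - K, n - k) for k in ks}
            lo, hi = or_exact_ci(ContingencyTable2x2(a, b, c, d))
            for psi, tail in ((lo, "ge"), (hi, "le")):
                pf = Fraction(psi).limit_denominator(10**12)
                den = sum(w[k] * pf**k for k in ks)
                num = sum(w[k] * pf**k for k in ks if (k >= a if tail == "ge" else k <= a))
                assert float(num / den) == pytest.approx(0.025, rel=1e-5)


class TestBhFdr:
    def test_all_equal(self):
        assert np.allclose(bh_fdr([0.2] * 5), 0.2)

    def test_hand_computed_step_up(self):
        assert np.allclose(bh_fdr([0.001, 0.02, 0.9]), [0.003, 0.03, 0.9])

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_discovery_set_matches_threshold_rule(self, ps):
        """q <= alpha exactly reproduces the classic BH step-up rule."""
        alpha = 0.1
        q = bh_fdr(ps)
        m = len(ps)
        order = np.argsort(ps, kind="mergesort")
        sorted_p = np.asarray(ps)[order]
        passing = np.nonzero(sorted_p <= alpha * (np.arange(m) + 1) / m)[0]
        k = passing.max() + 1 if passing.size else 0
        classic = set(order[:k].tolist())
        assert set(np.nonzero(q <= alpha)[0].tolist()) == classic


class TestResultContainer:
    def test_exact_table_test_bundle(self):
        res = exact_table_test(ContingencyTable2x2(4, 33, 1, 207))
        assert res.ci_low <= res.or_hat <= res.ci_high
        assert res.p_two_sided == pytest.approx(0.002, abs=5e-4)
        assert res.or_sample == pytest.approx(4 * 207 / 33, rel=1e-12)

    def test_table_validation(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 5, 2, 3)
        with pytest.raises(ValueError):
            ContingencyTable2x2(0, 0, 2, 3)
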