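"""RPM normalisation, log2 ratios, the two-library count test, DE calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from soymir.datasets import chilling_de_mirnas
from soymir.diffexpr import (call_differential, count_test, fisher_test,
                             log2_ratio, rpm_normalize)


class TestRpm:
    def test_basic_value(self):
        assert rpm_normalize(5, 1_000_000) == pytest.approx(5.0)

    def test_zero_count(self):
        assert rpm_normalize(0, 1000) == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            rpm_normalize(1, 0)

    def test_library_sums_to_one_million(self):
        counts = [3, 14, 159, 2653]
        total = sum(counts)
        assert sum(rpm_normalize(c, total) for c in counts) == pytest.approx(1e6)


class TestLog2Ratio:
    @pytest.mark.parametrize(
        "control, chilling, expected",
        [(2580.30, 127.89, -4.33), (627.16, 2452.21, 1.97), (71.43, 5.12, -3.80)],
    )
    def test_published_pairs(self, control, chilling, expected):
        assert round(log2_ratio(control, chilling), 2) == expected

    def test_identity(self):
        assert log2_ratio(1234.5, 1234.5) == 0.0

    def test_double_zero_undefined(self):
        assert log2_ratio(0.0, 0.0) is None

    def test_single_zero_with_pseudocount(self):
        assert log2_ratio(0.0, 8.0, pseudocount=1.0) == pytest.approx(np.log2(9.0))


class TestCountTest:
    def test_no_evidence_is_one(self):
        assert count_test(0, 0, 10_000, 10_000) == 1.0

    def test_matches_scipy_binomtest_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            n1, n2 = rng.integers(1_000, 100_000, size=2)
            x, y = int(rng.integers(0, 60)), int(rng.integers(0, 60))
            if x + y == 0:
                continue
            ours = count_test(x, y, int(n1), int(n2))
            ref = stats.binomtest(y, x + y, n2 / (n1 + n2)).pvalue
            assert ours == pytest.approx(ref, rel=1e-9), (x, y, n1, n2)

    def test_direct_summation_oracle_small_counts(self):
        """Exact fraction summation of the conditional distribution."""
        from fractions import Fraction

        def oracle(x, y, n1, n2):
            n = x + y
            p = Fraction(n2, n1 + n2)
            import math
            pmf = [Fraction(math.comb(n, k)) * p**k * (1 - p)**(n - k)
                   for k in range(n + 1)]
            return float(sum(q for q in pmf if q <= pmf[y]))

        for x, y in [(5, 50, ), (0, 3), (7, 7), (2, 19)]:
            assert count_test(x, y, 10**6, 10**6) == pytest.approx(
                oracle(x, y, 10**6, 10**6), rel=1e-6)

    @given(st.integers(0, 40), st.integers(0, 40),
           st.integers(1000, 10**6), st.integers(1000, 10**6))
    @settings(max_examples=60, deadline=None)
    def test_symmetric_under_library_swap(self, x, y, n1, n2):
        assert count_test(x, y, n1, n2) == pytest.approx(
            count_test(y, x, n2, n1), rel=1e-9)

    def test_fisher_alternative_agrees_in_order_of_magnitude(self):
        p1 = count_test(5, 50, 10**6, 10**6)
        p2 = fisher_test(5, 50, 10**6, 10**6)
        assert p1 < 1e-6 and p2 < 1e-6


def _de_frame(rows):
    return pd.DataFrame(rows, columns=["control", "chilling"],
                        index=[f"m{i}" for i in range(len(rows))])


class TestCalls:
    def test_threshold_boundaries(self):
        # counts engineered to straddle the |log2| >= 1 boundary at tiny p
        counts = _de_frame([(1000, 2050), (1000, 990), (4000, 250), (100_000, 101_000)])
        de = call_differential(counts).set_index("mirna_id")
        assert de.loc["m0", "call"] == "up"       # log2 ≈ 1.05, p tiny
        assert de.loc["m2", "call"] == "down"
        assert de.loc["m1", "call"] == "ns"
        assert de.loc["m3", "call"] == "ns"       # log2 ≈ 0.01

    def test_p_gate_blocks_large_ratio(self):
        counts = _de_frame([(2, 9), (5000, 5200)])
        de = call_differential(counts).set_index("mirna_id")
        assert de.loc["m0", "call"] == "ns"  # ratio > 2 but p above 0.001

    def test_sorted_by_log2_ascending(self):
        counts = _de_frame([(10, 1000), (1000, 10), (50, 50)])
        de = call_differential(counts)
        log2s = de["log2_ratio"].dropna().tolist()
        assert log2s == sorted(log2s)

    def test_label_swap_negates_ratios_and_keeps_pvalues(self):
        rng = np.random.default_rng(5)
        counts = _de_frame(rng.integers(0, 500, size=(30, 2)).tolist())
        swapped = counts.rename(columns={"control": "chilling", "chilling": "control"})
        a = call_differential(counts).set_index("mirna_id").sort_index()
        b = call_differential(swapped).set_index("mirna_id").sort_index()
        both = a["log2_ratio"].notna() & b["log2_ratio"].notna()
        finite = np.isfinite(a["log2_ratio"][both])
        assert np.allclose(a["log2_ratio"][both][finite],
                           -b["log2_ratio"][both][finite])
        assert np.allclose(a["p_value"], b["p_value"], rtol=1e-9)


def test_null_simulation_controls_type_one_error(rng):
    """Fold change 1 everywhere: ≤0.5% of miRNAs reach p ≤ 0.001.

    Counts are negative binomial via a shared Gamma latent per miRNA with
    independent Poisson sampling per library, the generative model of the
    synthetic libraries.
    """
    n = 1000
    means = np.exp(rng.uniform(np.log(50), np.log(2000), size=n))
    lam = rng.gamma(10.0, means / 10.0)
    x = rng.poisson(lam)
    y = rng.poisson(lam)
    tot_x, tot_y = int(x.sum()), int(y.sum())
    pvals = np.array([count_test(int(a), int(b), tot_x, tot_y)
                      for a, b in zip(x, y)])
    assert (pvals <= 0.001).mean() <= 0.005


def test_power_at_fold_change_four(rng):
    """Fold change 4 at mean ≥ 50, embedded among null miRNAs: ≥95% called.

    The test conditions on library totals, so differential miRNAs must be
    a minority of total abundance for their relative change to be visible —
    the situation the study design assumes.
    """
    n_de, n_null = 40, 400
    means = np.concatenate([
        np.exp(rng.uniform(np.log(50), np.log(250), size=n_de)),
        np.exp(rng.uniform(np.log(200), np.log(2000), size=n_null))])
    fc = np.concatenate([np.full(n_de, 4.0), np.ones(n_null)])
    lam = rng.gamma(10.0, means / 10.0)
    x = rng.poisson(lam)
    y = rng.poisson(lam * fc)
    counts = pd.DataFrame({"control": x, "chilling": y},
                          index=[f"m{i}" for i in range(n_de + n_null)])
    de = call_differential(counts).set_index("mirna_id")
    recovered = (de.loc[[f"m{i}" for i in range(n_de)], "call"] == "up").mean()
    assert recovered >= 0.95


def test_published_de_table_recomputes():
    table = chilling_de_mirnas()
    recomputed = np.round(np.log2(table["norm_chilling"] / table["norm_control"]), 2)
    assert np.allclose(recomputed, table["log2_reported"], atol=0.011)
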