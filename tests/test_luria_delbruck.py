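"""Fluctuation-assay estimator tests against closed forms and the branching oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mutscale.luria_delbruck import (
    MutantCountSample,
    NoCountablePlatesError,
    P0InapplicableError,
    PlateCountSet,
    TruncationLimitError,
    cfu_from_plates,
    estimate_m_mle,
    estimate_m_p0,
    estimate_rate,
    ld_pmf,
    mutation_rate_per_bp,
)
from mutscale.synthetic_data import sample_ld_counts


class TestLdPmf:
    def test_zero_mutations_concentrates_at_zero(self):
        assert np.allclose(ld_pmf(0.0, 3).pmf, [1, 0, 0, 0])

    def test_p0_is_exp_minus_m(self):
        assert ld_pmf(1.0, 0).pmf[0] == pytest.approx(0.367879, abs=1e-6)

    def test_low_count_cells_match_recursion_values(self):
        # frozen from the MSS recursion, cross-validated against the
        # branching oracle (1e6 cultures) in test_synthetic_data
        pmf = ld_pmf(1.0, 2).pmf
        assert pmf[1] == pytest.approx(0.183940, abs=1e-6)
        assert pmf[2] == pytest.approx(0.107298, abs=1e-6)

    def test_negative_m_rejected(self):
        with pytest.raises(ValueError):
            ld_pmf(-0.5, 10)

    @settings(max_examples=25, deadline=None)
    @given(m=st.floats(0.0, 5.0), n_max=st.integers(1, 60))
    def test_pmf_invariants(self, m, n_max):
        dist = ld_pmf(m, n_max)
        p = dist.pmf
        assert p[0] == pytest.approx(math.exp(-m), abs=1e-12)
        assert np.all(p >= 0) and np.all(p <= 1)
        assert np.all(np.cumsum(p) <= 1 + 1e-12)
        # monotone decreasing beyond the mode (for m <= 2 the mode is
        # below ceil(m); for larger m it shifts right)
        start = max(int(np.argmax(p)), int(math.ceil(m)) if m <= 2 else 0, 1)
        tail = p[start:]
        assert np.all(np.diff(tail) <= 1e-15)


class TestP0:
    def test_inverts_zero_fraction(self):
        counts = [0] * 37 + [3] * 63
        s = MutantCountSample("s", "M63", tuple(counts))
        assert estimate_m_p0(s) == pytest.approx(-math.log(0.37), abs=1e-12)

    def test_all_zero_gives_zero(self):
        s = MutantCountSample("s", "M63", (0,) * 10)
        assert estimate_m_p0(s) == 0.0

    def test_no_zeros_inapplicable(self):
        s = MutantCountSample("s", "M63", (1, 2, 3))
        with pytest.raises(P0InapplicableError):
            estimate_m_p0(s)


class TestMle:
    def test_all_zero_boundary(self):
        est = estimate_m_mle(MutantCountSample("s", "M63", (0,) * 20))
        assert est.m_hat == 0.0
        assert est.ci_low == 0.0
        assert est.ci_high > 0

    def test_recovers_generating_m(self):
        sample = sample_ld_counts(2.0, 1000, seed=7)
        est = estimate_m_mle(sample, compute_ci=False)
        assert est.m_hat == pytest.approx(2.0, rel=0.10)

    def test_single_culture_rejected(self):
        with pytest.raises(ValueError):
            MutantCountSample("s", "M63", (5,))

    def test_truncation_error_without_tail_bin(self):
        s = MutantCountSample("s", "M63", (0, 2, 150))
        with pytest.raises(TruncationLimitError):
            estimate_m_mle(s, n_max=100, tail_bin=False)

    def test_tail_binning_censors_jackpots(self):
        s = MutantCountSample("s", "M63", (0, 1, 0, 2, 0, 1, 150))
        capped = estimate_m_mle(s, n_max=100, compute_ci=False)
        full = estimate_m_mle(s, compute_ci=False)
        # censoring at 100 loses little information about m
        assert capped.m_hat == pytest.approx(full.m_hat, rel=0.15)

    def test_ci_brackets_estimate(self):
        sample = sample_ld_counts(1.0, 100, seed=3)
        est = estimate_m_mle(sample)
        assert est.ci_low < est.m_hat < est.ci_high

    def test_estimator_consistency_and_p0_agreement(self):
        """Mean MLE over seeded replicates near truth; P0 agrees within 10%."""
        mles, p0s = [], []
        for seed in range(50):
            s = sample_ld_counts(1.0, 200, seed=1000 + seed)
            mles.append(estimate_m_mle(s, compute_ci=False).m_hat)
            p0s.append(estimate_m_p0(s))
        assert np.mean(mles) == pytest.approx(1.0, rel=0.05)
        assert np.mean(p0s) == pytest.approx(np.mean(mles), rel=0.10)


class TestCfu:
    def test_reliability_filter(self):
        plates = PlateCountSet((8, 52, 187, 540), 1e6, 0.1)
        est = cfu_from_plates(plates)
        assert est.cells_per_ml == pytest.approx(1.195e9)
        assert est.n_reliable == 2
        assert est.n_plates == 4

    def test_closed_interval_bounds_included(self):
        est = cfu_from_plates(PlateCountSet((10, 500), 1.0, 1.0))
        assert float(est) == pytest.approx(255.0)

    def test_no_countable_plates(self):
        with pytest.raises(NoCountablePlatesError):
            cfu_from_plates(PlateCountSet((5, 600), 1.0, 1.0))

    def test_order_invariance_and_dilution_linearity(self):
        a = cfu_from_plates(PlateCountSet((52, 187, 30), 1e5, 0.1))
        b = cfu_from_plates(PlateCountSet((30, 52, 187), 1e5, 0.1))
        c = cfu_from_plates(PlateCountSet((52, 187, 30), 3e5, 0.1))
        assert a.cells_per_ml == b.cells_per_ml
        assert c.cells_per_ml == pytest.approx(3 * a.cells_per_ml)


class TestRateConversion:
    @pytest.mark.parametrize(
        "m_hat,nt,size,expected",
        [(1.0, 1e9, 1.0, 1e-9), (0.0, 1e9, 1.0, 0.0), (2.0, 1e9, 50.0, 4e-11)],
    )
    def test_per_bp_rate(self, m_hat, nt, size, expected):
        assert mutation_rate_per_bp(m_hat, nt, size) == pytest.approx(expected)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            mutation_rate_per_bp(1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            mutation_rate_per_bp(1.0, 1e9, -1.0)

    def test_estimate_rate_ties_fields_together(self):
        sample = sample_ld_counts(2.0, 200, seed=5)
        est = estimate_rate(sample, N_t=1e9, target_size_bp=1.0)
        assert est.M == pytest.approx(est.m_hat / 1e9)
        assert est.ci_low <= est.m_hat <= est.ci_high
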