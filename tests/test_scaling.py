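"""Scaling-law fits, rank statistics, permutation tests, expression helpers."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mutscale.scaling import (
    DegeneratePredictorError,
    InsufficientObservationsError,
    correlate_expression_growth,
    fit_genome_scaling,
    fit_growth_mutation,
    media_shift_test,
    normalize_expression,
    pearson_r,
    permutation_pvalue,
    spearman_rho,
)


def _obs(g, m, mu=None, medium="M63"):
    return pd.DataFrame(
        {
            "strain_id": [f"s{i}" for i in range(len(g))],
            "medium": medium,
            "genome_size_mb": g,
            "mutation_rate": m,
            "growth_rate": mu if mu is not None else np.ones(len(g)),
        }
    )


class TestGenomeScalingFit:
    def test_exact_collinear_recovery(self):
        g = np.linspace(3.62, 4.65, 5)
        m = 10 ** (-14.6 * np.log10(g) + 1.0)
        fit = fit_genome_scaling(_obs(g, m), n_perm=100, seed=0)
        assert fit.r == pytest.approx(-14.6, abs=1e-9)
        assert fit.b == pytest.approx(1.0, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.spearman_rho == pytest.approx(-1.0)

    def test_constant_rates_flagged(self):
        g = np.linspace(3.6, 4.6, 4)
        fit = fit_genome_scaling(_obs(g, np.full(4, 1e-9)), n_perm=50, seed=0)
        assert fit.r == pytest.approx(0.0)
        assert fit.rho_flagged
        assert fit.spearman_rho == 0.0

    def test_insufficient_observations(self):
        with pytest.raises(InsufficientObservationsError):
            fit_genome_scaling(_obs([4.0, 4.5], [1e-9, 2e-9]))

    def test_mixed_media_rejected(self):
        df = _obs(np.linspace(3.6, 4.6, 4), np.full(4, 1e-9))
        df.loc[0, "medium"] = "LB"
        with pytest.raises(ValueError):
            fit_genome_scaling(df)


class TestGrowthMutationFit:
    def test_exact_collinear_recovery(self):
        mu = np.array([0.2, 0.35, 0.5, 0.65])
        m = 10 ** (-6.1 - 4.9 * mu)
        fit = fit_growth_mutation(_obs(np.full(4, 4.0), m, mu), n_perm=100, seed=0)
        assert fit.alpha == pytest.approx(-4.9, abs=1e-9)
        assert fit.log10_M0 == pytest.approx(-6.1, abs=1e-9)
        assert fit.M0 == pytest.approx(10**-6.1, rel=1e-9)

    def test_degenerate_predictor(self):
        with pytest.raises(DegeneratePredictorError):
            fit_growth_mutation(
                _obs(np.full(4, 4.0), [1e-9, 2e-9, 3e-9, 4e-9], np.full(4, 0.5))
            )

    def test_rate_rescaling_moves_intercept_not_slope(self):
        mu = np.array([0.2, 0.4, 0.6, 0.8])
        m = 10 ** (-6.0 - 3.0 * mu) * (1 + 0.05 * np.sin(np.arange(4)))
        base = fit_growth_mutation(_obs(np.full(4, 4.0), m, mu), n_perm=10, seed=0)
        scaled = fit_growth_mutation(
            _obs(np.full(4, 4.0), 100 * m, mu), n_perm=10, seed=0
        )
        assert scaled.alpha == pytest.approx(base.alpha, rel=1e-9)
        assert scaled.log10_M0 == pytest.approx(base.log10_M0 + 2.0, abs=1e-9)


class TestRankStatistics:
    def test_perfect_anticorrelation(self):
        assert spearman_rho(range(1, 6), range(5, 0, -1)) == pytest.approx(-1.0)

    def test_identity_correlation(self):
        x = [3.0, 1.0, 2.0, 5.0]
        assert spearman_rho(x, x) == pytest.approx(1.0)

    def test_midrank_ties_hand_value(self):
        # ranks of y=[2,2,3] are [1.5, 1.5, 3]; Pearson vs [1,2,3] = sqrt(3)/2
        assert spearman_rho([1, 2, 3], [2, 2, 3]) == pytest.approx(
            math.sqrt(3) / 2, abs=1e-4
        )

    def test_zero_rank_variance_undefined(self):
        assert math.isnan(spearman_rho([1, 2, 3], [7, 7, 7]))

    def test_pearson_signs(self):
        assert pearson_r([1, 2, 3], [6, 4, 2]) == pytest.approx(-1.0)
        assert pearson_r([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert math.isnan(pearson_r([1, 1, 1], [1, 2, 3]))

    @settings(max_examples=20, deadline=None)
    @given(
        st.lists(st.integers(-300, 300), min_size=4, max_size=12, unique=True)
    )
    def test_monotone_transform_invariance(self, xs):
        x = np.array(xs, dtype=float)
        y = np.sin(x) + 0.1 * x  # arbitrary paired variable
        rho = spearman_rho(x, y)
        assert spearman_rho(np.exp(x / 50), y) == pytest.approx(rho, abs=1e-12)
        assert spearman_rho(x, 3 * y - 7) == pytest.approx(rho, abs=1e-12)


class TestPermutationPvalues:
    def test_exact_enumeration_identity(self):
        p = permutation_pvalue([1, 2, 3], [1, 2, 3], "spearman", alternative="greater")
        assert p == pytest.approx(1 / 6)

    def test_exact_enumeration_anticorrelated(self):
        p = permutation_pvalue(
            [1, 2, 3, 4, 5], [5, 4, 3, 2, 1], "spearman", alternative="less"
        )
        assert p == pytest.approx(1 / 120)

    def test_two_sided_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for n in (6, 12):
            x, y = rng.normal(size=n), rng.normal(size=n)
            p = permutation_pvalue(x, y, "pearson", n_perm=200, seed=1)
            assert 0 < p <= 1

    def test_monte_carlo_add_one_floor(self):
        x = np.arange(12.0)
        p = permutation_pvalue(x, x, "spearman", n_perm=99, seed=0,
                               alternative="greater")
        assert p == pytest.approx(1 / 100)


class TestMediaShift:
    def test_uniform_shift_most_extreme_p(self):
        poor = 10 ** (-8 + 0.1 * np.arange(10))
        rich = poor / 3.0
        res = media_shift_test(poor, rich)
        assert res.p_value == pytest.approx(2.0**-10)
        assert res.direction == "poor>rich"

    def test_identical_rates_p_one(self):
        rates = 10 ** (-9 + 0.2 * np.arange(8))
        res = media_shift_test(rates, rates)
        assert res.p_value == 1.0
        assert res.flagged

    def test_needs_five_pairs(self):
        with pytest.raises(ValueError):
            media_shift_test([1e-9] * 4, [1e-8] * 4)


class TestExpression:
    def test_column_means_equalized(self):
        df = pd.DataFrame({"a": [7.0, 9.0], "b": [9.0, 11.0]})
        norm = normalize_expression(df)
        assert norm["a"].mean() == pytest.approx(9.0)
        assert norm["b"].mean() == pytest.approx(9.0)

    def test_single_column_unchanged(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        assert normalize_expression(df).equals(df)

    def test_replicate_averaging(self):
        df = pd.DataFrame({"c1r1": [8.0, 10.0], "c1r2": [10.0, 12.0]})
        norm = normalize_expression(df, replicate_groups={"c1": ["c1r1", "c1r2"]})
        assert list(norm.columns) == ["c1"]

    def test_gene_equal_to_growth_has_unit_correlation(self):
        mu = np.array([0.2, 0.4, 0.5, 0.7, 0.9])
        expr = pd.DataFrame([mu, np.full(5, 3.0)], index=["g1", "gflat"])
        res = correlate_expression_growth(expr, mu, n_perm=50, seed=0)
        assert res.loc["g1", "r"] == pytest.approx(1.0)
        assert res.loc["gflat", "flagged"]
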