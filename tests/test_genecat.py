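"""Deleted-gene category counting and rate-correlation heat maps."""

import numpy as np
import pandas as pd
import pytest

from mutscale.genecat import (
    DEFAULT_CATEGORIES,
    GeneCategoryTable,
    UnknownCategoryError,
    category_correlation,
    cumulative_deletion_counts,
    filter_categories,
)
from mutscale.synthetic_data import gen_gene_category_table


def _records(rows):
    return pd.DataFrame(rows, columns=["strain_id", "gene_id", "category"])


def _table(final_counts, strains=("wt", "r1")):
    cum = pd.DataFrame(
        [np.zeros(len(final_counts), dtype=int), list(final_counts.values())],
        index=list(strains),
        columns=list(final_counts),
    )
    return GeneCategoryTable(cumulative=cum, totals=cum.iloc[-1] + 5)


class TestCumulativeCounts:
    def test_empty_records_all_zero(self):
        table = cumulative_deletion_counts(_records([]), ["wt", "r1", "r2"])
        assert (table.cumulative.to_numpy() == 0).all()

    def test_running_sum_of_new_genes(self):
        rows = (
            [("r1", f"t{i}", "t") for i in range(2)]
            + [("r2", f"t{i}", "t") for i in range(2, 5)]
            + [("r3", f"t{i}", "t") for i in range(5, 10)]
        )
        table = cumulative_deletion_counts(_records(rows), ["wt", "r1", "r2", "r3"])
        assert list(table.cumulative["t"]) == [0, 2, 5, 10]

    def test_unknown_category_named_in_error(self):
        with pytest.raises(UnknownCategoryError, match="zz"):
            cumulative_deletion_counts(_records([("r1", "g1", "zz")]), ["wt", "r1"])

    def test_duplicates_dropped_with_warning(self):
        rows = [("r1", "g1", "t"), ("r1", "g1", "t"), ("r1", "g2", "t")]
        with pytest.warns(UserWarning, match="duplicate"):
            table = cumulative_deletion_counts(_records(rows), ["wt", "r1"])
        assert table.cumulative.loc["r1", "t"] == 2

    def test_generator_output_is_monotone(self):
        d = gen_gene_category_table(seed=3)
        table = cumulative_deletion_counts(
            d.records, list(d.series_order), totals=d.totals
        )
        assert (np.diff(table.cumulative.to_numpy(), axis=0) >= 0).all()
        assert (table.cumulative.iloc[0] == 0).all()


class TestFilter:
    def test_strictly_greater_than_threshold(self):
        table = _table({"d": 44, "k": 8, "t": 25})
        assert filter_categories(table) == ["d", "t"]

    def test_exactly_ten_excluded(self):
        table = _table({"d": 10, "t": 11})
        assert filter_categories(table) == ["t"]

    def test_zero_threshold_keeps_any_deleted(self):
        table = _table({"d": 1, "k": 0, "t": 3})
        assert filter_categories(table, min_deleted=0) == ["d", "t"]

    def test_default_synthetic_table_retains_14(self):
        d = gen_gene_category_table(seed=0)
        table = cumulative_deletion_counts(
            d.records, list(d.series_order), totals=d.totals
        )
        assert len(filter_categories(table)) == 14


class TestCategoryCorrelation:
    def _obs(self, strains, rates, medium="M63"):
        return pd.DataFrame(
            {"strain_id": strains, "medium": medium, "mutation_rate": rates}
        )

    def test_proportional_counts_correlate_perfectly(self):
        strains = ["wt", "r1", "r2", "r3"]
        log_m = np.array([-9.0, -8.5, -8.0, -7.5])
        cum = pd.DataFrame(
            {"t": [0, 10, 20, 30], "d": [0, 1, 1, 1]}, index=strains
        )
        table = GeneCategoryTable(cumulative=cum, totals=cum.iloc[-1] + 100)
        res = category_correlation(
            table, self._obs(strains, 10.0**log_m), n_perm=200, seed=0
        )
        assert res.correlation.loc["t", "M63"] == pytest.approx(1.0)

    def test_constant_column_flagged(self):
        strains = ["wt", "r1", "r2"]
        cum = pd.DataFrame({"t": [0, 0, 0]}, index=strains)
        table = GeneCategoryTable(cumulative=cum, totals=cum.iloc[-1] + 1)
        res = category_correlation(
            table, self._obs(strains, [1e-9, 2e-9, 4e-9]), n_perm=50, seed=0
        )
        assert ("t", "M63") in res.flagged
        assert np.isnan(res.correlation.loc["t", "M63"])

    def test_consistent_strain_relabeling_invariance(self):
        strains = ["wt", "r1", "r2", "r3"]
        rng = np.random.default_rng(5)
        cum = pd.DataFrame(
            {"t": np.sort(rng.integers(0, 20, 4)), "d": np.sort(rng.integers(0, 9, 4))},
            index=strains,
        )
        cum.iloc[0] = 0
        table = GeneCategoryTable(cumulative=cum, totals=cum.iloc[-1] + 50)
        rates = [1e-9, 3e-9, 2e-9, 9e-9]
        res1 = category_correlation(table, self._obs(strains, rates), n_perm=99, seed=2)
        renamed = {s: f"x{s}" for s in strains}
        cum2 = cum.rename(index=renamed)
        table2 = GeneCategoryTable(cumulative=cum2, totals=table.totals)
        res2 = category_correlation(
            table2, self._obs([renamed[s] for s in strains], rates), n_perm=99, seed=2
        )
        assert np.allclose(
            res1.correlation.to_numpy(dtype=float),
            res2.correlation.to_numpy(dtype=float),
        )

    def test_neg_log10_p_finite_and_nonnegative(self):
        d = gen_gene_category_table(seed=1)
        table = cumulative_deletion_counts(
            d.records, list(d.series_order), totals=d.totals
        )
        kept = filter_categories(table)
        rng = np.random.default_rng(0)
        rates = 10 ** (-9 + 0.15 * np.arange(10) + rng.normal(0, 0.05, 10))
        res = category_correlation(
            table,
            self._obs(list(d.series_order), rates),
            categories=kept,
            n_perm=500,
            seed=0,
        )
        vals = res.neg_log10_p.to_numpy(dtype=float)
        assert np.isfinite(vals).all()
        assert (vals >= 0).all()


class TestTableInvariants:
    def test_non_monotone_rejected(self):
        cum = pd.DataFrame({"t": [0, 5, 3]}, index=["wt", "r1", "r2"])
        with pytest.raises(ValueError):
            GeneCategoryTable(cumulative=cum, totals=pd.Series({"t": 10}))

    def test_nonzero_wild_type_rejected(self):
        cum = pd.DataFrame({"t": [1, 5]}, index=["wt", "r1"])
        with pytest.raises(ValueError):
            GeneCategoryTable(cumulative=cum, totals=pd.Series({"t": 10}))

    def test_vocabulary_has_23_codes(self):
        assert len(DEFAULT_CATEGORIES) == 23
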