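"""Deleted-gene category counting and correlation with mutation rates.

Genes removed along a genome-reduction series are classified into 23
functional categories (Riley-style single/short-letter codes, configurable:
the code list is study metadata, not biology hard-wired here). Deletions
accumulate down the series, so the per-category cumulative count is
non-decreasing; categories with more than ``min_deleted`` genes removed in
the most-reduced strain are correlated (per medium) with log10 mutation
rates across the series, giving a category x medium heat map of -log10 p.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scaling import pearson_r, permutation_pvalue, spearman_rho

__all__ = [
    "DEFAULT_CATEGORIES",
    "CATEGORY_NAMES",
    "DeletionRecord",
    "GeneCategoryTable",
    "CategoryCorrelationResult",
    "UnknownCategoryError",
    "cumulative_deletion_counts",
    "filter_categories",
    "category_correlation",
]

# 23 functional category codes (Riley-style). Configurable: pass your own
# vocabulary to cumulative_deletion_counts for a different classification.
CATEGORY_NAMES: dict[str, str] = {
    "e": "enzyme",
    "pe": "predicted enzyme",
    "f": "factor",
    "pf": "predicted factor",
    "t": "transporter",
    "pt": "predicted transporter",
    "r": "regulator",
    "pr": "predicted regulator",
    "m": "membrane",
    "pm": "predicted membrane",
    "lp": "lipoprotein",
    "plp": "predicted lipoprotein",
    "s": "structural component",
    "ps": "predicted structural component",
    "c": "carrier",
    "pc": "predicted carrier",
    "rna": "RNA gene",
    "ph": "phage/transposon related",
    "tu": "transcription unit component",
    "d": "partial information",
    "o": "ORF, unknown function",
    "ou": "ORF, unknown function, conserved",
    "u": "unclassified",
}
DEFAULT_CATEGORIES: tuple[str, ...] = tuple(CATEGORY_NAMES)


class UnknownCategoryError(ValueError):
    pass


@dataclass(frozen=True)
class DeletionRecord:
    strain_id: str
    gene_id: str
    category: str


@dataclass(frozen=True)
class GeneCategoryTable:
    """Cumulative deleted-gene counts per category along a reduction series.

    ``cumulative`` is a strains x categories frame (wild type first, all
    zeros); ``totals`` holds the per-category gene totals of the wild-type
    genome.
    """

    cumulative: pd.DataFrame
    totals: pd.Series

    strains: tuple[str, ...] = field(init=False)
    categories: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "strains", tuple(self.cumulative.index))
        object.__setattr__(self, "categories", tuple(self.cumulative.columns))
        vals = self.cumulative.to_numpy()
        if np.any(np.diff(vals, axis=0) < 0):
            raise ValueError("cumulative counts must be non-decreasing down the series")
        if np.any(vals[0] != 0):
            raise ValueError("wild-type (first) row must be all zeros")
        if np.any(vals > self.totals.reindex(self.cumulative.columns).to_numpy()):
            raise ValueError("cumulative counts exceed per-category totals")


@dataclass(frozen=True)
class CategoryCorrelationResult:
    correlation: pd.DataFrame  # category x medium
    p_value: pd.DataFrame
    neg_log10_p: pd.DataFrame
    flagged: tuple[tuple[str, str], ...]  # (category, medium) cells left undefined


def cumulative_deletion_counts(
    records: pd.DataFrame,
    series_order: list[str],
    categories: tuple[str, ...] = DEFAULT_CATEGORIES,
    totals: pd.Series | None = None,
) -> GeneCategoryTable:
    """Count distinct deleted genes per category, cumulatively along the series.

    ``records`` needs columns strain_id, gene_id, category; row i of the
    result counts genes of each category deleted anywhere in strains 1..i of
    ``series_order`` (deletions are nested in a reduction series, so listing
    only newly deleted genes per strain gives the same table). Duplicate
    (strain, gene) pairs are deduplicated with a warning. When ``totals`` is
    omitted the final cumulative row is used as the per-category total.
    """
    records = records[["strain_id", "gene_id", "category"]].copy()
    unknown = set(records["category"]) - set(categories)
    if unknown:
        raise UnknownCategoryError(
            f"unknown category code(s): {sorted(unknown)}; "
            f"valid codes: {list(categories)}"
        )
    dup = records.duplicated(subset=["strain_id", "gene_id"])
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} duplicate (strain, gene) deletion records dropped",
            stacklevel=2,
        )
        records = records[~dup]

    seen_genes: set[str] = set()
    gene_cat: dict[str, str] = {}
    rows = []
    counts = {c: 0 for c in categories}
    for strain in series_order:
        sub = records[records["strain_id"] == strain]
        for gene, cat in zip(sub["gene_id"], sub["category"]):
            if gene in seen_genes:
                continue
            seen_genes.add(gene)
            gene_cat[gene] = cat
            counts[cat] += 1
        rows.append([counts[c] for c in categories])
    cumulative = pd.DataFrame(rows, index=list(series_order), columns=list(categories))
    if totals is None:
        totals = cumulative.iloc[-1].copy()
    return GeneCategoryTable(cumulative=cumulative, totals=totals)


def filter_categories(table: GeneCategoryTable, min_deleted: int = 10) -> list[str]:
    """Categories whose final cumulative count strictly exceeds ``min_deleted``."""
    final = table.cumulative.iloc[-1]
    return [c for c in table.categories if final[c] > min_deleted]


def category_correlation(
    table: GeneCategoryTable,
    obs: pd.DataFrame,
    categories: list[str] | None = None,
    method: str = "pearson",
    include_wild_type: bool = True,
    n_perm: int = 10_000,
    seed: int = 0,
) -> CategoryCorrelationResult:
    """Correlate per-category cumulative deletions with log10 mutation rates.

    ``obs`` needs columns strain_id, medium, mutation_rate covering the
    table's strains for each medium. Per (category, medium) the Pearson
    correlation (Spearman via ``method="spearman"``) between cumulative
    deleted-gene count and log10 rate is computed with a seeded permutation
    p-value; p is floored at 1/(n_perm + 1) so -log10 p stays finite.
    Constant category columns are flagged undefined and excluded.
    """
    if categories is None:
        categories = list(table.categories)
    strains = list(table.strains) if include_wild_type else list(table.strains)[1:]
    stat_fn = {"pearson": pearson_r, "spearman": spearman_rho}[method]
    media = list(dict.fromkeys(obs["medium"]))
    corr = pd.DataFrame(index=categories, columns=media, dtype=float)
    pval = pd.DataFrame(index=categories, columns=media, dtype=float)
    flagged: list[tuple[str, str]] = []
    for medium in media:
        sub = obs[obs["medium"] == medium].set_index("strain_id")
        missing = [s for s in strains if s not in sub.index]
        if missing:
            raise ValueError(
                f"strains missing from observations for {medium}: {missing}"
            )
        log_m = np.log10(sub.loc[strains, "mutation_rate"].to_numpy(dtype=float))
        for cat in categories:
            x = table.cumulative.loc[strains, cat].to_numpy(dtype=float)
            r = stat_fn(x, log_m)
            if math.isnan(r):
                flagged.append((cat, medium))
                continue
            p = permutation_pvalue(
                x, log_m, method, n_perm=n_perm, seed=seed, alternative="two-sided"
            )
            p = max(p, 1.0 / (n_perm + 1))
            corr.loc[cat, medium] = r
            pval.loc[cat, medium] = p
    neg = -np.log10(pval)
    return CategoryCorrelationResult(
        correlation=corr, p_value=pval, neg_log10_p=neg, flagged=tuple(flagged)
    )
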