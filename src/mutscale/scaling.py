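"""Scaling-law fits and correlation statistics.

Two empirical laws link the per-bp mutation rate M of a genome-reduced
strain to its genome size G (Mb) and exponential growth rate mu (h^-1):

    log10(M) = r * log10(G) + b          (genome-size scaling)
    log10(M) = log10(M0) + alpha * mu    (growth-rate coupling)

Both are fit by ordinary least squares on log10 rates, with Spearman rank
correlations and seeded permutation p-values attached (exact enumeration for
n <= 8, Monte-Carlo with add-one correction otherwise). A paired one-sided
exact Wilcoxon signed-rank test quantifies the shift of mutation rates
between a poorer and a richer medium, and helpers normalize log expression
matrices and correlate per-gene expression with growth rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StrainObservation",
    "GenomeScalingFit",
    "GrowthMutationFit",
    "MediaShiftResult",
    "InsufficientObservationsError",
    "DegeneratePredictorError",
    "spearman_rho",
    "pearson_r",
    "permutation_pvalue",
    "fit_genome_scaling",
    "fit_growth_mutation",
    "media_shift_test",
    "normalize_expression",
    "correlate_expression_growth",
    "observations_frame",
]

EXACT_ENUMERATION_MAX_N = 8  # 8! = 40320 permutations


class InsufficientObservationsError(ValueError):
    pass


class DegeneratePredictorError(ValueError):
    pass


@dataclass(frozen=True)
class StrainObservation:
    """One strain in one medium: genome size, mutation rate, growth rate."""

    strain_id: str
    medium: str
    genome_size_mb: float
    M: float  # mutation rate, per bp per division
    mu: float  # growth rate, h^-1

    def __post_init__(self) -> None:
        if self.genome_size_mb <= 0:
            raise ValueError("genome_size_mb must be positive")
        if self.M <= 0:
            raise ValueError("mutation rate must be positive")


def observations_frame(obs: list[StrainObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "strain_id": [o.strain_id for o in obs],
            "medium": [o.medium for o in obs],
            "genome_size_mb": [o.genome_size_mb for o in obs],
            "mutation_rate": [o.M for o in obs],
            "growth_rate": [o.mu for o in obs],
        }
    )


@dataclass(frozen=True)
class GenomeScalingFit:
    r: float  # slope, log10 rate per log10 Mb
    b: float  # intercept
    r2: float
    spearman_rho: float
    p_value: float
    rho_flagged: bool = False


@dataclass(frozen=True)
class GrowthMutationFit:
    alpha: float  # slope, log10 rate per h^-1
    log10_M0: float
    r2: float
    spearman_rho: float
    p_value: float
    rho_flagged: bool = False

    @property
    def M0(self) -> float:
        return 10.0 ** self.log10_M0


@dataclass(frozen=True)
class MediaShiftResult:
    p_value: float
    direction: str  # "poor>rich", "rich>poor" or "none"
    n_pairs: int
    flagged: bool = False


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Ties get average ranks. Returns NaN (undefined) when either rank vector
    has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    return pearson_r(stats.rankdata(x), stats.rankdata(y))


def pearson_r(x, y) -> float:
    """Product-moment correlation; NaN when either variable is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.dot(xc, xc))
    sy = float(np.dot(yc, yc))
    if sx < 1e-24 or sy < 1e-24:
        return math.nan
    return float(np.dot(xc, yc) / math.sqrt(sx * sy))


def _stat(name: str):
    if name == "spearman":
        return spearman_rho
    if name == "pearson":
        return pearson_r
    raise ValueError(f"unknown statistic {name!r}")


def permutation_pvalue(
    x,
    y,
    statistic: str = "spearman",
    n_perm: int = 10_000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> float:
    """Permutation p-value for a correlation statistic.

    Exact enumeration of all n! pairings when n <= 8; otherwise seeded
    Monte-Carlo with the add-one correction (b + 1)/(n_perm + 1). NaN
    observed statistics (constant input) give NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    fn = _stat(statistic)
    obs = fn(x, y)
    if math.isnan(obs):
        return math.nan
    tol = 1e-12

    def tail_hit(s: float) -> bool:
        if alternative == "greater":
            return s >= obs - tol
        if alternative == "less":
            return s <= obs + tol
        return abs(s) >= abs(obs) - tol

    n = len(x)
    if n <= EXACT_ENUMERATION_MAX_N:
        hits = total = 0
        for perm in permutations(range(n)):
            total += 1
            if tail_hit(fn(x, y[list(perm)])):
                hits += 1
        return hits / total
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if tail_hit(fn(x, rng.permutation(y))):
            hits += 1
    return (hits + 1) / (n_perm + 1)


def _check_one_medium(df: pd.DataFrame) -> None:
    media = df["medium"].unique()
    if len(media) > 1:
        raise ValueError(f"observations span several media: {sorted(media)}")
    if len(df) < 3:
        raise InsufficientObservationsError(
            f"insufficient observations: {len(df)} < 3"
        )


def fit_genome_scaling(
    obs: pd.DataFrame, n_perm: int = 10_000, seed: int = 0
) -> GenomeScalingFit:
    """OLS of log10(mutation rate) on log10(genome size) for one medium.

    ``obs`` needs columns genome_size_mb, mutation_rate, medium. Attaches
    the Spearman correlation of rate vs size and its permutation p-value.
    """
    _check_one_medium(obs)
    g = np.log10(obs["genome_size_mb"].to_numpy(dtype=float))
    m = np.log10(obs["mutation_rate"].to_numpy(dtype=float))
    if np.ptp(g) == 0:
        raise DegeneratePredictorError("all genome sizes identical")
    res = stats.linregress(g, m)
    rho = spearman_rho(obs["mutation_rate"], obs["genome_size_mb"])
    flagged = math.isnan(rho)
    p = (
        1.0
        if flagged
        else permutation_pvalue(
            obs["genome_size_mb"].to_numpy(dtype=float),
            obs["mutation_rate"].to_numpy(dtype=float),
            "spearman",
            n_perm=n_perm,
            seed=seed,
        )
    )
    return GenomeScalingFit(
        r=float(res.slope),
        b=float(res.intercept),
        r2=float(res.rvalue**2) if not math.isnan(res.rvalue) else 0.0,
        spearman_rho=0.0 if flagged else float(rho),
        p_value=float(p),
        rho_flagged=flagged,
    )


def fit_growth_mutation(
    obs: pd.DataFrame, n_perm: int = 10_000, seed: int = 0
) -> GrowthMutationFit:
    """OLS of log10(mutation rate) on growth rate for one medium."""
    _check_one_medium(obs)
    mu = obs["growth_rate"].to_numpy(dtype=float)
    m = np.log10(obs["mutation_rate"].to_numpy(dtype=float))
    if np.ptp(mu) == 0:
        raise DegeneratePredictorError("degenerate predictor: growth rate constant")
    res = stats.linregress(mu, m)
    rho = spearman_rho(obs["growth_rate"], obs["mutation_rate"])
    flagged = math.isnan(rho)
    p = (
        1.0
        if flagged
        else permutation_pvalue(
            mu,
            obs["mutation_rate"].to_numpy(dtype=float),
            "spearman",
            n_perm=n_perm,
            seed=seed,
        )
    )
    return GrowthMutationFit(
        alpha=float(res.slope),
        log10_M0=float(res.intercept),
        r2=float(res.rvalue**2) if not math.isnan(res.rvalue) else 0.0,
        spearman_rho=0.0 if flagged else float(rho),
        p_value=float(p),
        rho_flagged=flagged,
    )


def media_shift_test(rates_poor, rates_rich) -> MediaShiftResult:
    """Paired one-sided exact Wilcoxon signed-rank test on log10 rates.

    Tests whether mutation rates in the poorer medium are shifted above
    those in the richer medium, pairing strains. Zero differences are
    dropped (standard practice); all-zero differences give p = 1, flagged.
    """
    poor = np.log10(np.asarray(rates_poor, dtype=float))
    rich = np.log10(np.asarray(rates_rich, dtype=float))
    if poor.shape != rich.shape:
        raise ValueError("paired rate vectors must have equal length")
    if len(poor) < 5:
        raise ValueError("need at least 5 paired strains")
    d = poor - rich
    nz = d[d != 0]
    if nz.size == 0:
        return MediaShiftResult(p_value=1.0, direction="none", n_pairs=0, flagged=True)
    method = "exact" if np.unique(np.abs(nz)).size == nz.size else "auto"
    res = stats.wilcoxon(nz, alternative="greater", method=method)
    direction = "poor>rich" if np.median(nz) > 0 else "rich>poor"
    return MediaShiftResult(
        p_value=float(res.pvalue), direction=direction, n_pairs=int(nz.size)
    )


def normalize_expression(
    log_expr: pd.DataFrame, replicate_groups: dict[str, list[str]] | None = None
) -> pd.DataFrame:
    """Global normalization of a genes x samples log-expression matrix.

    Each sample column is shifted additively so every column mean equals the
    grand mean. If ``replicate_groups`` maps condition -> column names,
    replicate columns are then averaged into one column per condition.
    """
    mat = log_expr.astype(float)
    if not np.isfinite(mat.to_numpy()).all():
        raise ValueError("expression matrix must be finite")
    grand = float(mat.to_numpy().mean())
    mat = mat - mat.mean(axis=0) + grand
    if replicate_groups:
        mat = pd.DataFrame(
            {cond: mat[cols].mean(axis=1) for cond, cols in replicate_groups.items()},
            index=mat.index,
        )
    return mat


def correlate_expression_growth(
    expr: pd.DataFrame,
    growth: pd.Series | np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene Pearson correlation of log expression with growth rate.

    Returns a frame indexed by gene with columns r, p_value and flagged
    (constant expression rows are undefined and flagged).
    """
    mu = np.asarray(growth, dtype=float)
    if expr.shape[1] != len(mu):
        raise ValueError("sample count mismatch between expression and growth")
    rows = []
    for i, gene in enumerate(expr.index):
        x = expr.iloc[i].to_numpy(dtype=float)
        r = pearson_r(x, mu)
        if math.isnan(r):
            rows.append((gene, math.nan, math.nan, True))
            continue
        p = permutation_pvalue(
            x, mu, "pearson", n_perm=n_perm, seed=seed + i, alternative="two-sided"
        )
        rows.append((gene, r, p, False))
    return pd.DataFrame(
        rows, columns=["gene", "r", "p_value", "flagged"]
    ).set_index("gene")
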