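"""Luria-Delbruck fluctuation analysis.

Estimates the expected number of mutational events per culture (``m``) from
the distribution of mutant colony counts observed across parallel cultures,
and converts it into a mutation rate per base pair per division,

    M = m / (Nt * target_size_bp),

where ``Nt`` is the number of cells per culture at plating (measured here by
a CFU assay with a plate-count reliability filter) and ``target_size_bp`` is
the effective size of the mutational target selected for (for nalidixic-acid
resistance the conversion is assay-specific and left configurable).

The mutant-count likelihood is the Lea-Coulson distribution computed by the
Ma-Sandri-Sarkar (MSS) recursion; ``m`` is estimated by maximum likelihood
with a likelihood-ratio confidence interval, or by the classical P0 method
as a quick diagnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import chi2

__all__ = [
    "MutantCountSample",
    "PlateCountSet",
    "LDDistribution",
    "RateEstimate",
    "CFUEstimate",
    "P0InapplicableError",
    "TruncationLimitError",
    "NoCountablePlatesError",
    "ld_pmf",
    "estimate_m_p0",
    "estimate_m_mle",
    "cfu_from_plates",
    "mutation_rate_per_bp",
    "estimate_rate",
]

DEFAULT_N_MAX = 10_000


class P0InapplicableError(ValueError):
    """Raised when no culture has zero mutants, so p0 cannot be inverted."""


class TruncationLimitError(ValueError):
    """Raised when a count exceeds the pmf truncation cap and tail binning is off."""


class NoCountablePlatesError(ValueError):
    """Raised when no plate count falls in the reliable range."""


@dataclass(frozen=True)
class MutantCountSample:
    """Mutant colony counts across parallel cultures of one strain/medium."""

    strain_id: str
    medium: str
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.counts)
        if any(c != float(raw) for c, raw in zip(counts, self.counts)):
            raise ValueError("mutant counts must be integers")
        if any(c < 0 for c in counts):
            raise ValueError("mutant counts must be non-negative")
        if len(counts) < 2:
            raise ValueError("a fluctuation sample needs at least 2 cultures")
        object.__setattr__(self, "counts", counts)

    @property
    def n_cultures(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class PlateCountSet:
    """Colony counts from replicate CFU plates of one diluted culture."""

    colony_counts: tuple[int, ...]
    dilution_factor: float
    plated_volume_ml: float

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.colony_counts)
        if len(counts) < 1:
            raise ValueError("need at least one plate")
        if any(c < 0 for c in counts):
            raise ValueError("colony counts must be non-negative")
        if self.dilution_factor <= 0 or self.plated_volume_ml <= 0:
            raise ValueError("dilution_factor and plated_volume_ml must be positive")
        object.__setattr__(self, "colony_counts", counts)


@dataclass(frozen=True)
class LDDistribution:
    """Truncated Lea-Coulson pmf for a given expected mutations-per-culture m.

    ``pmf[n]`` is P(n mutant colonies) for n = 0..n_max; ``tail`` is the
    probability mass beyond n_max (used as a censoring cell for jackpots).
    """

    m: float
    pmf: np.ndarray
    tail: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "tail", max(0.0, 1.0 - float(self.pmf.sum())))


@dataclass(frozen=True)
class RateEstimate:
    """Mutations-per-culture MLE with CI and the derived per-bp rate."""

    m_hat: float
    ci_low: float
    ci_high: float
    N_t: float = math.nan
    target_size_bp: float = math.nan
    M: float = math.nan

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.m_hat <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


@dataclass(frozen=True)
class CFUEstimate:
    """Cells/ml from reliable plate counts, with bookkeeping of plates used."""

    cells_per_ml: float
    n_reliable: int
    n_plates: int

    def __float__(self) -> float:
        return self.cells_per_ml


def ld_pmf(m: float, n_max: int) -> LDDistribution:
    """Lea-Coulson pmf p0..p_nmax via the MSS recursion.

    p0 = exp(-m);  p_n = (m/n) * sum_{k=0}^{n-1} p_k / (n - k + 1).
    """
    if m < 0:
        raise ValueError("m must be non-negative")
    n_max = int(n_max)
    if n_max < 0:
        raise ValueError("n_max must be non-negative")
    p = np.zeros(n_max + 1)
    p[0] = math.exp(-m)
    if m > 0 and n_max > 0:
        # weights[j] = 1/(j+2); step n uses weights[0:n] against p[n-1::-1]
        weights = 1.0 / np.arange(2.0, n_max + 2.0)
        for n in range(1, n_max + 1):
            p[n] = (m / n) * np.dot(p[n - 1 :: -1], weights[:n])
    return LDDistribution(m=m, pmf=p)


def estimate_m_p0(sample: MutantCountSample) -> float:
    """P0 estimate m = -ln(fraction of zero-mutant cultures)."""
    counts = np.asarray(sample.counts)
    n_zero = int((counts == 0).sum())
    if n_zero == 0:
        raise P0InapplicableError(
            "P0 inapplicable: no culture with zero mutants; use estimate_m_mle"
        )
    return -math.log(n_zero / sample.n_cultures)


def _log_likelihood(m: float, counts: np.ndarray, support: int, n_tail: int) -> float:
    dist = ld_pmf(m, support)
    tiny = 1e-300
    ll = float(np.log(np.maximum(dist.pmf[counts], tiny)).sum())
    if n_tail:
        ll += n_tail * math.log(max(dist.tail, tiny))
    return ll


def estimate_m_mle(
    sample: MutantCountSample,
    ci_level: float = 0.95,
    n_max: int = DEFAULT_N_MAX,
    tail_bin: bool = True,
    compute_ci: bool = True,
) -> RateEstimate:
    """Maximum-likelihood m under the Lea-Coulson distribution.

    Counts at or above ``n_max`` are censored into a ">= n_max" tail cell
    (jackpot cultures are expected under Luria-Delbruck); set
    ``tail_bin=False`` to make such counts a hard error instead. The CI is
    the likelihood-ratio interval (chi-square, 1 df) at ``ci_level``, which
    behaves sensibly when m_hat is near the m = 0 boundary.
    """
    counts = np.asarray(sample.counts, dtype=np.int64)
    n = len(counts)
    crit = chi2.ppf(ci_level, df=1)

    if counts.max() == 0:
        # boundary: log-likelihood is -n*m, maximized at m = 0
        hi = crit / (2.0 * n) if compute_ci else 0.0
        return RateEstimate(m_hat=0.0, ci_low=0.0, ci_high=hi)

    over = counts >= n_max
    if over.any() and not tail_bin:
        raise TruncationLimitError(
            f"count {int(counts.max())} exceeds the truncation limit n_max={n_max}; "
            "raise n_max or enable tail binning"
        )
    support = int(min(counts.max(), n_max - 1))
    n_tail = int(over.sum())
    body = counts[~over]

    # m_hat cannot exceed the mean count (each mutation yields >= 1 mutant)
    upper = float(np.minimum(counts, n_max).mean()) + 2.0

    def nll(log_m: float) -> float:
        return -_log_likelihood(math.exp(log_m), body, support, n_tail)

    res = minimize_scalar(
        nll, bounds=(math.log(1e-6), math.log(upper)), method="bounded",
        options={"xatol": 1e-8},
    )
    m_hat = math.exp(res.x)
    ll_hat = -res.fun

    if not compute_ci:
        return RateEstimate(m_hat=m_hat, ci_low=m_hat, ci_high=m_hat)

    def lr_root(m: float) -> float:
        return 2.0 * (ll_hat - _log_likelihood(m, body, support, n_tail)) - crit

    lo_bound = 1e-9
    ci_low = lo_bound if lr_root(lo_bound) <= 0 else brentq(lr_root, lo_bound, m_hat)
    hi_probe = max(2.0 * m_hat, upper)
    while lr_root(hi_probe) < 0:
        hi_probe *= 2.0
    ci_high = brentq(lr_root, m_hat, hi_probe)
    return RateEstimate(m_hat=m_hat, ci_low=float(ci_low), ci_high=float(ci_high))


def cfu_from_plates(
    plates: PlateCountSet, reliable_range: tuple[int, int] = (10, 500)
) -> CFUEstimate:
    """Cells/ml from the mean of reliable plate counts.

    A plate is reliable when its colony count lies in the closed interval
    ``reliable_range`` (10-500 colonies by default); unreliable plates are
    dropped before averaging.
    """
    lo, hi = reliable_range
    counts = np.asarray(plates.colony_counts)
    reliable = counts[(counts >= lo) & (counts <= hi)]
    if reliable.size == 0:
        raise NoCountablePlatesError(
            f"no countable plates: no colony count in [{lo}, {hi}]"
        )
    cells = float(reliable.mean()) * plates.dilution_factor / plates.plated_volume_ml
    return CFUEstimate(
        cells_per_ml=cells, n_reliable=int(reliable.size), n_plates=len(counts)
    )


def mutation_rate_per_bp(m_hat: float, N_t: float, target_size_bp: float) -> float:
    """Per-bp-per-division mutation rate M = m / (Nt * target_size_bp)."""
    if m_hat < 0:
        raise ValueError("m_hat must be non-negative")
    if N_t <= 0 or target_size_bp <= 0:
        raise ValueError("N_t and target_size_bp must be positive")
    return m_hat / (N_t * target_size_bp)


def estimate_rate(
    sample: MutantCountSample,
    N_t: float,
    target_size_bp: float = 1.0,
    ci_level: float = 0.95,
    n_max: int = DEFAULT_N_MAX,
    compute_ci: bool = True,
) -> RateEstimate:
    """Full fluctuation-assay estimate: MLE of m plus the per-bp rate M."""
    est = estimate_m_mle(
        sample, ci_level=ci_level, n_max=n_max, compute_ci=compute_ci
    )
    M = mutation_rate_per_bp(est.m_hat, N_t, target_size_bp)
    return RateEstimate(
        m_hat=est.m_hat,
        ci_low=est.ci_low,
        ci_high=est.ci_high,
        N_t=N_t,
        target_size_bp=target_size_bp,
        M=M,
    )
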