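"""Synthetic inputs with the statistical structure the analysis assumes.

Generates every table the pipeline consumes, so all stages are testable
without external downloads:

* fluctuation-assay mutant counts drawn from a continuous-time branching
  simulation of the Luria-Delbruck process (the independent oracle for the
  MSS-recursion likelihood),
* CFU plate counts,
* logistic OD600 growth curves with reader noise,
* a strain panel whose true rates obey both scaling laws simultaneously
  (log10 M linear in log10 G, and mu derived from log10 M through the
  growth coupling law, plus independent noise) so genome size, mutation
  rate and growth rate carry the three pairwise correlations,
* nested deletion tables over 23 gene categories calibrated so exactly 14
  categories exceed the >10 deleted-genes filter,
* a log-expression matrix with planted per-gene correlations to growth.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genecat import DEFAULT_CATEGORIES
from .growth import GrowthCurve
from .luria_delbruck import MutantCountSample, PlateCountSet

__all__ = [
    "ScalingScenario",
    "StrainPanel",
    "SyntheticDeletions",
    "ExpressionData",
    "PRESETS",
    "preset",
    "sample_ld_counts",
    "gen_growth_curve",
    "gen_strain_panel",
    "gen_gene_category_table",
    "gen_expression_table",
]

WILD_TYPE_GENOME_MB = 4.65
# wild-type per-bp-per-division anchor rates used to place the (unprinted)
# genome-scaling intercepts b; chosen so per-target m = M * Nt stays in a
# realistic fluctuation-assay range and poorer media sit above LB for the
# reduced strains
_WT_LOG10_M = {"M63": -8.8, "MAA": -8.8, "LB": -8.9}

# strain ids mirror a wild type plus nine nested reduced genomes
DEFAULT_STRAIN_IDS = (
    "no0", "no3", "no4", "no10", "no11", "no14", "no19", "no23", "no27", "no28",
)


def _default_genome_sizes() -> tuple[float, ...]:
    # wild type 4.65 Mb; deletions from 89 kb up to just over 1 Mb
    reduced = np.linspace(WILD_TYPE_GENOME_MB - 0.089, 3.62, 9)
    return (WILD_TYPE_GENOME_MB, *np.round(reduced, 4))


@dataclass(frozen=True)
class ScalingScenario:
    """Generator settings for one medium's strain panel."""

    medium: str
    r: float  # genome-size scaling slope
    b: float  # genome-size scaling intercept
    alpha: float  # growth coupling slope
    log10_M0: float  # growth coupling intercept
    genome_sizes_mb: tuple[float, ...] = field(default_factory=_default_genome_sizes)
    strain_ids: tuple[str, ...] = DEFAULT_STRAIN_IDS
    noise_sd_log10M: float = 0.1
    noise_sd_mu: float = 0.02  # h^-1
    n_cultures: int = 96
    N_t: float = 1e9
    target_size_bp: float = 1.0
    # growth-curve emission: replicate plate wells and reader settings
    n_growth_replicates: int = 12
    od_dt_h: float = 0.1
    od_horizon_h: float = 36.0  # long enough for slow growers to plateau
    od_noise_sd: float = 0.003
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = np.asarray(self.genome_sizes_mb)
        if np.any(sizes <= 0):
            raise ValueError("genome sizes must be positive")
        if np.any(np.diff(sizes) > 0):
            raise ValueError("genome sizes must descend from the wild type")
        if len(self.strain_ids) != len(sizes):
            raise ValueError("strain_ids and genome_sizes_mb lengths differ")
        if self.alpha == 0:
            raise ValueError("inconsistent presets: alpha must be non-zero")


def _preset(medium: str, r: float, alpha: float, log10_M0: float) -> ScalingScenario:
    b = _WT_LOG10_M[medium] - r * math.log10(WILD_TYPE_GENOME_MB)
    return ScalingScenario(
        medium=medium, r=r, b=b, alpha=alpha, log10_M0=log10_M0
    )


# printed scaling coefficients per medium: genome-size slope r and growth
# coupling (alpha, log10 M0)
PRESETS: dict[str, ScalingScenario] = {
    "M63": _preset("M63", r=-14.6, alpha=-4.9, log10_M0=-6.1),
    "MAA": _preset("MAA", r=-10.1, alpha=-4.8, log10_M0=-4.3),
    "LB": _preset("LB", r=-5.1, alpha=-2.4, log10_M0=-5.4),
}


def preset(medium: str, **overrides) -> ScalingScenario:
    """A copy of the named preset, optionally with fields overridden."""
    return replace(PRESETS[medium], **overrides)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_ld_counts(
    m: float,
    n_cultures: int,
    seed,
    n_generations: int = 20,
    strain_id: str = "synthetic",
    medium: str = "M63",
) -> MutantCountSample:
    """Brute-force Luria-Delbruck oracle via branching simulation.

    The wild-type host grows deterministically through ``n_generations``
    doublings (Nt = 2^n_generations). Mutational events per culture are
    Poisson(m); each event happens at a time drawn with density proportional
    to population size (uniform in the population-size coordinate
    u = N(t)/Nt on (1/Nt, 1]) and founds a mutant clone that grows as a
    stochastic Yule birth process, whose size at harvest is Geometric(u).
    Independent of the MSS recursion by construction.
    """
    if m < 0:
        raise ValueError("m must be non-negative")
    rng = _as_rng(seed)
    counts = np.zeros(n_cultures, dtype=np.int64)
    if m > 0:
        k = rng.poisson(m, n_cultures)
        total = int(k.sum())
        if total:
            nt = 2.0**n_generations
            u = rng.uniform(1.0 / nt, 1.0, total)
            sizes = rng.geometric(u)
            np.add.at(counts, np.repeat(np.arange(n_cultures), k), sizes)
    return MutantCountSample(
        strain_id=strain_id, medium=medium, counts=tuple(int(c) for c in counts)
    )


def gen_growth_curve(
    mu: float,
    od0: float = 0.001,
    carrying_capacity: float = 1.0,
    dt_h: float = 0.25,
    horizon_h: float = 16.0,
    noise_sd: float = 0.003,
    seed=0,
    strain_id: str = "synthetic",
    medium: str = "M63",
) -> GrowthCurve:
    """Logistic OD600 curve with truncated Gaussian reader noise.

    OD(t) = K*od0*e^(mu t) / (K + od0*(e^(mu t) - 1)); noisy readings are
    floored at 1e-4 (a reader cannot report arbitrarily small densities).
    """
    if mu < 0:
        raise ValueError("mu must be non-negative")
    rng = _as_rng(seed)
    t = np.arange(0.0, horizon_h + 0.5 * dt_h, dt_h)
    k = carrying_capacity
    growth = np.exp(np.minimum(mu * t, 700.0))
    od = k * od0 * growth / (k + od0 * (growth - 1.0))
    if noise_sd > 0:
        od = od + rng.normal(0.0, noise_sd, size=od.shape)
    od = np.maximum(od, 1e-4)
    return GrowthCurve(strain_id=strain_id, medium=medium, times=t, od=od)


@dataclass(frozen=True)
class StrainPanel:
    """One medium's synthetic study: true values plus raw observables."""

    scenario: ScalingScenario
    observations: pd.DataFrame  # strain_id, medium, genome_size_mb, true M, mu
    samples: dict[str, MutantCountSample]
    curves: dict[str, tuple[GrowthCurve, ...]]  # replicate wells per strain
    plates: dict[str, PlateCountSet]


def gen_strain_panel(scenario: ScalingScenario, seed: int | None = None) -> StrainPanel:
    """Generate a strain panel obeying both scaling laws up to noise.

    True log10 M is drawn on the genome-size line (plus Gaussian noise),
    true mu is solved from the growth coupling law (plus independent
    Gaussian noise), then mutant counts, CFU plates and an OD curve are
    emitted per strain. With both noise SDs zero the observations lie
    exactly on both regression lines.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    sizes = np.asarray(scenario.genome_sizes_mb)
    n = len(sizes)
    log10_m_rate = (
        scenario.r * np.log10(sizes)
        + scenario.b
        + rng.normal(0.0, scenario.noise_sd_log10M, n)
    )
    mu = (log10_m_rate - scenario.log10_M0) / scenario.alpha + rng.normal(
        0.0, scenario.noise_sd_mu, n
    )
    mu = np.maximum(mu, 0.01)  # growth rates are physical
    rate = 10.0**log10_m_rate

    samples: dict[str, MutantCountSample] = {}
    curves: dict[str, tuple[GrowthCurve, ...]] = {}
    plates: dict[str, PlateCountSet] = {}
    dilution, vol, n_plates = 1e6, 0.1, 10
    for sid, m_rate, mu_i in zip(scenario.strain_ids, rate, mu):
        m_per_culture = m_rate * scenario.N_t * scenario.target_size_bp
        samples[sid] = sample_ld_counts(
            m_per_culture,
            scenario.n_cultures,
            rng,
            strain_id=sid,
            medium=scenario.medium,
        )
        curves[sid] = tuple(
            gen_growth_curve(
                mu_i,
                dt_h=scenario.od_dt_h,
                horizon_h=scenario.od_horizon_h,
                noise_sd=scenario.od_noise_sd,
                seed=rng,
                strain_id=sid,
                medium=scenario.medium,
            )
            for _ in range(scenario.n_growth_replicates)
        )
        expected_colonies = scenario.N_t * vol / dilution
        plates[sid] = PlateCountSet(
            colony_counts=tuple(
                int(c) for c in rng.poisson(expected_colonies, n_plates)
            ),
            dilution_factor=dilution,
            plated_volume_ml=vol,
        )
    observations = pd.DataFrame(
        {
            "strain_id": scenario.strain_ids,
            "medium": scenario.medium,
            "genome_size_mb": sizes,
            "mutation_rate": rate,
            "growth_rate": mu,
        }
    )
    return StrainPanel(
        scenario=scenario,
        observations=observations,
        samples=samples,
        curves=curves,
        plates=plates,
    )


@dataclass(frozen=True)
class SyntheticDeletions:
    records: pd.DataFrame  # strain_id, gene_id, category (newly deleted genes)
    totals: pd.Series  # per-category gene totals in the wild-type genome
    series_order: tuple[str, ...]


def gen_gene_category_table(
    n_strains: int = 10,
    seed: int = 0,
    categories: tuple[str, ...] = DEFAULT_CATEGORIES,
    n_abundant: int = 14,
    strain_ids: tuple[str, ...] | None = None,
) -> SyntheticDeletions:
    """Nested deletion records over the category vocabulary.

    Per-category increments are Poisson, with ``n_abundant`` categories
    given a guaranteed per-strain baseline so that exactly ``n_abundant``
    categories exceed 10 cumulative deletions in the final strain, and the
    remaining categories capped at 10.
    """
    rng = np.random.default_rng(seed)
    if strain_ids is None:
        strain_ids = DEFAULT_STRAIN_IDS[:n_strains]
    if len(strain_ids) != n_strains:
        raise ValueError("strain_ids length must equal n_strains")
    abundant = set(rng.choice(len(categories), size=n_abundant, replace=False))
    rows = []
    cum = {c: 0 for c in categories}
    for strain in strain_ids[1:]:  # wild type deletes nothing
        for ci, cat in enumerate(categories):
            if ci in abundant:
                new = 2 + int(rng.poisson(1.5))
            else:
                new = min(int(rng.poisson(0.4)), 10 - cum[cat])
            for _ in range(new):
                rows.append((strain, f"{cat}{cum[cat]:04d}", cat))
                cum[cat] += 1
    records = pd.DataFrame(rows, columns=["strain_id", "gene_id", "category"])
    totals = pd.Series(
        {c: cum[c] + int(rng.integers(20, 200)) for c in categories}, name="all_genes"
    )
    return SyntheticDeletions(
        records=records, totals=totals, series_order=tuple(strain_ids)
    )


@dataclass(frozen=True)
class ExpressionData:
    log_expr: pd.DataFrame  # genes x samples, log scale, un-normalized
    growth: pd.Series  # per-sample growth rate


def gen_expression_table(
    n_genes: int,
    n_samples: int = 75,
    planted: dict[str, float] | None = None,
    seed: int = 0,
) -> ExpressionData:
    """Log-expression matrix with planted gene-growth correlations.

    ``planted`` maps gene id -> target Pearson correlation with the drawn
    growth-rate vector; unplanted genes are uncorrelated. Per-sample
    additive offsets make raw column means differ (they vanish under global
    normalization).
    """
    planted = dict(planted or {})
    for gene, r in planted.items():
        if abs(r) > 1:
            raise ValueError(f"target correlation for {gene!r} outside [-1, 1]")
    rng = np.random.default_rng(seed)
    mu = np.maximum(rng.normal(0.5, 0.15, n_samples), 0.05)
    z = (mu - mu.mean()) / mu.std()
    genes = [f"gene{i:04d}" for i in range(n_genes)]
    for i, gene in enumerate(planted):
        if gene not in genes:
            genes[i] = gene  # planted genes occupy the leading rows
    base = rng.uniform(6.0, 12.0, n_genes)
    gene_sd = 0.5
    mat = np.empty((n_genes, n_samples))
    for i, gene in enumerate(genes):
        eps = rng.standard_normal(n_samples)
        r = planted.get(gene, 0.0)
        signal = r * z + math.sqrt(max(0.0, 1.0 - r * r)) * eps
        mat[i] = base[i] + gene_sd * signal
    sample_offsets = rng.normal(0.0, 0.3, n_samples)
    mat = mat + sample_offsets[None, :]
    cols = [f"sample{j:02d}" for j in range(n_samples)]
    return ExpressionData(
        log_expr=pd.DataFrame(mat, index=genes, columns=cols),
        growth=pd.Series(mu, index=cols, name="growth_rate"),
    )
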