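"""Parameter-recovery evaluation of the full estimation chain.

Runs the synthetic strain panels through the fluctuation-assay estimator
and the OD-curve growth fit, then refits both scaling laws, reporting the
multi-seed mean recovered coefficients. This is the package's own check
that the estimation pipeline returns the coefficients the generator was
given, at study scale (10 strains, 96 cultures, Nt = 1e9).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import growth, luria_delbruck as ld, scaling
from .synthetic_data import StrainPanel, gen_strain_panel, preset

__all__ = ["PanelFitResult", "estimate_panel", "recover_scaling_coefficients"]


@dataclass(frozen=True)
class PanelFitResult:
    medium: str
    seeds: tuple[int, ...]
    genome_slopes: tuple[float, ...]  # per-seed Eq. 1-style slope
    growth_slopes: tuple[float, ...]  # per-seed growth-coupling slope
    log10_M0s: tuple[float, ...]

    @property
    def mean_genome_slope(self) -> float:
        return float(np.mean(self.genome_slopes))

    @property
    def mean_growth_slope(self) -> float:
        return float(np.mean(self.growth_slopes))

    @property
    def mean_log10_M0(self) -> float:
        return float(np.mean(self.log10_M0s))


def estimate_panel(panel: StrainPanel, compute_ci: bool = False) -> pd.DataFrame:
    """Estimated observations table for one synthetic panel.

    Mutation rates come from the Lea-Coulson MLE on the simulated mutant
    counts with Nt from the simulated CFU plates; growth rates from the
    log-linear window fit on the simulated OD curves. True values are not
    consulted.
    """
    sc = panel.scenario
    rows = []
    for sid, size in zip(sc.strain_ids, sc.genome_sizes_mb):
        cfu = ld.cfu_from_plates(panel.plates[sid])
        n_t = cfu.cells_per_ml * 1.0  # 1 ml cultures
        est = ld.estimate_rate(
            panel.samples[sid],
            N_t=n_t,
            target_size_bp=sc.target_size_bp,
            compute_ci=compute_ci,
        )
        mu_hat = float(
            np.mean([growth.growth_rate(c).mu for c in panel.curves[sid]])
        )
        rows.append(
            {
                "strain_id": sid,
                "medium": sc.medium,
                "genome_size_mb": size,
                "mutation_rate": est.M,
                "growth_rate": mu_hat,
            }
        )
    return pd.DataFrame(rows)


def recover_scaling_coefficients(
    medium: str,
    n_seeds: int = 20,
    base_seed: int = 1,
    n_perm: int = 200,
) -> PanelFitResult:
    """Mean recovered scaling coefficients over seeded panel replicates."""
    seeds = tuple(int(base_seed + 7919 * i) % 2**31 for i in range(n_seeds))
    genome_slopes, growth_slopes, intercepts = [], [], []
    for seed in seeds:
        panel = gen_strain_panel(preset(medium), seed=seed)
        obs = estimate_panel(panel)
        gfit = scaling.fit_genome_scaling(obs, n_perm=n_perm, seed=seed)
        mfit = scaling.fit_growth_mutation(obs, n_perm=n_perm, seed=seed)
        genome_slopes.append(gfit.r)
        growth_slopes.append(mfit.alpha)
        intercepts.append(mfit.log10_M0)
    return PanelFitResult(
        medium=medium,
        seeds=seeds,
        genome_slopes=tuple(genome_slopes),
        growth_slopes=tuple(growth_slopes),
        log10_M0s=tuple(intercepts),
    )
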