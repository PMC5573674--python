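"""End-to-end orchestration: fluctuation -> growth -> scaling -> categories.

`run_pipeline` reads the configured input tables, runs each stage, writes
the per-stage TSV outputs plus a machine-readable JSON summary of every
fitted coefficient, p-value, parameter and seed. The summary is sufficient
to regenerate the figure-style outputs without re-running estimation.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import genecat, growth, luria_delbruck as ld, scaling, serial_transfer
from .io import read_table, write_table

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

# media ordered from poorest to richest (for the rate-shift test)
MEDIA_RICHNESS = ("M63", "MAA", "LB")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    outdir: str
    seed: int  # mandatory: permutation tests and simulations are stochastic
    fluctuation: str | None = None
    plates: str | None = None
    od: str | None = None
    observations: str | None = None
    deletions: str | None = None
    expression: str | None = None
    expression_growth: str | None = None
    target_size_bp: float = 1.0
    culture_volume_ml: float = 1.0
    od_range: tuple[float, float] = (0.02, 0.1)
    min_points: int = 5
    n_perm: int = 10_000
    ci_level: float = 0.95
    transfer: dict[str, Any] | None = None

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "od_range" in raw:
            raw["od_range"] = tuple(raw["od_range"])
        return cls(**raw)

    def input_paths(self) -> dict[str, str]:
        names = (
            "fluctuation",
            "plates",
            "od",
            "observations",
            "deletions",
            "expression",
            "expression_growth",
        )
        return {n: getattr(self, n) for n in names if getattr(self, n) is not None}


def _checksum(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _estimate_rates(config: PipelineConfig) -> pd.DataFrame:
    counts = read_table(config.fluctuation, schema="fluctuation")
    plates = read_table(config.plates, schema="plates")
    rows = []
    for (sid, medium), grp in counts.groupby(["strain_id", "medium"], sort=False):
        sample = ld.MutantCountSample(
            strain_id=sid,
            medium=medium,
            counts=tuple(int(c) for c in grp["mutant_count"]),
        )
        pgrp = plates[(plates["strain_id"] == sid) & (plates["medium"] == medium)]
        if pgrp.empty:
            raise PipelineError(f"no CFU plates for strain {sid!r} in {medium!r}")
        plate_set = ld.PlateCountSet(
            colony_counts=tuple(int(c) for c in pgrp["colony_count"]),
            dilution_factor=float(pgrp["dilution_factor"].iloc[0]),
            plated_volume_ml=float(pgrp["plated_volume_ml"].iloc[0]),
        )
        cfu = ld.cfu_from_plates(plate_set)
        n_t = cfu.cells_per_ml * config.culture_volume_ml
        est = ld.estimate_rate(
            sample, N_t=n_t, target_size_bp=config.target_size_bp,
            ci_level=config.ci_level,
        )
        rows.append(
            {
                "strain_id": sid,
                "medium": medium,
                "n_cultures": sample.n_cultures,
                "m_hat": est.m_hat,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "N_t": n_t,
                "n_reliable_plates": cfu.n_reliable,
                "mutation_rate": est.M,
            }
        )
    return pd.DataFrame(rows)


def _estimate_growth(config: PipelineConfig) -> pd.DataFrame:
    od = read_table(config.od, schema="od")
    rows = []
    for (sid, medium), grp in od.groupby(["strain_id", "medium"], sort=False):
        mus = []
        for _, rep in grp.groupby("replicate", sort=False):
            rep = rep.sort_values("time_h")
            keep = rep["od600"].to_numpy(dtype=float) > 0
            curve = growth.GrowthCurve(
                strain_id=sid,
                medium=medium,
                times=rep["time_h"].to_numpy(dtype=float)[keep],
                od=rep["od600"].to_numpy(dtype=float)[keep],
            )
            est = growth.growth_rate(
                curve, min_points=config.min_points, od_range=config.od_range
            )
            mus.append(est.mu)
        rows.append(
            {
                "strain_id": sid,
                "medium": medium,
                "growth_rate": float(np.mean(mus)),
                "n_replicates": len(mus),
            }
        )
    return pd.DataFrame(rows)


def _assemble_observations(
    config: PipelineConfig,
    rates: pd.DataFrame | None,
    growth_df: pd.DataFrame | None,
) -> pd.DataFrame:
    if rates is None:
        if config.observations is None:
            raise PipelineError(
                "scaling stage needs either raw inputs or an observations table"
            )
        return read_table(config.observations, schema="observations")
    if config.observations is None:
        raise PipelineError("an observations/strain table is needed for genome sizes")
    strain_meta = read_table(config.observations, schema="observations")
    sizes = strain_meta.drop_duplicates("strain_id").set_index("strain_id")[
        "genome_size_mb"
    ]
    obs = rates.merge(growth_df, on=["strain_id", "medium"], how="inner")
    obs["genome_size_mb"] = obs["strain_id"].map(sizes)
    if obs["genome_size_mb"].isna().any():
        missing = obs.loc[obs["genome_size_mb"].isna(), "strain_id"].tolist()
        raise PipelineError(f"no genome size for strain(s) {missing}")
    return obs[
        ["strain_id", "medium", "genome_size_mb", "mutation_rate", "growth_rate"]
    ]


def _fit_scaling(config: PipelineConfig, obs: pd.DataFrame):
    fits = []
    summary: dict[str, Any] = {}
    for medium, grp in obs.groupby("medium", sort=False):
        gfit = scaling.fit_genome_scaling(grp, n_perm=config.n_perm, seed=config.seed)
        mfit = scaling.fit_growth_mutation(grp, n_perm=config.n_perm, seed=config.seed)
        fits.append(
            {
                "medium": medium,
                "model": "genome_size",
                "slope": gfit.r,
                "intercept": gfit.b,
                "r2": gfit.r2,
                "spearman_rho": gfit.spearman_rho,
                "p_value": gfit.p_value,
            }
        )
        fits.append(
            {
                "medium": medium,
                "model": "growth_rate",
                "slope": mfit.alpha,
                "intercept": mfit.log10_M0,
                "r2": mfit.r2,
                "spearman_rho": mfit.spearman_rho,
                "p_value": mfit.p_value,
            }
        )
        summary[medium] = {
            "genome_scaling": {
                "r": gfit.r, "b": gfit.b, "r2": gfit.r2,
                "spearman_rho": gfit.spearman_rho, "p_value": gfit.p_value,
            },
            "growth_coupling": {
                "alpha": mfit.alpha, "log10_M0": mfit.log10_M0, "M0": mfit.M0,
                "r2": mfit.r2, "spearman_rho": mfit.spearman_rho,
                "p_value": mfit.p_value,
            },
        }
    # nutrition-shift test between the poorest and richest media present
    present = [m for m in MEDIA_RICHNESS if m in set(obs["medium"])]
    if len(present) >= 2:
        poor, rich = present[0], present[-1]
        a = obs[obs["medium"] == poor].set_index("strain_id")["mutation_rate"]
        b = obs[obs["medium"] == rich].set_index("strain_id")["mutation_rate"]
        shared = a.index.intersection(b.index)
        if len(shared) >= 5:
            res = scaling.media_shift_test(a[shared], b[shared])
            summary["media_shift"] = {
                "poor": poor,
                "rich": rich,
                "p_value": res.p_value,
                "direction": res.direction,
                "n_pairs": res.n_pairs,
            }
    return pd.DataFrame(fits), summary


def _run_genecat(config: PipelineConfig, obs: pd.DataFrame):
    records = read_table(config.deletions, schema="deletions")
    series = [s for s in obs["strain_id"].drop_duplicates()]
    table = genecat.cumulative_deletion_counts(records, series)
    kept = genecat.filter_categories(table)
    result = genecat.category_correlation(
        table, obs, categories=kept, n_perm=config.n_perm, seed=config.seed
    )
    heat = result.neg_log10_p.reset_index(names="category")
    corr = result.correlation.reset_index(names="category")
    summary = {
        "categories_retained": kept,
        "n_retained": len(kept),
        "flagged_cells": [list(f) for f in result.flagged],
    }
    return heat, corr, summary


def _run_expression(config: PipelineConfig):
    expr = pd.read_csv(config.expression, sep="\t", index_col=0)
    growth_tbl = read_table(
        config.expression_growth,
        required=["sample_id", "growth_rate"],
        numeric=["growth_rate"],
    ).set_index("sample_id")
    norm = scaling.normalize_expression(expr)
    res = scaling.correlate_expression_growth(
        norm,
        growth_tbl.loc[norm.columns, "growth_rate"],
        n_perm=min(config.n_perm, 2000),
        seed=config.seed,
    )
    return res.reset_index(), {
        "n_genes": int(len(res)),
        "n_flagged": int(res["flagged"].sum()),
    }


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the configured stages; returns the summary written to JSON."""
    inputs = config.input_paths()
    for name, path in inputs.items():
        if not Path(path).exists():
            raise PipelineError(f"missing input file for {name!r}: {path}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {
        "parameters": {
            "seed": config.seed,
            "target_size_bp": config.target_size_bp,
            "culture_volume_ml": config.culture_volume_ml,
            "od_range": list(config.od_range),
            "min_points": config.min_points,
            "n_perm": config.n_perm,
            "ci_level": config.ci_level,
        },
        "inputs": {n: {"path": p, "sha256_16": _checksum(p)} for n, p in inputs.items()},
    }

    rates = growth_df = None
    if config.fluctuation and config.plates:
        rates = _estimate_rates(config)
        write_table(rates, outdir / "rates.tsv", rate_columns=("mutation_rate",))
    if config.od:
        growth_df = _estimate_growth(config)
        write_table(growth_df, outdir / "growth.tsv")

    obs = _assemble_observations(config, rates, growth_df)
    write_table(
        obs, outdir / "observations_used.tsv", rate_columns=("mutation_rate",)
    )
    fits, scaling_summary = _fit_scaling(config, obs)
    write_table(fits, outdir / "fits.tsv")
    summary["scaling"] = scaling_summary

    if config.deletions:
        heat, corr, genecat_summary = _run_genecat(config, obs)
        write_table(heat, outdir / "heatmap.tsv")
        write_table(corr, outdir / "category_correlations.tsv")
        summary["gene_categories"] = genecat_summary

    if config.expression and config.expression_growth:
        expr_corr, expr_summary = _run_expression(config)
        write_table(expr_corr, outdir / "expression_correlations.tsv")
        summary["expression"] = expr_summary

    if config.transfer is not None:
        tcfg = dict(config.transfer)
        protocol = serial_transfer.TransferProtocol(
            **tcfg.get("protocol", {})
        )
        model = (
            serial_transfer.AdaptationModel(**tcfg["adaptation"])
            if "adaptation" in tcfg
            else None
        )
        traj = serial_transfer.run_serial_transfer(
            protocol=protocol,
            model=model,
            seed=config.seed if tcfg.get("od_noise_sd", 0.0) > 0 else None,
            od_noise_sd=tcfg.get("od_noise_sd", 0.0),
        )
        write_table(traj.to_frame(), outdir / "trajectory.tsv", rate_columns=("M",))
        summary["transfer"] = {
            "cumulative_generations": traj.cumulative_generations,
            "mu_fold_change": traj.mu_fold_change,
            "delta_log10_M": traj.delta_log10_M,
        }

    def _jsonify(x):
        if isinstance(x, (np.floating, np.integer)):
            return x.item()
        if isinstance(x, float) and math.isnan(x):
            return None
        raise TypeError(f"not JSON serializable: {type(x)}")

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")
    return summary
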