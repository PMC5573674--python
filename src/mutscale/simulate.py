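"""Write synthetic study inputs in the exact dialects the analysis reads."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .io import write_table
from .synthetic_data import (
    gen_expression_table,
    gen_gene_category_table,
    gen_strain_panel,
    preset,
)

__all__ = ["write_simulation"]


def write_simulation(
    outdir: str | Path,
    media: tuple[str, ...] = ("M63", "MAA", "LB"),
    seed: int = 0,
    noise_sd_log10M: float | None = None,
    noise_sd_mu: float | None = None,
    n_genes: int = 50,
    planted: dict[str, float] | None = None,
) -> dict[str, str]:
    """Generate panels for the given media and write every pipeline input.

    Returns a map of table name -> written path. ``observations.tsv`` holds
    the generator's true values (the estimation stages never read the true
    rates; the pipeline uses the table for genome sizes, or fits it directly
    when no raw inputs are configured).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    overrides = {}
    if noise_sd_log10M is not None:
        overrides["noise_sd_log10M"] = noise_sd_log10M
    if noise_sd_mu is not None:
        overrides["noise_sd_mu"] = noise_sd_mu

    fluct_rows, plate_rows, od_rows, obs_frames = [], [], [], []
    for i, medium in enumerate(media):
        panel = gen_strain_panel(preset(medium, **overrides), seed=seed + 1000 * i)
        obs_frames.append(panel.observations)
        for sid, sample in panel.samples.items():
            for cid, count in enumerate(sample.counts):
                fluct_rows.append((sid, medium, f"c{cid:03d}", count))
        for sid, plates in panel.plates.items():
            for pid, count in enumerate(plates.colony_counts):
                plate_rows.append(
                    (
                        sid,
                        medium,
                        f"p{pid:02d}",
                        count,
                        plates.dilution_factor,
                        plates.plated_volume_ml,
                    )
                )
        for sid, reps in panel.curves.items():
            for ri, curve in enumerate(reps):
                for t, od in zip(curve.times, curve.od):
                    od_rows.append((sid, medium, f"r{ri + 1:02d}", t, od))

    paths: dict[str, str] = {}

    def _write(name: str, df: pd.DataFrame, **kw) -> None:
        path = outdir / f"{name}.tsv"
        write_table(df, path, **kw)
        paths[name] = str(path)

    _write(
        "fluctuation",
        pd.DataFrame(
            fluct_rows, columns=["strain_id", "medium", "culture_id", "mutant_count"]
        ),
    )
    _write(
        "plates",
        pd.DataFrame(
            plate_rows,
            columns=[
                "strain_id",
                "medium",
                "plate_id",
                "colony_count",
                "dilution_factor",
                "plated_volume_ml",
            ],
        ),
    )
    _write(
        "od",
        pd.DataFrame(
            od_rows, columns=["strain_id", "medium", "replicate", "time_h", "od600"]
        ),
    )
    _write(
        "observations",
        pd.concat(obs_frames, ignore_index=True),
        rate_columns=("mutation_rate",),
    )

    deletions = gen_gene_category_table(seed=seed)
    _write("deletions", deletions.records)

    expr = gen_expression_table(n_genes=n_genes, planted=planted, seed=seed)
    expr_out = expr.log_expr.copy()
    expr_out.insert(0, "gene_id", expr_out.index)
    _write("expression", expr_out)
    _write(
        "expression_growth",
        expr.growth.rename_axis("sample_id").reset_index(),
    )
    return paths
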