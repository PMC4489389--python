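"""End-to-end pipeline driver.

Runs synthetic generation (or ingestion) -> motion QC -> band-pass ->
connectomes -> binary network families -> metric curves -> small-world
nulls -> group statistics -> cognition correlations, writing every table
as TSV plus a run log and a human-readable summary. A rerun with the same
config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectome import build_network_family, correlation_matrix
from .io import (
    PipelineConfig,
    config_hash,
    default_region_table,
    read_manifest,
    read_time_series,
    save_config,
    write_manifest,
    write_matrix,
    write_time_series,
)
from .metrics import compute_metric_curves
from .nulls import classify_small_world, small_world_indices
from .preprocess import apply_motion_qc, bandpass_filter
from .stats import compare_groups_over_grid, metric_cognition_correlation
from .synthetic import generate_cohort


class PipelineError(RuntimeError):
    def __init__(self, stage: str, context: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed ({context}): {cause}")
        self.stage = stage


def _tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _snap_range(auc_range, grid):
    """Clamp a requested AUC range to grid points (full span if absent)."""
    vals = grid.values
    lo, hi = auc_range
    on = lambda x: bool(np.isclose(vals, x).any())  # noqa: E731
    if not on(lo) or not on(hi) or hi <= lo:
        return float(vals[0]), float(vals[-1])
    return float(lo), float(hi)


def run_pipeline(config: PipelineConfig, write_per_subject: bool = False) -> dict:
    """Execute the full pipeline; returns the result bundle as a dict of DataFrames.

    ``write_per_subject`` additionally writes each subject's filtered time
    series and correlation matrix (off by default to keep output small).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [
        f"restconn {__version__}",
        f"config_hash {config_hash(config)}",
        f"seed {config.seed}",
    ]

    # --- cohort ---------------------------------------------------------
    stage = "cohort"
    try:
        if config.input_dir is None:
            spec = dataclasses.replace(config.cohort, seed=config.seed)
            manifest, series = generate_cohort(spec)
            filtered = series  # generator band-limits through the same filter
        else:
            manifest = read_manifest(Path(config.input_dir) / "manifest.tsv")
            region_table = default_region_table(config.cohort.n_regions)
            series = [
                read_time_series(
                    Path(config.input_dir) / f"{sid}.tsv",
                    subject_id=sid,
                    tr_seconds=config.cohort.tr_seconds,
                    region_table=region_table,
                )
                for sid in manifest.subjects["subject_id"]
            ]
            filtered = [bandpass_filter(ts, config.bandpass) for ts in series]
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, "generating/ingesting cohort", e) from e
    write_manifest(manifest, out / "manifest.tsv")
    log.append(f"stage cohort: {len(series)} subjects")

    # --- motion QC ------------------------------------------------------
    stage = "qc"
    try:
        if config.apply_qc:
            kept, excluded = apply_motion_qc(manifest, config.motion)
        else:
            kept, excluded = list(manifest.subjects["subject_id"]), []
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, "applying motion rule", e) from e
    _tsv(pd.DataFrame(dict(subject_id=kept + excluded,
                           status=["kept"] * len(kept) + ["excluded"] * len(excluded))),
         out / "qc.tsv")
    filtered = [ts for ts in filtered if ts.subject_id in set(kept)]
    log.append(f"stage qc: kept {len(kept)}, excluded {len(excluded)}")

    groups = manifest.groups.loc[kept]

    # --- connectomes and metric curves ---------------------------------
    stage = "metrics"
    global_parts, nodal_parts = [], []
    families = {}
    for ts in filtered:
        try:
            cm = correlation_matrix(ts)
            fam = build_network_family(cm, config.grid, edge_sign=config.edge_sign)
            families[ts.subject_id] = fam
            gdf, ndf = compute_metric_curves(
                fam, config.grid, nodal=config.compute_nodal,
                lp_convention=config.lp_convention,
            )
        except Exception as e:  # noqa: BLE001
            raise PipelineError(stage, f"subject {ts.subject_id}", e) from e
        global_parts.append(gdf)
        if ndf is not None:
            nodal_parts.append(ndf)
        if write_per_subject:
            write_time_series(ts, out / f"ts_{ts.subject_id}.tsv")
            write_matrix(cm, out / f"corr_{ts.subject_id}.tsv")
    global_curves = pd.concat(global_parts, ignore_index=True)
    nodal_curves = pd.concat(nodal_parts, ignore_index=True) if nodal_parts else None
    _tsv(
        global_curves.melt(
            id_vars=["subject", "sparsity"],
            value_vars=["Cp", "Lp", "Eglob", "Eloc"],
            var_name="metric", value_name="value",
        ).sort_values(["subject", "metric", "sparsity"], kind="stable"),
        out / "global_metric_curves.tsv",
    )
    if nodal_curves is not None:
        _tsv(nodal_curves.sort_values(["subject", "metric", "region", "sparsity"],
                                      kind="stable"),
             out / "nodal_metric_curves.tsv")
    log.append(f"stage metrics: {len(global_curves)} global curve rows")

    # --- small-world nulls ---------------------------------------------
    stage = "nulls"
    null_sparsities = [float(s) for s in (config.null_sparsities or config.grid.values)]
    sw_rows = []
    try:
        nspec = dataclasses.replace(config.nulls, seed=config.seed)
        for sid, fam in sorted(families.items()):
            for net in fam:
                if not any(np.isclose(net.sparsity, s) for s in null_sparsities):
                    continue
                idx = small_world_indices(net, nspec, lp_convention=config.lp_convention)
                sw_rows.append(dict(
                    subject=sid, group=groups.loc[sid], sparsity=net.sparsity,
                    gamma=idx.gamma, lam=idx.lam, sigma=idx.sigma,
                    cp_random_mean=idx.cp_random_mean, cp_random_sd=idx.cp_random_sd,
                    lp_random_mean=idx.lp_random_mean, lp_random_sd=idx.lp_random_sd,
                ))
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, "null ensemble", e) from e
    sw_df = pd.DataFrame(sw_rows)
    _tsv(sw_df, out / "small_world_indices.tsv")
    sw_grid = config.grid
    if len(null_sparsities) > 1:
        steps = np.round(np.diff(sorted(null_sparsities)), 10)
        if np.all(steps == steps[0]):  # evenly spaced subset: classify on it
            from .connectome import SparsityGrid

            sw_grid = SparsityGrid(min(null_sparsities), max(null_sparsities),
                                   float(steps[0]))
    sw_means, sw_report = classify_small_world(sw_df, sw_grid) if len(sw_df) else (None, None)
    if sw_means is not None:
        _tsv(sw_means, out / "small_world_classification.tsv")
    log.append(f"stage nulls: {len(sw_df)} (subject, sparsity) index rows")

    # --- group statistics ----------------------------------------------
    stage = "stats"
    try:
        if len(config.grid.values) > 1:
            comparison = compare_groups_over_grid(
                global_curves, groups, config.grid,
                nodal_curves=nodal_curves, fdr_q=config.fdr_q,
                report_sparsity=config.report_sparsity,
                auc_range=(float(config.grid.values[0]), float(config.grid.values[-1])),
            )
        else:
            log.append("stage stats: single-threshold grid, AUC comparison skipped")
            comparison = compare_groups_over_grid(
                global_curves, groups, config.grid,
                nodal_curves=nodal_curves, fdr_q=config.fdr_q,
                report_sparsity=float(config.grid.values[0]),
            )
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, "group comparison", e) from e
    _tsv(comparison, out / "group_comparison.tsv")
    log.append(f"stage stats: {len(comparison)} tests")

    # --- cognition correlation ------------------------------------------
    stage = "correlate"
    try:
        if len(config.grid.values) > 1:
            scores = manifest.score_table().loc[kept]
            patients = [s for s in kept if groups.loc[s] == "patient"]
            corr = metric_cognition_correlation(
                global_curves, scores, auc_range=_snap_range(config.auc_range, config.grid),
                nodal_curves=nodal_curves, subjects=patients,
            )
        else:
            log.append("stage correlate: single-threshold grid, AUC correlation skipped")
            corr = pd.DataFrame(
                columns=["metric", "scope", "region", "score", "r", "p", "q", "n"]
            )
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, "metric-cognition correlation", e) from e
    _tsv(corr, out / "cognition_correlation.tsv")
    log.append(f"stage correlate: {len(corr)} correlations")

    # --- report ---------------------------------------------------------
    save_config(config, out / "config.yaml")
    (out / "run.log").write_text("\n".join(log) + "\n", encoding="utf-8")
    summary = _summarise(comparison, sw_report, corr, len(kept), len(excluded))
    (out / "summary.txt").write_text(summary, encoding="utf-8")

    return dict(
        manifest=manifest, kept=kept, excluded=excluded,
        global_curves=global_curves, nodal_curves=nodal_curves,
        small_world=sw_df, small_world_report=sw_report,
        comparison=comparison, correlation=corr, log=log,
    )


def _summarise(comparison, sw_report, corr, n_kept, n_excluded) -> str:
    lines = [
        "Pipeline summary",
        "================",
        f"subjects analysed: {n_kept} (excluded by motion QC: {n_excluded})",
    ]
    if sw_report is not None and sw_report["contiguous_ranges"]:
        rng = sw_report["contiguous_ranges"][-1]
        lines.append(f"small-world sparsity range (both groups): {rng[0]:.2f}-{rng[1]:.2f}")
    auc = comparison[comparison["scope"] == "global_auc"]
    for _, row in auc.iterrows():
        flag = "significant" if row["significant"] else "ns"
        lines.append(
            f"AUC {row['metric']}: t = {row['t']:+.3f}, p = {row['p']:.3g}, "
            f"q = {row['q']:.3g} ({flag}; positive t = higher in patients)"
        )
    g = corr[(corr["scope"] == "global")]
    for _, row in g.iterrows():
        lines.append(
            f"corr {row['metric']} AUC vs {row['score']}: r = {row['r']:+.3f}, "
            f"p = {row['p']:.3g} (n = {row['n']})"
        )
    return "\n".join(lines) + "\n"
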