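"""Shared setup for the analysis drivers: the study-sized cohort and its curves."""

from pathlib import Path

import pandas as pd

from restconn.connectome import SparsityGrid, build_network_family, correlation_matrix
from restconn.metrics import compute_metric_curves
from restconn.synthetic import CohortSpec, generate_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 7
GRID = SparsityGrid()  # 0.05 .. 0.40, step 0.01


def cohort(seed: int = SEED):
    """The default synthetic cohort at the study design size (23 + 20, 90 x 230)."""
    return generate_cohort(CohortSpec(seed=seed))


def metric_curves(series, grid=GRID, nodal=False):
    """Global (and optionally nodal) metric curves for every subject."""
    g_parts, n_parts = [], []
    for ts in series:
        fam = build_network_family(correlation_matrix(ts), grid)
        gdf, ndf = compute_metric_curves(fam, grid, nodal=nodal)
        g_parts.append(gdf)
        if ndf is not None:
            n_parts.append(ndf)
    global_curves = pd.concat(g_parts, ignore_index=True)
    nodal_curves = pd.concat(n_parts, ignore_index=True) if n_parts else None
    return global_curves, nodal_curves


def save(df: pd.DataFrame, name: str) -> Path:
    RESULTS.mkdir(exist_ok=True)
    path = RESULTS / name
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path
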