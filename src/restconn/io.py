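"""Tabular formats, the bundled region table, and pipeline configuration.

All tabular IO is TSV with a header row, UTF-8, '.' decimal — diff-able and
language-neutral. Region indexing is 1-based in files (atlas convention)
and 0-based in memory; this module is the boundary. Time-series files are
regions x timepoints with a ``region`` index column and timepoint-index
header; matrices are square with region ids as both header and first
column.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectome import ConnectivityMatrix, SparsityGrid
from .nulls import NullEnsembleSpec
from .preprocess import BandPassSpec, MotionRule, TimeSeriesMatrix
from .synthetic import CohortManifest, CohortSpec

__all__ = [
    "default_region_table",
    "read_time_series",
    "write_time_series",
    "read_manifest",
    "write_manifest",
    "read_matrix",
    "write_matrix",
    "PipelineConfig",
    "load_config",
    "save_config",
    "config_hash",
]


class IOError_(ValueError):
    """Raised for malformed input tables."""


# 45 bilateral region pairs of the standard 90-region automated anatomical
# labelling (AAL) cortical/subcortical parcellation, in atlas order
# (odd index = left, even = right).
_AAL_PAIRS = [
    ("PreCG", "Precentral gyrus"),
    ("SFGdor", "Superior frontal gyrus, dorsolateral"),
    ("ORBsup", "Superior frontal gyrus, orbital part"),
    ("MFG", "Middle frontal gyrus"),
    ("ORBmid", "Middle frontal gyrus, orbital part"),
    ("IFGoperc", "Inferior frontal gyrus, opercular part"),
    ("IFGtriang", "Inferior frontal gyrus, triangular part"),
    ("ORBinf", "Inferior frontal gyrus, orbital part"),
    ("ROL", "Rolandic operculum"),
    ("SMA", "Supplementary motor area"),
    ("OLF", "Olfactory cortex"),
    ("SFGmed", "Superior frontal gyrus, medial"),
    ("ORBsupmed", "Superior frontal gyrus, medial orbital"),
    ("REC", "Gyrus rectus"),
    ("INS", "Insula"),
    ("ACG", "Anterior cingulate and paracingulate gyri"),
    ("DCG", "Median cingulate and paracingulate gyri"),
    ("PCG", "Posterior cingulate gyrus"),
    ("HIP", "Hippocampus"),
    ("PHG", "Parahippocampal gyrus"),
    ("AMYG", "Amygdala"),
    ("CAL", "Calcarine fissure and surrounding cortex"),
    ("CUN", "Cuneus"),
    ("LING", "Lingual gyrus"),
    ("SOG", "Superior occipital gyrus"),
    ("MOG", "Middle occipital gyrus"),
    ("IOG", "Inferior occipital gyrus"),
    ("FFG", "Fusiform gyrus"),
    ("PoCG", "Postcentral gyrus"),
    ("SPG", "Superior parietal gyrus"),
    ("IPL", "Inferior parietal, but supramarginal and angular gyri"),
    ("SMG", "Supramarginal gyrus"),
    ("ANG", "Angular gyrus"),
    ("PCUN", "Precuneus"),
    ("PCL", "Paracentral lobule"),
    ("CAU", "Caudate nucleus"),
    ("PUT", "Lenticular nucleus, putamen"),
    ("PAL", "Lenticular nucleus, pallidum"),
    ("THA", "Thalamus"),
    ("HES", "Heschl gyrus"),
    ("STG", "Superior temporal gyrus"),
    ("TPOsup", "Temporal pole: superior temporal gyrus"),
    ("MTG", "Middle temporal gyrus"),
    ("TPOmid", "Temporal pole: middle temporal gyrus"),
    ("ITG", "Inferior temporal gyrus"),
]


def default_region_table(n_regions: int = 90) -> pd.DataFrame:
    """Region table: 1-based index, name, abbreviation, hemisphere.

    For the default 90 regions this is the standard AAL-90 parcellation in
    atlas order (left/right interleaved). For other sizes a generic
    numbered table is returned.
    """
    if n_regions == 90:
        rows = []
        for i, (abbr, name) in enumerate(_AAL_PAIRS):
            for j, side in enumerate(("L", "R")):
                rows.append(
                    dict(index=2 * i + j + 1, name=name, abbreviation=f"{abbr}.{side}",
                         hemisphere=side)
                )
        return pd.DataFrame(rows)
    return pd.DataFrame(
        dict(
            index=np.arange(1, n_regions + 1),
            name=[f"region {i}" for i in range(1, n_regions + 1)],
            abbreviation=[f"R{i}" for i in range(1, n_regions + 1)],
            hemisphere=["?"] * n_regions,
        )
    )


def write_time_series(ts: TimeSeriesMatrix, path) -> None:
    df = pd.DataFrame(
        ts.data,
        index=pd.Index(ts.region_ids, name="region"),
        columns=np.arange(ts.n_timepoints),
    )
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_time_series(path, subject_id: str | None = None, tr_seconds: float = 2.0,
                     region_table: pd.DataFrame | None = None) -> TimeSeriesMatrix:
    """Read a regions x timepoints TSV; validates against a region table when given."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col="region")
    except Exception as e:
        raise IOError_(f"{path}: cannot parse time-series table ({e})") from e
    if df.isna().any().any():
        bad = int(np.argmax(df.isna().any(axis=1).to_numpy())) + 2  # +header +1-based
        raise IOError_(f"{path}: non-numeric or missing cell near line {bad}")
    region_ids = [str(r) for r in df.index]
    if region_table is not None:
        expected = [str(i) for i in region_table["index"]]
        if region_ids != expected:
            raise IOError_(
                f"{path}: region ids do not match the region table "
                f"({len(region_ids)} regions vs {len(expected)} expected)"
            )
    return TimeSeriesMatrix(
        subject_id=subject_id or path.stem,
        data=df.to_numpy(dtype=float),
        tr_seconds=tr_seconds,
        region_ids=region_ids,
    )


def write_manifest(manifest: CohortManifest, path) -> None:
    manifest.subjects.to_csv(path, sep="\t", index=False, float_format="%.10g")
    mod_path = Path(path).with_suffix(".modules.tsv")
    pd.DataFrame(
        dict(region=np.arange(1, len(manifest.module_assignment) + 1),
             module=manifest.module_assignment)
    ).to_csv(mod_path, sep="\t", index=False)


def read_manifest(path) -> CohortManifest:
    path = Path(path)
    subjects = pd.read_csv(path, sep="\t")
    mod_path = path.with_suffix(".modules.tsv")
    if mod_path.exists():
        modules = pd.read_csv(mod_path, sep="\t")["module"].to_numpy()
    else:
        modules = np.zeros(0, dtype=int)
    return CohortManifest(subjects=subjects, module_assignment=modules)


def write_matrix(cm: ConnectivityMatrix, path) -> None:
    pd.DataFrame(cm.r, index=pd.Index(cm.region_ids, name="region"),
                 columns=cm.region_ids).to_csv(path, sep="\t", float_format="%.10g")


def read_matrix(path, subject_id: str | None = None) -> ConnectivityMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col="region")
    return ConnectivityMatrix(
        subject_id=subject_id or path.stem,
        r=df.to_numpy(dtype=float),
        region_ids=[str(r) for r in df.index],
    )


@dataclass
class PipelineConfig:
    """Everything a full pipeline run needs; round-trips through YAML."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    input_dir: str | None = None  # ingest instead of simulate when set
    bandpass: BandPassSpec = field(default_factory=BandPassSpec)
    motion: MotionRule = field(default_factory=MotionRule)
    apply_qc: bool = True
    grid: SparsityGrid = field(default_factory=SparsityGrid)
    edge_sign: str = "positive"
    nulls: NullEnsembleSpec = field(default_factory=NullEnsembleSpec)
    null_sparsities: list = field(default_factory=list)  # [] = full grid
    lp_convention: str = "finite_mean"
    fdr_q: float = 0.05
    report_sparsity: float = 0.18
    auc_range: tuple = (0.08, 0.31)
    compute_nodal: bool = True
    out_dir: str = "results/pipeline"
    seed: int = 0


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=True)


def load_config(path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return _config_from_dict(raw)


def _config_from_dict(raw: dict) -> PipelineConfig:
    raw = dict(raw)
    cohort_raw = dict(raw.pop("cohort", {}))
    bp_cohort = cohort_raw.pop("bandpass", None)
    cohort = CohortSpec(**cohort_raw) if bp_cohort is None else CohortSpec(
        bandpass=BandPassSpec(**bp_cohort), **cohort_raw
    )
    kwargs = dict(
        cohort=cohort,
        bandpass=BandPassSpec(**raw.pop("bandpass", {})),
        motion=MotionRule(**raw.pop("motion", {})),
        grid=SparsityGrid(**raw.pop("grid", {})),
        nulls=NullEnsembleSpec(**raw.pop("nulls", {})),
    )
    if "auc_range" in raw:
        raw["auc_range"] = tuple(raw["auc_range"])
    kwargs.update(raw)
    return PipelineConfig(**kwargs)


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(_to_plain(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
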