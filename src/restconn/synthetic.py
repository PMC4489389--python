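"""Synthetic two-group cohort generator with known modular ground truth.

Emulates the study design the pipeline targets: a patient group and a
control group of resting-state ROI time series (90 regions, 230 retained
volumes at TR = 2 s by default), where functional connectivity arises from
a block-modular covariance structure. Patients have weaker within-module
coupling than controls, each subject carries a latent coupling level drawn
around the group target, and cognitive scores are linearly coupled to that
latent level — so every downstream stage (connectome construction, graph
metrics, group statistics, metric-cognition correlation) has a known
ground truth to recover.

The generator works in signal space only: no voxels, no haemodynamic
response, no lesion modelling. Sampled series pass through the identical
band-pass filter as real data so that the synthetic cohort exercises the
same preprocessing path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import BandPassSpec, TimeSeriesMatrix, bandpass_filter

__all__ = [
    "CohortSpec",
    "CohortManifest",
    "generate_cohort",
    "empirical_block_correlation",
    "module_assignment",
]


class CohortSpecError(ValueError):
    """Raised when a cohort specification violates its bounds."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort.

    Defaults mirror the target study design: 23 patients vs 20 controls,
    90 atlas regions, 230 retained volumes at TR = 2 s, six covariance
    modules. ``within_r_*`` are the target within-module correlations per
    group (patients <= controls); ``between_r`` the baseline correlation
    between modules. ``coupling_sd`` is the SD of the per-subject latent
    coupling around its group target (truncated to (between_r, 0.95)).
    Cognitive scores are ``intercept + cognition_slope * coupling + noise``.
    """

    n_patients: int = 23
    n_controls: int = 20
    n_regions: int = 90
    n_timepoints: int = 230
    tr_seconds: float = 2.0
    n_modules: int = 6
    within_r_control: float = 0.6
    within_r_patient: float = 0.3
    between_r: float = 0.05
    noise_sd: float = 0.2
    coupling_sd: float = 0.08
    cognition_slope: float = 57.0
    cognition_sd: float = 5.0
    seed: int = 0
    bandpass: BandPassSpec = field(default_factory=BandPassSpec)

    # fixed affine anchors for the two scores (chosen to put the scores on
    # the scale of a CAMCOG-like total and praxis subscore)
    COG_INTERCEPT = 59.0
    PRAXIS_INTERCEPT = 4.1
    PRAXIS_SLOPE_FRAC = 0.2
    PRAXIS_SD_FRAC = 0.25

    def validate(self) -> None:
        for name in ("n_patients", "n_controls", "n_regions", "n_timepoints", "n_modules"):
            if getattr(self, name) <= 0:
                raise CohortSpecError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n_modules > self.n_regions:
            raise CohortSpecError("n_modules cannot exceed n_regions")
        if not (0.0 <= self.between_r < self.within_r_patient <= self.within_r_control < 1.0):
            raise CohortSpecError(
                "need 0 <= between_r < within_r_patient <= within_r_control < 1, got "
                f"between_r={self.between_r}, within_r_patient={self.within_r_patient}, "
                f"within_r_control={self.within_r_control}"
            )
        if self.noise_sd < 0 or self.cognition_sd < 0 or self.coupling_sd < 0:
            raise CohortSpecError("noise_sd, cognition_sd and coupling_sd must be >= 0")
        if self.tr_seconds <= 0:
            raise CohortSpecError("tr_seconds must be positive")


@dataclass
class CohortManifest:
    """Per-subject ground truth and scores.

    ``subjects`` is a DataFrame with columns: subject_id, group
    ('patient'/'control'), true_coupling (the latent within-module
    correlation actually used — ground truth for recovery tests),
    camcog_total, praxis, max_translation_mm, max_rotation_deg.
    ``module_assignment`` maps each region to its covariance block.
    """

    subjects: pd.DataFrame
    module_assignment: np.ndarray

    def __post_init__(self):
        ids = self.subjects["subject_id"]
        if ids.duplicated().any():
            raise CohortSpecError("subject ids must be unique")

    @property
    def groups(self) -> pd.Series:
        return self.subjects.set_index("subject_id")["group"]

    def score_table(self) -> pd.DataFrame:
        return self.subjects.set_index("subject_id")[["camcog_total", "praxis"]]


def module_assignment(n_regions: int, n_modules: int) -> np.ndarray:
    """Contiguous block labels 0..n_modules-1; the last block absorbs any remainder."""
    size = n_regions // n_modules
    labels = np.repeat(np.arange(n_modules), size)
    return np.concatenate([labels, np.full(n_regions - len(labels), n_modules - 1)])


def _nearest_pd_correlation(c: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues at ``eig_floor`` and renormalise to unit diagonal."""
    w, v = np.linalg.eigh(c)
    w = np.clip(w, eig_floor, None)
    c2 = (v * w) @ v.T
    d = np.sqrt(np.diag(c2))
    c2 = c2 / np.outer(d, d)
    np.fill_diagonal(c2, 1.0)
    return c2


def _block_correlation(labels: np.ndarray, within_r: float, between_r: float) -> np.ndarray:
    same = labels[:, None] == labels[None, :]
    c = np.where(same, within_r, between_r)
    np.fill_diagonal(c, 1.0)
    return c


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float, high: float) -> float:
    if sd == 0:
        return float(np.clip(mean, low, high))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if low < x < high:
            return float(x)
    return float(np.clip(mean, low + 1e-9, high - 1e-9))


def generate_cohort(spec: CohortSpec):
    """Generate the cohort: returns ``(CohortManifest, list of TimeSeriesMatrix)``.

    For each subject a latent coupling is drawn from
    Normal(group target, coupling_sd) truncated to (between_r, 0.95); a
    block-constant correlation matrix at that coupling is projected to the
    nearest positive-definite correlation matrix; Gaussian series are
    sampled from it, white noise of SD ``noise_sd`` is added, and the
    result is band-limited through the standard preprocessing filter.
    Cognitive scores are affine in the latent coupling plus Gaussian
    noise. Motion summaries are drawn log-normal, with a small fraction of
    subjects exceeding the exclusion bounds so the QC path is exercised.
    Fully reproducible from ``spec.seed``.
    """
    spec.validate()
    labels = module_assignment(spec.n_regions, spec.n_modules)
    rng = np.random.default_rng(spec.seed)

    rows = []
    series = []
    group_plan = [("patient", spec.within_r_patient)] * spec.n_patients + [
        ("control", spec.within_r_control)
    ] * spec.n_controls
    width = len(str(len(group_plan)))
    for i, (group, target) in enumerate(group_plan):
        sid = f"sub-{i + 1:0{width}d}"
        coupling = _truncated_normal(rng, target, spec.coupling_sd, spec.between_r, 0.95)
        corr = _nearest_pd_correlation(_block_correlation(labels, coupling, spec.between_r))
        chol = np.linalg.cholesky(corr)
        raw = chol @ rng.standard_normal((spec.n_regions, spec.n_timepoints))
        raw += spec.noise_sd * rng.standard_normal(raw.shape)
        ts = TimeSeriesMatrix(
            subject_id=sid,
            data=raw,
            tr_seconds=spec.tr_seconds,
            region_ids=[str(r + 1) for r in range(spec.n_regions)],
        )
        ts = bandpass_filter(ts, spec.bandpass)
        series.append(ts)

        camcog = spec.COG_INTERCEPT + spec.cognition_slope * coupling
        praxis = spec.PRAXIS_INTERCEPT + spec.PRAXIS_SLOPE_FRAC * spec.cognition_slope * coupling
        if spec.cognition_sd > 0:
            camcog += rng.normal(0.0, spec.cognition_sd)
            praxis += rng.normal(0.0, spec.PRAXIS_SD_FRAC * spec.cognition_sd)
        # log-normal motion: ~5% of subjects beyond each 3.0 bound
        trans = float(rng.lognormal(mean=np.log(0.8), sigma=0.80))
        rot = float(rng.lognormal(mean=np.log(0.8), sigma=0.80))
        rows.append(
            dict(
                subject_id=sid,
                group=group,
                true_coupling=coupling,
                camcog_total=float(camcog),
                praxis=float(praxis),
                max_translation_mm=trans,
                max_rotation_deg=rot,
            )
        )

    manifest = CohortManifest(subjects=pd.DataFrame(rows), module_assignment=labels)
    return manifest, series


def empirical_block_correlation(ts: TimeSeriesMatrix, module_labels: np.ndarray):
    """Mean off-diagonal Pearson r within vs between modules.

    Returns ``(within_r, between_r)``. Requires at least one module with
    >= 2 regions; raises otherwise. Used to verify that generated cohorts
    realise their design targets.
    """
    labels = np.asarray(module_labels)
    if labels.shape[0] != ts.n_regions:
        raise CohortSpecError("module labels must cover all regions")
    r = np.corrcoef(ts.data)
    same = labels[:, None] == labels[None, :]
    off = ~np.eye(ts.n_regions, dtype=bool)
    within_mask = same & off
    if not within_mask.any():
        raise CohortSpecError("within-module correlation undefined: every module has < 2 regions")
    within = float(r[within_mask].mean())
    between_mask = ~same
    between = float(r[between_mask].mean()) if between_mask.any() else float("nan")
    return within, between
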