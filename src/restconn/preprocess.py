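"""Final time-series preprocessing: volume discarding, motion QC, band-pass filtering.

Image-space preprocessing (realignment, normalisation, smoothing) is assumed
done upstream; the pipeline's entry format is extracted ROI time series
(regions x timepoints). The stages here are the ones that act on those
series directly: discarding initial volumes to allow for T1 equilibration,
excluding subjects whose head motion exceeds the study bounds, and temporal
band-pass filtering to the low-frequency BOLD range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "TimeSeriesMatrix",
    "BandPassSpec",
    "MotionRule",
    "bandpass_filter",
    "apply_motion_qc",
    "discard_initial_volumes",
]


class PreprocessError(ValueError):
    """Raised for invalid preprocessing inputs or specs."""


@dataclass
class TimeSeriesMatrix:
    """One subject's ROI signals: a regions x timepoints real array.

    Parameters
    ----------
    subject_id : str
        Cohort-unique subject identifier.
    data : ndarray, shape (n_regions, n_timepoints)
        Real-valued BOLD signal per region.
    tr_seconds : float
        Sampling interval (repetition time) in seconds.
    region_ids : list of str
        Ordered region labels; order must match the cohort's region table.
    """

    subject_id: str
    data: np.ndarray
    tr_seconds: float = 2.0
    region_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise PreprocessError("time-series data must be 2-D (regions x timepoints)")
        if not np.all(np.isfinite(self.data)):
            raise PreprocessError(f"subject {self.subject_id}: non-finite values in time series")
        if self.data.shape[0] < 2:
            raise PreprocessError(f"subject {self.subject_id}: need >= 2 regions")
        if self.data.shape[1] < 8:
            raise PreprocessError(f"subject {self.subject_id}: need >= 8 timepoints")
        if self.tr_seconds <= 0:
            raise PreprocessError("tr_seconds must be positive")
        if not self.region_ids:
            self.region_ids = [str(i + 1) for i in range(self.data.shape[0])]
        if len(self.region_ids) != self.data.shape[0]:
            raise PreprocessError("region_ids length must match the number of regions")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.tr_seconds


@dataclass(frozen=True)
class BandPassSpec:
    """Temporal pass band in Hz. Default 0.01-0.08 Hz, the low-frequency BOLD band."""

    f_low: float = 0.01
    f_high: float = 0.08

    def validate(self, tr_seconds: float) -> None:
        nyquist = 0.5 / tr_seconds
        if not (0.0 < self.f_low < self.f_high):
            raise PreprocessError(f"need 0 < f_low < f_high, got ({self.f_low}, {self.f_high})")
        if self.f_high >= nyquist:
            raise PreprocessError(
                f"f_high = {self.f_high} Hz is at/above Nyquist ({nyquist} Hz for TR {tr_seconds}s)"
            )


@dataclass(frozen=True)
class MotionRule:
    """Head-motion exclusion bounds: a subject is excluded when motion *exceeds* either."""

    max_translation_mm: float = 3.0
    max_rotation_deg: float = 3.0

    def __post_init__(self):
        if self.max_translation_mm <= 0 or self.max_rotation_deg <= 0:
            raise PreprocessError("motion bounds must be positive")


_FILTER_ORDER = 4


def _design_sos(spec: BandPassSpec, tr_seconds: float) -> np.ndarray:
    return butter(
        _FILTER_ORDER,
        [spec.f_low, spec.f_high],
        btype="bandpass",
        fs=1.0 / tr_seconds,
        output="sos",
    )


def bandpass_filter(ts: TimeSeriesMatrix, spec: BandPassSpec = BandPassSpec()) -> TimeSeriesMatrix:
    """Zero-phase Butterworth band-pass of every region's series.

    An order-4 Butterworth band-pass is applied forward-backward
    (zero phase, so no lag is introduced that would shift correlations),
    with reflective (even) padding of the settling length at each end to
    limit edge transients on short series. Each series is demeaned before
    and after so the output carries no DC component.
    """
    spec.validate(ts.tr_seconds)
    sos = _design_sos(spec, ts.tr_seconds)
    padlen = 3 * (2 * sos.shape[0] + 1)
    if ts.n_timepoints <= max(padlen, 3 * _FILTER_ORDER):
        raise PreprocessError(
            f"series of length {ts.n_timepoints} too short for stable filtering "
            f"(need > {max(padlen, 3 * _FILTER_ORDER)} timepoints)"
        )
    x = ts.data - ts.data.mean(axis=1, keepdims=True)
    y = sosfiltfilt(sos, x, axis=1, padtype="even", padlen=padlen)
    y = y - y.mean(axis=1, keepdims=True)
    return replace(ts, data=y)


def apply_motion_qc(manifest, rule: MotionRule = MotionRule()):
    """Split subjects into (kept, excluded) by the head-motion rule.

    A subject is excluded iff max translation strictly exceeds
    ``rule.max_translation_mm`` or max rotation strictly exceeds
    ``rule.max_rotation_deg`` — a subject exactly at a bound is kept.

    Parameters
    ----------
    manifest : CohortManifest or pandas.DataFrame
        Must carry columns ``subject_id``, ``max_translation_mm``,
        ``max_rotation_deg``.

    Returns
    -------
    (kept, excluded) : pair of lists of subject ids, disjoint, covering all.
    """
    table = getattr(manifest, "subjects", manifest)
    for col in ("max_translation_mm", "max_rotation_deg"):
        if col not in table.columns:
            raise PreprocessError(f"manifest lacks motion column {col!r}")
        bad = table[table[col].isna()]
        if len(bad):
            raise PreprocessError(
                f"missing motion summary for subject {bad['subject_id'].iloc[0]!r}"
            )
    excl_mask = (table["max_translation_mm"] > rule.max_translation_mm) | (
        table["max_rotation_deg"] > rule.max_rotation_deg
    )
    kept = list(table.loc[~excl_mask, "subject_id"])
    excluded = list(table.loc[excl_mask, "subject_id"])
    return kept, excluded


def discard_initial_volumes(ts: TimeSeriesMatrix, n_discard: int = 10) -> TimeSeriesMatrix:
    """Drop the first ``n_discard`` timepoints (T1-equilibration volumes)."""
    if n_discard < 0:
        raise PreprocessError("n_discard must be >= 0")
    if n_discard >= ts.n_timepoints:
        raise PreprocessError(
            f"cannot discard {n_discard} of {ts.n_timepoints} timepoints"
        )
    if n_discard == 0:
        return replace(ts, data=ts.data.copy())
    return replace(ts, data=ts.data[:, n_discard:].copy())
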