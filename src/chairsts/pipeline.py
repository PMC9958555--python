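"""End-to-end concurrent-validity pipeline.

Chair chain: low-pass the two distance channels at 30 Hz, invert the
two-link geometry. Reference chain: low-pass the marker coordinates at their
native 100 Hz, spline-resample to 30 Hz, compute marker-based angles. Both
angle series are then segmented by their own trunk events, and compared
phase by phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import events as _ev
from . import stats as _stats
from .geometry import AngleSeries, ChairGeometry, DistanceSeries, angles_from_distances
from .signal import FilterSpec, butterworth_lowpass, spline_resample
from .synthetic import MarkerSeries, angles_from_markers

__all__ = [
    "TrialResult",
    "chair_angles",
    "marker_angles",
    "validate_trial",
    "summarize_condition",
]


@dataclass
class TrialResult:
    """One trial's validation metrics plus the segmentations behind them."""

    validation: _stats.TrialValidation
    chair_seg: _ev.PhaseSegmentation
    ref_seg: _ev.PhaseSegmentation
    chair_excursions: _ev.ExcursionPair
    ref_excursions: _ev.ExcursionPair

    def to_dict(self) -> dict:
        return {
            "validation": self.validation.to_dict(),
            "chair_segmentation": self.chair_seg.to_dict(),
            "reference_segmentation": self.ref_seg.to_dict(),
            "chair_excursions": {
                "flexion_deg": self.chair_excursions.flexion_deg,
                "extension_deg": self.chair_excursions.extension_deg,
            },
            "reference_excursions": {
                "flexion_deg": self.ref_excursions.flexion_deg,
                "extension_deg": self.ref_excursions.extension_deg,
            },
        }


def _fill_gaps(x: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Linearly interpolate invalid samples so the filter sees finite data;
    edge gaps are held at the nearest valid value. Validity flags are kept by
    the caller, so filled samples stay marked invalid downstream."""
    if valid.all():
        return x
    if not valid.any():
        raise ValueError("series has no valid samples")
    idx = np.arange(x.size)
    return np.interp(idx, idx[valid], x[valid])


def chair_angles(
    distances: DistanceSeries,
    geom: ChairGeometry = ChairGeometry(),
    filt: FilterSpec | None = FilterSpec(),
) -> AngleSeries:
    """Distances -> filtered distances -> two-link inverse -> angle series."""
    distances = distances.flag_out_of_range(geom)
    d_thigh, d_trunk = distances.d_thigh, distances.d_trunk
    if filt is not None:
        ok = distances.valid & np.isfinite(d_thigh) & np.isfinite(d_trunk)
        d_thigh = butterworth_lowpass(_fill_gaps(d_thigh, ok), distances.fs, filt)
        d_trunk = butterworth_lowpass(_fill_gaps(d_trunk, ok), distances.fs, filt)
    filtered = DistanceSeries(distances.t, d_thigh, d_trunk,
                              distances.valid, distances.fs)
    return angles_from_distances(filtered, geom)


def marker_angles(
    markers: MarkerSeries,
    fs_out: float = 30.0,
    filt: FilterSpec | None = FilterSpec(),
) -> AngleSeries:
    """Markers -> filtered coordinates at native rate -> 30 Hz -> angles."""
    coords = {}
    for name in ("c7", "sacrum", "greater_trochanter", "lateral_femoral_condyle"):
        arr = getattr(markers, name)
        cols = []
        for j in (0, 1):
            x = arr[:, j]
            if filt is not None:
                x = butterworth_lowpass(x, markers.fs, filt)
            t_new, x_new = spline_resample(markers.t, x, fs_out)
            cols.append(x_new)
        coords[name] = np.column_stack(cols)
    resampled = MarkerSeries(t_new, coords["c7"], coords["sacrum"],
                             coords["greater_trochanter"],
                             coords["lateral_femoral_condyle"], fs=fs_out)
    return angles_from_markers(resampled)


def _phase_segments(series: AngleSeries, seg: _ev.PhaseSegmentation):
    """Trunk flexion / trunk extension / whole-window thigh segments."""
    trunk = np.asarray(series.theta_trunk, dtype=float)
    thigh = np.asarray(series.theta_thigh, dtype=float)
    flex = trunk[seg.start_idx : seg.max_flexion_idx + 1]
    ext = trunk[seg.max_flexion_idx : seg.max_extension_idx + 1]
    thigh_win = thigh[seg.start_idx : seg.max_extension_idx + 1]
    return flex, ext, thigh_win


def validate_trial(
    chair: AngleSeries,
    reference: AngleSeries,
    onset_threshold_deg: float = 1.0,
    max_lag_s: float = 0.0,
) -> TrialResult:
    """Compare a chair-model angle series against a reference series.

    Each series is segmented by its own trunk events (onset at a 1 degree
    rise above quiet-sitting baseline; phases split at maximum flexion).
    Waveform similarity is computed per phase for the trunk and over the
    whole movement window for the thigh; excursion errors per phase.
    ``max_lag_s > 0`` switches the similarity to its lag-search mode.
    """
    c_start = _ev.detect_sts_start(chair, onset_threshold_deg)
    r_start = _ev.detect_sts_start(reference, onset_threshold_deg)
    c_seg = _ev.segment_phases(chair, c_start)
    r_seg = _ev.segment_phases(reference, r_start)
    c_exc = _ev.excursions(chair, c_seg)
    r_exc = _ev.excursions(reference, r_seg)

    c_flex, c_ext, c_thigh = _phase_segments(chair, c_seg)
    r_flex, r_ext, r_thigh = _phase_segments(reference, r_seg)
    fs = chair.fs
    r_tf = _stats.waveform_similarity(c_flex, r_flex, fs=fs, max_lag_s=max_lag_s)
    r_te = _stats.waveform_similarity(c_ext, r_ext, fs=fs, max_lag_s=max_lag_s)
    r_th = _stats.waveform_similarity(c_thigh, r_thigh, fs=fs, max_lag_s=max_lag_s)
    errs = _stats.excursion_errors(c_exc, r_exc)

    validation = _stats.TrialValidation(
        r_thigh=r_th,
        r_trunk_flexion=r_tf,
        r_trunk_extension=r_te,
        abs_err_flexion_deg=errs["abs_err_flexion_deg"],
        abs_err_extension_deg=errs["abs_err_extension_deg"],
        pct_err_flexion=errs["pct_err_flexion"],
        pct_err_extension=errs["pct_err_extension"],
    )
    return TrialResult(validation, c_seg, r_seg, c_exc, r_exc)


def summarize_condition(
    condition: str, trials: list[_stats.TrialValidation]
) -> _stats.ConditionSummary:
    """Fisher-average the per-trial correlations and average the absolute
    errors over one condition's trials (the five-trial averaging step)."""
    if not trials:
        raise ValueError("summarize_condition needs at least one trial")
    fisher_r = {
        name: _stats.fisher_mean([getattr(tv, name) for tv in trials])
        for name in ("r_thigh", "r_trunk_flexion", "r_trunk_extension")
    }
    mean_err = {
        name: float(np.mean([getattr(tv, name) for tv in trials]))
        for name in ("abs_err_flexion_deg", "abs_err_extension_deg")
    }
    return _stats.ConditionSummary(condition, len(trials), fisher_r, mean_err)
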