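"""Sit-to-stand phase segmentation from the trunk angle series.

Movement onset is the first sample where the trunk flexion angle exceeds its
quiet-sitting baseline by at least 1 degree (with a short non-decreasing
confirmation to reject single-sample noise). The flexion phase runs from
onset to maximum trunk flexion; the extension phase from that peak to the
maximum trunk extension (the post-peak minimum). Segmentation is always
computed on the trunk series and applied unchanged to the thigh analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import AngleSeries

__all__ = ["PhaseSegmentation", "ExcursionPair", "detect_sts_start",
           "segment_phases", "excursions"]


@dataclass(frozen=True)
class PhaseSegmentation:
    """Sample indices bounding the two sit-to-stand phases.

    flexion phase = [start_idx, max_flexion_idx];
    extension phase = [max_flexion_idx, max_extension_idx].
    baseline_deg is the quiet-sitting trunk-angle reference the onset
    threshold was measured against.
    """

    start_idx: int
    max_flexion_idx: int
    max_extension_idx: int
    baseline_deg: float

    def __post_init__(self) -> None:
        if not self.start_idx < self.max_flexion_idx < self.max_extension_idx:
            raise ValueError(
                "segmentation indices must satisfy "
                f"start < peak < end, got {self.start_idx}, "
                f"{self.max_flexion_idx}, {self.max_extension_idx}"
            )

    def to_dict(self) -> dict:
        return {
            "start_idx": int(self.start_idx),
            "max_flexion_idx": int(self.max_flexion_idx),
            "max_extension_idx": int(self.max_extension_idx),
            "baseline_deg": float(self.baseline_deg),
        }


@dataclass(frozen=True)
class ExcursionPair:
    """Angular excursions, degrees: maximum displacement within each phase."""

    flexion_deg: float
    extension_deg: float

    def __post_init__(self) -> None:
        if self.flexion_deg < 0 or self.extension_deg < 0:
            raise ValueError("excursions must be non-negative")


def _trunk(series: AngleSeries) -> np.ndarray:
    """Trunk angles with invalid samples as NaN."""
    x = np.asarray(series.theta_trunk, dtype=float).copy()
    x[~series.valid] = np.nan
    return x


def detect_sts_start(
    trunk: AngleSeries,
    threshold_deg: float = 1.0,
    baseline_window_s: float = 0.5,
    confirm_samples: int = 3,
) -> int:
    """Index of sit-to-stand onset on a trunk angle series.

    The baseline is the mean trunk angle over the first ``baseline_window_s``
    of quiet sitting. Onset is the first sample whose angle exceeds
    baseline + ``threshold_deg`` and whose following ``confirm_samples``
    samples are non-decreasing (noise-trigger guard; the threshold itself
    stays at 1 degree).
    """
    x = _trunk(trunk)
    n_base = max(1, int(round(baseline_window_s * trunk.fs)))
    if n_base >= x.size:
        raise ValueError("series shorter than the baseline window")
    window = x[:n_base]
    if not np.any(np.isfinite(window)):
        raise ValueError("baseline window contains no valid samples")
    baseline = float(np.nanmean(window))
    above = x >= baseline + threshold_deg
    for i in np.flatnonzero(above):
        seg = x[i : i + confirm_samples + 1]
        seg = seg[np.isfinite(seg)]
        if seg.size < 2 or np.all(np.diff(seg) >= 0):
            return int(i)
    raise ValueError("no STS onset detected")


def segment_phases(trunk: AngleSeries, start_idx: int) -> PhaseSegmentation:
    """Locate maximum trunk flexion and maximum trunk extension after onset.

    The flexion peak is the post-onset argmax of the trunk angle; the
    extension bound is the post-peak argmin (global, so late standing
    oscillation larger than the first dip moves the bound — by design the
    deepest extension ends the analysis window). Ties break to the earliest
    index for determinism.
    """
    x = _trunk(trunk)
    n = x.size
    if not 0 <= start_idx < n - 2:
        raise ValueError(f"start_idx {start_idx} leaves no room for two phases")
    post = x[start_idx:]
    if np.all(np.isnan(post)):
        raise ValueError("no valid samples after onset")
    flex_idx = start_idx + int(np.nanargmax(post))
    if flex_idx >= n - 1 or flex_idx == start_idx:
        raise ValueError("no flexion peak before the end of the series")
    tail = x[flex_idx:]
    if np.all(np.isnan(tail[1:])):
        raise ValueError("no valid samples after the flexion peak")
    ext_idx = flex_idx + int(np.nanargmin(tail))
    if ext_idx == flex_idx:
        raise ValueError("trunk angle does not extend after the flexion peak")
    n_base = max(1, int(round(0.5 * trunk.fs)))
    baseline = float(np.nanmean(x[: min(n_base, start_idx + 1)]))
    return PhaseSegmentation(start_idx, flex_idx, ext_idx, baseline)


def excursions(trunk: AngleSeries, seg: PhaseSegmentation) -> ExcursionPair:
    """Angular excursions of the two phases.

    flexion = angle(peak) - angle(onset); extension = angle(peak) -
    angle(extension bound). Both are invariant to adding a constant to the
    whole series.
    """
    x = _trunk(trunk)
    if seg.max_extension_idx >= x.size:
        raise ValueError("segmentation out of bounds for this series")
    a0, ap, ae = x[seg.start_idx], x[seg.max_flexion_idx], x[seg.max_extension_idx]
    if not (np.isfinite(a0) and np.isfinite(ap) and np.isfinite(ae)):
        raise ValueError("segmentation lands on invalid samples")
    return ExcursionPair(flexion_deg=float(ap - a0), extension_deg=float(ap - ae))
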