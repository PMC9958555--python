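"""Pre-processing applied identically to distance and marker data.

Both data streams pass through a fourth-order low-pass Butterworth filter
with a 6 Hz cutoff before any analysis; marker trajectories (100 Hz) are then
cubic-spline resampled onto the 30 Hz grid of the range sensors. Filtering is
zero-phase by default (forward-backward), because a phase lag would bias
event timing; a causal mode is available. The nominal cutoff is specified per
single pass — the doubled application in zero-phase mode is not compensated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.typing as npt
from scipy import signal as _sig
from scipy.interpolate import CubicSpline

__all__ = ["FilterSpec", "butterworth_lowpass", "spline_resample"]


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth filter parameters.

    order is the single-pass order (even, >= 2); cutoff_hz must stay below
    the Nyquist frequency of the series it is applied to; zero_phase selects
    forward-backward filtering (no group delay).
    """

    order: int = 4
    cutoff_hz: float = 6.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.order < 2 or self.order % 2:
            raise ValueError(f"order must be even and >= 2, got {self.order}")
        if not self.cutoff_hz > 0:
            raise ValueError(f"cutoff_hz must be > 0, got {self.cutoff_hz}")


def butterworth_lowpass(
    x: npt.ArrayLike, fs: float, spec: FilterSpec = FilterSpec()
) -> np.ndarray:
    """Low-pass a uniformly sampled series; length and timestamps unchanged.

    Zero-phase mode runs scipy's forward-backward pass with reflective
    ("even") padding of 3x the filter order, which suppresses startup
    transients on short sit-to-stand trials. NaNs must be removed or
    interpolated first.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("butterworth_lowpass expects a 1-D series")
    if spec.cutoff_hz >= fs / 2:
        raise ValueError(
            f"cutoff {spec.cutoff_hz} Hz must be below Nyquist {fs / 2} Hz"
        )
    if x.size <= 3 * spec.order:
        raise ValueError(
            f"series too short to filter: {x.size} <= {3 * spec.order} samples"
        )
    if np.any(~np.isfinite(x)):
        raise ValueError("series contains non-finite samples; interpolate gaps first")
    b, a = _sig.butter(spec.order, spec.cutoff_hz, btype="low", fs=fs)
    if spec.zero_phase:
        return _sig.filtfilt(b, a, x, padtype="even", padlen=3 * spec.order)
    return _sig.lfilter(b, a, x)


def spline_resample(
    t: npt.ArrayLike, x: npt.ArrayLike, fs_out: float
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-spline a sampled series onto a uniform grid at ``fs_out``.

    The output grid is ``t[0] + k / fs_out`` for every k with
    ``t[0] + k / fs_out <= t[-1]`` (up to rounding slack), so the starting
    point is preserved exactly and the final grid point never extrapolates.
    Returns ``(t_new, x_new)``.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.ndim != 1 or t.shape != x.shape:
        raise ValueError("spline_resample expects matching 1-D t and x")
    if t.size < 4:
        raise ValueError(f"need >= 4 samples for a cubic spline, got {t.size}")
    if not fs_out > 0:
        raise ValueError(f"fs_out must be > 0, got {fs_out}")
    span = t[-1] - t[0]
    n_out = int(np.floor(span * fs_out + 1e-9)) + 1
    t_new = t[0] + np.arange(n_out) / fs_out
    spline = CubicSpline(t, x)
    return t_new, spline(t_new)
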