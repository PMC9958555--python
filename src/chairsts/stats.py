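"""Concurrent-validity statistics for chair-model vs reference angle series.

Per trial: waveform similarity (zero-lag normalised correlation, optionally
maximised over a small lag window) per phase, and absolute / percentage
errors of the phase excursions. Across trials: Fisher r-to-z averaged
correlations per condition (avoiding ceiling effects near r = 1) and the
Pearson correlation of excursions across all trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt
from scipy import stats as _st
from scipy.interpolate import CubicSpline

from .events import ExcursionPair

__all__ = [
    "TrialValidation",
    "ConditionSummary",
    "waveform_similarity",
    "fisher_mean",
    "excursion_errors",
    "across_trial_correlation",
]

_R_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class TrialValidation:
    """Similarity and error metrics for one trial (chair vs reference).

    Correlations are in [-1, 1]; excursion errors in degrees (>= 0) with the
    companion percentage taken relative to the reference excursion, or None
    when the reference excursion is zero.
    """

    r_thigh: float
    r_trunk_flexion: float
    r_trunk_extension: float
    abs_err_flexion_deg: float
    abs_err_extension_deg: float
    pct_err_flexion: float | None
    pct_err_extension: float | None

    def to_dict(self) -> dict:
        return {
            "r_thigh": self.r_thigh,
            "r_trunk_flexion": self.r_trunk_flexion,
            "r_trunk_extension": self.r_trunk_extension,
            "abs_err_flexion_deg": self.abs_err_flexion_deg,
            "abs_err_extension_deg": self.abs_err_extension_deg,
            "pct_err_flexion": self.pct_err_flexion,
            "pct_err_extension": self.pct_err_extension,
        }


@dataclass(frozen=True)
class ConditionSummary:
    """Fisher-averaged correlations and mean errors over a condition's trials."""

    condition: str
    n_trials: int
    fisher_r: dict[str, float] = field(default_factory=dict)
    mean_abs_err_deg: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("a condition summary needs at least one trial")


def _match_lengths(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spline both segments onto the shorter one's sample count.

    The two systems segment a phase by their own events, so the windows may
    differ by a few samples; resampling to a common count compares the
    phases shape-to-shape (phase-normalised) rather than clock-to-clock.
    """
    if a.size == b.size:
        return a, b
    n = min(a.size, b.size)

    def squeeze(x: np.ndarray) -> np.ndarray:
        if x.size == n:
            return x
        s = np.linspace(0.0, 1.0, x.size)
        return CubicSpline(s, x)(np.linspace(0.0, 1.0, n))

    return squeeze(a), squeeze(b)


def waveform_similarity(
    a: npt.ArrayLike,
    b: npt.ArrayLike,
    fs: float | None = None,
    max_lag_s: float = 0.0,
) -> float:
    """Normalised correlation of two phase segments.

    Default is the zero-lag coefficient on the time-aligned segments
    (mean-removed inner product over the product of standard deviations).
    With ``max_lag_s > 0`` and ``fs`` given, returns the maximum coefficient
    over integer-sample lags within +/- ``max_lag_s`` — for when the two
    systems' clocks may be slightly offset. Segments of unequal length are
    spline-resampled to the shorter length first.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("waveform_similarity expects 1-D segments")
    a, b = _match_lengths(a, b)
    if a.size < 3:
        raise ValueError("segments too short after truncation (need >= 3)")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("degenerate segment: zero variance")

    def r_at(x: np.ndarray, y: np.ndarray) -> float:
        x = x - x.mean()
        y = y - y.mean()
        return float(np.dot(x, y) / (x.size * x.std() * y.std()))

    if max_lag_s <= 0:
        return r_at(a, b)
    if fs is None:
        raise ValueError("lag-search mode needs the sampling rate fs")
    max_lag = int(round(max_lag_s * fs))
    best = -np.inf
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            x, y = a[lag:], b[: b.size - lag]
        else:
            x, y = a[: a.size + lag], b[-lag:]
        if x.size >= 3 and np.std(x) > 0 and np.std(y) > 0:
            best = max(best, r_at(x, y))
    return best


def fisher_mean(rs: npt.ArrayLike) -> float:
    """Average correlation coefficients through Fisher's r-to-z transform.

    z_i = atanh(r_i) are averaged and mapped back with tanh, which keeps the
    mean well-behaved near the +/-1 ceiling. Coefficients at or beyond the
    ceiling are clipped to +/-(1 - 1e-7) with a warning, since atanh cannot
    represent them.
    """
    rs = np.asarray(rs, dtype=float)
    if rs.size == 0:
        raise ValueError("fisher_mean of an empty list")
    if np.any(np.abs(rs) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    if np.any(np.abs(rs) >= 1):
        warnings.warn("|r| >= 1 clipped before Fisher transform", stacklevel=2)
        rs = np.clip(rs, -_R_CLIP, _R_CLIP)
    return float(np.tanh(np.mean(np.arctanh(rs))))


def excursion_errors(
    chair: ExcursionPair, ref: ExcursionPair
) -> dict[str, float | None]:
    """Absolute (degrees) and percentage errors of the chair-model excursions
    against the reference, per phase. Percentages use the reference excursion
    as denominator and are None when it is zero."""
    out: dict[str, float | None] = {}
    for phase, c, r in (
        ("flexion", chair.flexion_deg, ref.flexion_deg),
        ("extension", chair.extension_deg, ref.extension_deg),
    ):
        abs_err = abs(c - r)
        out[f"abs_err_{phase}_deg"] = abs_err
        out[f"pct_err_{phase}"] = 100.0 * abs_err / r if r > 0 else None
    return out


def across_trial_correlation(xs: npt.ArrayLike, ys: npt.ArrayLike) -> float:
    """Pearson correlation of excursions across trials (chair vs reference)."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1 or xs.size < 3:
        raise ValueError("need two equal-length 1-D arrays with >= 3 points")
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise ValueError("zero variance input")
    return float(_st.pearsonr(xs, ys).statistic)
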