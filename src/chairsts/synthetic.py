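"""Synthetic sit-to-stand trials: ground-truth trajectories, virtual laser
distances and virtual optical markers.

No public sit-to-stand dataset accompanies the chair-sensor method, so this
module is the package's test bed. It builds smooth ground-truth trunk and
thigh trajectories for seven movement conditions (normal, larger / smaller
anterior trunk tilt, slow, fast, right / left weight shift), then renders
them two ways:

* through exact ray-segment geometry into the two laser distances at 30 Hz
  (what the chair would measure), and
* into sagittal positions of the four reference markers — C7, sacrum, right
  greater trochanter, right lateral femoral condyle — at 100 Hz (what an
  optical motion-capture system would measure).

Perturbations deliberately violate the inverse model's assumptions: a
clothing-thickness offset along each beam, a posterior translation of the
knee axis ramped over the extension phase (the mechanism behind the method's
large extension-phase errors), and Gaussian sensor / marker noise.

Trajectories are minimum-jerk profiles (zero velocity and acceleration at
segment boundaries), the standard smoothness model for point-to-point human
movement. Each condition's amplitudes and durations are configurable
defaults of this package, not measured values. The trunk flexes from 0 to
the condition amplitude, extends to a small overshoot past vertical, and
settles back to upright; the thigh rises from its seated angle (5 degrees —
exactly horizontal is degenerate for the seat beam) to vertical, starting at
peak trunk flexion and completing at the end of the settle, so the thigh
reaches 90 degrees (where the seat-beam inversion degenerates) only after
the trunk's maximum extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import numpy.typing as npt

from .geometry import AngleSeries, ChairGeometry, DistanceSeries, Point2D

__all__ = [
    "ConditionPreset",
    "PerturbationSpec",
    "MarkerSeries",
    "SimulatedTrial",
    "CONDITION_PRESETS",
    "generate_trajectory",
    "forward_distance_thigh",
    "forward_distance_trunk",
    "simulate_markers",
    "angles_from_markers",
    "simulate_trial",
    "thigh_offset_for_weight_shift",
]

#: Hip-to-sacrum offset along the trunk line, mm (marker model).
SACRUM_OFFSET_MM = 100.0
#: Sacrum-to-C7 length along the trunk line, mm (marker model).
TRUNK_SEGMENT_MM = 400.0
#: Quiet sitting prepended before movement onset, s.
QUIET_SIT_S = 0.5
#: Trunk settle (extension overshoot back to upright) after the extension
#: phase, s. The thigh completes its rise over extension + settle.
SETTLE_S = 0.4
#: Fraction of the movement duration spent in the flexion phase.
FLEXION_FRACTION = 0.45
#: Seated thigh angle, degrees. Exactly 0 is degenerate for the seat beam
#: (the sensor origin lies on the thigh line, representable only as zero
#: distance); a real seated thigh reads a small positive angle, and the
#: model's valid domain starts around here.
SEATED_THIGH_DEG = 5.0
#: Per-trial uniform jitter bound on amplitude and duration.
JITTER_FRACTION = 0.05


@dataclass(frozen=True)
class ConditionPreset:
    """One movement condition: trunk amplitude/timing and thigh rise.

    ``asymmetry_gain`` skews the flexion/extension timing split to mimic the
    in-plane signature of a lateral weight shift (the sagittal model cannot
    represent the shift itself; see the methods note). Positive values
    lengthen the flexion phase.
    """

    label: str
    flexion_amplitude_deg: float
    extension_overshoot_deg: float = 5.0
    duration_s: float = 2.0
    thigh_rise_deg: float = 90.0
    asymmetry_gain: float = 0.0

    def __post_init__(self) -> None:
        if not self.flexion_amplitude_deg > 0:
            raise ValueError("flexion amplitude must be > 0")
        if not self.duration_s > 0:
            raise ValueError("duration must be > 0")


#: The seven built-in movement conditions. Amplitudes and durations are this
#: package's defaults for plausible young-adult sit-to-stand motion.
CONDITION_PRESETS: dict[str, ConditionPreset] = {
    "normal": ConditionPreset("normal", 50.0, 5.0, 2.0),
    "tilt_increase": ConditionPreset("tilt_increase", 70.0, 5.0, 2.2),
    "tilt_decrease": ConditionPreset("tilt_decrease", 30.0, 5.0, 1.8),
    "slow": ConditionPreset("slow", 50.0, 5.0, 4.0),
    "fast": ConditionPreset("fast", 50.0, 5.0, 1.0),
    "weight_shift_right": ConditionPreset(
        "weight_shift_right", 45.0, 5.0, 2.2, asymmetry_gain=0.15
    ),
    "weight_shift_left": ConditionPreset(
        "weight_shift_left", 45.0, 5.0, 2.2, asymmetry_gain=-0.15
    ),
}


@dataclass(frozen=True)
class PerturbationSpec:
    """Model-violation and noise terms applied when rendering a trial.

    surface_offset_mm
        Clothing / body-surface thickness, subtracted along each beam (the
        sensor ranges to the surface, the model assumes the skeleton line).
    knee_shift_mm
        Posterior translation of the knee axis, ramped linearly from 0 at
        peak trunk flexion to the full value at the end of the extension
        phase and held thereafter. This violates the fixed-knee assumption
        exactly where the method's extension errors arise.
    thigh_distance_offset_mm
        Constant additive offset on the seat-beam distance, the in-plane
        stand-in for a lateral weight shift moving the measured thigh
        surface toward/away from the off-centre seat sensor.
    distance_noise_sd_mm, marker_noise_sd_mm
        Gaussian measurement noise, per sample (and per marker coordinate).
    """

    surface_offset_mm: float = 0.0
    knee_shift_mm: float = 0.0
    thigh_distance_offset_mm: float = 0.0
    distance_noise_sd_mm: float = 0.0
    marker_noise_sd_mm: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.distance_noise_sd_mm < 0 or self.marker_noise_sd_mm < 0:
            raise ValueError("noise standard deviations must be >= 0")


NO_PERTURBATION = PerturbationSpec()


def thigh_offset_for_weight_shift(preset: ConditionPreset,
                                  mm_per_unit_gain: float = 100.0) -> float:
    """Additive seat-beam distance offset implied by a preset's asymmetry.

    Shifting weight toward the sensed (right) side presses the thigh toward
    the off-centre seat sensor; shifting away lifts it. Scaled linearly from
    the preset's asymmetry_gain; returns 0 for symmetric conditions.
    """
    return mm_per_unit_gain * preset.asymmetry_gain


def _minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Normalised minimum-jerk position profile on [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


@dataclass(frozen=True)
class _TrajectoryParams:
    """Jittered per-trial trajectory timing/amplitude, evaluable on any grid."""

    amplitude_deg: float
    overshoot_deg: float
    thigh_rise_deg: float
    t_onset: float          # trunk starts moving
    t_peak: float           # maximum trunk flexion
    t_max_extension: float  # maximum trunk extension (end of extension phase)
    t_end: float            # end of settle = trial end

    def trunk(self, t: np.ndarray) -> np.ndarray:
        a, b = self.amplitude_deg, self.overshoot_deg
        t0, tp, te, tz = self.t_onset, self.t_peak, self.t_max_extension, self.t_end
        out = np.zeros_like(t)
        m = (t >= t0) & (t < tp)
        out[m] = a * _minimum_jerk((t[m] - t0) / (tp - t0))
        m = (t >= tp) & (t < te)
        out[m] = a - (a + b) * _minimum_jerk((t[m] - tp) / (te - tp))
        m = (t >= te) & (t < tz)
        out[m] = -b + b * _minimum_jerk((t[m] - te) / (tz - te))
        out[t >= tz] = 0.0
        return out

    def thigh(self, t: np.ndarray) -> np.ndarray:
        tp, tz = self.t_peak, self.t_end
        out = np.full_like(t, SEATED_THIGH_DEG)
        m = t >= tp
        out[m] += (self.thigh_rise_deg - SEATED_THIGH_DEG) * _minimum_jerk(
            (t[m] - tp) / (tz - tp)
        )
        return out

    def knee_shift(self, t: np.ndarray, shift_mm: float) -> np.ndarray:
        """Posterior knee translation: linear ramp over the extension phase."""
        tp, te = self.t_peak, self.t_max_extension
        ramp = np.clip((t - tp) / (te - tp), 0.0, 1.0)
        return shift_mm * ramp


def _draw_params(
    preset: ConditionPreset, rng: np.random.Generator | None
) -> _TrajectoryParams:
    amp, dur = preset.flexion_amplitude_deg, preset.duration_s
    if rng is not None:
        amp *= 1 + rng.uniform(-JITTER_FRACTION, JITTER_FRACTION)
        dur *= 1 + rng.uniform(-JITTER_FRACTION, JITTER_FRACTION)
    frac = np.clip(FLEXION_FRACTION * (1 + preset.asymmetry_gain), 0.2, 0.8)
    t_flex = frac * dur
    return _TrajectoryParams(
        amplitude_deg=amp,
        overshoot_deg=preset.extension_overshoot_deg,
        thigh_rise_deg=preset.thigh_rise_deg,
        t_onset=QUIET_SIT_S,
        t_peak=QUIET_SIT_S + t_flex,
        t_max_extension=QUIET_SIT_S + dur,
        t_end=QUIET_SIT_S + dur + SETTLE_S,
    )


def _grid(t_end: float, fs: float) -> np.ndarray:
    return np.arange(int(np.floor(t_end * fs + 1e-9)) + 1) / fs


def generate_trajectory(
    preset: ConditionPreset | str,
    fs: float = 30.0,
    seed: int | None = None,
) -> AngleSeries:
    """Ground-truth trunk/thigh angle series for one condition.

    0.5 s of quiet sitting, a minimum-jerk trunk flexion to the condition
    amplitude, extension to a small overshoot, and a settle back to upright;
    the thigh rises from its 5 degree seated angle to 90 degrees between
    peak trunk flexion and the end of the settle. A seed draws the per-trial +/-5 % amplitude and duration jitter;
    ``seed=None`` gives the nominal trajectory.
    """
    if isinstance(preset, str):
        preset = CONDITION_PRESETS[preset]
    if fs < 30:
        raise ValueError(f"fs must be >= 30 Hz, got {fs}")
    rng = None if seed is None else np.random.default_rng(seed)
    p = _draw_params(preset, rng)
    t = _grid(p.t_end, fs)
    return AngleSeries(t, p.trunk(t), p.thigh(t), source="ground-truth", fs=fs)


# ---------------------------------------------------------------------------
# Forward ray-cast rendering
# ---------------------------------------------------------------------------

def _cross(ax, ay, bx, by):
    return ax * by - ay * bx


def _ray_cast_thigh(
    theta_thigh_deg: np.ndarray,
    geom: ChairGeometry,
    knee_shift_mm: np.ndarray | float = 0.0,
    body_thigh_mm: float | None = None,
) -> np.ndarray:
    """Distance from the seat sensor to the thigh segment, mm (NaN = miss).

    The thigh is the segment from the (possibly posteriorly shifted) knee to
    the hip; the beam leaves S1 at (l_s1 + l_offset, 0) along
    (-cos phi_s1, +sin phi_s1).
    """
    th = np.radians(np.asarray(theta_thigh_deg, dtype=float))
    l_body = geom.l_thigh if body_thigh_mm is None else body_thigh_mm
    k = np.broadcast_to(np.asarray(knee_shift_mm, dtype=float), th.shape)
    p0 = geom.s1_origin
    ux, uy = geom.s1_direction
    vx, vy = np.cos(th), np.sin(th)
    wx, wy = k - p0.x, -p0.y
    det = _cross(ux, uy, vx, vy)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = _cross(wx, wy, vx, vy) / det
        tt = _cross(wx, wy, ux, uy) / det
    miss = (np.abs(det) < 1e-12) | (s <= 0) | (tt < 0) | (tt > l_body)
    return np.where(miss, np.nan, s)


def _ray_cast_trunk(
    theta_trunk_deg: np.ndarray,
    theta_thigh_deg: np.ndarray,
    geom: ChairGeometry,
    knee_shift_mm: np.ndarray | float = 0.0,
    body_thigh_mm: float | None = None,
) -> np.ndarray:
    """Distance from the backrest sensor to the trunk line, mm (NaN = miss).

    The trunk is a half-line from the hip along (-sin theta, +cos theta):
    the model assumes the beam always meets the trunk axis, so no upper
    endpoint is enforced (a literal C7 cutoff would lose the beam at deep
    flexion, which the inverse model cannot represent).
    """
    tr = np.radians(np.asarray(theta_trunk_deg, dtype=float))
    th = np.radians(np.asarray(theta_thigh_deg, dtype=float))
    l_body = geom.l_thigh if body_thigh_mm is None else body_thigh_mm
    k = np.broadcast_to(np.asarray(knee_shift_mm, dtype=float), tr.shape)
    hx = k + l_body * np.cos(th)
    hy = l_body * np.sin(th)
    p0 = geom.s2_origin
    ux, uy = geom.s2_direction
    vx, vy = -np.sin(tr), np.cos(tr)
    wx, wy = hx - p0.x, hy - p0.y
    det = _cross(ux, uy, vx, vy)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = _cross(wx, wy, vx, vy) / det
        tt = _cross(wx, wy, ux, uy) / det
    miss = (np.abs(det) < 1e-12) | (s <= 0) | (tt < -1e-9)
    return np.where(miss, np.nan, s)


def forward_distance_thigh(
    theta_thigh: float | npt.ArrayLike,
    geom: ChairGeometry = ChairGeometry(),
    perturb: PerturbationSpec = NO_PERTURBATION,
    *,
    knee_shift_mm: npt.ArrayLike | None = None,
    body_thigh_mm: float | None = None,
    rng: np.random.Generator | None = None,
) -> float | np.ndarray:
    """Seat-beam distance a perfect ToF sensor would report for a thigh angle.

    With all perturbations zero this is the exact inverse of the seat-beam
    angle conversion. ``knee_shift_mm`` overrides the perturbation's scalar
    shift with a per-sample ramp when rendering a full trial. Scalar input with no
    beam-thigh intersection raises; array input yields NaN there.
    """
    scalar = np.isscalar(theta_thigh) or np.ndim(theta_thigh) == 0
    th = np.atleast_1d(np.asarray(theta_thigh, dtype=float))
    shift = perturb.knee_shift_mm if knee_shift_mm is None else knee_shift_mm
    d = _ray_cast_thigh(th, geom, shift, body_thigh_mm)
    d = d - perturb.surface_offset_mm + perturb.thigh_distance_offset_mm
    if perturb.distance_noise_sd_mm > 0:
        if rng is None:
            rng = np.random.default_rng(perturb.seed)
        d = d + rng.normal(0.0, perturb.distance_noise_sd_mm, d.shape)
    if scalar:
        if np.isnan(d[0]):
            raise ValueError("seat beam does not intersect the thigh segment")
        return float(d[0])
    return d


def forward_distance_trunk(
    theta_trunk: float | npt.ArrayLike,
    theta_thigh: float | npt.ArrayLike,
    geom: ChairGeometry = ChairGeometry(),
    perturb: PerturbationSpec = NO_PERTURBATION,
    *,
    knee_shift_mm: npt.ArrayLike | None = None,
    body_thigh_mm: float | None = None,
    rng: np.random.Generator | None = None,
) -> float | np.ndarray:
    """Backrest-beam distance for a trunk angle at a given thigh posture.

    The knee shift translates the whole two-link origin posteriorly before
    intersection, so the rendered distance reflects a body standing behind
    where the inverse model assumes it is.
    """
    scalar = np.isscalar(theta_trunk) or np.ndim(theta_trunk) == 0
    tr = np.atleast_1d(np.asarray(theta_trunk, dtype=float))
    th = np.broadcast_to(
        np.atleast_1d(np.asarray(theta_thigh, dtype=float)), tr.shape
    )
    shift = perturb.knee_shift_mm if knee_shift_mm is None else knee_shift_mm
    d = _ray_cast_trunk(tr, th, geom, shift, body_thigh_mm)
    d = d - perturb.surface_offset_mm
    if perturb.distance_noise_sd_mm > 0:
        if rng is None:
            rng = np.random.default_rng(perturb.seed)
        d = d + rng.normal(0.0, perturb.distance_noise_sd_mm, d.shape)
    if scalar:
        if np.isnan(d[0]):
            raise ValueError("backrest beam does not intersect the trunk line")
        return float(d[0])
    return d


# ---------------------------------------------------------------------------
# Virtual markers
# ---------------------------------------------------------------------------

@dataclass
class MarkerSeries:
    """Sagittal (x, y) trajectories, mm, of the four reference landmarks:
    C7 spinous process, sacrum, right greater trochanter, right lateral
    femoral condyle. Arrays are (n, 2); frame as in :mod:`chairsts.geometry`."""

    t: np.ndarray
    c7: np.ndarray
    sacrum: np.ndarray
    greater_trochanter: np.ndarray
    lateral_femoral_condyle: np.ndarray
    fs: float = 100.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        n = self.t.size
        for name in ("c7", "sacrum", "greater_trochanter", "lateral_femoral_condyle"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n, 2):
                raise ValueError(f"MarkerSeries: {name} must have shape ({n}, 2)")
            setattr(self, name, arr)

    def __len__(self) -> int:
        return self.t.size


def simulate_markers(
    truth: AngleSeries,
    geom: ChairGeometry = ChairGeometry(),
    perturb: PerturbationSpec = NO_PERTURBATION,
    *,
    body_thigh_mm: float | None = None,
    rng: np.random.Generator | None = None,
) -> MarkerSeries:
    """Render ground-truth angles into the four marker trajectories.

    The condyle marker sits on the knee axis (and follows its posterior
    shift, since markers track the real body); the trochanter on the hip;
    the sacrum 100 mm up the trunk line from the hip; C7 a further 400 mm.
    Gaussian noise is added independently per coordinate. The knee-shift
    ramp is reconstructed from the truth series' own flexion peak and
    post-peak extension minimum.
    """
    if truth.fs < 100:
        raise ValueError("marker simulation expects truth sampled at >= 100 Hz")
    tr = np.radians(truth.theta_trunk)
    th = np.radians(truth.theta_thigh)
    l_body = geom.l_thigh if body_thigh_mm is None else body_thigh_mm

    if perturb.knee_shift_mm != 0.0:
        i_peak = int(np.nanargmax(truth.theta_trunk))
        i_ext = i_peak + int(np.nanargmin(truth.theta_trunk[i_peak:]))
        ramp = np.clip(
            (truth.t - truth.t[i_peak])
            / max(truth.t[i_ext] - truth.t[i_peak], 1e-9),
            0.0, 1.0,
        )
        shift = perturb.knee_shift_mm * ramp
    else:
        shift = np.zeros_like(truth.t)

    knee = np.column_stack([shift, np.zeros_like(shift)])
    hip = knee + l_body * np.column_stack([np.cos(th), np.sin(th)])
    trunk_dir = np.column_stack([-np.sin(tr), np.cos(tr)])
    sacrum = hip + SACRUM_OFFSET_MM * trunk_dir
    c7 = sacrum + TRUNK_SEGMENT_MM * trunk_dir

    markers = {"c7": c7, "sacrum": sacrum,
               "greater_trochanter": hip, "lateral_femoral_condyle": knee}
    if perturb.marker_noise_sd_mm > 0:
        if rng is None:
            rng = np.random.default_rng(perturb.seed)
        for name in markers:
            markers[name] = markers[name] + rng.normal(
                0.0, perturb.marker_noise_sd_mm, markers[name].shape
            )
    return MarkerSeries(truth.t, markers["c7"], markers["sacrum"],
                        markers["greater_trochanter"],
                        markers["lateral_femoral_condyle"], fs=truth.fs)


def angles_from_markers(markers: MarkerSeries) -> AngleSeries:
    """Marker-based segment angles: trunk from the C7-sacrum line against
    vertical (forward lean positive), thigh from the trochanter-condyle line
    against horizontal. Frames with coincident markers come out invalid."""
    dtrunk = markers.c7 - markers.sacrum
    dthigh = markers.greater_trochanter - markers.lateral_femoral_condyle
    ok = (np.hypot(dtrunk[:, 0], dtrunk[:, 1]) > 1e-9) & (
        np.hypot(dthigh[:, 0], dthigh[:, 1]) > 1e-9
    )
    with np.errstate(invalid="ignore"):
        theta_trunk = np.degrees(np.arctan2(-dtrunk[:, 0], dtrunk[:, 1]))
        theta_thigh = np.degrees(np.arctan2(dthigh[:, 1], dthigh[:, 0]))
    theta_trunk[~ok] = np.nan
    theta_thigh[~ok] = np.nan
    return AngleSeries(markers.t, theta_trunk, theta_thigh,
                       source="marker-based", valid=ok, fs=markers.fs)


# ---------------------------------------------------------------------------
# Full trial bundle
# ---------------------------------------------------------------------------

@dataclass
class SimulatedTrial:
    """Everything one virtual trial produces, plus its ground truth.

    ``events`` records the programmed motion-onset, peak-flexion and
    maximum-extension times (s) and their 30 Hz sample indices, and the true
    phase excursions (amplitude and amplitude + overshoot).
    """

    distances: DistanceSeries
    markers: MarkerSeries
    truth: AngleSeries
    events: dict
    preset: ConditionPreset
    perturb: PerturbationSpec
    seed: int | None
    trajectory_seed: int | None


def simulate_trial(
    preset: ConditionPreset | str,
    geom: ChairGeometry = ChairGeometry(),
    perturb: PerturbationSpec = NO_PERTURBATION,
    seed: int | None = None,
    *,
    trajectory_seed: int | None = None,
    body_thigh_mm: float | None = None,
    distance_fs: float = 30.0,
    marker_fs: float = 100.0,
) -> SimulatedTrial:
    """Simulate one trial end to end, fully reproducible from its seeds.

    ``seed`` drives the measurement noise streams only; ``trajectory_seed``
    (default None = nominal trajectory) drives the per-trial amplitude and
    duration jitter. Keeping them separate lets different noise realisations
    share an identical noiseless core.
    """
    if isinstance(preset, str):
        preset = CONDITION_PRESETS[preset]
    traj_rng = None if trajectory_seed is None else np.random.default_rng(
        trajectory_seed
    )
    p = _draw_params(preset, traj_rng)

    t30 = _grid(p.t_end, distance_fs)
    t100 = _grid(p.t_end, marker_fs)
    tr30, th30 = p.trunk(t30), p.thigh(t30)
    tr100, th100 = p.trunk(t100), p.thigh(t100)

    noise_rng = np.random.default_rng(seed if seed is not None else perturb.seed)
    shift30 = p.knee_shift(t30, perturb.knee_shift_mm)
    d_thigh = forward_distance_thigh(
        th30, geom, perturb, knee_shift_mm=shift30,
        body_thigh_mm=body_thigh_mm, rng=noise_rng,
    )
    d_trunk = forward_distance_trunk(
        tr30, th30, geom, perturb, knee_shift_mm=shift30,
        body_thigh_mm=body_thigh_mm, rng=noise_rng,
    )
    valid = np.isfinite(d_thigh) & np.isfinite(d_trunk)
    distances = DistanceSeries(
        t30, np.where(valid, d_thigh, np.nan), np.where(valid, d_trunk, np.nan),
        valid, fs=distance_fs,
    )

    truth100 = AngleSeries(t100, tr100, th100, source="ground-truth", fs=marker_fs)
    markers = simulate_markers(truth100, geom, perturb,
                               body_thigh_mm=body_thigh_mm, rng=noise_rng)

    truth30 = AngleSeries(t30, tr30, th30, source="ground-truth", fs=distance_fs)
    events = {
        "t_onset": p.t_onset,
        "t_peak_flexion": p.t_peak,
        "t_max_extension": p.t_max_extension,
        "onset_idx": int(round(p.t_onset * distance_fs)),
        "peak_flexion_idx": int(round(p.t_peak * distance_fs)),
        "max_extension_idx": int(round(p.t_max_extension * distance_fs)),
        "true_flexion_excursion_deg": p.amplitude_deg,
        "true_extension_excursion_deg": p.amplitude_deg + p.overshoot_deg,
    }
    return SimulatedTrial(distances, markers, truth30, events,
                          preset, perturb, seed, trajectory_seed)
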