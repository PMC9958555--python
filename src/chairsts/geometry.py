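"""Two-link inverse geometry: range-sensor distances to segment angles.

The chair carries two time-of-flight range finders: one in the seat aimed
up-and-forward at the thigh, one in the backrest aimed forward at the trunk.
A planar two-link model (thigh link rotating about a fixed knee centre, trunk
link rotating about the hip) converts the two measured distances into the
thigh angle (from horizontal) and the trunk angle (from vertical,
flexion-positive).

Coordinate frame
----------------
Origin at the knee centre; x positive toward the backrest (posterior),
y positive upward from the seat plane. The backrest plane is at
``x = L_seat``, the seat plane at ``y = 0``. The seat sensor S1 sits at
``(L_s1 + L_offset, 0)`` with beam direction ``(-cos phi_s1, +sin phi_s1)``;
the backrest sensor S2 sits at ``(L_seat, L_s2)`` with beam direction
``(-sin phi_s2, -cos phi_s2)``. This is the unique frame in which the three
closed-form conversions below are literal identities of the ray-cast forward
model (see :mod:`chairsts.synthetic`).

Angles are degrees at every interface and radians internally. The arctangent
form is deliberately plain ``atan`` (not ``atan2``): the model has no meaning
once its denominator is non-positive (the beam has passed the knee plane, or
the trunk hit point has fallen to hip height), so such samples are flagged
invalid instead of being wrapped to another quadrant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import numpy.typing as npt

__all__ = [
    "ChairGeometry",
    "Point2D",
    "DistanceSeries",
    "AngleSeries",
    "thigh_angle_from_distance",
    "hip_position",
    "trunk_angle_from_distance",
    "angles_from_distances",
]

AngleSource = Literal["chair-model", "marker-based", "ground-truth"]

#: Thigh-length presets, mm. 403 mm is the 50th percentile of young Japanese
#: adults (the recommended portable default); 446 mm matches taller users.
THIGH_LENGTH_P50_MM = 403.0
THIGH_LENGTH_TALL_MM = 446.0


@dataclass(frozen=True)
class ChairGeometry:
    """Fixed lengths and installation angles of the chair-sensor model.

    Parameters
    ----------
    phi_s1 : float
        Seat-sensor installation angle, degrees from the seat plane.
    l_s1 : float
        Seat sensor to seat edge, mm.
    l_offset : float
        Seat edge to knee centre, measured along the seat plane, mm.
    phi_s2 : float
        Backrest-sensor installation angle, degrees from the backrest plane.
    l_seat : float
        Seat depth (knee centre to backrest plane), mm.
    l_s2 : float
        Backrest sensor height above the seat plane, mm.
    l_thigh : float
        Model thigh length (knee centre to hip), mm. The model is meant to
        run without per-user anthropometry, so this is a preset, not a
        measurement; 403 mm adapts well across young adults.
    seat_height : float
        Seat height above the floor, mm. Metadata only; no equation uses it.
    sensor_max_range : float
        Distances beyond this are flagged invalid, mm (ToF-class ceiling).
    """

    phi_s1: float = 63.5
    l_s1: float = 130.0
    l_offset: float = 50.0
    phi_s2: float = 90.0
    l_seat: float = 550.0
    l_s2: float = 465.0
    l_thigh: float = THIGH_LENGTH_P50_MM
    seat_height: float = 400.0
    sensor_max_range: float = 2000.0

    def __post_init__(self) -> None:
        for name in ("l_s1", "l_offset", "l_seat", "l_s2", "l_thigh",
                     "seat_height", "sensor_max_range"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0 < self.phi_s1 < 180:
            raise ValueError(f"phi_s1 must be in (0, 180), got {self.phi_s1}")
        if not 0 < self.phi_s2 <= 180:
            raise ValueError(f"phi_s2 must be in (0, 180], got {self.phi_s2}")

    def with_thigh_length(self, l_thigh: float) -> "ChairGeometry":
        """Same chair, different thigh-length preset."""
        return replace(self, l_thigh=l_thigh)

    # -- sensor placement in the knee-origin frame -------------------------
    @property
    def s1_origin(self) -> "Point2D":
        return Point2D(self.l_s1 + self.l_offset, 0.0)

    @property
    def s1_direction(self) -> tuple[float, float]:
        a = np.radians(self.phi_s1)
        return (-float(np.cos(a)), float(np.sin(a)))

    @property
    def s2_origin(self) -> "Point2D":
        return Point2D(self.l_seat, self.l_s2)

    @property
    def s2_direction(self) -> tuple[float, float]:
        a = np.radians(self.phi_s2)
        return (-float(np.sin(a)), -float(np.cos(a)))


@dataclass(frozen=True)
class Point2D:
    """Sagittal-plane point, mm: x posterior-positive from the knee centre,
    y upward-positive from the seat plane."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"Point2D must be finite, got ({self.x}, {self.y})")


def _as_time_axis(t: npt.ArrayLike, fs: float, what: str) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError(f"{what}: time axis must be a non-empty 1-D array")
    if t.size > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError(f"{what}: time axis must be strictly increasing")
        if not np.allclose(dt, 1.0 / fs, rtol=1e-6, atol=1e-9):
            raise ValueError(f"{what}: time axis must be uniform at 1/fs = {1.0 / fs}")
    return t


@dataclass
class DistanceSeries:
    """Timestamped range-sensor samples: seat-to-thigh and backrest-to-trunk
    distances in mm, with a per-sample validity flag."""

    t: np.ndarray
    d_thigh: np.ndarray
    d_trunk: np.ndarray
    valid: np.ndarray | None = None
    fs: float = 30.0

    def __post_init__(self) -> None:
        self.t = _as_time_axis(self.t, self.fs, "DistanceSeries")
        self.d_thigh = np.asarray(self.d_thigh, dtype=float)
        self.d_trunk = np.asarray(self.d_trunk, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.t.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        n = self.t.size
        for name in ("d_thigh", "d_trunk", "valid"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"DistanceSeries: {name} length mismatch")

    def __len__(self) -> int:
        return self.t.size

    def flag_out_of_range(self, geom: ChairGeometry) -> "DistanceSeries":
        """Return a copy with samples outside (0, sensor_max_range] invalidated."""
        ok = (
            (self.d_thigh > 0) & (self.d_thigh <= geom.sensor_max_range)
            & (self.d_trunk > 0) & (self.d_trunk <= geom.sensor_max_range)
            & np.isfinite(self.d_thigh) & np.isfinite(self.d_trunk)
        )
        return DistanceSeries(self.t, self.d_thigh, self.d_trunk,
                              self.valid & ok, self.fs)


@dataclass
class AngleSeries:
    """Timestamped trunk and thigh segment angles, degrees.

    ``theta_trunk`` is measured from vertical, flexion (forward lean)
    positive; ``theta_thigh`` from horizontal (0 = seated, 90 = standing).
    ``source`` records provenance: chair-model, marker-based or ground-truth.
    Invalid samples hold NaN angles.
    """

    t: np.ndarray
    theta_trunk: np.ndarray
    theta_thigh: np.ndarray
    source: AngleSource = "ground-truth"
    valid: np.ndarray | None = None
    fs: float = 30.0

    def __post_init__(self) -> None:
        self.t = _as_time_axis(self.t, self.fs, "AngleSeries")
        self.theta_trunk = np.asarray(self.theta_trunk, dtype=float)
        self.theta_thigh = np.asarray(self.theta_thigh, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.theta_trunk) & np.isfinite(self.theta_thigh)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        n = self.t.size
        for name in ("theta_trunk", "theta_thigh", "valid"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"AngleSeries: {name} length mismatch")

    def __len__(self) -> int:
        return self.t.size


def thigh_angle_from_distance(
    d_thigh: float | npt.ArrayLike, geom: ChairGeometry
) -> float | np.ndarray:
    """Thigh angle (degrees from horizontal) from the seat-to-thigh distance.

    theta = atan( d * sin(phi_s1) / ((l_s1 + l_offset) - d * cos(phi_s1)) )

    Scalar input with a non-positive distance or non-positive denominator
    (the beam has crossed the knee plane) raises ``ValueError``; array input
    returns NaN at such samples so the caller can flag them invalid.
    """
    scalar = np.isscalar(d_thigh) or np.ndim(d_thigh) == 0
    d = np.atleast_1d(np.asarray(d_thigh, dtype=float))
    a = np.radians(geom.phi_s1)
    num = d * np.sin(a)
    den = (geom.l_s1 + geom.l_offset) - d * np.cos(a)
    bad = (d <= 0) | (den <= 0) | ~np.isfinite(d)
    if scalar and bad[0]:
        if d[0] <= 0:
            raise ValueError(f"d_thigh must be > 0, got {d[0]}")
        raise ValueError(
            "thigh model denominator non-positive: beam beyond the knee plane"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.degrees(np.arctan(num / den))
    theta[bad] = np.nan
    return float(theta[0]) if scalar else theta


def hip_position(theta_thigh: float, geom: ChairGeometry) -> Point2D:
    """Hip-joint position (mm, knee-origin frame) for a thigh angle in degrees."""
    if not -90 < theta_thigh < 90:
        raise ValueError(f"theta_thigh must be in (-90, 90), got {theta_thigh}")
    a = np.radians(theta_thigh)
    return Point2D(geom.l_thigh * float(np.cos(a)), geom.l_thigh * float(np.sin(a)))


def trunk_angle_from_distance(
    d_trunk: float | npt.ArrayLike,
    hip: Point2D | tuple[npt.ArrayLike, npt.ArrayLike],
    geom: ChairGeometry,
) -> float | np.ndarray:
    """Trunk angle (degrees from vertical, flexion-positive) from the
    backrest-to-trunk distance and the current hip position.

    theta = atan( (d * sin(phi_s2) - (l_seat - x_hip))
                  / (l_s2 - d * cos(phi_s2) - y_hip) )

    A non-positive denominator means the trunk hit point lies at or below hip
    height; scalar input raises, array input yields NaN.
    """
    scalar = np.isscalar(d_trunk) or np.ndim(d_trunk) == 0
    d = np.atleast_1d(np.asarray(d_trunk, dtype=float))
    if isinstance(hip, Point2D):
        x_hip, y_hip = np.full_like(d, hip.x), np.full_like(d, hip.y)
    else:
        x_hip = np.broadcast_to(np.asarray(hip[0], dtype=float), d.shape).copy()
        y_hip = np.broadcast_to(np.asarray(hip[1], dtype=float), d.shape).copy()
    a = np.radians(geom.phi_s2)
    num = d * np.sin(a) - (geom.l_seat - x_hip)
    den = geom.l_s2 - d * np.cos(a) - y_hip
    bad = (d <= 0) | (den <= 0) | ~np.isfinite(d) | ~np.isfinite(num)
    if scalar and bad[0]:
        if d[0] <= 0:
            raise ValueError(f"d_trunk must be > 0, got {d[0]}")
        raise ValueError(
            "trunk model denominator non-positive: hit point at or below hip height"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.degrees(np.arctan(num / den))
    theta[bad] = np.nan
    return float(theta[0]) if scalar else theta


def angles_from_distances(series: DistanceSeries, geom: ChairGeometry) -> AngleSeries:
    """Vectorised composition of the three conversions over a distance series.

    Per sample: thigh angle first, hip position second, trunk angle third.
    Samples that are already invalid, out of sensor range, or that hit a
    degenerate denominator come out flagged invalid with NaN angles.
    """
    if len(series) == 0:
        raise ValueError("angles_from_distances: empty series")
    series = series.flag_out_of_range(geom)
    theta_thigh = thigh_angle_from_distance(series.d_thigh, geom)
    a = np.radians(theta_thigh)
    with np.errstate(invalid="ignore"):
        x_hip = geom.l_thigh * np.cos(a)
        y_hip = geom.l_thigh * np.sin(a)
    theta_trunk = trunk_angle_from_distance(series.d_trunk, (x_hip, y_hip), geom)
    valid = series.valid & np.isfinite(theta_thigh) & np.isfinite(theta_trunk)
    theta_thigh = np.where(valid, theta_thigh, np.nan)
    theta_trunk = np.where(valid, theta_trunk, np.nan)
    return AngleSeries(series.t, theta_trunk, theta_thigh,
                       source="chair-model", valid=valid, fs=series.fs)
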