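"""Room-frame coordinate conventions, target-matrix geometry and circular angle arithmetic.

The room frame is right-handed with its origin on the rotation axis of the
swivel chair at eye height: +x points from the chair toward the center of the
target wall, +y toward the seated participant's left, +z up.  With this
convention the azimuth is the signed horizontal angle from straight ahead
(positive toward the participant's left) and is exactly the plane of the
passive whole-body yaw rotations; the polar angle is the elevation above the
horizontal plane.  All public interfaces use degrees; radians appear only
inside trigonometric calls.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Direction3",
    "SphericalAngles",
    "TargetGrid",
    "InvalidDirectionError",
    "UnknownTargetError",
    "to_spherical",
    "from_spherical",
    "angular_diff",
    "circular_mean_deg",
    "target_true_angles",
    "ROWS",
    "COLS",
    "TARGET_LABELS",
]

ROWS = ("top", "center", "bottom")
COLS = ("left", "center", "right")
#: The nine (row, column) labels of the 3 x 3 target matrix, row-major.
TARGET_LABELS = tuple(itertools.product(ROWS, COLS))


class InvalidDirectionError(ValueError):
    """A pointing direction could not be normalized (zero or non-finite input)."""


class UnknownTargetError(KeyError):
    """A target label is not one of the nine grid positions."""


@dataclass(frozen=True)
class Direction3:
    """Unit pointing direction in the room frame.

    The constructor normalizes any nonzero finite input, so downstream code
    can rely on ``x**2 + y**2 + z**2 == 1`` to within 1e-9.
    """

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        v = (float(self.x), float(self.y), float(self.z))
        if not all(math.isfinite(c) for c in v):
            raise InvalidDirectionError(f"non-finite direction components {v}")
        n = math.sqrt(v[0] * v[0] + v[1] * v[1] + v[2] * v[2])
        if n == 0.0:
            raise InvalidDirectionError("zero-length direction vector")
        object.__setattr__(self, "x", v[0] / n)
        object.__setattr__(self, "y", v[1] / n)
        object.__setattr__(self, "z", v[2] / n)

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class SphericalAngles:
    """Azimuth/polar pair in degrees.

    azimuth lies in (-180, 180], positive toward the participant's left;
    polar lies in [-90, 90], positive upward.  Straight ahead is (0, 0).
    """

    azimuth: float
    polar: float

    def __post_init__(self) -> None:
        if not (-180.0 < self.azimuth <= 180.0 + 1e-12):
            raise ValueError(f"azimuth {self.azimuth} outside (-180, 180]")
        if not (-90.0 - 1e-12 <= self.polar <= 90.0 + 1e-12):
            raise ValueError(f"polar {self.polar} outside [-90, 90]")


def to_spherical(v: Direction3) -> SphericalAngles:
    """Convert a room-frame unit vector to azimuth/polar angles in degrees.

    At the poles (|z| = 1) the azimuth is degenerate and reported as 0.
    """
    if abs(v.z) >= 1.0 - 1e-15:
        return SphericalAngles(0.0, math.copysign(90.0, v.z))
    az = math.degrees(math.atan2(v.y, v.x))
    pol = math.degrees(math.asin(max(-1.0, min(1.0, v.z))))
    if az <= -180.0:
        az += 360.0
    return SphericalAngles(az, pol)


def from_spherical(angles: SphericalAngles) -> Direction3:
    """Inverse of :func:`to_spherical`."""
    az = math.radians(angles.azimuth)
    pol = math.radians(angles.polar)
    c = math.cos(pol)
    return Direction3(c * math.cos(az), c * math.sin(az), math.sin(pol))


def angular_diff(a: float, b: float) -> float:
    """Signed difference ``a - b`` wrapped into (-180, 180] degrees.

    This is the deviation metric used throughout scoring; wrapping matters
    only for responses near the +/-180 branch cut but keeps the arithmetic
    exact there.
    """
    d = (float(a) - float(b)) % 360.0
    if d > 180.0:
        d -= 360.0
    return d


def circular_mean_deg(angles) -> float:
    """Circular mean of angles in degrees, result in (-180, 180].

    Raises ValueError when the resultant vector length vanishes (the mean is
    undefined, e.g. two diametrically opposed angles).
    """
    a = np.radians(np.asarray(angles, dtype=float))
    s, c = np.sin(a).mean(), np.cos(a).mean()
    if math.hypot(s, c) < 1e-12:
        raise ValueError("circular mean undefined: zero resultant length")
    m = math.degrees(math.atan2(s, c))
    if m <= -180.0:
        m += 360.0
    return m


@dataclass(frozen=True)
class TargetGrid:
    """Geometry of the 3 x 3 wall-target matrix.

    The participant sits at ``wall_distance`` cm from the wall with eye level
    aligned with the center row, so the (center, center) target is exactly
    straight ahead.  The default spacing of 51.4 cm puts the off-center
    columns/rows at ~15 degrees, typical for this task family; the physical
    spacing is configurable because only the simulator depends on it (scores
    are deviations, not absolute angles).
    """

    wall_distance: float = 192.0
    horizontal_spacing: float = 51.4
    vertical_spacing: float = 51.4
    labels: tuple = field(default=TARGET_LABELS)

    def __post_init__(self) -> None:
        if self.wall_distance <= 0 or self.horizontal_spacing <= 0 or self.vertical_spacing <= 0:
            raise ValueError("grid dimensions must be positive")
        if tuple(self.labels) != TARGET_LABELS:
            raise ValueError("grid must carry exactly the nine canonical row/column labels")


_COL_SIGN = {"left": +1.0, "center": 0.0, "right": -1.0}  # +y is the participant's left
_ROW_SIGN = {"top": +1.0, "center": 0.0, "bottom": -1.0}


def target_true_angles(grid: TargetGrid, label) -> SphericalAngles:
    """True azimuth/polar of the eye-to-target line for one grid label.

    Left column and top row are positive (toward +y and +z respectively).
    """
    row, col = label
    if (row, col) not in TARGET_LABELS:
        raise UnknownTargetError(f"unknown target label {label!r}")
    x = grid.wall_distance
    y = _COL_SIGN[col] * grid.horizontal_spacing
    z = _ROW_SIGN[row] * grid.vertical_spacing
    return to_spherical(Direction3(x, y, z))
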