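"""Coordinate conventions, plate and marker-block geometry, and homogeneous
transform algebra.

The world frame is the CT couch coordinate system at simulation: X lateral,
Y longitudinal (couch travel), Z vertical, origin at the scanner isocenter.
All internal lengths are millimetres; reporting layers convert to
centimetres where the clinical tables use them.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Point3",
    "HomTransform",
    "CalibrationPlate",
    "MarkerBlock",
    "BlockPlacement",
    "SingularTransformError",
    "plate_point_coords",
    "compose",
    "invert",
    "apply",
    "PLATE_ROW_SPACING_MM",
    "PLATE_COL_SPACING_MM",
    "DEFAULT_PLATE",
    "DEFAULT_BLOCK",
]

PLATE_ROW_SPACING_MM = 150.0
PLATE_COL_SPACING_MM = 100.0


class SingularTransformError(ValueError):
    """Raised when a transform (or a fit's coefficient matrix) is singular."""


@dataclasses.dataclass(frozen=True)
class Point3:
    """A point in the world or camera-view frame, millimetres.

    Axes follow the IEC-style couch convention: ``x`` lateral, ``y``
    longitudinal, ``z`` vertical.
    """

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError(f"non-finite point components: {self}")

    def to_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, a: Iterable[float]) -> "Point3":
        x, y, z = np.asarray(a, dtype=float).reshape(3)
        return cls(float(x), float(y), float(z))

    def distance_to(self, other: "Point3") -> float:
        return float(np.linalg.norm(self.to_array() - other.to_array()))


class HomTransform:
    """A 4x4 homogeneous transform acting on column vectors [x, y, z, 1]^T.

    In affine mode (the default, and the only mode produced by this package)
    the bottom row is exactly [0, 0, 0, 1] and the upper-left 3x3 linear
    part is invertible.
    """

    def __init__(
        self, m: np.ndarray, *, require_affine: bool = True, require_invertible: bool = True
    ) -> None:
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"expected 4x4 matrix, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("transform matrix contains non-finite entries")
        if require_affine and not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=1e-12):
            raise ValueError("bottom row must be [0,0,0,1] in affine mode")
        # require_invertible=False admits degenerate estimates (flagged
        # minimum-norm fits); invert() still refuses them.
        if require_invertible and abs(np.linalg.det(m[:3, :3])) < 1e-12:
            raise SingularTransformError("3x3 linear part is singular")
        self.m = m

    # -- constructors -------------------------------------------------------

    @classmethod
    def identity(cls) -> "HomTransform":
        return cls(np.eye(4))

    @classmethod
    def from_parts(cls, linear: np.ndarray, translation: Iterable[float]) -> "HomTransform":
        m = np.eye(4)
        m[:3, :3] = np.asarray(linear, dtype=float)
        m[:3, 3] = np.asarray(translation, dtype=float).reshape(3)
        return cls(m)

    @classmethod
    def translation(cls, tx: float, ty: float, tz: float) -> "HomTransform":
        return cls.from_parts(np.eye(3), (tx, ty, tz))

    @classmethod
    def rotation(cls, axis: str, angle_rad: float) -> "HomTransform":
        """Rotation about a world axis ('x', 'y' or 'z') through the origin."""
        c, s = math.cos(angle_rad), math.sin(angle_rad)
        if axis == "x":
            r = [[1, 0, 0], [0, c, -s], [0, s, c]]
        elif axis == "y":
            r = [[c, 0, s], [0, 1, 0], [-s, 0, c]]
        elif axis == "z":
            r = [[c, -s, 0], [s, c, 0], [0, 0, 1]]
        else:
            raise ValueError(f"unknown axis {axis!r}")
        return cls.from_parts(np.array(r, dtype=float), (0.0, 0.0, 0.0))

    # -- algebra ------------------------------------------------------------

    @property
    def linear(self) -> np.ndarray:
        """The upper-left 3x3 linear part."""
        return self.m[:3, :3]

    @property
    def translation_vector(self) -> np.ndarray:
        return self.m[:3, 3]

    def compose(self, other: "HomTransform") -> "HomTransform":
        """Return self ∘ other (apply ``other`` first)."""
        return HomTransform(self.m @ other.m)

    def invert(self) -> "HomTransform":
        if abs(np.linalg.det(self.m[:3, :3])) < 1e-12:
            raise SingularTransformError("transform is not invertible")
        try:
            inv = np.linalg.inv(self.m)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded in __init__
            raise SingularTransformError("transform is not invertible") from exc
        # Clean up the bottom row of an affine inverse against round-off.
        if np.allclose(self.m[3], [0, 0, 0, 1], atol=1e-12):
            inv[3] = [0.0, 0.0, 0.0, 1.0]
        return HomTransform(inv)

    def apply(self, p: Point3) -> Point3:
        v = self.m @ np.array([p.x, p.y, p.z, 1.0])
        w = v[3]
        if abs(w) < 1e-15:
            raise SingularTransformError("point maps to infinity")
        return Point3.from_array(v[:3] / w)

    def apply_array(self, pts: np.ndarray) -> np.ndarray:
        """Apply to an (n, 3) array of points, returning (n, 3)."""
        pts = np.asarray(pts, dtype=float)
        return pts @ self.linear.T + self.translation_vector

    def almost_equal(self, other: "HomTransform", atol: float = 1e-9) -> bool:
        return bool(np.allclose(self.m, other.m, atol=atol))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"HomTransform(\n{np.array_str(self.m, precision=6)})"


def compose(t1: HomTransform, t2: HomTransform) -> HomTransform:
    """Return t1 ∘ t2 (t2 applied first)."""
    return t1.compose(t2)


def invert(t: HomTransform) -> HomTransform:
    return t.invert()


def apply(t: HomTransform, p: Point3) -> Point3:
    return t.apply(p)


# ---------------------------------------------------------------------------
# Calibration plate
# ---------------------------------------------------------------------------

# Fixed point numbering for the nine-point plate. The centre row carries
# #1 (isocenter), #5 and #9; the other six points sit on the rows 150 mm
# toward/away from the gantry. Which physical side is "#5" versus "#9" is a
# documented convention (all downstream statistics are symmetric in it); the
# within-row ordering is inferred from the column groups of the reordered
# calibration procedure (#1/#3/#7, #9/#2/#8, #5/#4/#6 share columns).
_PLATE_POINTS: Mapping[str, tuple[float, float, float]] = {
    "#1": (0.0, 0.0, 0.0),
    "#2": (PLATE_COL_SPACING_MM, PLATE_ROW_SPACING_MM, 0.0),
    "#3": (0.0, PLATE_ROW_SPACING_MM, 0.0),
    "#4": (-PLATE_COL_SPACING_MM, PLATE_ROW_SPACING_MM, 0.0),
    "#5": (-PLATE_COL_SPACING_MM, 0.0, 0.0),
    "#6": (-PLATE_COL_SPACING_MM, -PLATE_ROW_SPACING_MM, 0.0),
    "#7": (0.0, -PLATE_ROW_SPACING_MM, 0.0),
    "#8": (PLATE_COL_SPACING_MM, -PLATE_ROW_SPACING_MM, 0.0),
    "#9": (PLATE_COL_SPACING_MM, 0.0, 0.0),
}

PLATE_LABELS: tuple[str, ...] = tuple(f"#{i}" for i in range(1, 10))
CENTER_ROW_LABELS: tuple[str, ...] = ("#1", "#5", "#9")
OFF_ROW_LABELS: tuple[str, ...] = ("#2", "#3", "#4", "#6", "#7", "#8")


@dataclasses.dataclass(frozen=True)
class CalibrationPlate:
    """The nine-point calibration template: 3 rows x 3 columns, flat (z=0),
    rows 150 mm apart longitudinally, columns 100 mm apart laterally,
    point #1 on the isocenter."""

    row_spacing: float = PLATE_ROW_SPACING_MM
    col_spacing: float = PLATE_COL_SPACING_MM

    @property
    def points(self) -> dict[str, Point3]:
        sy = self.row_spacing / PLATE_ROW_SPACING_MM
        sx = self.col_spacing / PLATE_COL_SPACING_MM
        return {
            lbl: Point3(x * sx, y * sy, z) for lbl, (x, y, z) in _PLATE_POINTS.items()
        }

    def point(self, label: str) -> Point3:
        pts = self.points
        if label not in pts:
            raise KeyError(f"unknown plate point label {label!r}; expected #1..#9")
        return pts[label]


DEFAULT_PLATE = CalibrationPlate()


def plate_point_coords(label: str) -> Point3:
    """World coordinates of a default-plate calibration point (#1..#9)."""
    return DEFAULT_PLATE.point(label)


# ---------------------------------------------------------------------------
# Marker block
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class MarkerBlock:
    """Rigid reflector block with four non-coplanar infrared markers.

    ``marker_offsets`` are the marker positions relative to the block
    reference point (the point placed on a plate label), millimetres. The
    manufacturer does not publish the true geometry, so the default is a
    plausible tetrahedron of a few centimetres' extent; it is configurable.
    """

    marker_offsets: tuple[Point3, ...] = (
        Point3(-25.0, -15.0, 0.0),
        Point3(25.0, -15.0, 0.0),
        Point3(0.0, 25.0, 8.0),
        Point3(0.0, 0.0, 35.0),
    )

    def __post_init__(self) -> None:
        if len(self.marker_offsets) != 4:
            raise ValueError("a marker block carries exactly 4 markers")
        if self.tetra_volume() <= 0.0:
            raise ValueError("markers must be non-coplanar (tetrahedron volume > 0)")

    def offsets_array(self) -> np.ndarray:
        return np.array([p.to_array() for p in self.marker_offsets])

    def tetra_volume(self) -> float:
        a = self.offsets_array()
        return abs(float(np.linalg.det(a[1:] - a[0]))) / 6.0

    @property
    def half_height(self) -> float:
        z = self.offsets_array()[:, 2]
        return float(z.max() - z.min()) / 2.0


DEFAULT_BLOCK = MarkerBlock()


@dataclasses.dataclass(frozen=True)
class BlockPlacement:
    """A marker block placed in the world frame.

    ``center`` is the block reference point; ``yaw`` rotates the block about
    the vertical axis (the dominant orientation error when a block is set
    down by hand). Pitch and roll default to zero.
    """

    center: Point3
    yaw: float = 0.0
    pitch: float = 0.0
    roll: float = 0.0
    block: MarkerBlock = DEFAULT_BLOCK

    def __post_init__(self) -> None:
        for ang in (self.yaw, self.pitch, self.roll):
            if not math.isfinite(ang):
                raise ValueError("non-finite block orientation angle")

    def rotation_matrix(self) -> np.ndarray:
        rz = HomTransform.rotation("z", self.yaw).linear
        ry = HomTransform.rotation("y", self.roll).linear
        rx = HomTransform.rotation("x", self.pitch).linear
        return rz @ ry @ rx

    def marker_world_positions(self) -> np.ndarray:
        """(4, 3) array: center + R(yaw, pitch, roll) @ offsets."""
        r = self.rotation_matrix()
        return self.center.to_array() + self.block.offsets_array() @ r.T
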