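"""Synthetic calibration scene: ground-truth camera transform, placement
noise models, and full calibration sessions.

This module stands in for the physical CT room: the wall-mounted infrared
camera (a rigid world→camera-view transform), the operator placing a
reflector block on the nine plate points (per-axis placement noise whose
magnitudes come from the measured positioning-uncertainty table), and the
camera observing the block's four markers.

Two facts drive everything downstream:

* the calibration software pairs the *nominal* plate coordinates (where it
  believes the block is) with the *observed* camera coordinates of wherever
  the block actually is — so placement noise becomes calibration-matrix
  error;
* laser-guided and couch-move positioning are an order of magnitude more
  precise than free-hand placement, which is exactly what distinguishes the
  single-block and three-block calibration procedures.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping

import numpy as np
import pandas as pd

from .geometry import (
    CENTER_ROW_LABELS,
    DEFAULT_BLOCK,
    DEFAULT_PLATE,
    BlockPlacement,
    CalibrationPlate,
    HomTransform,
    MarkerBlock,
    PLATE_LABELS,
    Point3,
)

__all__ = [
    "TrueTransform",
    "NoiseModel",
    "CalibrationDataset",
    "default_camera_pose",
    "default_noise_map",
    "place_block",
    "observe_markers",
    "generate_session",
    "STRATEGY_NOISE_MODES",
]


def default_camera_pose(
    tilt_deg: float = 35.0, standoff_mm: float = 2000.0
) -> HomTransform:
    """A plausible wall-mounted camera pose: the camera looks down at the
    isocenter from a wall bracket, here a rigid tilt about the lateral axis
    plus a standoff translation along the tilted viewing direction. Rigid by
    construction, so its singular values are exactly 1."""
    tilt = HomTransform.rotation("x", math.radians(tilt_deg))
    return HomTransform.translation(0.0, 0.0, standoff_mm).compose(tilt)


@dataclasses.dataclass(frozen=True)
class TrueTransform:
    """Ground-truth world→camera-view transform (the matrix the calibration
    tries to recover). Built from Euler rotations, a translation and an
    optional per-axis scale; the default scale of 1 makes it rigid."""

    a_true: HomTransform

    @classmethod
    def from_pose(
        cls,
        rot_x_deg: float = 35.0,
        rot_y_deg: float = 0.0,
        rot_z_deg: float = 0.0,
        translation_mm: tuple[float, float, float] = (0.0, 0.0, 2000.0),
        scale: tuple[float, float, float] = (1.0, 1.0, 1.0),
    ) -> "TrueTransform":
        r = (
            HomTransform.rotation("z", math.radians(rot_z_deg))
            .compose(HomTransform.rotation("y", math.radians(rot_y_deg)))
            .compose(HomTransform.rotation("x", math.radians(rot_x_deg)))
        )
        lin = r.linear @ np.diag(scale)
        return cls(HomTransform.from_parts(lin, translation_mm))

    @classmethod
    def default(cls) -> "TrueTransform":
        return cls(default_camera_pose())

    @classmethod
    def identity(cls) -> "TrueTransform":
        return cls(HomTransform.identity())


# ---------------------------------------------------------------------------
# Placement noise
# ---------------------------------------------------------------------------

_MODES = ("manual", "manual_with_laser", "couch_move", "uniform_sweep")

# Per-axis placement SDs in mm, (lateral x, longitudinal y, vertical z),
# from the measured camera-view positioning-uncertainty table (cm → mm).
# Manual free-hand values were measured at points #3 and #7; laser-aided
# values at point #1; couch-move values at #3 (the #7 couch row is nearly
# identical). Yaw noise: 1 degree SD for free-hand placement, zero for the
# laser- and couch-guided modes (orientation error is what the laser and
# the plate indexing suppress); no published figure exists, this is a
# documented default.
TABLE_SD_MM: Mapping[str, tuple[float, float, float]] = {
    "point1_laser": (0.41, 0.41, 0.20),
    "point1_couch": (0.00, 0.16, 0.06),
    "point3_manual": (1.41, 1.73, 0.20),
    "point3_couch": (0.00, 0.25, 0.05),
    "point7_manual": (1.57, 1.65, 0.24),
    "point7_couch": (0.00, 0.25, 0.08),
}

_DEFAULT_MODE_SD: Mapping[str, tuple[float, float, float]] = {
    "manual": TABLE_SD_MM["point3_manual"],
    "manual_with_laser": TABLE_SD_MM["point1_laser"],
    "couch_move": TABLE_SD_MM["point3_couch"],
}

DEFAULT_MANUAL_YAW_SD_RAD = math.radians(1.0)


@dataclasses.dataclass(frozen=True)
class NoiseModel:
    """Per-axis placement uncertainty for one positioning mode.

    Gaussian modes (``manual``, ``manual_with_laser``, ``couch_move``) draw
    each axis from N(0, sd); ``uniform_sweep`` draws each axis uniformly on
    [-u, +u] with ``half_width_mm = u`` (the Monte Carlo convention for a
    stated "± u mm" uncertainty). Yaw is Gaussian with ``yaw_sd_rad``.

    ``per_marker`` distinguishes two physical pictures. A real operator
    misplaces the whole rigid block, so the Gaussian modes perturb the
    block center (one draw shared by its four markers). The uncertainty
    sweep instead perturbs every *marker coordinate* independently — the
    convention of perturbing the entries of the world-coordinate matrix X
    directly — which is what exposes the short vertical lever arm of the
    geometry (block-level draws cancel out of the within-block vertical
    regressor). Both are switchable on any mode.
    """

    mode: str
    sd_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    half_width_mm: float = 0.0
    yaw_sd_rad: float = 0.0
    per_marker: bool = False

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown noise mode {self.mode!r}; expected one of {_MODES}")
        if any(s < 0 for s in self.sd_mm) or self.half_width_mm < 0 or self.yaw_sd_rad < 0:
            raise ValueError("noise dispersions must be >= 0")

    @classmethod
    def for_mode(cls, mode: str, point_label: str | None = None) -> "NoiseModel":
        """Default noise model for a Gaussian positioning mode, per-point
        where the uncertainty table measured that point."""
        if mode not in _DEFAULT_MODE_SD:
            raise ValueError(f"no table defaults for mode {mode!r}")
        sd = _DEFAULT_MODE_SD[mode]
        if point_label is not None and mode in ("manual", "couch_move"):
            row = "#7" if point_label in ("#6", "#7", "#8") else "#3"
            key = f"point{row[1]}_{'manual' if mode == 'manual' else 'couch'}"
            sd = TABLE_SD_MM[key]
        yaw = DEFAULT_MANUAL_YAW_SD_RAD if mode == "manual" else 0.0
        return cls(mode=mode, sd_mm=sd, yaw_sd_rad=yaw)

    @classmethod
    def uniform(cls, half_width_mm: float, per_marker: bool = True) -> "NoiseModel":
        return cls(mode="uniform_sweep", half_width_mm=half_width_mm, per_marker=per_marker)

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(mode="manual_with_laser")

    def draw_offset(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        """(size, 3) array of positional draws (size > 1 for per-marker use)."""
        if self.mode == "uniform_sweep":
            out = rng.uniform(-self.half_width_mm, self.half_width_mm, size=(size, 3))
        else:
            out = rng.normal(0.0, self.sd_mm, size=(size, 3))
        return out[0] if size == 1 else out

    def draw_yaw(self, rng: np.random.Generator) -> float:
        return float(rng.normal(0.0, self.yaw_sd_rad)) if self.yaw_sd_rad > 0 else 0.0


# Which positioning mode each strategy uses per plate point: both strategies
# laser-align the center row; the single-block method free-hands the other
# six points while the three-block method reaches them by couch moves.
STRATEGY_NOISE_MODES: Mapping[str, Mapping[str, str]] = {
    "single_block": {
        lbl: ("manual_with_laser" if lbl in CENTER_ROW_LABELS else "manual")
        for lbl in PLATE_LABELS
    },
    "three_block": {
        lbl: ("manual_with_laser" if lbl in CENTER_ROW_LABELS else "couch_move")
        for lbl in PLATE_LABELS
    },
}


def default_noise_map(strategy: str) -> dict[str, NoiseModel]:
    """Per-point default noise models for a built-in strategy label."""
    try:
        modes = STRATEGY_NOISE_MODES[strategy]
    except KeyError as exc:
        raise ValueError(
            f"unknown strategy {strategy!r}; expected one of {tuple(STRATEGY_NOISE_MODES)}"
        ) from exc
    return {lbl: NoiseModel.for_mode(mode, lbl) for lbl, mode in modes.items()}


def uniform_noise_map(half_width_mm: float) -> dict[str, NoiseModel]:
    """The Monte Carlo sweep condition: every placement uniformly perturbed."""
    nm = NoiseModel.uniform(half_width_mm)
    return {lbl: nm for lbl in PLATE_LABELS}


# ---------------------------------------------------------------------------
# Session generation
# ---------------------------------------------------------------------------


def place_block(
    nominal: Point3,
    noise: NoiseModel,
    rng: np.random.Generator,
    block: MarkerBlock = DEFAULT_BLOCK,
) -> BlockPlacement:
    """Place a block at a nominal plate point with positioning noise."""
    center = Point3.from_array(nominal.to_array() + noise.draw_offset(rng))
    return BlockPlacement(center=center, yaw=noise.draw_yaw(rng), block=block)


def observe_markers(
    placement: BlockPlacement, a_true: TrueTransform
) -> list[Point3]:
    """Camera-view coordinates of the four markers of a placed block."""
    cam = a_true.a_true.apply_array(placement.marker_world_positions())
    return [Point3.from_array(row) for row in cam]


@dataclasses.dataclass
class CalibrationDataset:
    """Paired world/camera marker coordinates from one calibration session.

    ``world`` holds the coordinates the calibration software *assumes*
    (nominal plate point + block marker offsets, no noise); ``cam`` holds
    what the camera actually observed (the true transform applied to the
    noisy placement). ``world_actual`` keeps the noisy ground-truth world
    positions for diagnostics. All arrays are (n, 3) in mm with one row per
    marker observation (9 placements x 4 markers = 36 by default).
    """

    world: np.ndarray
    cam: np.ndarray
    world_actual: np.ndarray
    point_labels: list[str]
    marker_index: np.ndarray
    strategy: str = "custom"

    def __post_init__(self) -> None:
        self.world = np.asarray(self.world, dtype=float)
        self.cam = np.asarray(self.cam, dtype=float)
        self.world_actual = np.asarray(self.world_actual, dtype=float)
        if not (self.world.shape == self.cam.shape == self.world_actual.shape):
            raise ValueError("world/cam coordinate arrays must have matching shapes")
        if self.world.ndim != 2 or self.world.shape[1] != 3:
            raise ValueError("coordinates must be (n, 3) arrays")

    @property
    def n_obs(self) -> int:
        return self.world.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "point_label": self.point_labels,
                "marker_index": self.marker_index,
            }
        )
        for name, arr in (("world", self.world), ("cam", self.cam)):
            for j, ax in enumerate("xyz"):
                df[f"{name}_{ax}_mm"] = arr[:, j]
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, strategy: str = "custom") -> "CalibrationDataset":
        world = df[["world_x_mm", "world_y_mm", "world_z_mm"]].to_numpy(float)
        cam = df[["cam_x_mm", "cam_y_mm", "cam_z_mm"]].to_numpy(float)
        return cls(
            world=world,
            cam=cam,
            world_actual=world.copy(),
            point_labels=list(df["point_label"]),
            marker_index=df["marker_index"].to_numpy(int),
            strategy=strategy,
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, strategy: str = "custom") -> "CalibrationDataset":
        return cls.from_dataframe(pd.read_csv(path), strategy=strategy)


def generate_session(
    strategy: str,
    noise_per_point: Mapping[str, NoiseModel] | None = None,
    a_true: TrueTransform | None = None,
    rng: np.random.Generator | int | None = None,
    plate: CalibrationPlate = DEFAULT_PLATE,
    block: MarkerBlock = DEFAULT_BLOCK,
    centers_only: bool = False,
) -> CalibrationDataset:
    """Simulate one nine-point calibration session.

    One block placement per plate point; the dataset pairs nominal world
    marker coordinates with the observed camera coordinates of the noisy
    placement. With ``centers_only`` the block reference point itself is the
    single observation per placement (a deliberately degenerate mode: nine
    coplanar points on a levelled plate).
    """
    if a_true is None:
        a_true = TrueTransform.default()
    if noise_per_point is None:
        noise_per_point = default_noise_map(strategy)
    missing = [lbl for lbl in PLATE_LABELS if lbl not in noise_per_point]
    if missing:
        raise ValueError(f"no noise model for plate point(s): {missing}")
    rng = np.random.default_rng(rng)

    world_rows, cam_rows, actual_rows, labels, midx = [], [], [], [], []
    for lbl in PLATE_LABELS:
        nominal = plate.point(lbl)
        noise = noise_per_point[lbl]
        nominal_placement = BlockPlacement(center=nominal, block=block)
        if noise.per_marker:
            placement = nominal_placement
        else:
            placement = place_block(nominal, noise, rng, block=block)
        if centers_only:
            nominal_markers = nominal.to_array()[None, :]
            actual_markers = placement.center.to_array()[None, :]
            if noise.per_marker:
                actual_markers = actual_markers + noise.draw_offset(rng, size=1)
        else:
            nominal_markers = nominal_placement.marker_world_positions()
            actual_markers = placement.marker_world_positions()
            if noise.per_marker:
                actual_markers = actual_markers + noise.draw_offset(rng, size=4)
        cam_markers = a_true.a_true.apply_array(actual_markers)
        world_rows.append(nominal_markers)
        actual_rows.append(actual_markers)
        cam_rows.append(cam_markers)
        n = nominal_markers.shape[0]
        labels.extend([lbl] * n)
        midx.extend(range(n))

    return CalibrationDataset(
        world=np.vstack(world_rows),
        cam=np.vstack(cam_rows),
        world_actual=np.vstack(actual_rows),
        point_labels=labels,
        marker_index=np.array(midx, dtype=int),
        strategy=strategy,
    )
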