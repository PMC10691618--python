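"""Estimation of the 4x4 camera calibration matrix from point
correspondences, in a model/results idiom.

The tracking system relates physical-world and camera-view coordinates
through a homogeneous calibration matrix A,

    X' = A X,

with X the 4 x n matrix of homogeneous world coordinates and X' the
corresponding camera-view coordinates. Because the system reports metric 3D
positions, A is estimated as an *affine* transform (12 free parameters,
bottom row pinned to [0,0,0,1]); the textbook shorthand A = X' X^{-1} is
realised as the least-squares / pseudoinverse solution, since X is 4 x n
rather than square.

An ideal calibration is distortion-free: the singular values of the 3x3
linear part of A — the "eigenvalues" of the calibration, in the field's
loose usage — all equal 1 for a rigid camera pose. Their departure from 1
under placement noise is the object of the Monte Carlo study in
:mod:`rgscal.eigensweep`.
"""

from __future__ import annotations

import dataclasses
import io
import itertools
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .geometry import HomTransform, Point3
from .scene import CalibrationDataset, TrueTransform

__all__ = [
    "CalibrationModel",
    "CalibrationResults",
    "FitResult",
    "DegenerateGeometryError",
    "VerificationRecord",
    "fit_calibration",
    "singular_values",
    "verify_isocenter",
    "VERIFICATION_TOLERANCE_MM",
]

VERIFICATION_TOLERANCE_MM = 5.0

# Rank-deficiency threshold on the singular values of the design matrix,
# relative to its largest singular value.
_RCOND = 1e-8


class DegenerateGeometryError(ValueError):
    """World points are coplanar / rank-deficient for an affine fit."""


@dataclasses.dataclass(frozen=True)
class VerificationRecord:
    """Isocenter verification: per-axis offset (mm) and pass flag.

    The clinical rule is strict: every axis offset must be *less than* the
    tolerance (0.5 cm by default); an offset exactly at tolerance fails.
    """

    offset_mm: tuple[float, float, float]
    tolerance_mm: float
    passed: bool


class CalibrationModel:
    """Affine calibration-matrix model for a set of point correspondences.

    Parameters
    ----------
    dataset
        Paired world / camera-view marker coordinates.
    allow_minimum_norm
        If False (default), a rank-deficient world-point geometry (e.g. the
        nine coplanar block centers of a levelled plate) raises
        :class:`DegenerateGeometryError`. If True, the minimum-norm
        least-squares solution is returned instead, flagged on the results.
    """

    def __init__(self, dataset: CalibrationDataset, *, allow_minimum_norm: bool = False):
        if dataset.n_obs < 4:
            raise ValueError("affine calibration needs at least 4 observations")
        self.dataset = dataset
        self.allow_minimum_norm = allow_minimum_norm

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "CalibrationModel":
        """Build from a session table with columns point_label, marker_index,
        world_{x,y,z}_mm, cam_{x,y,z}_mm."""
        return cls(CalibrationDataset.from_dataframe(df), **kwargs)

    def fit(self) -> "CalibrationResults":
        """Least-squares estimate of A.

        Minimises sum ||x'_i - A x_i||^2 over affine A. The design matrix is
        the n x 4 homogeneous world-coordinate block shared by the three
        camera axes, so one ``lstsq`` solve yields the full 3 x 4 parameter
        block.
        """
        w = self.dataset.world
        c = self.dataset.cam
        n = w.shape[0]
        design = np.hstack([w, np.ones((n, 1))])  # (n, 4)
        sv = np.linalg.svd(design, compute_uv=False)
        rank = int(np.sum(sv > sv[0] * _RCOND))
        min_norm = rank < 4
        if min_norm and not self.allow_minimum_norm:
            raise DegenerateGeometryError(
                "world points are coplanar or otherwise rank-deficient "
                f"(design rank {rank} < 4); a flat-plate block-centers-only "
                "session cannot determine an affine transform. Pass "
                "allow_minimum_norm=True for the flagged minimum-norm solution."
            )
        coef, _, _, _ = np.linalg.lstsq(design, c, rcond=_RCOND)  # (4, 3)
        m = np.eye(4)
        m[:3, :3] = coef[:3].T
        m[:3, 3] = coef[3]
        a_hat = HomTransform(m, require_invertible=not min_norm)
        resid = c - design @ coef
        residual_rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
        return CalibrationResults(
            model=self, a_hat=a_hat, residual_rms=residual_rms, minimum_norm=min_norm
        )


class CalibrationResults:
    """Fitted calibration matrix with residual diagnostics.

    Attributes
    ----------
    a_hat : HomTransform
        The estimated world→camera-view calibration matrix.
    residual_rms : float
        Root-mean-square camera-view residual, mm per observation.
    minimum_norm : bool
        True when the geometry was rank-deficient and the minimum-norm
        solution was returned.
    """

    def __init__(
        self,
        model: CalibrationModel,
        a_hat: HomTransform,
        residual_rms: float,
        minimum_norm: bool = False,
    ):
        self.model = model
        self.a_hat = a_hat
        self.residual_rms = residual_rms
        self.minimum_norm = minimum_norm
        self._sv: tuple[float, float, float] | None = None

    @property
    def n_obs(self) -> int:
        return self.model.dataset.n_obs

    def singular_values(self) -> tuple[float, float, float]:
        """Singular values of the 3x3 linear part, ordered by world axis.

        The SVD of the linear part gives singular values in descending
        order; each is assigned to the world axis its *right* singular
        vector is most parallel to. When the per-axis choices conflict (the
        generic case for a near-identity matrix, whose singular vectors mix
        under noise) the assignment maximising the *total* alignment is
        taken, which is the consistent global reading of "most parallel";
        an exact tie breaks deterministically (lowest axis/index first, via
        the assignment solver) with a warning. For a rigid transform all
        three equal 1.
        """
        if self._sv is not None:
            return self._sv
        _, s, vt = np.linalg.svd(self.a_hat.linear)
        align = np.abs(vt)  # align[i, axis] = |cos angle(v_i, e_axis)|
        rows, cols = linear_sum_assignment(-align)
        pairs = list(zip(rows, cols))
        for (i1, a1), (i2, a2) in itertools.combinations(pairs, 2):
            swap_loss = align[i1, a1] + align[i2, a2] - align[i1, a2] - align[i2, a1]
            if abs(swap_loss) < 1e-12:
                warnings.warn(
                    "ambiguous singular-vector/axis alignment; deterministic "
                    "tie-break by axis index",
                    RuntimeWarning,
                    stacklevel=2,
                )
                break
        assigned = {int(ax): float(s[i]) for i, ax in pairs}
        self._sv = (assigned[0], assigned[1], assigned[2])
        return self._sv

    def axis_gains(self) -> tuple[float, float, float]:
        """Scale of the fitted linear part along each world axis,
        ||A e_axis||_2 — a coupling-free per-axis diagnostic that equals the
        singular values when the transform is axis-aligned."""
        lin = self.a_hat.linear
        return tuple(float(np.linalg.norm(lin[:, j])) for j in range(3))

    def verify_isocenter(
        self,
        a_true: TrueTransform | HomTransform,
        tolerance_mm: float = VERIFICATION_TOLERANCE_MM,
    ) -> VerificationRecord:
        """The clinical verification step: map the isocenter through the true
        camera and back through the fitted calibration; pass iff each axis
        offset is strictly below tolerance (0.5 cm default)."""
        at = a_true.a_true if isinstance(a_true, TrueTransform) else a_true
        iso = Point3(0.0, 0.0, 0.0)
        back = self.a_hat.invert().apply(at.apply(iso))
        offset = (back.x - iso.x, back.y - iso.y, back.z - iso.z)
        passed = all(abs(o) < tolerance_mm for o in offset)
        return VerificationRecord(offset_mm=offset, tolerance_mm=tolerance_mm, passed=passed)

    def residual_drift(self, a_true: TrueTransform | HomTransform, scan_length_mm: float = 400.0) -> float:
        """Baseline drift (cm) this calibration would leave over a scan; see
        :func:`rgscal.drift.residual_drift`."""
        from .drift import residual_drift

        return residual_drift(self.a_hat, a_true, scan_length_mm)

    def simulate_dibh(self, a_true: TrueTransform | HomTransform, **kwargs):
        """Simulated DIBH waveform through this calibration; see
        :func:`rgscal.drift.simulate_dibh_waveform`."""
        from .drift import simulate_dibh_waveform

        return simulate_dibh_waveform(self.a_hat, a_true, **kwargs)

    # -- serialization ------------------------------------------------------

    def to_series(self) -> pd.Series:
        sx, sy, sz = self.singular_values()
        vals = {f"a{i}{j}": self.a_hat.m[i, j] for i in range(4) for j in range(4)}
        vals.update(
            residual_rms_mm=self.residual_rms,
            n_obs=self.n_obs,
            sigma_x=sx,
            sigma_y=sy,
            sigma_z=sz,
            minimum_norm=self.minimum_norm,
        )
        return pd.Series(vals)

    def summary(self) -> str:
        sx, sy, sz = self.singular_values()
        buf = io.StringIO()
        buf.write("Camera calibration fit (affine, least squares)\n")
        buf.write("=" * 46 + "\n")
        buf.write(f"observations:        {self.n_obs}\n")
        buf.write(f"strategy:            {self.model.dataset.strategy}\n")
        buf.write(f"residual RMS:        {self.residual_rms:.4f} mm\n")
        buf.write(f"singular values:     X {sx:.6f}  Y {sy:.6f}  Z {sz:.6f}\n")
        if self.minimum_norm:
            buf.write("NOTE: rank-deficient geometry; minimum-norm solution\n")
        buf.write("calibration matrix A (world -> camera view):\n")
        buf.write(np.array_str(self.a_hat.m, precision=6, suppress_small=True))
        buf.write("\n")
        return buf.getvalue()


# Alias matching the field's vocabulary for the bundle of fit outputs.
FitResult = CalibrationResults


def fit_calibration(
    dataset: CalibrationDataset, *, allow_minimum_norm: bool = False
) -> CalibrationResults:
    """Estimate the calibration matrix A from a session dataset."""
    return CalibrationModel(dataset, allow_minimum_norm=allow_minimum_norm).fit()


def singular_values(fit: CalibrationResults) -> tuple[float, float, float]:
    """Axis-assigned singular values (sigma_x, sigma_y, sigma_z) of a fit."""
    return fit.singular_values()


def verify_isocenter(
    a_hat: HomTransform | CalibrationResults,
    a_true: TrueTransform | HomTransform,
    tolerance_mm: float = VERIFICATION_TOLERANCE_MM,
) -> VerificationRecord:
    """Isocenter verification for a fitted or raw calibration transform."""
    if isinstance(a_hat, CalibrationResults):
        return a_hat.verify_isocenter(a_true, tolerance_mm)
    at = a_true.a_true if isinstance(a_true, TrueTransform) else a_true
    iso = Point3(0.0, 0.0, 0.0)
    back = a_hat.invert().apply(at.apply(iso))
    offset = (back.x, back.y, back.z)
    passed = all(abs(o) < tolerance_mm for o in offset)
    return VerificationRecord(offset_mm=offset, tolerance_mm=tolerance_mm, passed=passed)
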