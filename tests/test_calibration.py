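"""Calibration-matrix estimation: least-squares fit, singular values,
isocenter verification."""

import numpy as np
import pytest

from rgscal.calibration import (
    CalibrationModel,
    DegenerateGeometryError,
    fit_calibration,
    verify_isocenter,
)
from rgscal.geometry import HomTransform
from rgscal.scene import (
    NoiseModel,
    TrueTransform,
    generate_session,
    uniform_noise_map,
)

from conftest import random_affine


def normal_equations_oracle(dataset):
    """Independent brute-force solve of the same least-squares problem via
    the normal equations (X^T X) beta = X^T X'."""
    w, c = dataset.world, dataset.cam
    design = np.hstack([w, np.ones((w.shape[0], 1))])
    beta = np.linalg.solve(design.T @ design, design.T @ c)
    m = np.eye(4)
    m[:3, :3] = beta[:3].T
    m[:3, 3] = beta[3]
    return m


def test_zero_noise_fit_recovers_truth(zero_noise_map, rng):
    """A noiseless session generated from an affine truth is interpolated
    exactly: max element deviation < 1e-6 and residual RMS < 1e-6 mm."""
    for _ in range(10):
        a_true = TrueTransform(random_affine(rng))
        ds = generate_session("three_block", zero_noise_map, a_true, rng=0)
        res = fit_calibration(ds)
        assert np.abs(res.a_hat.m - a_true.a_true.m).max() < 1e-6
        assert res.residual_rms < 1e-6


def test_fit_matches_normal_equations_oracle(a_true_default):
    """On noisy sessions the lstsq solution equals the independent
    normal-equations solve to 1e-9."""
    for seed in range(100):
        ds = generate_session(
            "uniform_sweep", uniform_noise_map(5.0), a_true_default, rng=seed
        )
        res = fit_calibration(ds)
        np.testing.assert_allclose(
            res.a_hat.m, normal_equations_oracle(ds), atol=1e-9
        )


def test_block_centers_only_is_degenerate(a_true_default, zero_noise_map):
    """Nine block centers on a levelled (flat) plate are coplanar: the
    affine fit is rank-deficient and must refuse unless the flagged
    minimum-norm mode is requested explicitly."""
    ds = generate_session(
        "single_block", zero_noise_map, a_true_default, rng=0, centers_only=True
    )
    with pytest.raises(DegenerateGeometryError):
        fit_calibration(ds)
    res = fit_calibration(ds, allow_minimum_norm=True)
    assert res.minimum_norm


@pytest.mark.parametrize(
    "a_true,expected",
    [
        (TrueTransform.identity(), (1, 1, 1)),
        (TrueTransform.from_pose(0, 0, 0, (5, 6, 7), scale=(1.02, 0.99, 1.00)), (1.02, 0.99, 1.00)),
        (TrueTransform.from_pose(35, 10, -20, (0, 0, 2000)), (1, 1, 1)),
    ],
    ids=["identity", "diagonal-scale", "pure-rotation"],
)
def test_singular_values_axis_assignment(a_true, expected, zero_noise_map):
    """Identity and rotations give (1,1,1); an axis-aligned scale returns
    each scale on its own axis regardless of SVD magnitude ordering."""
    ds = generate_session("three_block", zero_noise_map, a_true, rng=0)
    sv = fit_calibration(ds).singular_values()
    np.testing.assert_allclose(sv, expected, atol=1e-9)


def test_verification_pass_and_strict_tolerance(zero_noise_map):
    """Verification passes at equality of transforms, fails for a 6 mm
    offset, and fails at an offset of exactly 5.0 mm (strict 'less than'
    0.5 cm in every direction)."""
    a_true = TrueTransform.identity()
    rec = verify_isocenter(HomTransform.identity(), a_true)
    assert rec.passed and rec.offset_mm == (0, 0, 0)

    shifted = HomTransform.translation(0, 0, -6.0)  # camera-frame 6 mm error
    rec = verify_isocenter(shifted, a_true)
    assert not rec.passed
    assert np.linalg.norm(rec.offset_mm) == pytest.approx(6.0)

    edge = HomTransform.translation(-5.0, 0, 0)
    rec = verify_isocenter(edge, a_true)
    assert abs(rec.offset_mm[0]) == pytest.approx(5.0)
    assert not rec.passed


def test_noise_to_zero_consistency(a_true_default):
    """Shrinking placement noise shrinks the fit error monotonically in
    expectation: mean max-element error decreases over u = 3, 1, 0.1, 0 mm."""
    errs = []
    for u in (3.0, 1.0, 0.1):
        tot = 0.0
        for seed in range(60):
            ds = generate_session(
                "uniform_sweep", uniform_noise_map(u), a_true_default, rng=seed
            )
            res = fit_calibration(ds)
            tot += np.abs(res.a_hat.m - a_true_default.a_true.m).max()
        errs.append(tot / 60)
    zero = {k: NoiseModel.zero() for k in uniform_noise_map(1.0)}
    ds = generate_session("none", zero, a_true_default, rng=0)
    errs.append(np.abs(fit_calibration(ds).a_hat.m - a_true_default.a_true.m).max())
    assert errs == sorted(errs, reverse=True)


def test_residual_rms_equivariant_under_rigid_conjugation(a_true_default, rng):
    """Pre-composing the world frame with a rigid motion and post-composing
    the camera frame with its conjugate leaves the residual RMS unchanged."""
    ds = generate_session("uniform_sweep", uniform_noise_map(3.0), a_true_default, rng=7)
    base = fit_calibration(ds).residual_rms

    g = TrueTransform.from_pose(15, -25, 40, (30, -20, 10)).a_true  # rigid
    conj = ds.__class__(
        world=g.invert().apply_array(ds.world),
        cam=ds.cam,
        world_actual=g.invert().apply_array(ds.world_actual),
        point_labels=ds.point_labels,
        marker_index=ds.marker_index,
    )
    # camera-side conjugation by a rigid motion also preserves residuals
    h = TrueTransform.from_pose(-10, 5, 60, (0, 12, -7)).a_true
    conj2 = ds.__class__(
        world=ds.world,
        cam=h.apply_array(ds.cam),
        world_actual=ds.world_actual,
        point_labels=ds.point_labels,
        marker_index=ds.marker_index,
    )
    assert fit_calibration(conj).residual_rms == pytest.approx(base, abs=1e-9)
    assert fit_calibration(conj2).residual_rms == pytest.approx(base, abs=1e-9)


def test_model_from_dataframe_and_summary(a_true_default):
    ds = generate_session("three_block", a_true=a_true_default, rng=3)
    model = CalibrationModel.from_dataframe(ds.to_dataframe())
    res = model.fit()
    np.testing.assert_allclose(res.a_hat.m, fit_calibration(ds).a_hat.m, atol=1e-12)
    text = res.summary()
    assert "singular values" in text and "residual RMS" in text
    s = res.to_series()
    assert s["n_obs"] == 36 and s["residual_rms_mm"] >= 0


def test_too_few_observations_rejected(a_true_default, zero_noise_map):
    ds = generate_session("three_block", zero_noise_map, a_true_default, rng=0)
    small = ds.__class__(
        world=ds.world[:3],
        cam=ds.cam[:3],
        world_actual=ds.world_actual[:3],
        point_labels=ds.point_labels[:3],
        marker_index=ds.marker_index[:3],
    )
    with pytest.raises(ValueError, match="at least 4"):
        CalibrationModel(small)
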