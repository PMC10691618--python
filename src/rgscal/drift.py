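"""Baseline-drift propagation for DIBH scans through a miscalibrated camera.

With a wall-mounted camera, couch travel during acquisition moves the marker
block through the camera's field of view. A perfect calibration maps that
longitudinal travel back onto itself, so the reported vertical gating
amplitude stays flat during a breath hold. An imperfect calibration
A-hat != A-true leaks a fraction of the longitudinal travel into the
reported vertical coordinate — the baseline drift.

The drift has a closed form: the reported world position of a marker at
true world position p is  invert(A_hat) @ A_true @ p,  so over a scan that
translates the marker by L longitudinally the reported vertical coordinate
changes by the (z, y) element of (invert(A_hat) A_true - I) times L. The
waveform simulator exists for realism and CSV export and must agree with
this closed form exactly (both are affine).

Drift values are reported in cm normalised to a 40 cm scan length, the
typical breast DIBH CT scan, matching the clinical convention.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .calibration import fit_calibration
from .geometry import HomTransform
from .scene import (
    CalibrationDataset,
    NoiseModel,
    TrueTransform,
    default_noise_map,
    generate_session,
)

__all__ = [
    "Waveform",
    "DriftSummary",
    "residual_drift",
    "simulate_dibh_waveform",
    "drift_experiment",
    "DEFAULT_SCAN_LENGTH_MM",
]

DEFAULT_SCAN_LENGTH_MM = 400.0


def _as_hom(t: TrueTransform | HomTransform) -> HomTransform:
    return t.a_true if isinstance(t, TrueTransform) else t


def residual_drift(
    a_hat: HomTransform,
    a_true: TrueTransform | HomTransform,
    scan_length_mm: float = DEFAULT_SCAN_LENGTH_MM,
) -> float:
    """Signed residual baseline drift in cm over one scan.

    drift = vertical component of (invert(a_hat) ∘ a_true − I) applied to a
    longitudinal displacement of ``scan_length_mm``. Exactly linear in scan
    length (affine maps), zero iff the composition has no y→z coupling; the
    sign is preserved (a calibration can drift either way).
    """
    m = a_hat.invert().compose(_as_hom(a_true)).linear - np.eye(3)
    drift_mm = float(m[2, 1] * scan_length_mm)
    return drift_mm / 10.0


@dataclasses.dataclass
class Waveform:
    """A simulated DIBH gating trace.

    Columns: ``time_s``; ``amplitude_cm`` — the vertical marker coordinate
    as the tracking system reports it (through the fitted calibration);
    ``couch_y_mm`` — marker longitudinal world position driven by couch
    travel; ``phase`` — 'free', 'hold' or 'scan'.
    """

    time_s: np.ndarray
    amplitude_cm: np.ndarray
    couch_y_mm: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.time_s) > 0):
            raise ValueError("waveform time must be strictly increasing")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "amplitude_cm": self.amplitude_cm,
                "couch_y_mm": self.couch_y_mm,
                "phase": self.phase,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def scan_drift_cm(self) -> float:
        """Reported-amplitude change (end − start) over the scan phase."""
        scan = self.phase == "scan"
        amp = self.amplitude_cm[scan]
        return float(amp[-1] - amp[0])

    def plot(self, ax=None):
        """Amplitude-versus-time trace with the scan phase shaded."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 3))
        ax.plot(self.time_s, self.amplitude_cm, lw=1.2)
        scan = self.phase == "scan"
        if scan.any():
            ax.axvspan(self.time_s[scan][0], self.time_s[scan][-1], alpha=0.15, color="tab:orange")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("reported amplitude (cm)")
        return ax


def simulate_dibh_waveform(
    a_hat: HomTransform,
    a_true: TrueTransform | HomTransform,
    period_s: float = 4.0,
    amplitude_cm: float = 1.0,
    n_free_cycles: int = 2,
    hold_s: float = 5.0,
    scan_length_mm: float = DEFAULT_SCAN_LENGTH_MM,
    couch_speed_mm_s: float = 20.0,
    sample_rate_hz: float = 25.0,
    rng: np.random.Generator | int | None = None,
    breathing_noise_cm: float = 0.0,
) -> Waveform:
    """Simulate a DIBH acquisition trace.

    The phantom free-breathes sinusoidally (peak-to-peak ``amplitude_cm``)
    for ``n_free_cycles``, stops at maximum inhale, holds for ``hold_s``,
    then the couch carries it linearly through ``scan_length_mm`` of
    longitudinal travel while the breath hold continues. The reported
    amplitude is the vertical coordinate of invert(a_hat) ∘ a_true applied
    to the marker's true world position, so over the scan phase it drifts by
    exactly :func:`residual_drift` when the calibration is imperfect.
    Optional Gaussian sensor noise (off by default) roughens the trace.
    """
    if period_s <= 0 or sample_rate_hz <= 0 or couch_speed_mm_s <= 0:
        raise ValueError("period, sample rate and couch speed must be positive")
    scan_s = scan_length_mm / couch_speed_mm_s
    t_free = n_free_cycles * period_s
    total = t_free + hold_s + scan_s
    n = int(round(total * sample_rate_hz)) + 1
    t = np.linspace(0.0, total, n)

    phase = np.where(t < t_free, "free", np.where(t < t_free + hold_s, "hold", "scan"))
    # True vertical marker position (mm): sinusoid peaking at max inhale,
    # clamped at the peak from the start of the hold.
    half = amplitude_cm * 10.0 / 2.0
    z_true = np.where(
        phase == "free",
        half * np.sin(2.0 * np.pi * (t - t_free) / period_s + np.pi / 2.0),
        half,
    )
    # Marker longitudinal travel: stationary until the scan, then linear
    # from -L/2 to +L/2 (couch carries the marker through the bore).
    y_true = np.zeros_like(t)
    scan_mask = phase == "scan"
    y_true[scan_mask] = -scan_length_mm / 2.0 + couch_speed_mm_s * (
        t[scan_mask] - (t_free + hold_s)
    )

    world = np.column_stack([np.zeros_like(t), y_true, z_true])
    reported = a_hat.invert().compose(_as_hom(a_true)).apply_array(world)
    amp_cm = reported[:, 2] / 10.0
    if breathing_noise_cm > 0:
        rng = np.random.default_rng(rng)
        amp_cm = amp_cm + rng.normal(0.0, breathing_noise_cm, size=amp_cm.shape)
    return Waveform(time_s=t, amplitude_cm=amp_cm, couch_y_mm=y_true, phase=phase)


@dataclasses.dataclass
class DriftSummary:
    """Per-strategy residual drifts (cm per scan) over repeated calibrations."""

    strategy: str
    drifts_cm: np.ndarray
    n_degenerate: int = 0

    @property
    def n_reps(self) -> int:
        return self.drifts_cm.size

    @property
    def mean_cm(self) -> float:
        return float(np.mean(self.drifts_cm))

    @property
    def sd_cm(self) -> float:
        return float(np.std(self.drifts_cm, ddof=1)) if self.n_reps > 1 else 0.0

    @property
    def mean_abs_cm(self) -> float:
        return float(np.mean(np.abs(self.drifts_cm)))

    def fraction_within(self, threshold_cm: float = 0.2) -> float:
        """Fraction of calibrations meeting |drift| <= threshold (the vendor
        recommends residual drift below 0.2 cm)."""
        return float(np.mean(np.abs(self.drifts_cm) <= threshold_cm))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"rep": np.arange(self.n_reps), f"{self.strategy}_drift_cm": self.drifts_cm})


def drift_experiment(
    n_reps: int,
    a_true: TrueTransform | None = None,
    noise_maps: Mapping[str, Mapping[str, NoiseModel]] | None = None,
    scan_length_mm: float = DEFAULT_SCAN_LENGTH_MM,
    seed: int | None = None,
) -> dict[str, DriftSummary]:
    """Single-block vs three-block drift comparison.

    For each repetition and strategy: simulate a calibration session with
    the strategy's positioning-noise map, fit the calibration matrix, and
    evaluate the closed-form residual drift over one scan. Repetitions are
    paired across strategies through a shared per-repetition seed, so the
    comparison is between noise *magnitudes*, not luck of the draw order.
    """
    if n_reps < 2:
        raise ValueError("drift experiment needs n_reps >= 2")
    if a_true is None:
        a_true = TrueTransform.default()
    if noise_maps is None:
        noise_maps = {s: default_noise_map(s) for s in ("single_block", "three_block")}
    root = np.random.default_rng(seed)
    rep_seeds = root.integers(0, 2**31 - 1, size=n_reps)

    out: dict[str, DriftSummary] = {}
    for strategy, nmap in noise_maps.items():
        drifts = np.empty(n_reps)
        n_bad = 0
        for i, s in enumerate(rep_seeds):
            ds: CalibrationDataset = generate_session(
                strategy, noise_per_point=nmap, a_true=a_true, rng=int(s)
            )
            try:
                res = fit_calibration(ds)
            except Exception:
                drifts[i] = np.nan
                n_bad += 1
                continue
            drifts[i] = residual_drift(res.a_hat, a_true, scan_length_mm)
        out[strategy] = DriftSummary(
            strategy=strategy, drifts_cm=drifts[~np.isnan(drifts)], n_degenerate=n_bad
        )
    return out
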