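"""Summary statistics for measured calibration-quality tables.

Two small measured tables ship with the package:

* ``residual_drift_table`` — ten residual baseline drifts (cm per 40 cm
  scan) measured after single-block calibrations and ten after three-block
  calibrations of the same camera;
* ``positioning_sd_table`` — per-axis SDs (cm, camera-view frame) of
  repeated block positioning at plate points #1/#3/#7 under manual,
  manual-with-laser and couch-move positioning.

This module reproduces the derived statistics a QA report builds from them:
column summaries (sample SD, n−1 denominator — the convention the measured
summary rows follow), a pooled two-sample Student t-test, pass-rate counts
against the vendor's 0.2 cm drift recommendation, quadrature propagation of
the point-difference SDs, and the normal-tail / pair-combinatorics figures
behind the argument that free-hand placement errors will, with near
certainty, put some pair of calibration points more than 2 SD apart.
"""

from __future__ import annotations

import math
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "load_drift_table",
    "load_positioning_table",
    "summarize",
    "students_t_two_sample",
    "criterion_count",
    "quadrature_diff_sd",
    "pair_count",
    "tail_fraction_normal",
    "drift_table_report",
    "positioning_diff_report",
]


def _data_path(name: str):
    return resources.files("rgscal.data").joinpath(name)


def load_drift_table() -> pd.DataFrame:
    """Measured residual drifts (cm per 40 cm scan), 10 calibrations per
    method; columns single_block_cm, three_block_cm."""
    with resources.as_file(_data_path("residual_drift_table.csv")) as p:
        df = pd.read_csv(p)
    if len(df) != 10:
        raise ValueError("drift table fixture must hold exactly 10 rows")
    return df


def load_positioning_table() -> pd.DataFrame:
    """Measured per-axis positioning SDs (cm) by (point, mode)."""
    with resources.as_file(_data_path("positioning_sd_table.csv")) as p:
        return pd.read_csv(p)


def summarize(values) -> tuple[float, float]:
    """(mean, sample SD) of a list of measurements in cm.

    The SD uses the n−1 denominator; rounding to the 2 decimals of the
    clinical tables is left to the reporting layer.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("summary needs at least 2 values")
    return float(v.mean()), float(v.std(ddof=1))


def students_t_two_sample(a, b) -> tuple[float, int, float]:
    """Pooled-variance (equal-variance) two-sample Student t-test.

    Returns (t, df, two-sided p) with df = n_a + n_b − 2. Degenerate zero
    pooled variance: equal means give (0, df, 1); unequal means give a
    signed infinite t and p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    na, nb = a.size, b.size
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0, df, 1.0
        return math.copysign(math.inf, diff), df, 0.0
    t = diff / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def welch_t_two_sample(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance alternative, offered for sensitivity checks."""
    res = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def criterion_count(values, threshold_cm: float) -> tuple[int, float]:
    """How many measurements meet |value| <= threshold, and the fraction.

    Absolute values: drifts are signed, the criterion is on magnitude.
    """
    if threshold_cm <= 0:
        raise ValueError("threshold must be positive")
    v = np.abs(np.asarray(values, dtype=float))
    count = int(np.sum(v <= threshold_cm + 1e-12))
    return count, count / v.size


def quadrature_diff_sd(sd1: float, sd2: float) -> float:
    """SD of the difference of two independent measurements: sqrt(sd1²+sd2²)."""
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be non-negative")
    return math.hypot(sd1, sd2)


def pair_count(n: int, k: int) -> int:
    """Binomial coefficient C(n, k): how many point pairs can disagree."""
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got n={n}, k={k}")
    return math.comb(n, k)


def tail_fraction_normal(k_sd: float) -> float:
    """Fraction of a normal population beyond ±k SD: 2·(1 − Φ(k))."""
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    return float(2.0 * sps.norm.sf(k_sd))


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------


def drift_table_report(threshold_cm: float = 0.2) -> pd.DataFrame:
    """Summary of the measured drift table: per-method mean, sample SD and
    pass count against the drift recommendation, plus the pooled t-test."""
    df = load_drift_table()
    rows = []
    for col, label in (("single_block_cm", "single_block"), ("three_block_cm", "three_block")):
        mean, sd = summarize(df[col])
        cnt, frac = criterion_count(df[col], threshold_cm)
        rows.append(
            {
                "method": label,
                "n": len(df),
                "mean_cm": mean,
                "sd_cm": sd,
                f"n_within_{threshold_cm:g}cm": cnt,
                "fraction_within": frac,
            }
        )
    out = pd.DataFrame(rows)
    t, dof, p = students_t_two_sample(df["single_block_cm"], df["three_block_cm"])
    out.attrs["t"] = t
    out.attrs["df"] = dof
    out.attrs["p_two_sided"] = p
    return out


def positioning_diff_report(
    point_a: str = "#3", point_b: str = "#7", mode: str = "manual"
) -> pd.Series:
    """Quadrature SD of the coordinate difference between two plate points
    under one positioning mode, per axis (cm)."""
    tbl = load_positioning_table().set_index(["point", "mode"])
    a = tbl.loc[(point_a, mode)]
    b = tbl.loc[(point_b, mode)]
    return pd.Series(
        {
            ax: quadrature_diff_sd(float(a[ax]), float(b[ax]))
            for ax in ("vertical_cm", "longitudinal_cm", "lateral_cm")
        },
        name=f"({point_a} - {point_b}) ({mode})",
    )
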