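"""Measured-table statistics: summaries, t-test, criterion counts,
quadrature propagation, combinatorics and normal tails."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from rgscal.report import (
    criterion_count,
    drift_table_report,
    load_drift_table,
    load_positioning_table,
    pair_count,
    positioning_diff_report,
    quadrature_diff_sd,
    students_t_two_sample,
    summarize,
    tail_fraction_normal,
    welch_t_two_sample,
)


def test_drift_table_summary_rows():
    """The measured drift columns summarise to 0.30 +/- 0.12 cm
    (single-block) and 0.02 +/- 0.03 cm (three-block) at 2 decimals."""
    df = load_drift_table()
    mean_s, sd_s = summarize(df["single_block_cm"])
    assert mean_s == pytest.approx(0.296)
    assert round(mean_s, 2) == 0.30 and round(sd_s, 2) == 0.12
    mean_t, sd_t = summarize(df["three_block_cm"])
    assert mean_t == pytest.approx(0.023)
    assert round(mean_t, 2) == 0.02 and round(sd_t, 2) == 0.03


def test_sample_sd_convention_is_forced_by_the_summary_row():
    """Only the n-1 denominator reproduces the printed 0.12; the population
    SD of the single-block column rounds to 0.11."""
    col = load_drift_table()["single_block_cm"].to_numpy()
    assert round(float(np.std(col, ddof=1)), 2) == 0.12
    assert round(float(np.std(col, ddof=0)), 2) == 0.11


def test_summarize_validation_and_constant_list():
    with pytest.raises(ValueError):
        summarize([1.0])
    assert summarize([2.0, 2.0, 2.0])[1] == 0.0


def test_pooled_t_on_drift_table():
    """Pooled two-sample Student t on the measured columns: t near 6.86 with
    df = 18 and a two-sided p below 1e-4; agrees with an independent
    implementation."""
    df = load_drift_table()
    t, dof, p = students_t_two_sample(df["single_block_cm"], df["three_block_cm"])
    assert dof == 18
    assert t == pytest.approx(6.86, abs=0.02)
    assert p < 1e-4
    ref = sps.ttest_ind(df["single_block_cm"], df["three_block_cm"], equal_var=True)
    assert t == pytest.approx(ref.statistic, rel=1e-12)
    assert p == pytest.approx(ref.pvalue, rel=1e-12)


def test_t_identical_samples_and_scale_invariance(rng):
    a = list(rng.normal(0, 1, 8))
    t, dof, p = students_t_two_sample(a, a)
    assert t == 0.0 and p == 1.0
    b = list(rng.normal(1, 2, 6))
    t1, _, p1 = students_t_two_sample(a, b)
    t2, _, p2 = students_t_two_sample([2 * v for v in a], [2 * v for v in b])
    assert t2 == pytest.approx(t1, rel=1e-12)
    assert p2 == pytest.approx(p1, rel=1e-12)


def test_t_degenerate_zero_variance():
    t, dof, p = students_t_two_sample([1.0, 1.0], [1.0, 1.0])
    assert (t, p) == (0.0, 1.0)
    t, dof, p = students_t_two_sample([1.0, 1.0], [2.0, 2.0])
    assert math.isinf(t) and p == 0.0


def test_welch_variant_available():
    df = load_drift_table()
    t, dof, p = welch_t_two_sample(df["single_block_cm"], df["three_block_cm"])
    assert p < 1e-3 and dof < 18  # unequal variances shrink the df


def test_criterion_counts_on_drift_table():
    """Against the 0.2 cm drift recommendation: 1/10 single-block
    calibrations pass, 10/10 three-block; relaxing to 0.22 cm still passes
    only 30% of the single-block column."""
    df = load_drift_table()
    assert criterion_count(df["single_block_cm"], 0.20) == (1, 0.1)
    assert criterion_count(df["single_block_cm"], 0.22) == (3, 0.3)
    assert criterion_count(df["three_block_cm"], 0.20) == (10, 1.0)


def test_criterion_count_uses_absolute_values_and_is_monotone():
    vals = [-0.25, -0.1, 0.05, 0.3]
    assert criterion_count(vals, 0.1)[0] == 2
    counts = [criterion_count(vals, th)[0] for th in (0.01, 0.06, 0.11, 0.26, 0.31)]
    assert counts == sorted(counts)
    with pytest.raises(ValueError):
        criterion_count(vals, 0.0)


def test_quadrature_reproduces_difference_row():
    """Quadrature propagation of the per-point SDs reproduces the printed
    (#3 - #7) manual row: 0.031 / 0.239 / 0.211 cm at printed precision."""
    assert round(quadrature_diff_sd(0.020, 0.024), 3) == 0.031
    assert round(quadrature_diff_sd(0.173, 0.165), 3) == 0.239
    assert round(quadrature_diff_sd(0.141, 0.157), 3) == 0.211
    diff = positioning_diff_report("#3", "#7", "manual")
    assert [round(v, 3) for v in diff] == [0.031, 0.239, 0.211]


def test_quadrature_properties():
    assert quadrature_diff_sd(0.0, 0.7) == 0.7
    for a, b in [(0.1, 0.2), (0.5, 0.5), (0.0, 0.0)]:
        r = quadrature_diff_sd(a, b)
        assert r == quadrature_diff_sd(b, a)
        assert max(a, b) <= r <= a + b
    with pytest.raises(ValueError):
        quadrature_diff_sd(-0.1, 0.1)


@settings(deadline=None, derandomize=True, max_examples=100)
@given(sd1=st.floats(0, 10), sd2=st.floats(0, 10))
def test_quadrature_bounds_property(sd1, sd2):
    """Quadrature combination is symmetric and bounded between the larger
    input and the plain sum."""
    r = quadrature_diff_sd(sd1, sd2)
    assert r == quadrature_diff_sd(sd2, sd1)
    assert max(sd1, sd2) - 1e-12 <= r <= sd1 + sd2 + 1e-12


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    values=st.lists(st.floats(-1, 1), min_size=1, max_size=20),
    thresholds=st.lists(st.floats(0.01, 2), min_size=2, max_size=5),
)
def test_criterion_count_monotone_property(values, thresholds):
    """The pass count never decreases as the threshold loosens."""
    counts = [criterion_count(values, th)[0] for th in sorted(thresholds)]
    assert counts == sorted(counts)


def test_pair_count_against_enumeration():
    assert pair_count(6, 2) == 15
    assert pair_count(5, 0) == 1
    labels = "abcde"
    assert pair_count(5, 2) == len(list(itertools.combinations(labels, 2)))
    with pytest.raises(ValueError):
        pair_count(3, 5)


def test_normal_tail_fractions():
    """About 32% of a normal population lies beyond 1 SD and about 5%
    beyond 2 SD; the tail vanishes for large k."""
    assert tail_fraction_normal(1.0) == pytest.approx(0.3173, abs=5e-4)
    assert round(100 * tail_fraction_normal(1.0)) == 32
    assert tail_fraction_normal(2.0) == pytest.approx(0.0455, abs=5e-4)
    assert round(100 * tail_fraction_normal(2.0)) == 5
    assert tail_fraction_normal(10.0) < 1e-20
    with pytest.raises(ValueError):
        tail_fraction_normal(0.0)


def test_positioning_table_fixture_shape():
    tbl = load_positioning_table()
    assert set(tbl["mode"]) == {"manual", "manual_with_laser", "couch_move"}
    assert len(tbl) == 6
    assert (tbl[["vertical_cm", "longitudinal_cm", "lateral_cm"]] >= 0).all().all()


def test_drift_table_report_assembly():
    rep = drift_table_report()
    single = rep[rep.method == "single_block"].iloc[0]
    assert single["n_within_0.2cm"] == 1
    assert rep.attrs["df"] == 18 and rep.attrs["p_two_sided"] < 1e-4
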