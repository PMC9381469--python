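"""Statistical core: Pearson profiles, OLS calibration, threshold transfer."""
import math

import numpy as np
import pytest

from conftest import make_scan, ols_oracle, pearson_oracle

from vertecalib.cohort_qc import apply_exclusions
from vertecalib.levelwise_calibration import (
    CalibrationError,
    LevelCalibration,
    compare_correlation_profiles,
    derive_thresholds,
    fit_all_levels,
    fit_level_calibration,
    load_reference_calibrations,
    load_reference_thresholds,
    pearson_by_level,
    permutation_profile_pvalue,
    round_half_up,
)
from vertecalib.spine_model import Cohort, MEASUREMENT_LEVELS, Region, VertebraLevel


def _cohort_from_pairs(pairs, level="C6"):
    """One patient per (level value, lumbar value) pair."""
    scans = [
        make_scan(f"P{i:03d}", {level: y, "L1": x, "L2": x, "L3": x})
        for i, (x, y) in enumerate(pairs)
    ]
    cohort = Cohort(scans=scans)
    apply_exclusions(cohort)
    return cohort


# ---------------------------------------------------------------------------
# Pearson


def test_exact_anticorrelation():
    cohort = _cohort_from_pairs([(40, 10), (30, 20), (20, 30), (10, 40)])
    corr = pearson_by_level(cohort)
    assert corr[VertebraLevel.parse("C6")][0] == pytest.approx(-1.0, abs=1e-12)


def test_pearson_matches_sum_formula_oracle_with_outlier():
    xs = [100.0, 110.0, 120.0, 130.0, 300.0]
    ys = [90.0, 105.0, 118.0, 122.0, 140.0]
    cohort = _cohort_from_pairs(list(zip(xs, ys)))
    r, n = pearson_by_level(cohort)[VertebraLevel.parse("C6")]
    assert n == 5
    assert r == pytest.approx(pearson_oracle(xs, ys), abs=1e-12)


def test_small_levels_are_omitted_not_fatal():
    cohort = _cohort_from_pairs([(100, 90), (110, 95)])  # n=2 at C6
    assert pearson_by_level(cohort) == {}


def test_excluded_vertebrae_only_dropped_when_respecting_exclusions():
    pairs = [(100, 90), (110, 100), (120, 110), (130, 200)]
    scans = [
        make_scan(
            f"P{i}",
            {"C6": y, "L1": x, "L2": x, "L3": x},
            degeneration={"C6": 3} if i == 3 else {},
        )
        for i, (x, y) in enumerate(pairs)
    ]
    cohort = Cohort(scans=scans)
    apply_exclusions(cohort)
    lvl = VertebraLevel.parse("C6")
    r_after, n_after = pearson_by_level(cohort, respect_exclusions=True)[lvl]
    r_before, n_before = pearson_by_level(cohort, respect_exclusions=False)[lvl]
    assert (n_before, n_after) == (4, 3)
    assert r_after == pytest.approx(1.0, abs=1e-12)  # remaining points collinear
    assert r_before < r_after


# ---------------------------------------------------------------------------
# OLS


def test_fit_recovers_exact_line_from_reference_c6_row():
    xs = [60.0, 90.0, 130.0, 180.0]
    cohort = _cohort_from_pairs([(x, 1.138 * x + 80.98) for x in xs])
    cal = fit_level_calibration(cohort, VertebraLevel.parse("C6"))
    assert cal.slope == pytest.approx(1.138, abs=1e-9)
    assert cal.intercept == pytest.approx(80.98, abs=1e-9)
    assert cal.r2 == pytest.approx(1.0, abs=1e-12)
    assert cal.n == 4


def test_ols_matches_normal_equation_oracle_on_small_sets():
    rng = np.random.default_rng(77)
    for trial in range(10):
        n = int(rng.integers(3, 11))
        xs = list(rng.uniform(40, 250, n))
        ys = list(1.1 * np.asarray(xs) + 30 + rng.normal(0, 20, n))
        cohort = _cohort_from_pairs(list(zip(xs, ys)))
        cal = fit_level_calibration(cohort, VertebraLevel.parse("C6"))
        slope, intercept = ols_oracle(xs, ys)
        assert cal.slope == pytest.approx(slope, abs=1e-9)
        assert cal.intercept == pytest.approx(intercept, abs=1e-9)
        assert cal.r == pytest.approx(pearson_oracle(xs, ys), abs=1e-9)


def test_fit_r_equals_pearson_r(default_cohort):
    corr = pearson_by_level(default_cohort)
    cals = fit_all_levels(default_cohort)
    for lvl, cal in cals.items():
        assert cal.r == pytest.approx(corr[lvl][0], abs=1e-12)
        assert cal.n == corr[lvl][1]
        assert cal.r2 == pytest.approx(cal.r**2, abs=1e-12)


def test_fit_rejects_insufficient_or_degenerate_data():
    with pytest.raises(CalibrationError, match="n="):
        fit_level_calibration(
            _cohort_from_pairs([(100, 90), (110, 95)]), VertebraLevel.parse("C6")
        )
    with pytest.raises(CalibrationError, match="variance"):
        fit_level_calibration(
            _cohort_from_pairs([(100, 90), (100, 95), (100, 99)]),
            VertebraLevel.parse("C6"),
        )
    with pytest.raises(CalibrationError, match="reference"):
        fit_level_calibration(_cohort_from_pairs([]), VertebraLevel.parse("L1"))


# ---------------------------------------------------------------------------
# threshold transfer


def test_reference_table_reproduces_all_printed_thresholds():
    """All 36 published one-decimal thresholds follow from slope*cutoff+intercept."""
    table = derive_thresholds(load_reference_calibrations())
    printed = load_reference_thresholds()
    assert len(table.levels()) == 18
    for lvl in table.levels():
        for cat in ("osteoporosis", "osteopenia"):
            assert round_half_up(table.threshold(lvl, cat), 1) == pytest.approx(
                printed.threshold(lvl, cat), abs=0.1
            ), f"{lvl} {cat}"


def test_identity_calibration_maps_cutoff_to_itself():
    lvl = VertebraLevel.parse("T1")
    cal = {lvl: LevelCalibration(lvl, 1.0, 0.0, 1.0, 1.0, 10)}
    table = derive_thresholds(cal)
    assert table.threshold(lvl, "osteoporosis") == pytest.approx(80.0)
    assert table.threshold(lvl, "osteopenia") == pytest.approx(120.0)


def test_threshold_monotone_in_cutoff():
    cals = load_reference_calibrations()
    t_low = derive_thresholds(cals, {"osteoporosis": 70.0, "osteopenia": 110.0})
    t_high = derive_thresholds(cals, {"osteoporosis": 90.0, "osteopenia": 130.0})
    for lvl in cals:
        assert t_low.threshold(lvl, "osteoporosis") < t_high.threshold(lvl, "osteoporosis")
        assert t_low.threshold(lvl, "osteopenia") < t_high.threshold(lvl, "osteopenia")
        assert t_low.threshold(lvl, "osteopenia") > t_low.threshold(lvl, "osteoporosis")


def test_nonpositive_slope_or_low_r2_is_flagged():
    lvl = VertebraLevel.parse("T1")
    bad = {lvl: LevelCalibration(lvl, -0.5, 200.0, -0.7, 0.49, 10)}
    table = derive_thresholds(bad)
    assert lvl in table.unreliable_levels
    weak = {lvl: LevelCalibration(lvl, 0.8, 50.0, 0.4, 0.16, 10)}
    assert lvl in derive_thresholds(weak).unreliable_levels
    good = {lvl: LevelCalibration(lvl, 0.8, 50.0, 0.8, 0.64, 10)}
    assert derive_thresholds(good).unreliable_levels == []


def test_cutoff_validation():
    cals = load_reference_calibrations()
    with pytest.raises(CalibrationError):
        derive_thresholds(cals, {"osteoporosis": 120.0, "osteopenia": 80.0})
    with pytest.raises(CalibrationError):
        derive_thresholds(cals, {"osteoporosis": 80.0})


def test_regional_threshold_summary_with_reference_calibrations():
    table = derive_thresholds(load_reference_calibrations())
    for lvl in table.levels():
        t = table.threshold(lvl, "osteoporosis")
        if lvl.region is Region.CERVICAL:
            assert t >= 150.0
        elif lvl.region is Region.THORACIC:
            assert t <= 125.0


@pytest.mark.parametrize(
    "value,expected", [(99.746, 99.7), (123.348, 123.3), (83.77, 83.8), (121.05, 121.1)]
)
def test_display_rounding_is_half_up(value, expected):
    assert round_half_up(value, 1) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# profile comparison


def _profile(values):
    return {
        lvl: (v, 100)
        for lvl, v in zip(sorted(MEASUREMENT_LEVELS)[: len(values)], values)
    }


def test_identical_profiles_compare_equal():
    prof = _profile([0.8, 0.85, 0.9, 0.7])
    result = compare_correlation_profiles(prof, prof)
    assert result.p_value == pytest.approx(1.0)
    assert result.median_before == result.median_after


def test_uniform_fisher_z_shift_is_detected_and_matches_permutation_oracle():
    rng = np.random.default_rng(3)
    z_before = np.arctanh(rng.uniform(0.7, 0.95, 17))
    z_after = z_before + 0.2 + rng.normal(0, 0.01, 17)  # tiny jitter
    before = _profile(list(np.tanh(z_before)))
    after = _profile(list(np.tanh(z_after)))
    result = compare_correlation_profiles(before, after)
    assert result.p_value < 1e-3
    assert result.median_after > result.median_before
    p_perm = permutation_profile_pvalue(before, after, n_perm=20000, seed=0)
    # sign-flip permutation floor for 17 levels is ~1.5e-5
    assert p_perm < 1e-3


def test_mismatched_level_sets_rejected():
    before = _profile([0.8, 0.85, 0.9])
    after = _profile([0.8, 0.85, 0.9, 0.92])
    with pytest.raises(CalibrationError, match="C5"):
        compare_correlation_profiles(before, after)
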