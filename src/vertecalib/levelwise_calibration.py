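"""Level-wise calibration of cervicothoracic vBMD against the lumbar reference.

The statistical core of the pipeline: for each level C2-T12, ordinary
least squares of the level's trabecular vBMD on the patient's mean L1-L3
vBMD (the lumbar reference) yields a per-level line

    E[vBMD_level] = a * lumbar + b.

Evaluating that line at the lumbar ACR cut-offs (osteoporosis 80 mg/ml,
osteopenia 120 mg/ml) transfers the cut-off to the level:

    threshold_x(level) = a_level * cutoff_x + b_level.

Note the transfer evaluates the fitted line at the cut-off; it does NOT
invert the line (the two differ whenever r^2 < 1).

A bundled reference calibration table derived from a published clinical
cohort ships with the package (see :func:`load_reference_calibrations`).
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .spine_model import (
    Cohort,
    MEASUREMENT_LEVELS,
    Region,
    SpineModelError,
    VertebraLevel,
)

log = logging.getLogger(__name__)


class CalibrationError(ValueError):
    """Raised when a fit or threshold derivation is not possible."""


@dataclass(frozen=True)
class LevelCalibration:
    """Fitted line predicting a level's vBMD from the lumbar reference."""

    level: VertebraLevel
    slope: float
    intercept: float
    r: float
    r2: float
    n: int
    residual_sd: float = float("nan")

    def predict(self, lumbar_vbmd: float) -> float:
        return self.slope * lumbar_vbmd + self.intercept


#: default lumbar cut-offs in mg/ml (ACR): below 80 osteoporosis, below 120 osteopenia
DEFAULT_LUMBAR_CUTOFFS: dict[str, float] = {"osteoporosis": 80.0, "osteopenia": 120.0}

#: minimum r^2 below which a transferred threshold is flagged unreliable
DEFAULT_R2_FLOOR = 0.3


@dataclass
class ThresholdTable:
    """Per-level diagnostic cut-offs plus the lumbar cut-offs they derive from.

    ``thresholds`` maps each calibrated level to
    ``{"osteoporosis": ..., "osteopenia": ...}`` in mg/ml, at full
    precision; display rounding is half-up to one decimal via
    :meth:`to_frame`.  Lumbar levels always carry the lumbar cut-offs
    themselves.
    """

    lumbar_cutoffs: dict[str, float]
    thresholds: dict[VertebraLevel, dict[str, float]]
    calibrations: dict[VertebraLevel, LevelCalibration] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    unreliable_levels: list[VertebraLevel] = field(default_factory=list)

    def threshold(self, level: VertebraLevel, category: str) -> float:
        from .spine_model import LUMBAR_REFERENCE_LEVELS

        if level in LUMBAR_REFERENCE_LEVELS:  # L4/L5 carried but never covered
            return self.lumbar_cutoffs[category]
        try:
            return self.thresholds[level][category]
        except KeyError:
            raise CalibrationError(f"no threshold for level {level}") from None

    def levels(self) -> list[VertebraLevel]:
        return sorted(self.thresholds)

    def to_frame(self, rounded: bool = False) -> pd.DataFrame:
        rows = []
        for lvl in self.levels():
            cal = self.calibrations.get(lvl)
            row = {
                "level": lvl.name,
                "slope": cal.slope if cal else np.nan,
                "intercept": cal.intercept if cal else np.nan,
                "r2": cal.r2 if cal else np.nan,
                "n": cal.n if cal else np.nan,
                "threshold_osteopenia": self.thresholds[lvl]["osteopenia"],
                "threshold_osteoporosis": self.thresholds[lvl]["osteoporosis"],
            }
            if rounded:
                for key in ("threshold_osteopenia", "threshold_osteoporosis"):
                    row[key] = round_half_up(row[key], 1)
            rows.append(row)
        return pd.DataFrame(rows)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero, matching clinical-table formatting."""
    factor = 10.0**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


# ---------------------------------------------------------------------------
# correlation


def pearson_by_level(
    cohort: Cohort, respect_exclusions: bool = True
) -> dict[VertebraLevel, tuple[float, int]]:
    """Per-level Pearson correlation with the lumbar reference.

    The lumbar reference always honours its own QC rule (it is computed
    once by ``cohort_qc``); ``respect_exclusions`` only controls whether
    excluded vertebrae are dropped from the *level* side, which is how
    the before/after-exclusion comparison is defined.

    Levels with fewer than 3 usable patients are omitted with a warning.
    """
    df = cohort.to_frame()
    df = df[df["lumbar_reference"].notna() & df["vbmd"].notna()]
    if respect_exclusions:
        df = df[~(df["excluded_fracture"] | df["excluded_degeneration"])]
    out: dict[VertebraLevel, tuple[float, int]] = {}
    for lvl in MEASUREMENT_LEVELS:
        sub = df[df["level"] == lvl.name]
        n = len(sub)
        if n < 3:
            log.warning("level %s has n=%d < 3 usable patients; r omitted", lvl, n)
            continue
        x = sub["lumbar_reference"].to_numpy(dtype=float)
        y = sub["vbmd"].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            log.warning("level %s has zero variance; r omitted", lvl)
            continue
        r = float(stats.pearsonr(x, y).statistic)
        out[lvl] = (r, n)
    return out


@dataclass(frozen=True)
class ProfileComparison:
    median_before: float
    median_after: float
    p_value: float
    n_levels: int


def compare_correlation_profiles(
    r_before: Mapping[VertebraLevel, tuple[float, int]],
    r_after: Mapping[VertebraLevel, tuple[float, int]],
) -> ProfileComparison:
    """Paired comparison of two per-level correlation profiles.

    Coefficients are Fisher z-transformed and compared with a paired
    two-sided t test across levels; medians of the raw r are reported.
    """
    before_set, after_set = set(r_before), set(r_after)
    if before_set != after_set:
        diff = sorted(lvl.name for lvl in before_set ^ after_set)
        raise CalibrationError(f"correlation profiles cover different levels: {diff}")
    levels = sorted(before_set)
    if len(levels) < 3:
        raise CalibrationError("need at least 3 levels to compare profiles")
    rb = np.array([r_before[lvl][0] for lvl in levels])
    ra = np.array([r_after[lvl][0] for lvl in levels])
    eps = 1e-15  # keep |r| = 1 finite under the z-transform
    zb = np.arctanh(np.clip(rb, -1 + eps, 1 - eps))
    za = np.arctanh(np.clip(ra, -1 + eps, 1 - eps))
    if np.allclose(zb, za):
        p = 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero-variance differences -> nan
            p = float(stats.ttest_rel(za, zb).pvalue)
        if math.isnan(p):  # constant nonzero shift: degenerate, maximally significant
            p = 0.0
    return ProfileComparison(
        median_before=float(np.median(rb)),
        median_after=float(np.median(ra)),
        p_value=p,
        n_levels=len(levels),
    )


def permutation_profile_pvalue(
    r_before: Mapping[VertebraLevel, tuple[float, int]],
    r_after: Mapping[VertebraLevel, tuple[float, int]],
    n_perm: int = 10000,
    seed: int = 0,
) -> float:
    """Sign-flip permutation p-value for the paired Fisher-z comparison.

    Independent cross-check of :func:`compare_correlation_profiles`.
    """
    levels = sorted(set(r_before) & set(r_after))
    d = np.array(
        [np.arctanh(r_after[lvl][0]) - np.arctanh(r_before[lvl][0]) for lvl in levels]
    )
    obs = abs(d.mean())
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, len(d)))
    null = np.abs((signs * d).mean(axis=1))
    return float((np.sum(null >= obs - 1e-15) + 1) / (n_perm + 1))


# ---------------------------------------------------------------------------
# regression


def fit_level_calibration(cohort: Cohort, level: VertebraLevel) -> LevelCalibration:
    """OLS of one level's vBMD on the lumbar reference (exclusions honoured)."""
    if level.region is Region.LUMBAR:
        raise CalibrationError("lumbar levels are the reference, not a target")
    return fit_all_levels(cohort, levels=[level])[level]


def fit_all_levels(
    cohort: Cohort, levels: Optional[list[VertebraLevel]] = None
) -> dict[VertebraLevel, LevelCalibration]:
    """Fit every requested level in one pass over the cohort."""
    if levels is None:
        levels = list(MEASUREMENT_LEVELS)
    df = cohort.to_frame()
    df = df[
        df["lumbar_reference"].notna()
        & df["vbmd"].notna()
        & ~(df["excluded_fracture"] | df["excluded_degeneration"])
    ]
    out: dict[VertebraLevel, LevelCalibration] = {}
    for lvl in levels:
        sub = df[df["level"] == lvl.name]
        n = len(sub)
        if n < 3:
            raise CalibrationError(f"level {lvl}: n={n} < 3 usable patients")
        x = sub["lumbar_reference"].to_numpy(dtype=float)
        y = sub["vbmd"].to_numpy(dtype=float)
        if np.std(x) == 0:
            raise CalibrationError(f"level {lvl}: zero variance in lumbar reference")
        fit = stats.linregress(x, y)
        resid = y - (fit.slope * x + fit.intercept)
        residual_sd = float(np.sqrt(np.sum(resid**2) / (n - 2))) if n > 2 else float("nan")
        out[lvl] = LevelCalibration(
            level=lvl,
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            r=float(fit.rvalue),
            r2=float(fit.rvalue) ** 2,
            n=n,
            residual_sd=residual_sd,
        )
    return out


# ---------------------------------------------------------------------------
# threshold transfer


def derive_thresholds(
    calibrations: Mapping[VertebraLevel, LevelCalibration],
    lumbar_cutoffs: Optional[Mapping[str, float]] = None,
    r2_floor: float = DEFAULT_R2_FLOOR,
    provenance: Optional[dict] = None,
) -> ThresholdTable:
    """Evaluate each level's calibration line at the lumbar cut-offs.

    Levels with non-positive slope or r^2 below ``r2_floor`` are still
    emitted but flagged in ``unreliable_levels`` (the osteopenia >
    osteoporosis ordering is only guaranteed for positive slope).
    """
    cutoffs = dict(DEFAULT_LUMBAR_CUTOFFS if lumbar_cutoffs is None else lumbar_cutoffs)
    if set(cutoffs) != {"osteoporosis", "osteopenia"}:
        raise CalibrationError("lumbar_cutoffs must define osteoporosis and osteopenia")
    if not (0 < cutoffs["osteoporosis"] < cutoffs["osteopenia"]):
        raise CalibrationError(
            "cut-offs must be positive with osteopenia above osteoporosis"
        )
    thresholds: dict[VertebraLevel, dict[str, float]] = {}
    unreliable: list[VertebraLevel] = []
    for lvl, cal in calibrations.items():
        thresholds[lvl] = {
            cat: cal.slope * cutoff + cal.intercept for cat, cutoff in cutoffs.items()
        }
        if cal.slope <= 0 or (not math.isnan(cal.r2) and cal.r2 < r2_floor):
            unreliable.append(lvl)
            log.warning(
                "level %s calibration flagged unreliable (slope=%.4g, r2=%.3g)",
                lvl,
                cal.slope,
                cal.r2,
            )
    return ThresholdTable(
        lumbar_cutoffs=cutoffs,
        thresholds=thresholds,
        calibrations=dict(calibrations),
        provenance=dict(provenance or {}),
        unreliable_levels=sorted(unreliable),
    )


# ---------------------------------------------------------------------------
# bundled reference table


def _reference_frame() -> pd.DataFrame:
    with resources.files("vertecalib.data").joinpath(
        "cervicothoracic_calibration_reference.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def load_reference_calibrations() -> dict[VertebraLevel, LevelCalibration]:
    """Published per-level calibration coefficients (C2-T12).

    Slope/intercept/r^2 come from a clinical cohort of 260 adults; the
    per-level n is not published and is recorded as 0.
    """
    out: dict[VertebraLevel, LevelCalibration] = {}
    for row in _reference_frame().itertuples(index=False):
        lvl = VertebraLevel.parse(row.level)
        r2 = float(row.r2)
        out[lvl] = LevelCalibration(
            level=lvl,
            slope=float(row.slope),
            intercept=float(row.intercept),
            r=math.sqrt(r2),
            r2=r2,
            n=0,
        )
    return out


def load_reference_thresholds() -> ThresholdTable:
    """Bundled threshold table with the published one-decimal cut-offs."""
    thresholds: dict[VertebraLevel, dict[str, float]] = {}
    for row in _reference_frame().itertuples(index=False):
        lvl = VertebraLevel.parse(row.level)
        thresholds[lvl] = {
            "osteopenia": float(row.threshold_osteopenia),
            "osteoporosis": float(row.threshold_osteoporosis),
        }
    return ThresholdTable(
        lumbar_cutoffs=dict(DEFAULT_LUMBAR_CUTOFFS),
        thresholds=thresholds,
        calibrations=load_reference_calibrations(),
        provenance={"source": "bundled reference table"},
    )
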