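"""Exclusion-rule quality control and the per-patient lumbar reference.

Two exclusion rules protect the calibration from structurally abnormal
vertebrae: Genant fracture grade >= 1, and moderate-to-severe
degeneration (grade >= 2).  Exclusion is flag-based — records are never
deleted — so the before/after-exclusion correlation analysis can run on
one cohort object.  The lumbar reference is the mean vBMD over the
QC-surviving L1-L3 vertebrae; a patient whose entire reference region is
excluded has no reference and drops out of the calibration fits.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .spine_model import (
    Cohort,
    LUMBAR_REFERENCE_LEVELS,
    PatientScan,
    SpineModelError,
)

log = logging.getLogger(__name__)

FRACTURE_EXCLUSION_GRADE = 1  # Genant grade >= 1 excluded
DEGENERATION_EXCLUSION_GRADE = 2  # moderate-to-severe degeneration excluded


class QCError(ValueError):
    """Missing grades or degenerate grouping input."""


@dataclass
class QCReport:
    n_vertebrae_total: int = 0
    n_excluded_fracture: int = 0
    n_excluded_degeneration: int = 0
    n_patients_dropped: int = 0  # no usable lumbar reference
    per_level_fracture: dict = field(default_factory=dict)
    per_level_degeneration: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_vertebrae_total": self.n_vertebrae_total,
            "n_excluded_fracture": self.n_excluded_fracture,
            "n_excluded_degeneration": self.n_excluded_degeneration,
            "n_patients_dropped": self.n_patients_dropped,
            "per_level_fracture": dict(sorted(self.per_level_fracture.items())),
            "per_level_degeneration": dict(sorted(self.per_level_degeneration.items())),
        }


def apply_exclusions(
    cohort: Cohort, use_degeneration_rule_for_reference: bool = True
) -> tuple[Cohort, QCReport]:
    """Set exclusion flags, compute lumbar references, tally a QC report.

    Idempotent: flags are recomputed from the grades, so applying twice
    equals applying once.  A record missing either grade is an error
    naming the patient and level (grades are mandatory inputs, never
    assumed 0).
    """
    report = QCReport()
    for scan in cohort.scans:
        for rec in scan.records():
            if rec.fracture_grade is None or rec.degeneration_grade is None:
                raise QCError(
                    f"patient {scan.patient_id}, level {rec.level}: "
                    "fracture and degeneration grades are required"
                )
            report.n_vertebrae_total += 1
            rec.excluded_fracture = rec.fracture_grade >= FRACTURE_EXCLUSION_GRADE
            rec.excluded_degeneration = (
                rec.degeneration_grade >= DEGENERATION_EXCLUSION_GRADE
            )
            if rec.excluded_fracture:
                report.n_excluded_fracture += 1
                report.per_level_fracture[rec.level.name] = (
                    report.per_level_fracture.get(rec.level.name, 0) + 1
                )
            if rec.excluded_degeneration:
                report.n_excluded_degeneration += 1
                report.per_level_degeneration[rec.level.name] = (
                    report.per_level_degeneration.get(rec.level.name, 0) + 1
                )
        scan.lumbar_reference = lumbar_reference(
            scan, use_degeneration_rule=use_degeneration_rule_for_reference
        )
        if scan.lumbar_reference is None:
            report.n_patients_dropped += 1
    log.info(
        "QC: %d vertebrae, %d fracture-excluded, %d degeneration-excluded, "
        "%d patients without lumbar reference",
        report.n_vertebrae_total,
        report.n_excluded_fracture,
        report.n_excluded_degeneration,
        report.n_patients_dropped,
    )
    return cohort, report


def lumbar_reference(
    scan: PatientScan, use_degeneration_rule: bool = True
) -> Optional[float]:
    """Mean vBMD over L1-L3 vertebrae surviving QC; None if none survive.

    Non-fractured is always required; ``use_degeneration_rule`` (default
    on) additionally drops degeneration-excluded vertebrae, applying the
    global exclusion rule to the reference region as well.
    """
    values = []
    for lvl in LUMBAR_REFERENCE_LEVELS:
        rec = scan.vertebrae.get(lvl)
        if rec is None or rec.vbmd is None:
            continue
        if rec.excluded_fracture:
            continue
        if use_degeneration_rule and rec.excluded_degeneration:
            continue
        values.append(rec.vbmd)
    if not values:
        return None
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# group comparisons


@dataclass(frozen=True)
class GroupComparison:
    group_names: tuple[str, str]
    means: tuple[float, float]  # mg/ml
    sds: tuple[float, float]
    ns: tuple[int, int]
    p_value: float  # two-sided Welch t test


AGE_MATCH_CALIPER_YEARS = 5.0


def group_compare(cohort: Cohort, grouping: str) -> GroupComparison:
    """Welch t test on lumbar references between patient groups.

    ``grouping``:
      * ``"fractured-patient"`` — patients with >= 1 fractured vertebra
        vs patients with none;
      * ``"sex-age-matched"`` — women vs men after greedy 1:1
        nearest-age matching within a 5-year caliper (deterministic
        tie-break by patient_id; unknown sex excluded).
    """
    usable = [s for s in cohort.scans if s.lumbar_reference is not None]
    if grouping == "fractured-patient":
        def has_fracture(scan: PatientScan) -> bool:
            return any(
                (r.fracture_grade or 0) >= FRACTURE_EXCLUSION_GRADE
                for r in scan.vertebrae.values()
            )

        a = [s.lumbar_reference for s in usable if has_fracture(s)]
        b = [s.lumbar_reference for s in usable if not has_fracture(s)]
        names = ("fractured", "non_fractured")
    elif grouping == "sex-age-matched":
        women = sorted(
            (s for s in usable if s.sex == "F"), key=lambda s: (s.age, s.patient_id)
        )
        men = sorted(
            (s for s in usable if s.sex == "M"), key=lambda s: (s.age, s.patient_id)
        )
        pairs = _greedy_age_match(women, men, caliper=AGE_MATCH_CALIPER_YEARS)
        a = [w.lumbar_reference for w, _ in pairs]
        b = [m.lumbar_reference for _, m in pairs]
        names = ("women", "men")
    else:
        raise QCError(
            f"unknown grouping {grouping!r}; "
            "expected 'fractured-patient' or 'sex-age-matched'"
        )
    if len(a) < 2 or len(b) < 2:
        raise QCError(
            f"grouping {grouping!r}: need >= 2 patients per group, "
            f"got {len(a)} and {len(b)}"
        )
    a_arr, b_arr = np.asarray(a, float), np.asarray(b, float)
    if np.ptp(a_arr) == 0 and np.ptp(b_arr) == 0 and a_arr.mean() == b_arr.mean():
        p = 1.0  # identical constant groups: no evidence of difference
    else:
        p = float(stats.ttest_ind(a_arr, b_arr, equal_var=False).pvalue)
    return GroupComparison(
        group_names=names,
        means=(float(a_arr.mean()), float(b_arr.mean())),
        sds=(float(a_arr.std(ddof=1)), float(b_arr.std(ddof=1))),
        ns=(len(a), len(b)),
        p_value=p,
    )


def _greedy_age_match(
    women: list[PatientScan], men: list[PatientScan], caliper: float
) -> list[tuple[PatientScan, PatientScan]]:
    """Pair each woman with the closest-age unused man within the caliper.

    Women are processed in (age, patient_id) order; candidate men tie-break
    by patient_id, making the matching fully deterministic.
    """
    available = list(men)
    pairs = []
    for w in women:
        best = None
        best_key = None
        for m in available:
            gap = abs(m.age - w.age)
            if gap > caliper:
                continue
            key = (gap, m.patient_id)
            if best_key is None or key < best_key:
                best, best_key = m, key
        if best is not None:
            pairs.append((w, best))
            available.remove(best)
    return pairs
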