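"""Diagnostic classification of vertebrae and patients.

Boundary convention follows the clinical phrasing "vBMD < cut-off":
strict less-than enters the worse category, equality stays in the
better one.  Three policies are provided:

* ``table2`` — per-level thresholds from a :class:`ThresholdTable`
  (fitted or the bundled reference);
* ``rounded_regional`` — region-constant osteoporosis cut-offs
  (cervical < 200, thoracic < 100, lumbar < 80 mg/ml); it distinguishes
  only osteoporosis vs not-osteoporosis unless the caller supplies
  osteopenia constants;
* ``lumbar_acr`` — the lumbar ACR cut-offs (80/120 mg/ml), defined for
  lumbar levels only.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .levelwise_calibration import ThresholdTable, load_reference_thresholds
from .spine_model import (
    DiagnosticCategory,
    PatientScan,
    Region,
    VertebraLevel,
)


class ClassificationError(ValueError):
    """Level not covered by the policy, or no usable vertebrae."""


REGIONAL_OSTEOPOROSIS_CUTOFFS = {
    Region.CERVICAL: 200.0,
    Region.THORACIC: 100.0,
    Region.LUMBAR: 80.0,
}


@dataclass(frozen=True)
class ClassificationPolicy:
    """A named rule mapping (level, vBMD) to a diagnostic category."""

    name: str
    threshold_table: Optional[ThresholdTable] = None
    regional_osteoporosis: Optional[dict] = None
    regional_osteopenia: Optional[dict] = None

    def cutoffs(self, level: VertebraLevel) -> tuple[float, Optional[float]]:
        """(osteoporosis, osteopenia-or-None) cut-offs for a level."""
        if self.threshold_table is not None:
            try:
                return (
                    self.threshold_table.threshold(level, "osteoporosis"),
                    self.threshold_table.threshold(level, "osteopenia"),
                )
            except Exception:
                raise ClassificationError(
                    f"policy {self.name!r} does not cover level {level}"
                ) from None
        if self.regional_osteoporosis is not None:
            if level.region not in self.regional_osteoporosis:
                raise ClassificationError(
                    f"policy {self.name!r} does not cover region {level.region.value}"
                )
            porosis = self.regional_osteoporosis[level.region]
            penia = (
                self.regional_osteopenia.get(level.region)
                if self.regional_osteopenia
                else None
            )
            return porosis, penia
        raise ClassificationError(f"policy {self.name!r} has no threshold source")

    @staticmethod
    def from_threshold_table(
        table: ThresholdTable, name: str = "table2"
    ) -> "ClassificationPolicy":
        return ClassificationPolicy(name=name, threshold_table=table)

    @staticmethod
    def bundled_table2() -> "ClassificationPolicy":
        return ClassificationPolicy.from_threshold_table(load_reference_thresholds())

    @staticmethod
    def rounded_regional(
        osteopenia: Optional[dict] = None,
    ) -> "ClassificationPolicy":
        return ClassificationPolicy(
            name="rounded_regional",
            regional_osteoporosis=dict(REGIONAL_OSTEOPOROSIS_CUTOFFS),
            regional_osteopenia=dict(osteopenia) if osteopenia else None,
        )

    @staticmethod
    def lumbar_acr() -> "ClassificationPolicy":
        return ClassificationPolicy(
            name="lumbar_acr",
            regional_osteoporosis={Region.LUMBAR: 80.0},
            regional_osteopenia={Region.LUMBAR: 120.0},
        )


def get_policy(name: str, table: Optional[ThresholdTable] = None) -> ClassificationPolicy:
    if name == "table2":
        if table is not None:
            return ClassificationPolicy.from_threshold_table(table)
        return ClassificationPolicy.bundled_table2()
    if name == "rounded_regional":
        return ClassificationPolicy.rounded_regional()
    if name == "lumbar_acr":
        return ClassificationPolicy.lumbar_acr()
    raise ClassificationError(
        f"unknown policy {name!r}; expected table2, rounded_regional or lumbar_acr"
    )


def classify_vertebra(
    vbmd: float, level: VertebraLevel, policy: ClassificationPolicy
) -> DiagnosticCategory:
    """Classify one measured vertebra under a policy (strict-< boundaries)."""
    if vbmd < 0:
        raise ClassificationError("vbmd must be non-negative")
    porosis, penia = policy.cutoffs(level)
    if vbmd < porosis:
        return DiagnosticCategory.OSTEOPOROSIS
    if penia is not None and vbmd < penia:
        return DiagnosticCategory.OSTEOPENIA
    return DiagnosticCategory.NORMAL


def classify_patient(
    scan: PatientScan,
    policy: ClassificationPolicy,
    aggregation: str = "worst",
) -> DiagnosticCategory:
    """Aggregate per-vertebra categories to one per-patient call.

    Excluded (fractured/degenerated) vertebrae never contribute; a scan
    with no usable classified vertebra raises rather than defaulting to
    normal.  ``worst`` takes the most severe category (screening
    stance); ``median-level`` the median of per-level severities.
    """
    categories = []
    for rec in scan.records():
        if rec.excluded or rec.vbmd is None:
            continue
        try:
            categories.append(classify_vertebra(rec.vbmd, rec.level, policy))
        except ClassificationError:
            continue  # level outside the policy's coverage
    if not categories:
        raise ClassificationError(
            f"patient {scan.patient_id}: no usable vertebrae under policy "
            f"{policy.name!r}; unclassifiable"
        )
    severities = sorted(c.severity for c in categories)
    if aggregation == "worst":
        chosen = severities[-1]
    elif aggregation == "median-level":
        chosen = severities[(len(severities) - 1) // 2]
    else:
        raise ClassificationError(
            f"unknown aggregation {aggregation!r}; expected worst or median-level"
        )
    return {c.severity: c for c in DiagnosticCategory}[chosen]


@dataclass(frozen=True)
class PatientClassification:
    patient_id: str
    policy: str
    aggregation: str
    category: DiagnosticCategory
    per_level: dict = field(hash=False, default_factory=dict)  # level name -> category value


def classify_cohort(
    cohort, policy: ClassificationPolicy, aggregation: str = "worst"
) -> list[PatientClassification]:
    """Per-patient report rows; unclassifiable patients are skipped with a note."""
    out = []
    for scan in cohort.scans:
        per_level = {}
        for rec in scan.records():
            if rec.excluded or rec.vbmd is None:
                continue
            try:
                per_level[rec.level.name] = classify_vertebra(
                    rec.vbmd, rec.level, policy
                ).value
            except ClassificationError:
                continue
        try:
            category = classify_patient(scan, policy, aggregation)
        except ClassificationError:
            continue
        out.append(
            PatientClassification(
                patient_id=scan.patient_id,
                policy=policy.name,
                aggregation=aggregation,
                category=category,
                per_level=per_level,
            )
        )
    return out
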