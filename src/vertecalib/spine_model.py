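"""Vertebral-level coordinate system and in-memory domain model.

The study spine spans C2 through T12 for measurement plus L1-L3 as the
lumbar reference region.  C1 (atlas) has no measurable trabecular
vertebral body and is deliberately not representable.  L4 and L5 are
representable so that real-world input tables can be ingested, but they
never enter the lumbar reference.

All vBMD values are trabecular volumetric bone mineral density in
mg hydroxyapatite per ml (mg/ml).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional


class SpineModelError(ValueError):
    """Invalid domain value (unknown level, bad grade, duplicate record...)."""


class Region(str, Enum):
    CERVICAL = "cervical"
    THORACIC = "thoracic"
    LUMBAR = "lumbar"


@dataclass(frozen=True)
class VertebraLevel:
    """A named vertebral level with its craniocaudal rank.

    ``ordinal`` increases strictly from C2 (1) down to L5 (22); the
    region is a pure function of the name.
    """

    name: str
    region: Region
    ordinal: int  # C2 = 1 increasing craniocaudally through L5

    def __lt__(self, other: "VertebraLevel") -> bool:
        return self.ordinal < other.ordinal

    def __le__(self, other: "VertebraLevel") -> bool:
        return self.ordinal <= other.ordinal

    def __str__(self) -> str:  # canonical serialization
        return self.name

    @staticmethod
    def parse(token: str) -> "VertebraLevel":
        """Parse a level name (case-insensitive); reject anything else."""
        key = str(token).strip().upper()
        try:
            return LEVELS[key]
        except KeyError:
            raise SpineModelError(
                f"unknown vertebral level {token!r}; valid levels are C2-C7, T1-T12, L1-L5"
            ) from None


def _build_levels() -> dict[str, VertebraLevel]:
    table: dict[str, VertebraLevel] = {}
    ordinal = 1
    for region, names in (
        (Region.CERVICAL, [f"C{i}" for i in range(2, 8)]),
        (Region.THORACIC, [f"T{i}" for i in range(1, 13)]),
        (Region.LUMBAR, [f"L{i}" for i in range(1, 6)]),
    ):
        for name in names:
            table[name] = VertebraLevel(name, region, ordinal)
            ordinal += 1
    return table


#: All 23 representable levels (C2-C7, T1-T12, L1-L5), keyed by canonical name.
LEVELS: dict[str, VertebraLevel] = _build_levels()

#: Levels calibrated against the lumbar reference (C2..T12, craniocaudal order).
MEASUREMENT_LEVELS: tuple[VertebraLevel, ...] = tuple(
    lvl for lvl in LEVELS.values() if lvl.region is not Region.LUMBAR
)

#: Levels whose (QC-surviving) mean defines the lumbar reference.
LUMBAR_REFERENCE_LEVELS: tuple[VertebraLevel, ...] = (
    LEVELS["L1"],
    LEVELS["L2"],
    LEVELS["L3"],
)


def level_order(a: VertebraLevel, b: VertebraLevel) -> int:
    """Three-way craniocaudal comparison: -1 if a is above b, 0, or 1."""
    return (a.ordinal > b.ordinal) - (a.ordinal < b.ordinal)


def region_of(level: VertebraLevel) -> Region:
    return level.region


class DiagnosticCategory(Enum):
    """Diagnostic bone-status category; ``severity`` orders worst-case logic."""

    NORMAL = "normal"
    OSTEOPENIA = "osteopenia"
    OSTEOPOROSIS = "osteoporosis"

    @property
    def severity(self) -> int:
        return {"normal": 0, "osteopenia": 1, "osteoporosis": 2}[self.value]


_VALID_GRADES = (0, 1, 2, 3)


@dataclass
class VertebraRecord:
    """One vertebra's measurement and QC state.

    ``vbmd`` is the measured (bias-carrying) value used downstream;
    ``true_vbmd`` is populated only by the simulator and holds the
    unbiased latent-model value for validation purposes.
    """

    level: VertebraLevel
    vbmd: Optional[float] = None
    hu: Optional[float] = None
    fracture_grade: Optional[int] = None
    degeneration_grade: Optional[int] = None
    excluded_fracture: bool = False
    excluded_degeneration: bool = False
    true_vbmd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.vbmd is None and self.hu is None:
            raise SpineModelError(
                f"{self.level}: at least one of vbmd, hu must be present"
            )
        if self.vbmd is not None and self.vbmd < 0:
            raise SpineModelError(f"{self.level}: vbmd must be non-negative")
        for label, grade in (
            ("fracture_grade", self.fracture_grade),
            ("degeneration_grade", self.degeneration_grade),
        ):
            if grade is not None and grade not in _VALID_GRADES:
                raise SpineModelError(
                    f"{self.level}: {label} must be in 0..3, got {grade!r}"
                )

    @property
    def excluded(self) -> bool:
        return self.excluded_fracture or self.excluded_degeneration


_VALID_SEX = ("F", "M", "U")


@dataclass
class PatientScan:
    """One patient's CT scan: demographics plus per-level vertebra records."""

    patient_id: str
    age: float
    sex: str
    scanner_id: str = ""
    contrast_phase: str = "none"
    vertebrae: dict[VertebraLevel, VertebraRecord] = field(default_factory=dict)
    lumbar_reference: Optional[float] = None

    def __post_init__(self) -> None:
        if not (18 <= self.age <= 100):
            raise SpineModelError(
                f"patient {self.patient_id}: age {self.age} outside 18..100"
            )
        if self.sex not in _VALID_SEX:
            raise SpineModelError(
                f"patient {self.patient_id}: sex must be one of {_VALID_SEX}"
            )
        for level, rec in self.vertebrae.items():
            if rec.level != level:
                raise SpineModelError(
                    f"patient {self.patient_id}: record keyed {level} carries level {rec.level}"
                )

    def add_record(self, record: VertebraRecord) -> None:
        if record.level in self.vertebrae:
            raise SpineModelError(
                f"patient {self.patient_id}: duplicate level {record.level}"
            )
        self.vertebrae[record.level] = record

    def records(self) -> list[VertebraRecord]:
        """Records in craniocaudal order."""
        return [self.vertebrae[lvl] for lvl in sorted(self.vertebrae)]


@dataclass
class Cohort:
    """A collection of patient scans plus free-form provenance metadata."""

    scans: list[PatientScan]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.patient_id for s in self.scans]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SpineModelError(f"duplicate patient_id(s) in cohort: {dupes}")

    def __len__(self) -> int:
        return len(self.scans)

    def to_frame(self):
        """Long-format pandas DataFrame, one row per vertebra record."""
        import pandas as pd

        rows = []
        for scan in self.scans:
            for rec in scan.records():
                rows.append(
                    (
                        scan.patient_id,
                        scan.age,
                        scan.sex,
                        scan.scanner_id,
                        scan.contrast_phase,
                        rec.level.name,
                        rec.level.region.value,
                        rec.level.ordinal,
                        rec.vbmd,
                        rec.hu,
                        rec.fracture_grade,
                        rec.degeneration_grade,
                        rec.excluded_fracture,
                        rec.excluded_degeneration,
                        scan.lumbar_reference,
                        rec.true_vbmd,
                    )
                )
        return pd.DataFrame(
            rows,
            columns=[
                "patient_id",
                "age",
                "sex",
                "scanner_id",
                "contrast_phase",
                "level",
                "region",
                "ordinal",
                "vbmd",
                "hu",
                "fracture_grade",
                "degeneration_grade",
                "excluded_fracture",
                "excluded_degeneration",
                "lumbar_reference",
                "true_vbmd",
            ],
        )
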