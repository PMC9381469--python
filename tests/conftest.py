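"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid numpy/scipy vectorized routines: plain
Python summation of the textbook formulas, so they cannot share a code
path with the implementation they check.
"""
from __future__ import annotations

import math

import pytest

from vertecalib.cohort_qc import apply_exclusions
from vertecalib.spine_model import (
    Cohort,
    PatientScan,
    VertebraLevel,
    VertebraRecord,
)
from vertecalib.synthetic_cohort import (
    SimulationConfig,
    noiseless_config,
    simulate_cohort,
)


# ---------------------------------------------------------------------------
# oracles


def pearson_oracle(xs, ys):
    """Textbook sum-formula Pearson r."""
    n = len(xs)
    sx = sum(xs)
    sy = sum(ys)
    sxx = sum(x * x for x in xs)
    syy = sum(y * y for y in ys)
    sxy = sum(x * y for x, y in zip(xs, ys))
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    return num / den


def ols_oracle(xs, ys):
    """Normal-equation least squares: returns (slope, intercept)."""
    n = len(xs)
    sx = sum(xs)
    sy = sum(ys)
    sxx = sum(x * x for x in xs)
    sxy = sum(x * y for x, y in zip(xs, ys))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


# ---------------------------------------------------------------------------
# cohort builders


def make_scan(
    patient_id: str,
    levels_vbmd: dict[str, float],
    fracture: dict[str, int] | None = None,
    degeneration: dict[str, int] | None = None,
    age: float = 60.0,
    sex: str = "M",
    **kwargs,
) -> PatientScan:
    """Toy scan with grade-0 defaults everywhere."""
    fracture = fracture or {}
    degeneration = degeneration or {}
    scan = PatientScan(patient_id=patient_id, age=age, sex=sex, **kwargs)
    for name, vbmd in levels_vbmd.items():
        scan.add_record(
            VertebraRecord(
                level=VertebraLevel.parse(name),
                vbmd=vbmd,
                fracture_grade=fracture.get(name, 0),
                degeneration_grade=degeneration.get(name, 0),
            )
        )
    return scan


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Exact linear generation: every level a deterministic line of the latent."""
    cohort = simulate_cohort(noiseless_config(n_patients=260, seed=7))
    apply_exclusions(cohort)
    return cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Study-sized cohort with all nuisance models active, QC applied."""
    cohort = simulate_cohort(SimulationConfig(n_patients=260, seed=20))
    apply_exclusions(cohort)
    return cohort


@pytest.fixture(scope="session")
def big_cohort():
    """Large cohort for distributional checks (placement, bias, correlations)."""
    cohort = simulate_cohort(SimulationConfig(n_patients=20000, seed=1234))
    apply_exclusions(cohort)
    return cohort
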