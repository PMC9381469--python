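"""HU to vBMD conversion and contrast-phase correction.

Scanner-specific HU-to-vBMD lines are phantom-derived configuration,
never built-in constants: there is no universal conversion, so a missing
calibration is an error rather than a silent default.  Contrast
correction is a linear map applied in vBMD space after conversion; the
"none" phase is always the identity.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)


class DensitometryError(ValueError):
    """Missing calibration, unknown phase, or degenerate fit input."""


@dataclass(frozen=True)
class ScannerCalibration:
    """Linear HU->vBMD conversion: vbmd = slope*hu + intercept."""

    scanner_id: str
    slope: float  # (mg/ml) per HU
    intercept: float  # mg/ml

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise DensitometryError(
                f"scanner {self.scanner_id!r}: calibration slope must be > 0"
            )


@dataclass(frozen=True)
class ContrastCorrection:
    """Linear de-enhancement: corrected = slope*measured + intercept."""

    phase: str
    slope: float = 1.0
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.phase == "none" and (self.slope != 1.0 or self.intercept != 0.0):
            raise DensitometryError('phase "none" must be the identity correction')


IDENTITY_CORRECTION = ContrastCorrection(phase="none")


def hu_to_vbmd(hu: float, cal: ScannerCalibration) -> float:
    """Convert HU to trabecular vBMD (mg/ml), truncated at the physical floor 0."""
    return max(cal.slope * hu + cal.intercept, 0.0)


def lookup_calibration(
    scanner_id: str, calibrations: Mapping[str, ScannerCalibration]
) -> ScannerCalibration:
    try:
        return calibrations[scanner_id]
    except KeyError:
        raise DensitometryError(
            f"no HU->vBMD calibration for scanner {scanner_id!r}; "
            f"known scanners: {sorted(calibrations)}"
        ) from None


def correct_contrast(
    vbmd: float, phase: str, corrections: Mapping[str, ContrastCorrection]
) -> float:
    """Apply the phase's linear correction; "none" is always a no-op."""
    if phase == "none":
        return vbmd
    try:
        corr = corrections[phase]
    except KeyError:
        raise DensitometryError(
            f"no contrast correction for phase {phase!r}; "
            f"known phases: {sorted(set(corrections) | {'none'})}"
        ) from None
    out = corr.slope * vbmd + corr.intercept
    if out < 0:
        log.warning(
            "contrast-corrected vBMD %.2f (phase %s) truncated to 0", out, phase
        )
        out = 0.0
    return out


def fit_contrast_correction(
    paired: Sequence[tuple[float, float]], phase: str
) -> ContrastCorrection:
    """OLS line mapping enhanced vBMD to unenhanced reference vBMD.

    ``paired`` holds (enhanced, reference) value pairs for one contrast
    phase; at least 3 pairs with non-zero variance in the enhanced
    values are required.
    """
    if len(paired) < 3:
        raise DensitometryError(
            f"need >= 3 (enhanced, reference) pairs to fit phase {phase!r}, "
            f"got {len(paired)}"
        )
    enhanced = np.asarray([p[0] for p in paired], dtype=float)
    reference = np.asarray([p[1] for p in paired], dtype=float)
    if np.std(enhanced) == 0:
        raise DensitometryError(
            f"zero variance in enhanced values; cannot fit phase {phase!r}"
        )
    fit = stats.linregress(enhanced, reference)
    return ContrastCorrection(
        phase=phase, slope=float(fit.slope), intercept=float(fit.intercept)
    )
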