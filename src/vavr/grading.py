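"""Clinical classification of simulated valve outcomes.

Stenosis severity by peak jet velocity, patient-prosthesis mismatch (PPM)
by indexed effective orifice area, and per-metric normality flags against
healthy-reference percentile bands (3rd/97th).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .errors import InputError

__all__ = [
    "StenosisGrade",
    "PpmClass",
    "PercentileFlag",
    "ReferenceRange",
    "StenosisThresholds",
    "GradedResult",
    "stenosis_grade",
    "ppm_class",
    "percentile_flag",
]


class StenosisGrade(enum.Enum):
    NONE = "none"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"


class PpmClass(enum.Enum):
    NONE = "none"
    MODERATE = "moderate"
    SEVERE = "severe"


class PercentileFlag(enum.Enum):
    NORMAL = "normal"
    ABOVE_P97 = "above_p97"
    BELOW_P3 = "below_p3"


@dataclass(frozen=True)
class StenosisThresholds:
    """Velocity cut points (m/s) for the echo-style severity grades.

    Boundary handling: velocities below ``mild`` are unremarkable;
    [mild, moderate) is mild; [moderate, severe] is moderate; strictly
    above ``severe`` is severe.
    """

    mild: float = 2.5
    moderate: float = 3.0
    severe: float = 4.0


@dataclass(frozen=True)
class ReferenceRange:
    """Healthy-cohort reference band for one flow metric.

    ``direction`` records which tail is pathological ('high' for NFD and
    flow angle, 'low' for WPD); it is informational — flagging itself is
    symmetric about the band.
    """

    metric: str
    median: float
    p3: float
    p97: float
    direction: str = "high"

    def __post_init__(self) -> None:
        if not (self.p3 <= self.median <= self.p97):
            raise InputError(
                f"{self.metric}: require p3 <= median <= p97, got "
                f"({self.p3}, {self.median}, {self.p97})")


@dataclass(frozen=True)
class GradedResult:
    stenosis: StenosisGrade
    ppm: PpmClass | None
    flags: dict[str, PercentileFlag]


def stenosis_grade(vmax: float,
                   thresholds: StenosisThresholds | None = None) -> StenosisGrade:
    """Grade stenosis severity from peak jet velocity (m/s).

    Default cut points: < 2.5 none, [2.5, 3.0) mild, [3.0, 4.0] moderate,
    > 4.0 severe.
    """
    if vmax < 0:
        raise InputError(f"vmax must be non-negative, got {vmax}")
    t = thresholds or StenosisThresholds()
    if vmax < t.mild:
        return StenosisGrade.NONE
    if vmax < t.moderate:
        return StenosisGrade.MILD
    if vmax <= t.severe:
        return StenosisGrade.MODERATE
    return StenosisGrade.SEVERE


def ppm_class(eoa: float, bsa: float) -> PpmClass:
    """Patient-prosthesis mismatch class from indexed EOA.

    iEOA = eoa / bsa (cm²/m²); > 0.85 none, [0.65, 0.85] moderate,
    < 0.65 severe.
    """
    if eoa <= 0 or bsa <= 0:
        raise InputError(f"eoa and bsa must be positive, got ({eoa}, {bsa})")
    ieoa = eoa / bsa
    if ieoa > 0.85:
        return PpmClass.NONE
    if ieoa >= 0.65:
        return PpmClass.MODERATE
    return PpmClass.SEVERE


def percentile_flag(value: float, ref: ReferenceRange) -> PercentileFlag:
    """Flag a metric value against its healthy 3rd-97th percentile band."""
    if value > ref.p97:
        return PercentileFlag.ABOVE_P97
    if value < ref.p3:
        return PercentileFlag.BELOW_P3
    return PercentileFlag.NORMAL
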