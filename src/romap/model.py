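"""Age-stratified ROMA risk scoring.

The Risk of Ovarian Malignancy Algorithm (ROMA) combines serum HE4 and
CA125 into a logistic risk score through a predictive index

    PI = A + w_HE4 * ln(HE4) + w_CA125 * ln(CA125)
    risk% = 100 * exp(PI) / (1 + exp(PI))

The classical algorithm uses two coefficient sets selected by menopausal
status.  The age-stratified variant implemented here ("ROMA P") replaces
the menopausal dichotomy with eight age intervals (W1: <=20 y ... W8:
>=81 y) whose coefficient triples step linearly from the youngest to the
oldest set, so that a single risk cutoff can be applied to the whole
population.  The eight triples are stored as published constants; the
linear construction is exposed separately as a generator/verifier and is
never re-run at scoring time.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "MenopausalStatus",
    "Label",
    "Algorithm",
    "RiskClass",
    "PatientRecord",
    "AgeStratum",
    "CoefficientSet",
    "RiskScore",
    "STRATA",
    "ROMA_P_COEFFICIENTS",
    "PREMENOPAUSAL_COEFFICIENTS",
    "POSTMENOPAUSAL_COEFFICIENTS",
    "DEFAULT_CUTOFF_ROMA_P",
    "DEFAULT_CUTOFF_ROMA_PRE",
    "DEFAULT_CUTOFF_ROMA_POST",
    "HE4_ASSAY_FLOOR",
    "CA125_ASSAY_FLOOR",
    "age_stratum_for",
    "coefficients_for_stratum",
    "interpolate_coefficients",
    "predictive_index",
    "risk_percent",
    "score_roma_p",
    "score_roma_standard",
    "classify",
    "default_cutoff",
]


class MenopausalStatus(str, enum.Enum):
    PRE = "pre"
    POST = "post"
    UNKNOWN = "unknown"


class Label(str, enum.Enum):
    MALIGNANT = "malignant"
    BENIGN = "benign"


class Algorithm(str, enum.Enum):
    ROMA_STANDARD = "roma"
    ROMA_P = "roma-p"


class RiskClass(str, enum.Enum):
    HIGH = "high_risk"
    LOW = "low_risk"


# Assay detection floors (pmol/l, U/ml). Values below these are accepted
# but flagged: they are outside the quantification range of the assays the
# score was built on, not physically impossible.
HE4_ASSAY_FLOOR = 15.0
CA125_ASSAY_FLOOR = 1.0

DEFAULT_CUTOFF_ROMA_P = 23.5
DEFAULT_CUTOFF_ROMA_PRE = 14.1
DEFAULT_CUTOFF_ROMA_POST = 25.0


@dataclass(frozen=True)
class PatientRecord:
    """One subject: age (years), menopausal status, HE4 (pmol/l),
    CA125 (U/ml) and an optional histopathology label."""

    id: str
    age: float
    menopausal_status: MenopausalStatus
    he4: float
    ca125: float
    label: Optional[Label] = None

    def __post_init__(self) -> None:
        for name, value in (("age", self.age), ("he4", self.he4), ("ca125", self.ca125)):
            if not math.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be positive and finite, got {value!r}")
        if self.he4 < HE4_ASSAY_FLOOR:
            warnings.warn(
                f"HE4 = {self.he4} pmol/l is below the assay detection floor "
                f"({HE4_ASSAY_FLOOR}); value used as given",
                stacklevel=2,
            )
        if self.ca125 < CA125_ASSAY_FLOOR:
            warnings.warn(
                f"CA125 = {self.ca125} U/ml is below the assay detection floor "
                f"({CA125_ASSAY_FLOOR}); value used as given",
                stacklevel=2,
            )


@dataclass(frozen=True)
class AgeStratum:
    """One of the eight age intervals W1..W8.

    ``age_high`` is ``None`` for the open-ended oldest stratum.  Bounds are
    inclusive integer years; fractional ages floor before lookup.
    """

    index: int
    label: str
    age_low: int
    age_high: Optional[int]

    def contains(self, age: float) -> bool:
        years = math.floor(age)
        if self.age_high is None:
            return years >= self.age_low
        return self.age_low <= years <= self.age_high


@dataclass(frozen=True)
class CoefficientSet:
    """Intercept and ln-marker weights of the predictive index."""

    A: float
    w_he4: float
    w_ca125: float

    def __post_init__(self) -> None:
        if not (self.w_he4 >= 0 and self.w_ca125 >= 0):
            raise ValueError("marker weights must be non-negative")


@dataclass(frozen=True)
class RiskScore:
    pi: float
    percent: float
    algorithm: Algorithm
    stratum_or_group: str


# Any positive age <= 20 maps to W1 (lower bound 0 with the age > 0 domain).
STRATA: tuple[AgeStratum, ...] = (
    AgeStratum(1, "W1", 0, 20),
    AgeStratum(2, "W2", 21, 30),
    AgeStratum(3, "W3", 31, 40),
    AgeStratum(4, "W4", 41, 50),
    AgeStratum(5, "W5", 51, 60),
    AgeStratum(6, "W6", 61, 70),
    AgeStratum(7, "W7", 71, 80),
    AgeStratum(8, "W8", 81, None),
)

# Published per-stratum triples (A, w_he4, w_ca125), stored exactly as
# printed.  They equal, to printed precision, the linear interpolation
# between the W1 and W8 endpoints (see interpolate_coefficients), but the
# printed values — with their mixed rounding — are authoritative at runtime.
ROMA_P_COEFFICIENTS: dict[int, CoefficientSet] = {
    1: CoefficientSet(-12.00, 2.38, 0.063),
    2: CoefficientSet(-11.44, 2.19, 0.158),
    3: CoefficientSet(-10.88, 2.00, 0.254),
    4: CoefficientSet(-10.32, 1.81, 0.349),
    5: CoefficientSet(-9.77, 1.61, 0.445),
    6: CoefficientSet(-9.21, 1.42, 0.541),
    7: CoefficientSet(-8.65, 1.23, 0.636),
    8: CoefficientSet(-8.09, 1.04, 0.732),
}

# The standard (menopause-dichotomized) comparator uses the two endpoint
# sets, which coincide with the youngest/oldest age-stratum triples.
PREMENOPAUSAL_COEFFICIENTS = ROMA_P_COEFFICIENTS[1]
POSTMENOPAUSAL_COEFFICIENTS = ROMA_P_COEFFICIENTS[8]


def age_stratum_for(age: float) -> AgeStratum:
    """Map a positive age in years to its unique stratum W1..W8."""
    if not (isinstance(age, (int, float)) and math.isfinite(age) and age > 0):
        raise ValueError(f"age must be positive and finite, got {age!r}")
    years = math.floor(age)
    if years <= 20:
        return STRATA[0]
    if years >= 81:
        return STRATA[7]
    # interior decades: 21-30 -> W2, ..., 71-80 -> W7
    return STRATA[(years - 21) // 10 + 1]


def coefficients_for_stratum(stratum: AgeStratum | int) -> CoefficientSet:
    """Published coefficient triple for an age stratum (index 1..8)."""
    index = stratum.index if isinstance(stratum, AgeStratum) else int(stratum)
    try:
        return ROMA_P_COEFFICIENTS[index]
    except KeyError:
        raise ValueError(f"stratum index must be 1..8, got {index}") from None


def interpolate_coefficients(
    endpoint_young: CoefficientSet,
    endpoint_old: CoefficientSet,
    n_strata: int = 8,
) -> list[CoefficientSet]:
    """Step component-wise linearly from the youngest to the oldest triple.

    This is the construction behind the published table: with the endpoints
    (-12, 2.38, 0.063) and (-8.09, 1.04, 0.732) and ``n_strata=8`` it
    reproduces every printed coefficient within 0.001 absolute.
    """
    if n_strata < 2:
        raise ValueError(f"n_strata must be >= 2, got {n_strata}")
    steps = n_strata - 1
    out = []
    for k in range(n_strata):
        f = k / steps
        out.append(
            CoefficientSet(
                endpoint_young.A + f * (endpoint_old.A - endpoint_young.A),
                endpoint_young.w_he4 + f * (endpoint_old.w_he4 - endpoint_young.w_he4),
                endpoint_young.w_ca125 + f * (endpoint_old.w_ca125 - endpoint_young.w_ca125),
            )
        )
    return out


def predictive_index(he4: float, ca125: float, coeffs: CoefficientSet) -> float:
    """PI = A + w_he4*ln(HE4) + w_ca125*ln(CA125), natural logarithm."""
    if not (math.isfinite(he4) and he4 > 0):
        raise ValueError(f"he4 must be positive, got {he4!r}")
    if not (math.isfinite(ca125) and ca125 > 0):
        raise ValueError(f"ca125 must be positive, got {ca125!r}")
    return coeffs.A + coeffs.w_he4 * math.log(he4) + coeffs.w_ca125 * math.log(ca125)


def risk_percent(pi: float) -> float:
    """Logistic transform of the predictive index onto the 0-100 scale.

    Evaluated in the overflow-safe branch form, so it is finite for any
    finite PI; extreme indices are clamped to the nearest representable
    value inside the open interval (0, 100) to keep the range contract.
    """
    if not math.isfinite(pi):
        raise ValueError(f"predictive index must be finite, got {pi!r}")
    if pi >= 0:
        return min(100.0 / (1.0 + math.exp(-pi)), math.nextafter(100.0, 0.0))
    e = math.exp(pi)
    return max(100.0 * e / (1.0 + e), math.nextafter(0.0, 1.0))


def score_roma_p(patient: PatientRecord) -> RiskScore:
    """Age-stratified risk score: stratum lookup, published coefficients,
    predictive index, logistic transform.  Menopausal status is ignored."""
    stratum = age_stratum_for(patient.age)
    coeffs = coefficients_for_stratum(stratum)
    pi = predictive_index(patient.he4, patient.ca125, coeffs)
    return RiskScore(pi, risk_percent(pi), Algorithm.ROMA_P, stratum.label)


def score_roma_standard(patient: PatientRecord) -> RiskScore:
    """Menopause-dichotomized comparator: premenopausal patients scored
    with the youngest-stratum triple, postmenopausal with the oldest."""
    status = MenopausalStatus(patient.menopausal_status)
    if status is MenopausalStatus.PRE:
        coeffs, group = PREMENOPAUSAL_COEFFICIENTS, "premenopausal"
    elif status is MenopausalStatus.POST:
        coeffs, group = POSTMENOPAUSAL_COEFFICIENTS, "postmenopausal"
    else:
        raise ValueError(
            "menopausal status is unknown: supply pre/post status or use the "
            "age-stratified scorer (score_roma_p), which does not need it"
        )
    pi = predictive_index(patient.he4, patient.ca125, coeffs)
    return RiskScore(pi, risk_percent(pi), Algorithm.ROMA_STANDARD, group)


def classify(score: RiskScore | float, cutoff: float, *, equal_is_high: bool = True) -> RiskClass:
    """Dichotomize a risk percentage at a cutoff.

    A score equal to the cutoff is classified high-risk by default
    (screening favours sensitivity at the boundary); set
    ``equal_is_high=False`` for the strict-inequality convention.
    """
    if not (0 < cutoff < 100):
        raise ValueError(f"cutoff must be in (0, 100), got {cutoff!r}")
    percent = score.percent if isinstance(score, RiskScore) else float(score)
    high = percent >= cutoff if equal_is_high else percent > cutoff
    return RiskClass.HIGH if high else RiskClass.LOW


def default_cutoff(algorithm: Algorithm, status: MenopausalStatus | None = None) -> float:
    """Published cutoffs: 23.5 % for the age-stratified score on the whole
    population; 14.1 % / 25 % pre/post for the standard comparator."""
    if Algorithm(algorithm) is Algorithm.ROMA_P:
        return DEFAULT_CUTOFF_ROMA_P
    status = MenopausalStatus(status) if status is not None else MenopausalStatus.UNKNOWN
    if status is MenopausalStatus.PRE:
        return DEFAULT_CUTOFF_ROMA_PRE
    if status is MenopausalStatus.POST:
        return DEFAULT_CUTOFF_ROMA_POST
    raise ValueError("standard ROMA cutoff requires pre/post menopausal status")
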