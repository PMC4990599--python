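"""Seeded synthetic ovarian-tumor cohort generator.

Emulates the statistical structure of a 413-patient case-control cohort
(162 malignant / 251 benign): per-class age-interval frequencies, log-normal
HE4 and CA125 levels with class- and age-stratum-specific medians and
dispersions, an age-increasing benign HE4 trend (about +40 % by the seventh
decade relative to the youngest stratum), and menopausal status derived from
age.  It produces data with the right group separations and skew for
exercising the scoring and evaluation pipeline; it does not reproduce any
real per-patient data.

Dispersions are set by matching the printed min-max spans of each marker
cell to the central ~99 % mass of a log-normal (so sigma =
ln(max/min) / (2 * 2.576)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import Label, MenopausalStatus, PatientRecord, STRATA

__all__ = [
    "MarkerModel",
    "StratumMarkers",
    "CohortSpec",
    "default_spec",
    "generate",
    "POSTMENOPAUSE_AGE",
]

# Menopause assigned deterministically from age; 51 is the usual median age
# at natural menopause.
POSTMENOPAUSE_AGE = 51

# Age sampling bounds for the open-ended strata.
_W1_MIN_AGE = 16
_W8_MAX_AGE = 90


@dataclass(frozen=True)
class MarkerModel:
    """Log-normal marker: ln(level) ~ Normal(ln(median), sigma^2)."""

    median: float
    sigma: float

    def __post_init__(self) -> None:
        if self.median <= 0 or self.sigma <= 0:
            raise ValueError("median and sigma must be positive")


@dataclass(frozen=True)
class StratumMarkers:
    he4: MarkerModel
    ca125: MarkerModel


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of one synthetic cohort."""

    n_malignant: int
    n_benign: int
    age_weights: dict[Label, tuple[float, ...]]
    marker_params: dict[tuple[Label, int], StratumMarkers]
    he4_age_drift: float = 0.4
    marker_log_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_malignant < 0 or self.n_benign < 0:
            raise ValueError("group sizes must be non-negative")
        if not -1 < self.marker_log_correlation < 1:
            raise ValueError("marker_log_correlation must be in (-1, 1)")
        for label, w in self.age_weights.items():
            w = np.asarray(w, dtype=float)
            if len(w) != len(STRATA) or np.any(w < 0) or not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
                raise ValueError(f"age weights for {label} must be 8 non-negative values summing to 1")
            for s in STRATA:
                if w[s.index - 1] > 0 and (label, s.index) not in self.marker_params:
                    raise ValueError(f"no marker parameters for populated cell ({label}, {s.label})")


def _sigma_from_range(lo: float, hi: float) -> float:
    # min-max span ~ central 99 % mass of the log-normal
    return math.log(hi / lo) / (2 * 2.576)


# (median, min, max) per marker and populated (class, stratum) cell, on the
# scale of a skewed case-control cohort: malignant CA125 medians in the
# hundreds of U/ml rising with age, benign CA125 in the tens, malignant HE4
# climbing past 400 pmol/l in older strata.
_MALIGNANT_CELLS: dict[int, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    # stratum: (CA125 (median, lo, hi), HE4 (median, lo, hi))
    2: ((55.2, 27.0, 135.1), (45.4, 44.1, 103.9)),
    3: ((403.6, 98.1, 1252.0), (95.4, 15.0, 464.8)),
    4: ((265.4, 14.0, 4638.8), (92.9, 15.0, 1500.0)),
    5: ((500.0, 9.0, 5887.0), (439.3, 12.0, 1655.0)),
    6: ((233.3, 9.8, 7459.1), (334.5, 22.0, 9264.0)),
    7: ((839.0, 21.0, 5659.0), (658.4, 37.0, 8160.0)),
    8: ((777.5, 66.9, 3724.0), (871.2, 85.8, 4940.0)),
}
_BENIGN_CA125_CELLS: dict[int, tuple[float, float, float]] = {
    1: (16.0, 4.1, 274.8),
    2: (28.1, 7.7, 377.0),
    3: (32.3, 7.1, 191.5),
    4: (21.6, 5.5, 168.8),
    5: (12.4, 3.2, 82.1),
    6: (15.9, 6.7, 79.8),
    7: (9.55, 6.3, 52.7),
    8: (9.5, 6.0, 50.0),  # sparsest cell (one subject expected); extrapolated
}
# Benign HE4 dispersion spans per stratum (lo, hi); W8 reuses W7.
_BENIGN_HE4_SPANS: dict[int, tuple[float, float]] = {
    1: (24.2, 84.7),
    2: (26.3, 80.4),
    3: (31.7, 86.7),
    4: (17.8, 74.2),
    5: (27.5, 85.1),
    6: (47.1, 206.5),
    7: (52.0, 186.0),
    8: (52.0, 186.0),
}
_BENIGN_HE4_YOUNG_MEDIAN = 41.5  # pmol/l, youngest benign stratum

# Per-class age-interval counts of the emulated cohort (W1..W8).
_MALIGNANT_STRATUM_COUNTS = (0, 3, 7, 28, 47, 43, 25, 9)
_BENIGN_STRATUM_COUNTS = (38, 55, 73, 48, 22, 10, 4, 1)


def _benign_he4_median(stratum: int, drift: float) -> float:
    """Benign HE4 rises roughly linearly with age stratum: +drift (e.g. 40 %)
    relative to the youngest stratum by stratum 6, continuing beyond."""
    return _BENIGN_HE4_YOUNG_MEDIAN * (1.0 + drift * (stratum - 1) / 5.0)


def default_spec(seed: int = 0, *, he4_age_drift: float = 0.4) -> CohortSpec:
    """Cohort spec emulating the study conditions: 162 malignant / 251
    benign, the per-class age-interval frequencies above, and log-normal
    markers parameterized per (class, stratum)."""
    params: dict[tuple[Label, int], StratumMarkers] = {}
    for s, ((ca_m, ca_lo, ca_hi), (he_m, he_lo, he_hi)) in _MALIGNANT_CELLS.items():
        params[(Label.MALIGNANT, s)] = StratumMarkers(
            he4=MarkerModel(he_m, _sigma_from_range(he_lo, he_hi)),
            ca125=MarkerModel(ca_m, _sigma_from_range(ca_lo, ca_hi)),
        )
    for s in range(1, 9):
        ca_m, ca_lo, ca_hi = _BENIGN_CA125_CELLS[s]
        he_lo, he_hi = _BENIGN_HE4_SPANS[s]
        params[(Label.BENIGN, s)] = StratumMarkers(
            he4=MarkerModel(_benign_he4_median(s, he4_age_drift), _sigma_from_range(he_lo, he_hi)),
            ca125=MarkerModel(ca_m, _sigma_from_range(ca_lo, ca_hi)),
        )
    weights = {
        Label.MALIGNANT: tuple(c / sum(_MALIGNANT_STRATUM_COUNTS) for c in _MALIGNANT_STRATUM_COUNTS),
        Label.BENIGN: tuple(c / sum(_BENIGN_STRATUM_COUNTS) for c in _BENIGN_STRATUM_COUNTS),
    }
    return CohortSpec(
        n_malignant=162,
        n_benign=251,
        age_weights=weights,
        marker_params=params,
        he4_age_drift=he4_age_drift,
        seed=seed,
    )


def _age_bounds(stratum_index: int) -> tuple[int, int]:
    s = STRATA[stratum_index - 1]
    low = _W1_MIN_AGE if s.index == 1 else s.age_low
    high = _W8_MAX_AGE if s.age_high is None else s.age_high
    return low, high


def generate(spec: CohortSpec, seed: Optional[int] = None) -> list[PatientRecord]:
    """Draw one cohort.  Deterministic for a fixed spec and seed.

    Ages are drawn per the stratum weights, then uniformly (integer years)
    within the stratum; menopausal status is post iff age >= 51; HE4 and
    CA125 are drawn log-normally from the cell parameters, optionally with
    correlated log-levels.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rho = spec.marker_log_correlation
    records: list[PatientRecord] = []
    for label, n, prefix in (
        (Label.MALIGNANT, spec.n_malignant, "M"),
        (Label.BENIGN, spec.n_benign, "B"),
    ):
        if n == 0:
            continue
        w = np.asarray(spec.age_weights[label], dtype=float)
        strata = rng.choice(len(STRATA), size=n, p=w) + 1
        z1 = rng.standard_normal(n)
        z2 = rho * z1 + math.sqrt(1 - rho * rho) * rng.standard_normal(n)
        for i in range(n):
            s = int(strata[i])
            low, high = _age_bounds(s)
            age = int(rng.integers(low, high + 1))
            cell = spec.marker_params[(label, s)]
            he4 = cell.he4.median * math.exp(cell.he4.sigma * z1[i])
            ca125 = cell.ca125.median * math.exp(cell.ca125.sigma * z2[i])
            status = MenopausalStatus.POST if age >= POSTMENOPAUSE_AGE else MenopausalStatus.PRE
            records.append(
                PatientRecord(
                    id=f"{prefix}{i + 1:04d}",
                    age=age,
                    menopausal_status=status,
                    he4=he4,
                    ca125=ca125,
                    label=label,
                )
            )
    return records
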