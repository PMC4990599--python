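"""Nonparametric two-sample comparison (Mann-Whitney U).

Used for the group contrasts of marker levels and risk scores between
patient subgroups.  Small tie-free samples (pooled n <= 20) are tested by
exact enumeration of the rank distribution; larger or tied samples use the
normal approximation with midranks, tie-corrected variance and a
continuity correction.  P-values come from scipy's implementation; the U
statistic and the standardized z are computed here so callers get the full
test result in one object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["TwoSampleResult", "mann_whitney"]

EXACT_MAX_POOLED_N = 20


@dataclass(frozen=True)
class TwoSampleResult:
    u_statistic: float
    z: float
    p: float
    n1: int
    n2: int
    method: str


def _tie_corrected_z(u: float, x: np.ndarray, y: np.ndarray) -> float:
    """Standardized U with midrank tie correction and continuity correction."""
    n1, n2 = len(x), len(y)
    nt = n1 + n2
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((nt + 1) - tie_term / (nt * (nt - 1)))
    if var <= 0:  # all observations tied
        return 0.0
    mu = n1 * n2 / 2.0
    diff = u - mu
    cc = 0.5 * math.copysign(1.0, diff) if diff != 0 else 0.0
    return (diff - cc) / math.sqrt(var)


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    *,
    alternative: str = "two-sided",
    method: str = "auto",
) -> TwoSampleResult:
    """Mann-Whitney U test of ``x`` against ``y``.

    ``method`` is "exact", "asymptotic" or "auto" (exact for tie-free pooled
    samples of at most 20, asymptotic otherwise).  The reported U counts
    pairs where an x-observation exceeds a y-observation, ties 1/2, so
    U_x + U_y = n1*n2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if method == "auto":
        has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = "exact" if (len(x) + len(y) <= EXACT_MAX_POOLED_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    u = float(res.statistic)
    return TwoSampleResult(
        u_statistic=u,
        z=_tie_corrected_z(u, x, y),
        p=float(res.pvalue),
        n1=len(x),
        n2=len(y),
        method=method,
    )
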