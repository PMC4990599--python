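"""CSV input/output, batch scoring tables and evaluation reports.

The interchange format is a plain UTF-8 CSV with header columns
``id, age, menopausal_status, he4_pmol_l, ca125_u_ml`` and an optional
``label`` column (``malignant``/``benign``).  Rows that cannot be scored
(missing or non-positive markers, unparseable age) are rejected
individually with a reason rather than failing the file.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import diagnostics, model
from .model import Algorithm, Label, MenopausalStatus, PatientRecord

__all__ = [
    "REQUIRED_COLUMNS",
    "RejectedRow",
    "read_cohort",
    "write_cohort",
    "score_table",
    "evaluate_cohort",
    "compare_markers",
]

REQUIRED_COLUMNS = ("id", "age", "menopausal_status", "he4_pmol_l", "ca125_u_ml")
MARKER_NAMES = ("CA125", "HE4", "ROMA", "ROMA P")


@dataclass(frozen=True)
class RejectedRow:
    row: int  # 0-based data-row index
    reason: str


def _parse_positive(raw: object, what: str) -> float:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() == "":
        raise ValueError(f"missing {what}")
    try:
        value = float(str(raw).strip())
    except ValueError:
        raise ValueError(f"unparseable {what}") from None
    if not math.isfinite(value) or value <= 0:
        raise ValueError(f"non-positive {what}")
    return value


def read_cohort(path: str | Path) -> tuple[list[PatientRecord], list[RejectedRow]]:
    """Parse a cohort CSV into records plus a row-level rejection report."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    has_label = "label" in frame.columns
    records: list[PatientRecord] = []
    rejected: list[RejectedRow] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        row = row._asdict()
        try:
            age = _parse_positive(row["age"], "age")
            he4 = _parse_positive(row["he4_pmol_l"], "marker HE4")
            ca125 = _parse_positive(row["ca125_u_ml"], "marker CA125")
            raw_status = str(row["menopausal_status"]).strip().lower() or "unknown"
            status = MenopausalStatus(raw_status)
            label: Optional[Label] = None
            if has_label and str(row["label"]).strip():
                label = Label(str(row["label"]).strip().lower())
        except ValueError as exc:
            rejected.append(RejectedRow(row=i, reason=str(exc)))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # assay-floor flags handled at scoring
            records.append(
                PatientRecord(
                    id=str(row["id"]) or f"row{i}",
                    age=age,
                    menopausal_status=status,
                    he4=he4,
                    ca125=ca125,
                    label=label,
                )
            )
    return records, rejected


def cohort_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "age": [r.age for r in records],
            "menopausal_status": [r.menopausal_status.value for r in records],
            "he4_pmol_l": [r.he4 for r in records],
            "ca125_u_ml": [r.ca125 for r in records],
            "label": [r.label.value if r.label else "" for r in records],
        }
    )


def write_cohort(records: Sequence[PatientRecord], path: str | Path) -> None:
    cohort_frame(records).to_csv(path, index=False)


def score_table(
    records: Sequence[PatientRecord],
    algorithm: str = "both",
    *,
    cutoff_roma_p: float = model.DEFAULT_CUTOFF_ROMA_P,
    cutoff_pre: float = model.DEFAULT_CUTOFF_ROMA_PRE,
    cutoff_post: float = model.DEFAULT_CUTOFF_ROMA_POST,
) -> pd.DataFrame:
    """Per-patient risk table for one or both algorithms.

    Standard-ROMA columns are left empty for patients of unknown menopausal
    status; the age-stratified score is defined for everyone.
    """
    if algorithm not in {"roma", "roma-p", "both"}:
        raise ValueError(f"algorithm must be roma, roma-p or both, got {algorithm!r}")
    out = cohort_frame(records)
    if algorithm in {"roma-p", "both"}:
        scores = [model.score_roma_p(r) for r in records]
        out["roma_p_pi"] = [s.pi for s in scores]
        out["roma_p_percent"] = [s.percent for s in scores]
        out["stratum"] = [s.stratum_or_group for s in scores]
        out["roma_p_class"] = [model.classify(s, cutoff_roma_p).value for s in scores]
    if algorithm in {"roma", "both"}:
        pi, pct, grp, cls = [], [], [], []
        for r in records:
            if r.menopausal_status is MenopausalStatus.UNKNOWN:
                pi.append(np.nan), pct.append(np.nan), grp.append(""), cls.append("")
                continue
            s = model.score_roma_standard(r)
            cutoff = cutoff_pre if r.menopausal_status is MenopausalStatus.PRE else cutoff_post
            pi.append(s.pi), pct.append(s.percent), grp.append(s.stratum_or_group)
            cls.append(model.classify(s, cutoff).value)
        out["roma_pi"] = pi
        out["roma_percent"] = pct
        out["roma_group"] = grp
        out["roma_class"] = cls
    return out


def _subset_masks(records: Sequence[PatientRecord]) -> dict[str, np.ndarray]:
    status = np.array([r.menopausal_status.value for r in records])
    strata = np.array([model.age_stratum_for(r.age).label for r in records])
    masks = {
        "all": np.ones(len(records), dtype=bool),
        "premenopausal": status == "pre",
        "postmenopausal": status == "post",
    }
    for s in model.STRATA:
        masks[s.label] = strata == s.label
    return masks


def _evaluate_subset(scores: np.ndarray, labels: np.ndarray, called: np.ndarray) -> dict:
    pos = int(np.sum(labels))
    neg = int(len(labels) - pos)
    entry: dict = {"n": len(labels), "n_malignant": pos, "n_benign": neg}
    # count through the per-patient high-risk calls so subsets with mixed
    # (pre/post) cutoffs still produce additive confusion tables
    table = diagnostics.confusion_at_cutoff(called.astype(float), labels, 0.5)
    entry["confusion"] = {"tp": table.tp, "fp": table.fp, "tn": table.tn, "fn": table.fn}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        entry.update(diagnostics.metrics(table))
    if pos >= 2 and neg >= 2:
        d = diagnostics.delong_variance(scores, labels)
        entry["auc"] = d["auc"]
        entry["se_auc"] = d["se_auc"]
        entry["ci_auc"] = list(d["ci_auc"])
    elif pos >= 1 and neg >= 1:
        entry["auc"] = diagnostics.roc_curve(scores, labels).auc
    return entry


def evaluate_cohort(
    records: Sequence[PatientRecord],
    algorithm: str = "roma-p",
    cutoff: Optional[float] = None,
) -> dict:
    """Subset-wise diagnostic report (all / pre / post / per-stratum).

    Each subset gets its confusion table and metrics at the algorithm's
    cutoff plus AUC with DeLong SE/CI where the subset holds both classes.
    For the standard comparator the pre/post cutoffs are applied per
    patient and unknown-status patients are excluded.
    """
    labelled = [r for r in records if r.label is not None]
    if not labelled:
        raise ValueError("evaluation requires labelled records")
    if algorithm == "roma-p":
        kept = labelled
        scores = np.array([model.score_roma_p(r).percent for r in kept])
        cutoffs = np.full(len(kept), model.DEFAULT_CUTOFF_ROMA_P if cutoff is None else cutoff)
    elif algorithm == "roma":
        kept = [r for r in labelled if r.menopausal_status is not MenopausalStatus.UNKNOWN]
        if not kept:
            raise ValueError("standard ROMA evaluation requires pre/post menopausal status")
        scores = np.array([model.score_roma_standard(r).percent for r in kept])
        if cutoff is None:
            cutoffs = np.array(
                [
                    model.default_cutoff(Algorithm.ROMA_STANDARD, r.menopausal_status)
                    for r in kept
                ]
            )
        else:
            cutoffs = np.full(len(kept), cutoff)
    else:
        raise ValueError(f"algorithm must be roma or roma-p, got {algorithm!r}")
    is_pos = np.array([r.label is Label.MALIGNANT for r in kept])
    called = scores >= cutoffs
    report: dict = {"algorithm": algorithm, "n_scored": len(kept)}
    subsets = {}
    for name, mask in _subset_masks(kept).items():
        if not mask.any():
            continue
        entry = _evaluate_subset(scores[mask], is_pos[mask], called[mask])
        uniq = np.unique(cutoffs[mask])
        entry["cutoff"] = float(uniq[0]) if len(uniq) == 1 else uniq.tolist()
        subsets[name] = entry
    report["subsets"] = subsets
    return report


def evaluation_frame(report: dict) -> pd.DataFrame:
    """Flatten an evaluation report to one row per subset, percentages to
    one decimal as in clinical tables (full precision stays in the JSON)."""
    rows = []
    for name, e in report["subsets"].items():
        rows.append(
            {
                "subset": name,
                "n": e["n"],
                "n_malignant": e["n_malignant"],
                "n_benign": e["n_benign"],
                "sensitivity": round(e["sensitivity"], 1) if not math.isnan(e["sensitivity"]) else "",
                "specificity": round(e["specificity"], 1) if not math.isnan(e["specificity"]) else "",
                "ppv": round(e["ppv"], 1) if not math.isnan(e["ppv"]) else "",
                "npv": round(e["npv"], 1) if not math.isnan(e["npv"]) else "",
                "auc": round(e["auc"], 3) if "auc" in e else "",
            }
        )
    return pd.DataFrame(rows)


def marker_scores(records: Sequence[PatientRecord]) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Aligned score vectors for CA125, HE4, standard ROMA and ROMA P on the
    labelled known-status subset, plus the malignancy indicator."""
    kept = [
        r
        for r in records
        if r.label is not None and r.menopausal_status is not MenopausalStatus.UNKNOWN
    ]
    if not kept:
        raise ValueError("comparison requires labelled records with known menopausal status")
    scores = {
        "CA125": np.array([r.ca125 for r in kept]),
        "HE4": np.array([r.he4 for r in kept]),
        "ROMA": np.array([model.score_roma_standard(r).percent for r in kept]),
        "ROMA P": np.array([model.score_roma_p(r).percent for r in kept]),
    }
    labels = np.array([r.label is Label.MALIGNANT for r in kept])
    return scores, labels


def compare_markers(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Paired DeLong comparison matrix across CA125, HE4, ROMA and ROMA P.

    One row per marker with its AUC (DeLong SE/CI) and the two-sided
    p-values of the paired comparisons against every other marker.
    """
    scores, labels = marker_scores(records)
    rows = []
    for name, s in scores.items():
        d = diagnostics.delong_variance(s, labels)
        row = {
            "marker": name,
            "auc": d["auc"],
            "se_auc": d["se_auc"],
            "ci_low": d["ci_auc"][0],
            "ci_high": d["ci_auc"][1],
        }
        for other, s2 in scores.items():
            if other == name:
                continue
            row[f"p_vs_{other.replace(' ', '_')}"] = diagnostics.delong_compare(s, s2, labels).p
        rows.append(row)
    return pd.DataFrame(rows)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, allow_nan=True) + "\n")
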