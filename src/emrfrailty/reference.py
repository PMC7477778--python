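"""Binary frail / not-frail reference standard from Clinical Frailty Scale scores.

A patient is deemed frail when the sentinel physician's CFS score is at or
above the threshold (default 5, "mildly frail"; a score of 4 is "vulnerable"
and counts as not frail).  Eligibility for the reference set requires age 65+
and a clinic encounter within the 24 months ending at the as-of date.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from pathlib import Path

import pandas as pd

from .simulate import CfsAssessment, EmrTables

__all__ = ["LabelSet", "dichotomize", "check_eligibility"]

FRAIL, NOT_FRAIL = "frail", "not_frail"


@dataclass(frozen=True)
class LabelSet:
    """Patient-id -> binary frailty label, with the CFS threshold that made it."""

    labels: pd.Series  # index patient_id, values in {0, 1}; 1 = frail
    threshold: int = 5

    @property
    def n_frail(self) -> int:
        return int(self.labels.sum())

    @property
    def n_not_frail(self) -> int:
        return int((1 - self.labels).sum())

    @property
    def patient_ids(self) -> list[str]:
        return list(self.labels.index)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        out = pd.DataFrame({
            "patient_id": self.labels.index,
            "label": self.labels.map({1: FRAIL, 0: NOT_FRAIL}).to_numpy(),
        })
        out.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path, threshold: int = 5) -> "LabelSet":
        df = pd.read_csv(path, dtype=str)
        bad = set(df["label"]) - {FRAIL, NOT_FRAIL}
        if bad:
            raise ValueError(f"unknown label value(s) {sorted(bad)}")
        s = pd.Series(
            (df["label"] == FRAIL).astype(int).to_numpy(),
            index=pd.Index(df["patient_id"], name="patient_id"),
        )
        return cls(labels=s, threshold=threshold)


def dichotomize(assessments: list[CfsAssessment], threshold: int = 5) -> LabelSet:
    """Dichotomize CFS scores: frail iff score >= threshold.

    Scores outside 1..9 or duplicate assessments raise ``ValueError`` naming
    the offending patient.
    """
    seen: dict[str, int] = {}
    for a in assessments:
        if not 1 <= a.cfs_score <= 9:
            raise ValueError(
                f"CFS score {a.cfs_score} outside 1..9 for patient {a.patient_id}"
            )
        if a.patient_id in seen:
            raise ValueError(f"duplicate CFS assessment for patient {a.patient_id}")
        seen[a.patient_id] = a.cfs_score
    labels = pd.Series(
        {pid: int(score >= threshold) for pid, score in seen.items()},
        dtype=int,
    )
    labels.index.name = "patient_id"
    return LabelSet(labels=labels, threshold=threshold)


def check_eligibility(tables: EmrTables, patient_id: str, as_of: date) -> bool:
    """True iff the patient is 65+ at ``as_of`` and had an encounter in the
    previous 24 months."""
    pat = tables.patient
    row = pat[pat["patient_id"] == patient_id]
    if row.empty:
        raise KeyError(f"unknown patient_id {patient_id!r}")
    age = as_of.year - int(row["birth_year"].iloc[0])
    if age < 65:
        return False
    enc = tables.encounter
    enc = enc[enc["patient_id"] == patient_id]
    if enc.empty:
        return False
    dates = pd.to_datetime(enc["date"])
    as_of_ts = pd.Timestamp(as_of)
    window_start = as_of_ts - pd.DateOffset(months=24)
    return bool(((dates > window_start) & (dates <= as_of_ts)).any())
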