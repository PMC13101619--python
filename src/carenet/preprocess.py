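"""Aggregation of validated records into a case x activity matrix.

The unit of analysis is the case (one inpatient stay): per-application care
times are summed over the whole stay, giving one row per case and one column
per care activity.  A zero cell means the activity was not applied to that
case — an observed zero, not a missing value, because the correlations of
interest are across *all* cases.

Column-level filters (prevalence, zero variance) are applied here; by default
only constant columns are removed and any pruning of weakly connected
activities is left to the post-threshold network step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyMatrixError
from .records import RecordSet


@dataclass
class CaseActivityMatrix:
    """Cases x activities table of total care minutes per stay.

    ``data`` holds the totals with case ids as the index and activity labels
    as columns.  ``meta`` records provenance counts (source records, dropped
    activities).
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def case_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def activities(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_cases(self) -> int:
        return self.data.shape[0]

    @property
    def n_activities(self) -> int:
        return self.data.shape[1]

    def grand_total(self) -> float:
        """Total care minutes in the matrix (conserved under aggregation)."""
        return float(self.data.to_numpy().sum())

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.data.to_csv(path, index_label="case_id")
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "CaseActivityMatrix":
        data = pd.read_csv(path, index_col="case_id")
        data.index = data.index.astype(str)
        return cls(data=data.astype(float), meta={"source": str(path)})


def aggregate(rs: RecordSet) -> CaseActivityMatrix:
    """Sum care times per (case, activity) over the whole stay.

    Rows and columns are sorted lexicographically so the result is invariant
    to the input record order.  Raises :class:`EmptyMatrixError` on an empty
    record set.
    """
    if len(rs) == 0:
        raise EmptyMatrixError("no records to aggregate")
    frame = rs.to_frame()
    table = frame.pivot_table(
        index="Patient_ID",
        columns="Care_Activity",
        values="Care_Time",
        aggfunc="sum",
        fill_value=0.0,
    ).astype(float)
    table = table.sort_index(axis=0).sort_index(axis=1)
    table.index.name = None
    table.columns.name = None
    return CaseActivityMatrix(
        data=table,
        meta={"n_records": len(rs), "source": rs.source, "dropped_activities": []},
    )


@dataclass(frozen=True)
class Drop:
    """One activity column removed by :func:`filter_activities`."""

    activity: str
    reason: str


def filter_activities(
    m: CaseActivityMatrix,
    min_prevalence: float = 0.0,
    drop_zero_variance: bool = True,
) -> tuple[CaseActivityMatrix, list[Drop]]:
    """Remove rare and constant activity columns, logging each removal.

    ``min_prevalence`` is the minimal fraction of cases in which the activity
    must have been applied at least once.  Whole columns are removed, never
    rescaled.  Raises :class:`EmptyMatrixError` if nothing survives.
    """
    if m.n_activities == 0:
        raise EmptyMatrixError("matrix has no activity columns")
    data = m.data
    prevalence = (data > 0).mean(axis=0)
    drops: list[Drop] = []
    keep: list[str] = []
    for act in data.columns:
        if prevalence[act] < min_prevalence:
            drops.append(Drop(act, f"prevalence {prevalence[act]:.4g} < {min_prevalence:.4g}"))
        elif drop_zero_variance and data[act].nunique() <= 1:
            drops.append(Drop(act, "zero variance"))
        else:
            keep.append(act)
    if not keep:
        raise EmptyMatrixError("all activity columns dropped by filters")
    meta = dict(m.meta)
    meta["dropped_activities"] = meta.get("dropped_activities", []) + [
        (d.activity, d.reason) for d in drops
    ]
    return CaseActivityMatrix(data=data[keep].copy(), meta=meta), drops


@dataclass
class DurationSummary:
    """Per-activity and overall summaries of per-application care times."""

    per_activity: pd.DataFrame
    overall: dict


_SUMMARY_COLS = [
    "n_applications",
    "mean",
    "sd",
    "min",
    "q25",
    "median",
    "q75",
    "max",
    "case_frequency",
]


def summarize_activity_durations(rs: RecordSet) -> DurationSummary:
    """Summarize per-application durations (minutes) per activity and overall.

    ``sd`` is the sample standard deviation (ddof=1; NaN for a single
    application).  ``case_frequency`` is the fraction of cases in the record
    set with at least one application of the activity.
    """
    frame = rs.to_frame()
    n_cases = frame["Patient_ID"].nunique()
    if len(frame) == 0:
        empty = pd.DataFrame(columns=_SUMMARY_COLS)
        overall = {c: float("nan") for c in _SUMMARY_COLS}
        overall["n_applications"] = 0
        overall["n_cases"] = 0
        return DurationSummary(per_activity=empty, overall=overall)

    def _stats(g: pd.Series) -> pd.Series:
        q25, med, q75 = np.percentile(g, [25, 50, 75])
        return pd.Series(
            {
                "n_applications": len(g),
                "mean": g.mean(),
                "sd": g.std(ddof=1),
                "min": g.min(),
                "q25": q25,
                "median": med,
                "q75": q75,
                "max": g.max(),
            }
        )

    per_act = frame.groupby("Care_Activity")["Care_Time"].apply(_stats).unstack()
    freq = frame.groupby("Care_Activity")["Patient_ID"].nunique() / max(n_cases, 1)
    per_act["case_frequency"] = freq
    per_act = per_act[_SUMMARY_COLS].sort_index()

    overall = _stats(frame["Care_Time"]).to_dict()
    overall["case_frequency"] = 1.0 if len(frame) else float("nan")
    overall["n_cases"] = n_cases
    return DurationSummary(per_activity=per_act, overall=overall)
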