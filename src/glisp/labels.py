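"""Case-level binary genetic-event labels with explicit per-task missingness.

The nine prediction tasks cover the genetic events that matter for the
WHO-2021 classification of adult diffuse glioma. Labels live in a long table
(case_id, task, status) with status in {0, 1, NA}; each task has its own
labeled sub-cohort, so cross-validation folds are drawn per task.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

#: canonical task keys -> human-readable event names
TASKS: dict[str, str] = {
    "idh": "IDH1/2 mutation",
    "atrx": "ATRX mutation",
    "tp53": "TP53 mutation",
    "tert": "TERT promoter mutation",
    "egfr_amp": "EGFR amplification",
    "chd": "CDKN2A/B homozygous deletion",
    "gain7_loss10": "chromosome 7 gain / 10 loss",
    "codel_1p19q": "1p/19q co-deletion",
    "mgmt": "MGMT promoter methylation",
}


class GeneLabelTable:
    """Long-format label table; one row per (case, task), missing rows = NA."""

    def __init__(self, table: pd.DataFrame):
        required = {"case_id", "task", "status"}
        if not required.issubset(table.columns):
            raise ValueError(f"label table needs columns {sorted(required)}")
        bad = set(table["task"]) - set(TASKS)
        if bad:
            raise ValueError(f"unknown task keys: {sorted(bad)}")
        tab = table.copy()
        tab["status"] = pd.to_numeric(tab["status"], errors="coerce")
        ok = tab["status"].isin([0, 1]) | tab["status"].isna()
        if not ok.all():
            raise ValueError("status must be 0, 1 or NA")
        self.table = tab.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GeneLabelTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_case_dict(cls, statuses: dict[str, dict[str, int | None]]) -> "GeneLabelTable":
        """Build from {case_id: {task: 0/1/None}}."""
        rows = [
            {"case_id": cid, "task": task, "status": np.nan if s is None else s}
            for cid, tasks in statuses.items()
            for task, s in tasks.items()
        ]
        return cls(pd.DataFrame(rows, columns=["case_id", "task", "status"]))

    def for_task(self, task: str) -> pd.Series:
        """Labeled cases for one task: index case_id, int8 values, NAs dropped."""
        if task not in TASKS:
            raise ValueError(f"unknown task {task!r}; known: {sorted(TASKS)}")
        sub = self.table[self.table["task"] == task].dropna(subset=["status"])
        ser = sub.set_index("case_id")["status"].astype(np.int8)
        if ser.index.has_duplicates:
            raise ValueError(f"duplicate labels for task {task!r}")
        return ser

    def cases(self) -> list[str]:
        return sorted(self.table["case_id"].unique())

    def __len__(self) -> int:
        return len(self.table)
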