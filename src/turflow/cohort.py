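"""Cohort-level summaries of Tur indices across subjects and distances.

A cohort is a subjects x distances matrix of cycle-mean Tur percentages with
per-subject exclusion flags (an excluded subject's data remain inspectable
but are skipped by every summary).  Summaries report, per distance, the mean
and sample standard deviation over included subjects, counts of subjects
below/at-or-above the turbulence threshold, and how many subjects have their
row maximum at that distance.

Three reference cohorts from a canine femoral-artery stenosis experiment
ship with the package: the pre-operative baseline (single site, 12 dogs) and
the post-stenotic profiles at 50% and at 70% diameter stenosis (10 sites,
1-19 mm downstream; one 70%-group subject is excluded for post-stenotic
vessel spasm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .profile import TURBULENCE_THRESHOLD

__all__ = [
    "CohortTable",
    "SummaryRow",
    "summarize",
    "exceedance_series",
    "group_mean_series",
    "load_baseline_cohort",
    "load_cohort_50pct",
    "load_cohort_70pct",
]


@dataclass
class CohortTable:
    """Subjects x distances matrix of cycle-mean Tur percentages."""

    subject_ids: list
    distances: np.ndarray  # mm
    tur: np.ndarray  # (n_subjects, n_distances), percent
    excluded: np.ndarray = None  # bool per subject
    exclusion_reasons: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.tur = np.asarray(self.tur, dtype=float)
        if self.tur.shape != (len(self.subject_ids), self.distances.size):
            raise ValueError(
                f"Tur matrix shape {self.tur.shape} does not match "
                f"{len(self.subject_ids)} subjects x {self.distances.size} distances"
            )
        if self.excluded is None:
            self.excluded = np.zeros(len(self.subject_ids), dtype=bool)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if not self.exclusion_reasons:
            self.exclusion_reasons = ["" for _ in self.subject_ids]

    @property
    def included_mask(self) -> np.ndarray:
        return ~self.excluded

    @property
    def n_included(self) -> int:
        return int(self.included_mask.sum())

    @classmethod
    def from_csv(cls, path: "Path | str") -> "CohortTable":
        """Read a cohort CSV: a ``case`` column, optional ``excluded`` /
        ``exclusion_reason`` columns, and one numeric column per distance."""
        df = pd.read_csv(path, comment="#")
        if "case" not in df.columns:
            raise ValueError(f"{path}: cohort CSV must have a 'case' column")
        excluded = df["excluded"].astype(bool).to_numpy() if "excluded" in df else None
        reasons = (
            df["exclusion_reason"].fillna("").astype(str).tolist()
            if "exclusion_reason" in df
            else []
        )
        dist_cols = [
            c for c in df.columns if c not in ("case", "excluded", "exclusion_reason")
        ]
        return cls(
            subject_ids=df["case"].tolist(),
            distances=np.array([float(c) for c in dist_cols]),
            tur=df[dist_cols].to_numpy(dtype=float),
            excluded=excluded,
            exclusion_reasons=reasons,
        )

    def to_csv(self, path: "Path | str") -> None:
        df = pd.DataFrame(self.tur, columns=[f"{d:g}" for d in self.distances])
        df.insert(0, "case", self.subject_ids)
        if self.excluded.any():
            df.insert(1, "excluded", self.excluded.astype(int))
            df.insert(2, "exclusion_reason", self.exclusion_reasons)
        df.to_csv(path, index=False)


@dataclass(frozen=True)
class SummaryRow:
    """Cohort summary at one distance."""

    distance: float
    mean: float
    sd: float  # NaN when only one subject is included
    n_below: int
    n_above: int
    n_max_here: int
    n_included: int

    @property
    def pct_below(self) -> float:
        return round(self.n_below / self.n_included * 100.0, 1)

    @property
    def pct_above(self) -> float:
        return round(self.n_above / self.n_included * 100.0, 1)

    @property
    def pct_max_here(self) -> float:
        return round(self.n_max_here / self.n_included * 100.0, 1)


def _rows(table: CohortTable, threshold: float) -> list[SummaryRow]:
    mask = table.included_mask
    if not mask.any():
        raise ValueError("all subjects are excluded; nothing to summarise")
    tur = table.tur[mask]
    n_inc = tur.shape[0]
    # row maximum per included subject; argmax keeps the first (smallest
    # distance) on ties
    max_idx = np.argmax(tur, axis=1)
    rows = []
    for j, d in enumerate(table.distances):
        col = tur[:, j]
        n_above = int(np.sum(col >= threshold))
        rows.append(
            SummaryRow(
                distance=float(d),
                mean=float(np.mean(col)),
                sd=float(np.std(col, ddof=1)) if n_inc > 1 else float("nan"),
                n_below=n_inc - n_above,
                n_above=n_above,
                n_max_here=int(np.sum(max_idx == j)),
                n_included=n_inc,
            )
        )
    return rows


def summarize(table: CohortTable, threshold: float = TURBULENCE_THRESHOLD) -> pd.DataFrame:
    """Per-distance summary over included subjects.

    Returns a DataFrame indexed by distance with columns ``mean``, ``sd``
    (sample standard deviation, n-1 denominator; NaN for a single subject),
    ``n_below`` / ``n_above`` (counts below / at-or-above ``threshold``),
    ``pct_below`` / ``pct_above``, ``n_max_here`` / ``pct_max_here`` (how
    many subjects peak at this distance) and ``n_included``.
    """
    rows = _rows(table, threshold)
    df = pd.DataFrame(
        {
            "mean": [r.mean for r in rows],
            "sd": [r.sd for r in rows],
            "n_below": [r.n_below for r in rows],
            "pct_below": [r.pct_below for r in rows],
            "n_above": [r.n_above for r in rows],
            "pct_above": [r.pct_above for r in rows],
            "n_max_here": [r.n_max_here for r in rows],
            "pct_max_here": [r.pct_max_here for r in rows],
            "n_included": [r.n_included for r in rows],
        },
        index=pd.Index([r.distance for r in rows], name="distance_mm"),
    )
    return df


def exceedance_series(
    table: CohortTable, threshold: float = TURBULENCE_THRESHOLD
) -> pd.Series:
    """Percentage of included subjects at or above ``threshold`` per distance."""
    rows = _rows(table, threshold)
    return pd.Series(
        [r.n_above / r.n_included * 100.0 for r in rows],
        index=pd.Index([r.distance for r in rows], name="distance_mm"),
        name="pct_above_threshold",
    )


def group_mean_series(tables: dict) -> pd.DataFrame:
    """Mean +/- SD Tur per distance for each named cohort, aligned for
    plotting with error bars.

    ``tables`` maps a group label (e.g. ``"50%"``) to its
    :class:`CohortTable`; the result has MultiIndex columns
    ``(label, "mean")`` and ``(label, "sd")``.
    """
    pieces = {}
    for label, table in tables.items():
        summary = summarize(table)
        pieces[(label, "mean")] = summary["mean"]
        pieces[(label, "sd")] = summary["sd"]
    return pd.DataFrame(pieces)


# ---------------------------------------------------------------------------
# packaged reference cohorts

def _load_packaged(name: str) -> CohortTable:
    with resources.as_file(resources.files("turflow.data") / name) as path:
        return CohortTable.from_csv(path)


def load_baseline_cohort() -> CohortTable:
    """Pre-operative baseline Tur of 12 normal canine femoral arteries
    (single measurement site, recorded as distance 0)."""
    return _load_packaged("table1_baseline.csv")


def load_cohort_50pct() -> CohortTable:
    """Cycle-mean Tur 1-19 mm distal to a 50% stenosis, 12 subjects."""
    return _load_packaged("table2_50pct.csv")


def load_cohort_70pct() -> CohortTable:
    """Cycle-mean Tur 1-19 mm distal to a 70% stenosis, 12 subjects with
    one excluded for post-stenotic vessel spasm."""
    return _load_packaged("table3_70pct.csv")
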