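"""Binary expressed / not-expressed call rules for the four assay modalities.

* time-course log-ratios: three classes split at -0.5 / +0.5 (strict
  inequalities; boundary values are 'average'),
* replicate present/absent voting (>= 2 of 3 for the early-embryo chips,
  >= 3 of 4 for the adult-tissue arrays),
* adult arrays additionally accept a significant 'up' call against whole-fly
  reference,
* tiling-map transfrags: coverage of at least 10% of a gene's coding region
  (inclusive), by default as a union over all overlapping transfrags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .core import CallTable, GenomicInterval, PeakSet

TimecourseClass = Literal["low", "average", "high", "no_call"]


@dataclass(frozen=True)
class CallThresholds:
    low_cut: float = -0.5
    high_cut: float = 0.5
    min_present_of_3: int = 2
    min_present_of_4: int = 3
    min_transfrag_frac: float = 0.10
    #: "union": coverage pooled over all transfrags; "single": some one
    #: transfrag must itself cover the fraction
    transfrag_mode: Literal["union", "single"] = "union"

    def __post_init__(self):
        if not self.low_cut < self.high_cut:
            raise ValueError("low_cut must be < high_cut")
        if not (1 <= self.min_present_of_3 <= 3 and 1 <= self.min_present_of_4 <= 4):
            raise ValueError("replicate vote thresholds out of range")
        if not (0.0 < self.min_transfrag_frac <= 1.0):
            raise ValueError("min_transfrag_frac must be in (0, 1]")


def classify_timecourse_value(v: float, t: CallThresholds = CallThresholds()
                              ) -> TimecourseClass:
    """'low' below ``low_cut``, 'high' above ``high_cut``, 'average' in
    between (boundaries included); missing values give an explicit
    'no_call'."""
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return "no_call"
    if v < t.low_cut:
        return "low"
    if v > t.high_cut:
        return "high"
    return "average"


def expressed_by_replicates(calls: Sequence[bool | str], k_required: int) -> bool:
    """True iff at least ``k_required`` of the replicate calls are present.

    Calls may be booleans or 'P'/'A' / 'present'/'absent' strings.
    """
    if len(calls) == 0:
        raise ValueError("replicate call list must be nonempty")
    if k_required > len(calls):
        raise ValueError(
            f"k_required={k_required} exceeds replicate count {len(calls)}"
        )
    n_present = sum(1 for c in calls if c in (True, "P", "present"))
    return n_present >= k_required


def _merge(intervals: Iterable[GenomicInterval]) -> dict[str, list[tuple[int, int]]]:
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for iv in sorted(intervals):
        runs = by_contig.setdefault(iv.contig, [])
        if runs and iv.start <= runs[-1][1]:
            runs[-1] = (runs[-1][0], max(runs[-1][1], iv.end))
        else:
            runs.append((iv.start, iv.end))
    return by_contig


def _overlap_length(runs_a: dict[str, list[tuple[int, int]]],
                    runs_b: dict[str, list[tuple[int, int]]]) -> int:
    total = 0
    for contig, a in runs_a.items():
        b = runs_b.get(contig, [])
        i = j = 0
        while i < len(a) and j < len(b):
            lo = max(a[i][0], b[j][0])
            hi = min(a[i][1], b[j][1])
            if lo < hi:
                total += hi - lo
            if a[i][1] <= b[j][1]:
                i += 1
            else:
                j += 1
    return total


def expressed_by_transfrags(
    cds: Sequence[GenomicInterval],
    transfrags: PeakSet,
    t: CallThresholds = CallThresholds(),
) -> bool:
    """True iff transfrags cover at least ``min_transfrag_frac`` of the
    gene's coding region (boundary inclusive).

    In "union" mode (default) coverage is pooled over all transfrags; in
    "single" mode some one transfrag must reach the fraction on its own.
    """
    cds_runs = _merge(cds)
    cds_len = sum(e - s for runs in cds_runs.values() for s, e in runs)
    if cds_len == 0:
        raise ValueError("total coding-region length is zero")
    if t.transfrag_mode == "single":
        for iv in transfrags:
            cov = _overlap_length(cds_runs, {iv.contig: [(iv.start, iv.end)]})
            if cov / cds_len >= t.min_transfrag_frac:
                return True
        return False
    covered = _overlap_length(cds_runs, _merge(transfrags))
    return covered / cds_len >= t.min_transfrag_frac


def flyatlas_expressed(
    present: Sequence[bool | str],
    direction: Literal["up", "down", "none"],
    t: CallThresholds = CallThresholds(),
) -> bool:
    """Adult-array rule: at least ``min_present_of_4`` present calls in the
    four replicates OR a significant 'up' call versus whole-fly material."""
    if len(present) != 4:
        raise ValueError(f"expected 4 replicate calls, got {len(present)}")
    return direction == "up" or expressed_by_replicates(present, t.min_present_of_4)


def call_table_expressed(table: CallTable, t: CallThresholds = CallThresholds()
                         ) -> np.ndarray:
    """Apply the adult-array rule to a whole call table; returns a boolean
    gene × tissue matrix."""
    votes = table.present.sum(axis=2) >= t.min_present_of_4
    return votes | (table.direction == "up")
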