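"""Two-factor ChIP peak co-occupancy across two timepoints.

Genomic sites are defined data-driven: single-linkage merging (>= 1 shared
base; half-open abutment is not overlap) of all peaks of both factors at both
timepoints yields a disjoint site universe.  Each site is then classified at
each timepoint as A_only / B_only / double / none by which factors have at
least one peak overlapping it, and occupancy-state transition fractions are
tabulated per origin state, plus summary fractions over the ever-occupied
universe (with both the t1-occupied and ever-occupied denominators emitted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenomicInterval, PeakSet

STATES = ("A_only", "B_only", "double", "none")


@dataclass
class SiteUniverse:
    """Disjoint, sorted merged regions; every input peak overlaps exactly
    one region."""

    regions: list[GenomicInterval]


def build_site_universe(*peak_sets: PeakSet, min_overlap: int = 1) -> SiteUniverse:
    """Transitively merge overlapping intervals across all peak sets.

    ``min_overlap`` is the number of shared bases required to link two
    intervals (default 1).  Idempotent: merging the merged regions returns
    them unchanged.
    """
    by_contig: dict[str, list[GenomicInterval]] = {}
    for ps in peak_sets:
        for iv in ps:
            by_contig.setdefault(iv.contig, []).append(iv)
    regions = []
    for contig in sorted(by_contig):
        ivs = sorted(by_contig[contig])
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e - min_overlap:
                cur_e = max(cur_e, iv.end)
            else:
                regions.append(GenomicInterval(contig, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        regions.append(GenomicInterval(contig, cur_s, cur_e))
    return SiteUniverse(regions=regions)


def _occupied_regions(universe: SiteUniverse, peaks: PeakSet,
                      min_overlap: int) -> np.ndarray:
    """Boolean flag per region: does any peak overlap it by >= min_overlap
    bases?  Raises if a peak overlaps no region (internal inconsistency)."""
    flags = np.zeros(len(universe.regions), dtype=bool)
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    index: dict[str, np.ndarray] = {}
    for contig in {r.contig for r in universe.regions}:
        idx = np.array([i for i, r in enumerate(universe.regions) if r.contig == contig])
        starts[contig] = np.array([universe.regions[i].start for i in idx])
        ends[contig] = np.array([universe.regions[i].end for i in idx])
        index[contig] = idx
    for iv in peaks:
        if iv.contig not in starts:
            raise ValueError(f"peak {iv} overlaps no region of the site universe")
        j = int(np.searchsorted(starts[iv.contig], iv.start, side="right")) - 1
        if j < 0 or min(ends[iv.contig][j], iv.end) - max(starts[iv.contig][j], iv.start) < min_overlap:
            raise ValueError(f"peak {iv} overlaps no region of the site universe")
        flags[index[iv.contig][j]] = True
    return flags


def occupancy_states(
    universe: SiteUniverse, peaks_a: PeakSet, peaks_b: PeakSet,
    min_overlap: int = 1,
) -> list[str]:
    """Per-region occupancy state at one timepoint from the two factors'
    peak sets."""
    a = _occupied_regions(universe, peaks_a, min_overlap)
    b = _occupied_regions(universe, peaks_b, min_overlap)
    out = []
    for ai, bi in zip(a, b):
        if ai and bi:
            out.append("double")
        elif ai:
            out.append("A_only")
        elif bi:
            out.append("B_only")
        else:
            out.append("none")
    return out


@dataclass
class TransitionResult:
    #: rows = t1 state, columns = t2 state, entries = fraction of the origin
    #: state (rows sum to 1; all-NaN row for an unpopulated origin state)
    fractions: pd.DataFrame
    counts: pd.DataFrame
    #: per (state, timepoint) fraction of the ever-occupied universe
    occupancy_fractions: pd.DataFrame
    n_regions: int
    n_ever_occupied: int
    n_occupied_t1: int


def transition_fractions(states_t1: list[str], states_t2: list[str]
                         ) -> TransitionResult:
    """Occupancy-state transition matrix between the two timepoints over a
    shared region universe."""
    if len(states_t1) != len(states_t2):
        raise ValueError("state lists must cover the same region universe")
    counts = pd.DataFrame(0, index=list(STATES), columns=list(STATES), dtype=int)
    for a, b in zip(states_t1, states_t2):
        counts.loc[a, b] += 1
    row_sums = counts.sum(axis=1)
    fractions = counts.div(row_sums.replace(0, np.nan), axis=0)

    ever = [i for i, (a, b) in enumerate(zip(states_t1, states_t2))
            if a != "none" or b != "none"]
    n_ever = len(ever)
    occ = pd.DataFrame(0.0, index=list(STATES), columns=["t1", "t2"])
    if n_ever:
        for t, states in (("t1", states_t1), ("t2", states_t2)):
            for i in ever:
                occ.loc[states[i], t] += 1
        occ /= n_ever
    return TransitionResult(
        fractions=fractions,
        counts=counts,
        occupancy_fractions=occ,
        n_regions=len(states_t1),
        n_ever_occupied=n_ever,
        n_occupied_t1=sum(1 for s in states_t1 if s != "none"),
    )


def chip_cooccupancy(
    peaks: dict[tuple[str, str], PeakSet], min_overlap: int = 1
) -> tuple[SiteUniverse, list[str], list[str], TransitionResult]:
    """End-to-end: build the site universe from the four peak sets, classify
    states at both timepoints, and tabulate transitions."""
    universe = build_site_universe(*peaks.values(), min_overlap=min_overlap)
    if not universe.regions:
        empty = TransitionResult(
            fractions=pd.DataFrame(np.nan, index=list(STATES), columns=list(STATES)),
            counts=pd.DataFrame(0, index=list(STATES), columns=list(STATES)),
            occupancy_fractions=pd.DataFrame(0.0, index=list(STATES), columns=["t1", "t2"]),
            n_regions=0, n_ever_occupied=0, n_occupied_t1=0,
        )
        return universe, [], [], empty
    s1 = occupancy_states(universe, peaks[("A", "t1")], peaks[("B", "t1")], min_overlap)
    s2 = occupancy_states(universe, peaks[("A", "t2")], peaks[("B", "t2")], min_overlap)
    return universe, s1, s2, transition_fractions(s1, s2)
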