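"""Temporal expression classification and TF-fraction time courses.

Each gene's binary support over the six stage ranges is assigned to exactly
one of six temporal classes.  The classes are defined by support shape:

* ``no_expression``       — empty support.
* ``maternal_continuous`` — expressed at every stage range (maternal deposit
  plus uninterrupted zygotic expression through the end of embryogenesis).
* ``early_only``          — a contiguous prefix starting at range 1 and ending
  no later than ``early_cutoff`` (default range 3, stages 7-8): maternal or
  early zygotic transcripts that decay.
* ``continuous_zygotic``  — no maternal contribution, onset no later than
  range ``early_cutoff + 1``, and expression persisting through range 6.
* ``late_only``           — a contiguous block whose onset is after the early
  window (start >= ``early_cutoff + 1``) and that is not continuous_zygotic.
* ``diverse``             — everything else, in particular any support with
  gaps.

With these definitions the six labels partition all 2^6 supports (checked
exhaustively in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GeneCatalog, N_STAGES, STAGE_LABELS, StageTissueMatrix

TEMPORAL_CLASSES: tuple[str, ...] = (
    "no_expression",
    "diverse",
    "early_only",
    "late_only",
    "continuous_zygotic",
    "maternal_continuous",
)

DEFAULT_EARLY_CUTOFF = 3  # 1-based stage-range index of the end of the early window


def classify_temporal_class(
    support: Sequence[bool], early_cutoff: int = DEFAULT_EARLY_CUTOFF
) -> str:
    """Assign one of the six temporal classes to a stage-range support."""
    if len(support) != N_STAGES:
        raise ValueError(f"support must have length {N_STAGES}, got {len(support)}")
    support = tuple(bool(b) for b in support)
    if not any(support):
        return "no_expression"
    on = [i + 1 for i, b in enumerate(support) if b]  # 1-based indices
    start, end = on[0], on[-1]
    contiguous = len(on) == end - start + 1
    if not contiguous:
        return "diverse"
    if start == 1 and end == N_STAGES:
        return "maternal_continuous"
    if start == 1 and end <= early_cutoff:
        return "early_only"
    if 2 <= start <= early_cutoff + 1 and end == N_STAGES:
        return "continuous_zygotic"
    if start >= early_cutoff + 1:
        return "late_only"
    return "diverse"


def classify_matrix(
    matrix: StageTissueMatrix, early_cutoff: int = DEFAULT_EARLY_CUTOFF
) -> dict[str, str]:
    """Temporal class per gene of the matrix."""
    return {
        g: classify_temporal_class(matrix.support(g), early_cutoff)
        for g in matrix.genes
    }


def class_counts(labels: Mapping[str, str]) -> dict[str, int]:
    counts = {c: 0 for c in TEMPORAL_CLASSES}
    for lab in labels.values():
        counts[lab] += 1
    return counts


def maternal_fraction(matrix: StageTissueMatrix, catalog: GeneCatalog) -> float:
    """Fraction of catalogued TFs in the matrix expressed at stage range 1-3
    (the maternal window)."""
    tfs = [g for g in matrix.genes if g in catalog and catalog.is_tf(g)]
    if not tfs:
        raise ValueError("no annotated TFs in the matrix")
    maternal = sum(1 for g in tfs if matrix.support(g)[0])
    return maternal / len(tfs)


@dataclass
class TemporalProfile:
    """Per-stage expression counts and TF share, plus per-family breakdowns."""

    per_stage: pd.DataFrame          # index stage label; tf, nontf, tf_share
    per_family: pd.DataFrame | None = None  # family × stage counts / percentages


def family_temporal_profile(
    matrix: StageTissueMatrix, catalog: GeneCatalog
) -> TemporalProfile:
    """Count expressed TFs per DBD family and stage range, and each family's
    percentage of all TFs expressed at that stage.

    TFs with family "none" are excluded from family rows.  A stage with no
    expressed TF has undefined percentages, reported as NaN rather than 0.
    """
    tf_genes = [g for g in matrix.genes if g in catalog and catalog.is_tf(g)]
    families = sorted(
        {catalog.family_of(g) for g in tf_genes if catalog.family_of(g) != "none"}
    )
    counts = pd.DataFrame(0, index=families, columns=list(STAGE_LABELS), dtype=int)
    totals = pd.Series(0, index=list(STAGE_LABELS), dtype=int)
    for g in tf_genes:
        sup = matrix.support(g)
        fam = catalog.family_of(g)
        for s_idx, expressed in enumerate(sup):
            if expressed:
                totals[STAGE_LABELS[s_idx]] += 1
                if fam != "none":
                    counts.loc[fam, STAGE_LABELS[s_idx]] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * counts / totals.replace(0, np.nan)
    per_family = pd.concat({"count": counts, "percent": pct}, axis=0)

    per_stage_rows = []
    for s_idx, lab in enumerate(STAGE_LABELS):
        expressed = matrix.expressed_at(s_idx)
        n_tf = sum(1 for g in expressed if g in catalog and catalog.is_tf(g))
        n_nontf = sum(1 for g in expressed if g in catalog and not catalog.is_tf(g))
        share = n_tf / (n_tf + n_nontf) if (n_tf + n_nontf) else np.nan
        per_stage_rows.append((lab, n_tf, n_nontf, share))
    per_stage = pd.DataFrame(
        per_stage_rows, columns=["stage_range", "tf", "nontf", "tf_share"]
    ).set_index("stage_range")
    return TemporalProfile(per_stage=per_stage, per_family=per_family)


def tf_share_timecourse(
    expressed_sets: Sequence[Iterable[str]],
    catalog: GeneCatalog,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """TF share among expressed genes per timepoint, and its ratio to the
    genomic TF share.

    ``expressed_sets`` is one gene set per timepoint.  An empty expressed set
    yields NaN (no call), never 0.
    """
    genomic_share = len(catalog.tf_ids) / len(catalog)
    rows = []
    for i, genes in enumerate(expressed_sets):
        genes = set(genes)
        n_tf = sum(1 for g in genes if catalog.is_tf(g))
        n_tot = len(genes)
        share = n_tf / n_tot if n_tot else np.nan
        ratio = share / genomic_share if n_tot else np.nan
        rows.append((labels[i] if labels else i, n_tf, n_tot, share, ratio))
    return pd.DataFrame(
        rows, columns=["timepoint", "n_tf", "n_expressed", "tf_share", "ratio_to_genomic"]
    ).set_index("timepoint")
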