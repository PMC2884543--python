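"""Tissue-specificity analyses: ubiquity vs restriction (TF vs non-TF 2×2
chi-square), expression breadth, adult up-call clustering, and the
embryo-vs-adult cross-tabulation.

"Ubiquitous" is an annotation term, not a derived breadth threshold; breadth
counts slim-anatomy terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import chi2_contingency

from .core import CallTable, GeneCatalog, STAGE_LABELS, StageTissueMatrix, UBIQUITOUS

logger = logging.getLogger(__name__)


@dataclass
class UbiquityTest:
    stage_range: str            # a single range, or "pooled"
    tf_ubiq: int
    tf_restricted: int
    nontf_ubiq: int
    nontf_restricted: int
    chi2: float
    p_value: float
    degenerate: bool = False

    @property
    def table(self) -> np.ndarray:
        return np.array(
            [[self.tf_ubiq, self.tf_restricted],
             [self.nontf_ubiq, self.nontf_restricted]]
        )


def _chi2_2x2(table: np.ndarray) -> tuple[float, float, bool]:
    """Pearson chi-square without continuity correction, 1 df; degenerate if
    any marginal is zero."""
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan"), float("nan"), True
    chi2, p, _, _ = chi2_contingency(table, correction=False)
    return float(chi2), float(p), False


def ubiquity_by_stage(
    matrix: StageTissueMatrix, catalog: GeneCatalog, pooled: bool = False,
    pooled_stages: tuple[int, ...] = (1, 2, 3, 4),
) -> list[UbiquityTest]:
    """Per stage range (or pooled over ``pooled_stages``, default ranges
    4-6 .. 11-12, i.e. stages 4 through 12), count ubiquitously vs
    restrictedly expressed TFs and non-TFs among the genes expressed there
    and test the 2×2 table."""
    def counts_at(s_idx: int) -> np.ndarray:
        tab = np.zeros((2, 2), dtype=int)
        for g in matrix.expressed_at(s_idx):
            if g not in catalog:
                continue
            row = 0 if catalog.is_tf(g) else 1
            col = 0 if UBIQUITOUS in matrix.terms_at(g, s_idx) else 1
            tab[row, col] += 1
        return tab

    if pooled:
        tab = sum(counts_at(s) for s in pooled_stages)
        chi2, p, degen = _chi2_2x2(tab)
        return [UbiquityTest("pooled", *tab.ravel().tolist(), chi2, p, degen)]
    out = []
    for s_idx, stage in enumerate(STAGE_LABELS):
        tab = counts_at(s_idx)
        chi2, p, degen = _chi2_2x2(tab)
        out.append(UbiquityTest(stage, *tab.ravel().tolist(), chi2, p, degen))
    return out


def expression_breadth(matrix: StageTissueMatrix) -> pd.DataFrame:
    """Breadth (number of slim terms) and ubiquity flag per gene × stage."""
    rows = []
    for g in matrix.genes:
        for s_idx, stage in enumerate(STAGE_LABELS):
            terms = matrix.terms_at(g, s_idx)
            if terms:
                rows.append((g, stage, len(terms), UBIQUITOUS in terms))
    return pd.DataFrame(rows, columns=["gene_id", "stage_range", "breadth", "ubiquitous"])


def never_ubiquitous_narrow_tfs(
    matrix: StageTissueMatrix, catalog: GeneCatalog, max_breadth: int = 3
) -> set[str]:
    """TFs never annotated 'ubiquitous' at any stage whose union-over-stages
    breadth is strictly less than ``max_breadth``."""
    out = set()
    for g in matrix.genes:
        if g not in catalog or not catalog.is_tf(g):
            continue
        sets = matrix.entries[g]
        if not any(sets):
            continue
        if any(UBIQUITOUS in s for s in sets):
            continue
        union = frozenset().union(*sets)
        if len(union) < max_breadth:
            out.add(g)
    return out


def exclusively_ubiquitous(matrix: StageTissueMatrix) -> set[str]:
    """Genes (among those ubiquitous at >= 1 stage) whose every nonempty
    stage annotation is exactly {ubiquitous}."""
    out = set()
    for g in matrix.genes:
        sets = [s for s in matrix.entries[g] if s]
        if not sets:
            continue
        if any(UBIQUITOUS in s for s in sets) and all(
            s == frozenset({UBIQUITOUS}) for s in sets
        ):
            out.add(g)
    return out


@dataclass
class AdultCluster:
    cluster_id: int
    members: list[str]
    defining_tissues: list[str]


def adult_specificity_clusters(
    calls: CallTable, linkage_cut: float, genes: list[str] | None = None
) -> list[AdultCluster]:
    """Hierarchically cluster binary 'up'-call profiles (Jaccard distance,
    average linkage), cut the tree at ``linkage_cut``, and name each cluster
    by the tissues with the most 'up' calls among its members.

    Genes without any 'up' call carry no signal for this distance and are
    excluded (logged).  Output is invariant to input gene order (genes are
    sorted internally).
    """
    pool = sorted(genes if genes is not None else calls.genes)
    g_idx = {g: i for i, g in enumerate(calls.genes)}
    up = np.stack([(calls.direction[g_idx[g]] == "up") for g in pool])
    keep = up.any(axis=1)
    dropped = [g for g, k in zip(pool, keep) if not k]
    if dropped:
        logger.info("excluding %d genes with no 'up' call", len(dropped))
    pool = [g for g, k in zip(pool, keep) if k]
    up = up[keep]
    if len(pool) == 0:
        return []
    if len(pool) == 1:
        j = np.flatnonzero(up[0])
        return [AdultCluster(1, pool, [calls.tissues[t] for t in j])]
    dist = pdist(up, metric="jaccard")
    tree = linkage(dist, method="average")
    labels = fcluster(tree, t=linkage_cut, criterion="distance")
    clusters = []
    for cid in sorted(set(labels)):
        members = [g for g, l in zip(pool, labels) if l == cid]
        sub = up[labels == cid]
        counts = sub.sum(axis=0)
        top = counts.max()
        defining = [calls.tissues[j] for j in np.flatnonzero(counts == top)] if top else []
        clusters.append(AdultCluster(int(cid), members, defining))
    return clusters


LATE_STAGE_IDX = STAGE_LABELS.index("13-16")


def embryo_adult_crosstab(
    clusters: list[AdultCluster], matrix: StageTissueMatrix
) -> pd.DataFrame:
    """Per adult cluster: how many members have late-embryo (stages 13-16)
    annotation, and the frequency of each embryonic term among them
    (percentages of annotated members)."""
    rows = []
    for cl in clusters:
        annotated = [
            g for g in cl.members
            if g in matrix and matrix.terms_at(g, LATE_STAGE_IDX)
        ]
        if not annotated:
            rows.append((cl.cluster_id, len(cl.members), 0, "", np.nan, True))
            continue
        freq: dict[str, int] = {}
        for g in annotated:
            for t in matrix.terms_at(g, LATE_STAGE_IDX):
                freq[t] = freq.get(t, 0) + 1
        for term, count in sorted(freq.items(), key=lambda kv: (-kv[1], kv[0])):
            rows.append(
                (cl.cluster_id, len(cl.members), len(annotated), term,
                 100.0 * count / len(annotated), False)
            )
    return pd.DataFrame(
        rows,
        columns=["cluster_id", "n_members", "n_annotated", "term",
                 "percent_of_annotated", "empty"],
    )
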