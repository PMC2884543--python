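"""Co-expression modules and their conservation across consecutive stages.

Two or three genes form a (potential) module at a stage when they are
*precisely* co-expressed: their slim-term annotation sets at that stage are
identical (and nonempty).  A module is *conserved* across a stage transition
when its members are still precisely co-expressed (possibly in a different
tissue vector) at the next stage.  Significance comes from a permutation
null: the later stage's gene labels are reshuffled (1,000 iterations by
default) and the conserved count recomputed, giving
z = (observed - null mean) / null sd.

A weaker notion, *co-occurrence* (term sets merely intersecting), is used
for the pairwise TF co-occurrence map; the two notions are implemented and
named distinctly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GeneCatalog, ModuleStats, N_STAGES, STAGE_LABELS, StageTissueMatrix


@dataclass
class CoexpressionPartition:
    """Genes expressed at one stage range, grouped by identical term sets."""

    stage_range: str
    groups: list[frozenset[str]]          # pairwise-disjoint gene sets
    vectors: list[frozenset[str]]         # the shared term set per group

    @property
    def membership(self) -> dict[str, int]:
        return {g: i for i, grp in enumerate(self.groups) for g in grp}


def coexpression_partition(matrix: StageTissueMatrix, stage: int) -> CoexpressionPartition:
    """Partition the genes expressed at 0-based stage index ``stage`` by
    exact equality of their term sets; unexpressed genes are excluded."""
    by_vector: dict[frozenset[str], set[str]] = {}
    for g in matrix.genes:
        terms = matrix.terms_at(g, stage)
        if terms:
            by_vector.setdefault(terms, set()).add(g)
    vectors = sorted(by_vector, key=sorted)
    return CoexpressionPartition(
        stage_range=STAGE_LABELS[stage],
        groups=[frozenset(by_vector[v]) for v in vectors],
        vectors=list(vectors),
    )


def _comb(counts: np.ndarray, k: int) -> int:
    counts = np.asarray(counts, dtype=np.int64)
    if k == 2:
        return int((counts * (counts - 1) // 2).sum())
    if k == 3:
        return int((counts * (counts - 1) * (counts - 2) // 6).sum())
    raise ValueError("k must be 2 or 3")


def count_comodules(partition: CoexpressionPartition, k: int) -> int:
    """Number of k-subsets of precisely co-expressed genes: sum over groups
    of C(|group|, k)."""
    return _comb(np.array([len(g) for g in partition.groups]), k)


def _joint_cells(p_s: CoexpressionPartition, p_s1: CoexpressionPartition
                 ) -> np.ndarray:
    m_s, m_s1 = p_s.membership, p_s1.membership
    common = [g for g in m_s1 if g in m_s]
    if not common:
        return np.zeros(0, dtype=np.int64)
    a = np.array([m_s[g] for g in common], dtype=np.int64)
    b = np.array([m_s1[g] for g in common], dtype=np.int64)
    keys = a * (max(m_s1.values()) + 1) + b
    return np.bincount(np.unique(keys, return_inverse=True)[1])


def conserved_comodules(
    p_s: CoexpressionPartition, p_s1: CoexpressionPartition, k: int
) -> int:
    """k-subsets co-grouped in both partitions, i.e. sum of C(cell, k) over
    the cells of the partition intersection — identical to exhaustive subset
    enumeration but linear in the number of genes."""
    if k not in (2, 3):
        raise ValueError("k must be 2 or 3")
    return _comb(_joint_cells(p_s, p_s1), k)


def permutation_z(
    p_s: CoexpressionPartition,
    p_s1: CoexpressionPartition,
    k: int,
    n_iter: int = 1000,
    seed: int = 0,
) -> ModuleStats:
    """Hold the earlier partition fixed, reshuffle which gene carries which
    group label in the later partition, and standardize the observed
    conserved-module count against the resulting null."""
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    observed = conserved_comodules(p_s, p_s1, k)
    rng = np.random.default_rng([int(seed), 7])

    genes_s1 = sorted(p_s1.membership)
    gid1 = np.array([p_s1.membership[g] for g in genes_s1], dtype=np.int64)
    m_s = p_s.membership
    gid0 = np.array([m_s.get(g, -1) for g in genes_s1], dtype=np.int64)
    mask = gid0 >= 0
    mult = int(gid1.max()) + 1 if len(gid1) else 1

    null = np.empty(n_iter)
    for i in range(n_iter):
        perm = rng.permutation(len(genes_s1))
        b = gid1[perm][mask]
        keys = gid0[mask] * mult + b
        cells = np.bincount(np.unique(keys, return_inverse=True)[1]) if len(keys) else np.zeros(0, dtype=np.int64)
        null[i] = _comb(cells, k)
    mean, sd = float(null.mean()), float(null.std(ddof=0))
    degenerate = sd == 0.0
    z = float("nan") if degenerate else (observed - mean) / sd
    return ModuleStats(
        from_stage=p_s.stage_range, to_stage=p_s1.stage_range, k=k,
        observed=observed, null_mean=mean, null_sd=sd, z=z,
        n_iterations=n_iter, degenerate=degenerate,
    )


def stage_transition_stats(
    matrix: StageTissueMatrix, k: int, n_iter: int = 1000, seed: int = 0
) -> list[ModuleStats]:
    """Permutation Z for every consecutive stage-range transition."""
    parts = [coexpression_partition(matrix, s) for s in range(N_STAGES)]
    return [
        permutation_z(parts[s], parts[s + 1], k, n_iter=n_iter, seed=seed + s)
        for s in range(N_STAGES - 1)
    ]


def random_geneset_baseline(
    matrix: StageTissueMatrix,
    catalog: GeneCatalog,
    set_size: int = 373,
    n_rep: int = 100,
    k: int = 2,
    n_iter: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Distribution of permutation Z-scores for random gene sets (TF and
    non-TF alike) of the size of the TF repertoire, for comparison with the
    TF-only scores.  Defaults: 373 genes, 100 repetitions."""
    pool = sorted(matrix.expressed_anywhere())
    if set_size > len(pool):
        raise ValueError(
            f"set_size {set_size} exceeds the {len(pool)} genes with annotation"
        )
    rng = np.random.default_rng([int(seed), 8])
    rows = []
    for rep in range(n_rep):
        chosen = rng.choice(len(pool), size=set_size, replace=False)
        sub = matrix.restrict(pool[i] for i in chosen)
        for ms in stage_transition_stats(sub, k, n_iter=n_iter,
                                         seed=int(rng.integers(2**31))):
            rows.append((rep, ms.from_stage, ms.to_stage, ms.observed, ms.z))
    return pd.DataFrame(rows, columns=["rep", "from_stage", "to_stage", "observed", "z"])


@dataclass
class CooccurrenceSummary:
    n_tf: int
    approx_pairs: float       # n^2 / 2, the repertoire-scale approximation
    exact_pairs: int          # C(n, 2)
    coexpressed_pairs: int    # pairs co-occurring in >= 1 tissue at >= 1 stage
    mean_fraction: float


def pairwise_cooccurrence(
    matrix: StageTissueMatrix, catalog: GeneCatalog
) -> tuple[pd.DataFrame, CooccurrenceSummary]:
    """Per TF pair, the fraction of the six stage ranges at which the two
    term sets intersect; diagonal is 1 by convention and excluded from pair
    counts."""
    tfs = sorted(g for g in matrix.genes if g in catalog and catalog.is_tf(g))
    n = len(tfs)
    if n < 2:
        raise ValueError("need at least two TFs")
    frac = np.zeros((n, n))
    all_terms = sorted({t for g in tfs for s in range(N_STAGES)
                        for t in matrix.terms_at(g, s)})
    t_idx = {t: j for j, t in enumerate(all_terms)}
    for s in range(N_STAGES):
        M = np.zeros((n, len(all_terms)), dtype=bool)
        for i, g in enumerate(tfs):
            for t in matrix.terms_at(g, s):
                M[i, t_idx[t]] = True
        frac += (M @ M.T) > 0
    frac /= N_STAGES
    np.fill_diagonal(frac, 1.0)
    iu = np.triu_indices(n, k=1)
    summary = CooccurrenceSummary(
        n_tf=n,
        approx_pairs=n * n / 2,
        exact_pairs=n * (n - 1) // 2,
        coexpressed_pairs=int((frac[iu] > 0).sum()),
        mean_fraction=float(frac[iu].mean()),
    )
    return pd.DataFrame(frac, index=tfs, columns=tfs), summary
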