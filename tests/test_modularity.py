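"""Co-expression modules: partition, counting oracles, permutation null,
pairwise co-occurrence."""

import itertools
from math import comb

import numpy as np
import pytest

from tfdynamics.core import StageTissueMatrix
from tfdynamics.modularity import (
    CoexpressionPartition,
    coexpression_partition,
    conserved_comodules,
    count_comodules,
    pairwise_cooccurrence,
    permutation_z,
    random_geneset_baseline,
    stage_transition_stats,
)
from conftest import make_catalog


def _part(stage, groups):
    return CoexpressionPartition(
        stage, [frozenset(g) for g in groups],
        [frozenset({str(i)}) for i in range(len(groups))],
    )


def test_partition_groups_by_identical_term_sets():
    A, AB = frozenset({"a"}), frozenset({"a", "b"})
    m = StageTissueMatrix({
        "g1": [A] + [frozenset()] * 5,
        "g2": [A] + [frozenset()] * 5,
        "g3": [AB] + [frozenset()] * 5,
        "g4": [frozenset()] * 6,
    })
    p = coexpression_partition(m, 0)
    assert sorted(sorted(g) for g in p.groups) == [["g1", "g2"], ["g3"]]
    assert sum(len(g) for g in p.groups) == 3  # g4 excluded


def test_comodule_counts_binomial():
    p = _part("1-3", [["a", "b"], ["c", "d", "e"]])
    assert count_comodules(p, 2) == 4
    assert count_comodules(p, 3) == 1
    with pytest.raises(ValueError):
        count_comodules(p, 4)


def test_conserved_examples():
    p_s = _part("1-3", [["g1", "g2"], ["g3", "g4"]])
    p_s1 = _part("4-6", [["g1", "g2"], ["g3"], ["g4"]])
    assert conserved_comodules(p_s, p_s1, 2) == 1
    # identity: conserved equals the comodule count
    assert conserved_comodules(p_s, p_s, 2) == count_comodules(p_s, 2)
    assert conserved_comodules(p_s, p_s, 3) == count_comodules(p_s, 3)


def _random_partition(rng, genes, stage):
    labels = rng.integers(0, max(2, len(genes) // 2), size=len(genes))
    groups = {}
    for g, l in zip(genes, labels):
        groups.setdefault(l, []).append(g)
    return _part(stage, list(groups.values()))


def _brute_force_conserved(p_s, p_s1, k):
    """Enumerate every k-subset and check co-grouping in both partitions."""
    m0, m1 = p_s.membership, p_s1.membership
    genes = sorted(set(m0) | set(m1))
    n = 0
    for sub in itertools.combinations(genes, k):
        if (
            all(g in m0 for g in sub)
            and all(g in m1 for g in sub)
            and len({m0[g] for g in sub}) == 1
            and len({m1[g] for g in sub}) == 1
        ):
            n += 1
    return n


def test_counting_matches_exhaustive_enumeration():
    """500 random instances with <= 12 genes: partition-intersection counting
    equals brute-force subset enumeration for pairs and triplets."""
    rng = np.random.default_rng(17)
    for _ in range(500):
        genes = [f"g{i}" for i in range(int(rng.integers(2, 13)))]
        p_s = _random_partition(rng, genes, "1-3")
        p_s1 = _random_partition(rng, genes, "4-6")
        for k in (2, 3):
            assert conserved_comodules(p_s, p_s1, k) == _brute_force_conserved(p_s, p_s1, k)
            brute_count = sum(comb(len(g), k) for g in p_s.groups)
            assert count_comodules(p_s, k) == brute_count


def test_conserved_bounded_by_either_stage():
    rng = np.random.default_rng(23)
    for _ in range(50):
        genes = [f"g{i}" for i in range(20)]
        p_s = _random_partition(rng, genes, "1-3")
        p_s1 = _random_partition(rng, genes, "4-6")
        for k in (2, 3):
            assert conserved_comodules(p_s, p_s1, k) <= min(
                count_comodules(p_s, k), count_comodules(p_s1, k)
            )


def test_permutation_z_identity_partition_highly_significant():
    genes = [f"g{i}" for i in range(40)]
    groups = [genes[i * 5:(i + 1) * 5] for i in range(8)]
    p = _part("4-6", groups)
    p2 = _part("7-8", groups)
    ms = permutation_z(p, p2, 2, n_iter=1000, seed=1)
    assert ms.observed == count_comodules(p, 2)
    assert ms.z > 3
    assert ms.n_iterations == 1000


def test_permutation_z_degenerate_flagged():
    p = _part("1-3", [["g1", "g2", "g3"]])
    ms = permutation_z(p, p, 2, n_iter=100, seed=0)
    # a single group is invariant under permutation: zero-spread null
    assert ms.degenerate and np.isnan(ms.z)


def test_permutation_null_exchangeable_under_prelabeling():
    """Pre-permuting the later partition's labels leaves the null distribution
    unchanged (same group sizes), so z only changes through the observed."""
    rng = np.random.default_rng(4)
    genes = [f"g{i}" for i in range(30)]
    p_s = _random_partition(rng, genes, "1-3")
    p_s1 = _random_partition(rng, genes, "4-6")
    perm = rng.permutation(len(genes))
    relabeled = _part(
        "4-6",
        [[genes[perm[i]] for i, g in enumerate(genes) if g in grp]
         for grp in p_s1.groups],
    )
    a = permutation_z(p_s, p_s1, 2, n_iter=2000, seed=11)
    b = permutation_z(p_s, relabeled, 2, n_iter=2000, seed=12)
    assert a.null_mean == pytest.approx(b.null_mean, rel=0.1, abs=0.3)
    assert a.null_sd == pytest.approx(b.null_sd, rel=0.25, abs=0.3)


def test_planted_conserved_groups_drive_transition_z(sim_data):
    from tfdynamics.simulate import SimulationConfig, simulate_all
    cfg = SimulationConfig(seed=31, n_genes=1600, n_coexpression_groups=12,
                           coexpression_group_size=4, conservation_spec=1.0)
    data = simulate_all(cfg)
    tf_matrix = data.matrix.restrict(
        g for g in data.matrix.genes if data.catalog.is_tf(g)
    )
    stats = stage_transition_stats(tf_matrix, 2, n_iter=500, seed=5)
    assert all(ms.z > 3 for ms in stats if not ms.degenerate)
    assert any(not ms.degenerate for ms in stats)


def test_random_geneset_baseline_shapes():
    from tfdynamics.simulate import SimulationConfig, simulate_all
    data = simulate_all(SimulationConfig(seed=41, n_genes=300))
    df = random_geneset_baseline(
        data.matrix, data.catalog, set_size=100, n_rep=3, k=2, n_iter=100, seed=1
    )
    assert set(df.columns) == {"rep", "from_stage", "to_stage", "observed", "z"}
    assert df["rep"].nunique() == 3
    with pytest.raises(ValueError):
        random_geneset_baseline(data.matrix, data.catalog, set_size=10**6, n_rep=1)


def test_pairwise_cooccurrence_extremes():
    cat = make_catalog(4, 4)
    g1, g2, g3, g4 = cat.gene_ids
    A, B = frozenset({"a"}), frozenset({"b"})
    m = StageTissueMatrix({
        g1: [A] * 6,          # identical everywhere with g2
        g2: [A] * 6,
        g3: [B] * 6,          # never shares a term with g1/g2
        g4: [frozenset()] * 6,
    })
    frac, summary = pairwise_cooccurrence(m, cat)
    assert frac.loc[g1, g2] == 1.0
    assert frac.loc[g1, g3] == 0.0
    assert frac.loc[g1, g1] == 1.0
    assert summary.exact_pairs == 6
    assert summary.approx_pairs == 8.0


def test_pairwise_counts_match_repertoire_formulas(sim_data):
    frac, summary = pairwise_cooccurrence(sim_data.matrix, sim_data.catalog)
    n = summary.n_tf
    assert summary.exact_pairs == n * (n - 1) // 2
    assert summary.approx_pairs == n * n / 2
    assert np.allclose(frac.to_numpy(), frac.to_numpy().T)
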