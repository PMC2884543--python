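"""Ubiquity chi-square, narrow/exclusive expression sets, adult clustering."""

import numpy as np
import pytest
from scipy.stats import chi2

from tfdynamics.core import CallTable, StageTissueMatrix, UBIQUITOUS
from tfdynamics.simulate import SimulationConfig, generate_call_table, generate_catalog
from tfdynamics.specificity import (
    _chi2_2x2,
    adult_specificity_clusters,
    embryo_adult_crosstab,
    exclusively_ubiquitous,
    expression_breadth,
    never_ubiquitous_narrow_tfs,
    ubiquity_by_stage,
    AdultCluster,
)
from conftest import make_catalog


def _pearson_by_hand(table):
    """Textbook Pearson statistic: sum (O - E)^2 / E over the four cells."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    rows, cols = table.sum(axis=1), table.sum(axis=0)
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / total
            stat += (table[i, j] - e) ** 2 / e
    return stat


def test_chi2_example_against_hand_formula():
    table = np.array([[20, 80], [50, 50]])
    stat, p, degen = _chi2_2x2(table)
    assert not degen
    assert stat == pytest.approx(_pearson_by_hand(table))
    assert stat == pytest.approx(19.78, abs=0.01)
    assert p == pytest.approx(chi2.sf(stat, 1))
    assert p == pytest.approx(8.7e-6, rel=0.02)


def test_chi2_identical_proportions_is_null():
    stat, p, _ = _chi2_2x2(np.array([[30, 70], [60, 140]]))
    assert stat == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_chi2_zero_marginal_flagged_degenerate():
    _, p, degen = _chi2_2x2(np.array([[0, 0], [10, 20]]))
    assert degen and np.isnan(p)


def test_chi2_agrees_with_permutation_null():
    """Pearson p-value matches a label-shuffling permutation test."""
    rng = np.random.default_rng(5)
    table = np.array([[18, 42], [35, 25]])
    stat, p, _ = _chi2_2x2(table)
    n1 = table[0].sum()
    labels = np.repeat([0, 1], table.sum(axis=1))
    outcome = np.concatenate([
        np.repeat([1, 0], table[0]), np.repeat([1, 0], table[1])
    ])
    hits = 0
    n_iter = 10_000
    for _ in range(n_iter):
        rng.shuffle(outcome)
        t = np.array([
            [outcome[:n1].sum(), n1 - outcome[:n1].sum()],
            [outcome[n1:].sum(), len(outcome) - n1 - outcome[n1:].sum()],
        ])
        hits += _pearson_by_hand(t) >= stat - 1e-9
    assert hits / n_iter == pytest.approx(p, abs=3 * np.sqrt(p * (1 - p) / n_iter) + 1e-3)


def test_planted_tf_restricted_design_is_strongly_significant():
    """TFs with reduced ubiquitous-staining odds yield p < 1e-4 pooled over
    the mid-embryogenesis stages at 2000 genes."""
    cfg = SimulationConfig(
        seed=13,
        enrichment_spec=[(UBIQUITOUS, s, 0.08) for s in ("4-6", "7-8", "9-10", "11-12")],
    )
    from tfdynamics.simulate import default_anatomy, generate_embryo_annotations
    cat = generate_catalog(cfg)
    m, _ = generate_embryo_annotations(cat, default_anatomy(cfg.n_terms), cfg)
    pooled = ubiquity_by_stage(m, cat, pooled=True)[0]
    assert not pooled.degenerate
    assert pooled.p_value < 1e-4
    # TFs are the less-ubiquitous group
    tf_rate = pooled.tf_ubiq / (pooled.tf_ubiq + pooled.tf_restricted)
    nontf_rate = pooled.nontf_ubiq / (pooled.nontf_ubiq + pooled.nontf_restricted)
    assert tf_rate < nontf_rate


def _matrix(entries):
    return StageTissueMatrix(entries)


def test_narrow_tf_rules():
    U, B, V = frozenset({UBIQUITOUS}), frozenset({"brain"}), frozenset({"brain", "vnc"})
    E = frozenset()
    cat = make_catalog(4, 4)
    g1, g2, g3, g4 = cat.gene_ids
    m = _matrix({
        g1: [B, U, E, E, E, E],          # ubiquitous at one stage: excluded
        g2: [B, V, E, E, E, E],          # union breadth 2 < 3: included
        g3: [V, frozenset({"brain", "vnc", "gut"}), E, E, E, E],  # breadth 3: out
        g4: [E] * 6,                     # never expressed: excluded
    })
    assert never_ubiquitous_narrow_tfs(m, cat) == {g2}


def test_exclusively_ubiquitous_rules():
    U, B, E = frozenset({UBIQUITOUS}), frozenset({"brain"}), frozenset()
    m = _matrix({
        "g1": [U, U, E, E, E, E],
        "g2": [U, B, E, E, E, E],
        "g3": [B, B, E, E, E, E],
        "g4": [frozenset({UBIQUITOUS, "brain"}), E, E, E, E, E],
    })
    assert exclusively_ubiquitous(m) == {"g1"}
    # subset invariant: exclusively ubiquitous genes are ubiquitous somewhere
    ubiq_somewhere = {
        g for g in m.genes if any(UBIQUITOUS in s for s in m.entries[g])
    }
    assert exclusively_ubiquitous(m) <= ubiq_somewhere


def test_planted_exclusive_ubiquity_fraction_recovered():
    U, B, E = frozenset({UBIQUITOUS}), frozenset({"brain"}), frozenset()
    entries = {}
    for i in range(100):
        if i < 20:
            entries[f"g{i:03d}"] = [U, U, U, E, E, E]
        else:
            entries[f"g{i:03d}"] = [U, B, E, E, E, E]
    m = _matrix(entries)
    assert len(exclusively_ubiquitous(m)) == 20


def test_breadth_counts_terms_per_stage():
    m = _matrix({"g1": [frozenset({"a", "b"}), frozenset({UBIQUITOUS})] + [frozenset()] * 4})
    df = expression_breadth(m)
    assert df.loc[df["stage_range"] == "1-3", "breadth"].item() == 2
    assert df.loc[df["stage_range"] == "4-6", "ubiquitous"].item()


def _noise_free_calls():
    genes = [f"g{i}" for i in range(6)]
    tissues = ["t1", "t2", "t3", "t4"]
    direction = np.full((6, 4), "none", dtype=object)
    for i in range(3):
        direction[i, 0] = direction[i, 1] = "up"
    for i in range(3, 6):
        direction[i, 2] = direction[i, 3] = "up"
    present = np.ones((6, 4, 4), dtype=bool)
    return CallTable(genes=genes, tissues=tissues, present=present, direction=direction)


def test_two_disjoint_blocks_give_two_exact_clusters():
    clusters = adult_specificity_clusters(_noise_free_calls(), linkage_cut=0.5)
    assert len(clusters) == 2
    members = sorted(tuple(sorted(c.members)) for c in clusters)
    assert members == [("g0", "g1", "g2"), ("g3", "g4", "g5")]
    named = {tuple(sorted(c.defining_tissues)) for c in clusters}
    assert named == {("t1", "t2"), ("t3", "t4")}


def test_cluster_output_invariant_to_gene_order():
    table = _noise_free_calls()
    a = adult_specificity_clusters(table, 0.5, genes=list(table.genes))
    b = adult_specificity_clusters(table, 0.5, genes=list(reversed(table.genes)))
    assert sorted(tuple(sorted(c.members)) for c in a) == sorted(
        tuple(sorted(c.members)) for c in b
    )


def test_single_gene_with_up_calls_is_singleton_cluster():
    table = _noise_free_calls()
    clusters = adult_specificity_clusters(table, 0.5, genes=["g0"])
    assert len(clusters) == 1 and clusters[0].members == ["g0"]


def test_genes_without_up_calls_excluded():
    table = _noise_free_calls()
    table.direction[5] = "none"
    clusters = adult_specificity_clusters(table, 0.5)
    assert all("g5" not in c.members for c in clusters)


def test_crosstab_percentage_rounding():
    # 8 of 23 annotated members in the midgut -> 34.8%, printed as 35%
    members = [f"g{i:02d}" for i in range(25)]
    entries = {}
    for i, g in enumerate(members):
        if i >= 23:
            terms = frozenset()          # no late-embryo annotation
        elif i < 8:
            terms = frozenset({"midgut"})
        else:
            terms = frozenset({"brain"})
        entries[g] = [frozenset()] * 5 + [terms]
    m = _matrix(entries)
    cluster = AdultCluster(1, members, ["head"])
    df = embryo_adult_crosstab([cluster], m)
    midgut = df[df["term"] == "midgut"]
    assert midgut["n_annotated"].item() == 23
    assert round(midgut["percent_of_annotated"].item(), 1) == 34.8
    assert round(midgut["percent_of_annotated"].item()) == 35


def test_crosstab_unannotated_cluster_flagged_empty():
    m = _matrix({"g0": [frozenset()] * 6})
    df = embryo_adult_crosstab([AdultCluster(1, ["g0"], [])], m)
    assert df["empty"].all()


def test_planted_adult_clusters_recovered():
    cfg = SimulationConfig(seed=21)
    cat = generate_catalog(cfg)
    calls, gt = generate_call_table(cat, config=cfg)
    tf_genes = [g for g in calls.genes if cat.is_tf(g)]
    clusters = adult_specificity_clusters(calls, 0.7, genes=tf_genes)
    assert len(clusters) == cfg.n_up_clusters
    from collections import Counter
    agree = sum(
        Counter(gt.up_clusters.get(g) for g in c.members).most_common(1)[0][1]
        for c in clusters
    )
    total = sum(len(c.members) for c in clusters)
    assert agree / total >= 0.9
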