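"""Temporal class definitions, maternal fraction, TF-share profiles."""

import itertools

import numpy as np
import pytest

from tfdynamics.core import StageTissueMatrix
from tfdynamics.temporal import (
    TEMPORAL_CLASSES,
    classify_temporal_class,
    class_counts,
    classify_matrix,
    family_temporal_profile,
    maternal_fraction,
    tf_share_timecourse,
)
from conftest import make_catalog


@pytest.mark.parametrize(
    "support,expected",
    [
        ((1, 1, 1, 1, 1, 1), "maternal_continuous"),
        ((0, 0, 0, 1, 1, 1), "continuous_zygotic"),
        ((0, 1, 1, 1, 1, 1), "continuous_zygotic"),
        ((1, 0, 1, 0, 1, 0), "diverse"),
        ((1, 1, 0, 0, 0, 0), "early_only"),
        ((1, 1, 1, 0, 0, 0), "early_only"),
        ((0, 0, 0, 0, 0, 1), "late_only"),
        ((0, 0, 0, 1, 1, 0), "late_only"),
        ((0, 0, 0, 0, 1, 1), "late_only"),
        ((0, 0, 0, 0, 0, 0), "no_expression"),
        ((1, 1, 1, 1, 1, 0), "diverse"),  # prefix past the early window
        ((0, 1, 1, 0, 0, 0), "diverse"),  # interior block, neither early nor late
    ],
)
def test_class_definitions(support, expected):
    assert classify_temporal_class(support) == expected


def test_classes_partition_all_supports():
    """Every one of the 64 supports gets exactly one of the six labels."""
    seen = {c: 0 for c in TEMPORAL_CLASSES}
    for bits in itertools.product((False, True), repeat=6):
        seen[classify_temporal_class(bits)] += 1
    assert sum(seen.values()) == 64
    assert seen["no_expression"] == 1
    assert seen["maternal_continuous"] == 1
    assert all(v > 0 for v in seen.values())


def test_wrong_length_support_rejected():
    with pytest.raises(ValueError):
        classify_temporal_class((1, 0, 1))


def _matrix_from_supports(supports):
    return StageTissueMatrix({
        g: [frozenset({"t"}) if b else frozenset() for b in sup]
        for g, sup in supports.items()
    })


def test_maternal_fraction_printed_count_pair():
    # 219 of 373 TFs expressed in the maternal window -> 58.7%
    cat = make_catalog(373, 373)
    supports = {}
    for i, g in enumerate(cat.gene_ids):
        supports[g] = (i < 219, False, False, False, False, True)
    m = _matrix_from_supports(supports)
    assert round(100 * maternal_fraction(m, cat), 1) == 58.7


def test_maternal_fraction_requires_tfs():
    cat = make_catalog(10, 0)
    m = _matrix_from_supports({g: (1, 0, 0, 0, 0, 0) for g in cat.gene_ids})
    with pytest.raises(ValueError):
        maternal_fraction(m, cat)


def test_class_counts_match_ground_truth_mixture(sim_data):
    labels = classify_matrix(sim_data.matrix)
    gt_counts = class_counts(sim_data.ground_truth.temporal_class)
    assert class_counts(labels) == gt_counts


def test_tf_share_whole_universe_is_genomic_share():
    cat = make_catalog(200, 10)
    df = tf_share_timecourse([set(cat.gene_ids)], cat)
    assert df["tf_share"].iloc[0] == pytest.approx(0.05)
    assert df["ratio_to_genomic"].iloc[0] == pytest.approx(1.0)


def test_tf_share_doubles_for_twofold_enriched_set():
    # expressed set with twice the genomic TF proportion: share 0.10, ratio 2
    cat = make_catalog(1000, 50)
    expressed = set(cat.gene_ids[:20]) | set(cat.gene_ids[50:230])
    df = tf_share_timecourse([expressed], cat)
    assert df["tf_share"].iloc[0] == pytest.approx(0.10)
    assert df["ratio_to_genomic"].iloc[0] == pytest.approx(2.0)


def test_tf_share_empty_set_is_missing_not_zero():
    cat = make_catalog(10, 2)
    df = tf_share_timecourse([set()], cat)
    assert np.isnan(df["tf_share"].iloc[0])


def test_tf_share_invariant_to_unexpressed_universe_padding():
    from tfdynamics.core import GeneCatalog, GeneRecord
    cat_small = make_catalog(100, 10)
    expressed = set(cat_small.gene_ids[:30])
    a = tf_share_timecourse([expressed], cat_small)["tf_share"].iloc[0]
    padded = GeneCatalog(
        cat_small.records
        + [GeneRecord(f"pad{i}", f"pad{i}", False, "none") for i in range(400)]
    )
    b = tf_share_timecourse([expressed], padded)["tf_share"].iloc[0]
    assert a == pytest.approx(b)


def test_family_profile_single_family_is_hundred_percent():
    from tfdynamics.core import GeneCatalog, GeneRecord
    cat = GeneCatalog([GeneRecord(f"g{i}", f"g{i}", True, "Homeobox") for i in range(5)])
    m = _matrix_from_supports({f"g{i}": (1, 1, 0, 0, 0, 0) for i in range(5)})
    prof = family_temporal_profile(m, cat)
    pct = prof.per_family.loc["percent"]
    assert pct.loc["Homeobox", "1-3"] == pytest.approx(100.0)
    # no TF expressed late: percentage undefined, not zero
    assert np.isnan(pct.loc["Homeobox", "13-16"])


def test_family_profile_counts_match_hand_tally(sim_data):
    prof = family_temporal_profile(sim_data.matrix, sim_data.catalog)
    cat = sim_data.catalog
    m = sim_data.matrix
    hand = sum(
        1 for g in m.genes
        if cat.is_tf(g) and cat.family_of(g) == "Homeobox" and m.support(g)[2]
    )
    assert prof.per_family.loc[("count", "Homeobox"), "7-8"] == hand
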