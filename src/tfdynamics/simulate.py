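"""Synthetic data generators for all five input modalities.

Every generator is a pure function of ``(inputs, SimulationConfig)``: the
mandatory integer seed is expanded into fixed per-generator substreams
(catalog=1, annotations=2, timecourse=3, calls=4, chip=5) via
``np.random.default_rng([seed, stream])``, so adding a generator never
perturbs another's stream and outputs are bit-identical across runs.

The planted ground truth (temporal class per gene, enriched (term, stage)
cells, ChIP occupancy state sequences, adult up-call cluster membership,
planted co-expression groups) is recorded alongside the emitted datasets so
every downstream analysis has a parameter-recovery test.
"""

from __future__ import annotations

import functools
import itertools
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    GeneCatalog,
    GeneRecord,
    GenomicInterval,
    CallTable,
    PeakSet,
    SlimAnatomy,
    StageTissueMatrix,
    STAGE_INDEX,
    STAGE_LABELS,
    N_STAGES,
    TimeCourse,
    UBIQUITOUS,
)
from .temporal import DEFAULT_EARLY_CUTOFF, TEMPORAL_CLASSES, classify_temporal_class

# Fixed substream ids of the master seed.
_STREAMS = {"catalog": 1, "annotations": 2, "timecourse": 3, "calls": 4, "chip": 5}

#: Median time-course log-ratio of genes detected / not detected by in situ
#: hybridization; the targets the expressed / unexpressed value distributions
#: are centred on.
MEDIAN_EXPRESSED = 0.72
MEDIAN_UNEXPRESSED = 0.14

#: DBD family weights loosely proportional to the fly TF repertoire (zf-C2H2
#: dominant, Homeobox second, a tail of small families).
DEFAULT_FAMILY_WEIGHTS: dict[str, float] = {
    "zf-C2H2": 0.24,
    "zf-C2H2+zf-AD": 0.09,
    "Homeobox": 0.13,
    "HLH": 0.07,
    "zf-C4": 0.03,
    "BESS": 0.03,
    "Forkhead": 0.025,
    "bZIP": 0.025,
    "Ets": 0.015,
    "T-box": 0.015,
    "GATA": 0.01,
    "HMG": 0.015,
    "MADF": 0.015,
    "HTH": 0.01,
    "other": 0.28,
}

_SLIM_TERMS: list[tuple[str, str]] = [
    ("procephalic ectoderm", "ectoderm"),
    ("dorsal ectoderm", "ectoderm"),
    ("ventral ectoderm", "ectoderm"),
    ("head epidermis", "ectoderm"),
    ("dorsal epidermis", "ectoderm"),
    ("ventral epidermis", "ectoderm"),
    ("tracheal system", "ectoderm"),
    ("salivary gland", "ectoderm"),
    ("foregut", "ectoderm"),
    ("hindgut", "ectoderm"),
    ("brain", "nervous system"),
    ("ventral nerve cord", "nervous system"),
    ("peripheral nervous system", "nervous system"),
    ("sensory organs", "nervous system"),
    ("stomatogastric nervous system", "nervous system"),
    ("mesectoderm", "mesectoderm"),
    ("trunk mesoderm", "mesoderm"),
    ("head mesoderm", "mesoderm"),
    ("cardiac mesoderm", "mesoderm"),
    ("visceral mesoderm", "mesoderm"),
    ("somatic muscle", "mesoderm"),
    ("fat body", "mesoderm"),
    ("hemocytes", "mesoderm"),
    ("midgut", "endoderm"),
    ("posterior endoderm", "endoderm"),
    ("anterior endoderm", "endoderm"),
    ("malpighian tubules", "endoderm"),
    ("amnioserosa", "extraembryonic"),
    ("yolk", "extraembryonic"),
    ("pole cells", "germ line"),
]

DEFAULT_TISSUES: tuple[str, ...] = (
    "brain", "head", "crop", "midgut", "hindgut", "malpighian_tubule",
    "ovary", "testis", "accessory_gland", "salivary_gland", "fat_body",
    "carcass", "thoracic_ganglion", "heart",
)

CHIP_STATES: tuple[str, ...] = ("A_only", "B_only", "double", "none")


def default_anatomy(n_terms: int = 31) -> SlimAnatomy:
    """A slim anatomy of ``n_terms`` terms including 'ubiquitous'."""
    if n_terms < 2:
        raise ValueError("anatomy needs at least 'ubiquitous' plus one term")
    named = _SLIM_TERMS[: n_terms - 1]
    extra = [(f"tissue_{i:02d}", "other") for i in range(len(named), n_terms - 1)]
    pairs = [(UBIQUITOUS, "ubiquitous")] + named + extra
    return SlimAnatomy(
        terms=tuple(t for t, _ in pairs), lineage_map={t: l for t, l in pairs}
    )


@dataclass
class ChipSpec:
    """Planted two-factor, two-timepoint occupancy model: disjoint anchor
    sites, an initial state distribution and a per-state transition matrix."""

    n_sites: int = 3000
    site_length: int = 1000
    spacing: int = 2000
    contig: str = "chrSim"
    initial: Mapping[str, float] = field(
        default_factory=lambda: {"A_only": 0.43, "B_only": 0.0, "double": 0.08, "none": 0.49}
    )
    transitions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "A_only": {"A_only": 2 / 3, "B_only": 0.0, "double": 1 / 3, "none": 0.0},
            "B_only": {"A_only": 0.0, "B_only": 1.0, "double": 0.0, "none": 0.0},
            "double": {"A_only": 0.0, "B_only": 0.0, "double": 1.0, "none": 0.0},
            "none": {"A_only": 0.2, "B_only": 0.5, "double": 0.2, "none": 0.1},
        }
    )

    def validate(self) -> None:
        if self.n_sites < 0:
            raise ValueError("n_sites must be >= 0")
        if self.site_length <= 0 or self.spacing < self.site_length:
            raise ValueError("sites must be positive-length and non-overlapping")
        if abs(sum(self.initial.get(s, 0.0) for s in CHIP_STATES) - 1.0) > 1e-9:
            raise ValueError("initial state distribution must sum to 1")
        for s in CHIP_STATES:
            row = self.transitions.get(s, {})
            if abs(sum(row.get(t, 0.0) for t in CHIP_STATES) - 1.0) > 1e-9:
                raise ValueError(f"transition row for {s!r} must sum to 1")


def _derive_class_mixture(maternal_fraction: float) -> dict[str, float]:
    """Default temporal-class mixture with the given expected maternal
    fraction.

    The diverse class is fixed at 0.21 and drawn uniformly over the 42
    non-contiguous supports, 26 of which include range 1, contributing
    0.21 * 26/42 = 0.13 to the expected maternal fraction; the remaining
    maternal mass is split early_only : maternal_continuous = 12 : 25 and the
    non-maternal mass no_expression : late_only : continuous_zygotic =
    7 : 15 : 20.
    """
    d = 0.21
    c = d * 26 / 42
    if not (c <= maternal_fraction <= c + (1 - d)):
        raise ValueError(
            f"maternal_fraction {maternal_fraction} outside the range of the "
            "default mixture; pass an explicit class_mixture"
        )
    m = maternal_fraction - c
    rest = 1.0 - d - m
    return {
        "no_expression": rest * 7 / 42,
        "diverse": d,
        "early_only": m * 12 / 37,
        "late_only": rest * 15 / 42,
        "continuous_zygotic": rest * 20 / 42,
        "maternal_continuous": m * 25 / 37,
    }


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-data study conditions; ``seed`` is mandatory
    (no implicit entropy)."""

    seed: int
    n_genes: int = 2000
    tf_fraction: float = 0.05
    family_weights: Mapping[str, float] | None = None
    maternal_fraction: float = 0.5
    class_mixture: Mapping[str, float] | None = None
    early_cutoff: int = DEFAULT_EARLY_CUTOFF
    # annotation sampling
    n_terms: int = 31
    term_prob: float = 0.08
    ubiquitous_prob: float = 0.10
    enrichment_spec: Sequence[tuple[str, str, float]] = ()
    # planted co-expression groups
    n_coexpression_groups: int = 0
    coexpression_group_size: int = 3
    conservation_spec: float = 0.8
    # time course
    noise_sd: float = 0.3
    # adult call table
    n_replicates: int = 4
    present_prob: float = 0.8
    n_up_clusters: int = 7
    up_flip_prob: float = 0.01
    down_prob: float = 0.05
    # ChIP
    chip_spec: ChipSpec = field(default_factory=ChipSpec)

    def __post_init__(self):
        for name in ("tf_fraction", "maternal_fraction", "present_prob",
                     "up_flip_prob", "down_prob", "term_prob",
                     "ubiquitous_prob", "conservation_spec"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.family_weights is None:
            self.family_weights = dict(DEFAULT_FAMILY_WEIGHTS)
        if abs(sum(self.family_weights.values()) - 1.0) > 1e-9:
            raise ValueError("family_weights must sum to 1")
        if self.class_mixture is None:
            self.class_mixture = _derive_class_mixture(self.maternal_fraction)
        if set(self.class_mixture) - set(TEMPORAL_CLASSES):
            raise ValueError("class_mixture has unknown class labels")
        self.class_mixture = {
            c: float(self.class_mixture.get(c, 0.0)) for c in TEMPORAL_CLASSES
        }
        if abs(sum(self.class_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("class_mixture must sum to 1")
        for term, stage, mult in self.enrichment_spec:
            if stage not in STAGE_INDEX:
                raise ValueError(f"enrichment_spec: unknown stage {stage!r}")
            if mult <= 0:
                raise ValueError("enrichment multiplier must be > 0")
        self.chip_spec.validate()

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])


@dataclass
class GroundTruth:
    """Planted truth recorded by the generators."""

    temporal_class: dict[str, str] = field(default_factory=dict)
    enriched_cells: list[tuple[str, str, float]] = field(default_factory=list)
    chip_states: list[tuple[str, str]] = field(default_factory=list)
    up_clusters: dict[str, int] = field(default_factory=dict)
    #: per consecutive stage pair, planted conserved co-expression groups as
    #: a list of group sizes whose term set carried over unchanged
    conserved_groups: dict[tuple[str, str], list[int]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "temporal_class": self.temporal_class,
                "enriched_cells": [list(c) for c in self.enriched_cells],
                "chip_states": [list(s) for s in self.chip_states],
                "up_clusters": self.up_clusters,
                "conserved_groups": {
                    f"{a}->{b}": sizes for (a, b), sizes in self.conserved_groups.items()
                },
            },
            indent=1,
        )


# ---------------------------------------------------------------------------
# catalog

def generate_catalog(config: SimulationConfig) -> GeneCatalog:
    """Exactly ``round(n_genes * tf_fraction)`` TFs with family labels drawn
    from ``family_weights``; non-TFs get family 'none'."""
    n_tf = round(config.n_genes * config.tf_fraction)
    if n_tf < 1:
        raise ValueError("tf_fraction * n_genes < 1: no TFs to analyze")
    rng = config.rng("catalog")
    width = len(str(config.n_genes))
    fams = list(config.family_weights)
    probs = np.array([config.family_weights[f] for f in fams])
    tf_flags = np.zeros(config.n_genes, dtype=bool)
    tf_flags[rng.choice(config.n_genes, size=n_tf, replace=False)] = True
    fam_draws = rng.choice(len(fams), size=config.n_genes, p=probs)
    records = []
    for i in range(config.n_genes):
        gid = f"g{i + 1:0{width}d}"
        fam = fams[fam_draws[i]] if tf_flags[i] else "none"
        records.append(GeneRecord(gene_id=gid, symbol=gid, is_tf=bool(tf_flags[i]),
                                  dbd_family=fam))
    return GeneCatalog(records)


# ---------------------------------------------------------------------------
# embryo annotations

@functools.lru_cache(maxsize=None)
def _supports_by_class(early_cutoff: int) -> dict[str, list[tuple[bool, ...]]]:
    out: dict[str, list[tuple[bool, ...]]] = {c: [] for c in TEMPORAL_CLASSES}
    for bits in itertools.product((False, True), repeat=N_STAGES):
        out[classify_temporal_class(bits, early_cutoff)].append(bits)
    return out


@functools.lru_cache(maxsize=None)
def _noncontiguous_supports(early_cutoff: int) -> list[tuple[bool, ...]]:
    diverse = _supports_by_class(early_cutoff)["diverse"]
    out = []
    for bits in diverse:
        on = [i for i, b in enumerate(bits) if b]
        if len(on) != on[-1] - on[0] + 1:
            out.append(bits)
    return out


def _draw_support(label: str, rng: np.random.Generator, early_cutoff: int
                  ) -> tuple[bool, ...]:
    if label == "no_expression":
        return (False,) * N_STAGES
    if label == "maternal_continuous":
        return (True,) * N_STAGES
    if label == "diverse":
        pool = _noncontiguous_supports(early_cutoff)
    else:
        pool = _supports_by_class(early_cutoff)[label]
    return pool[rng.integers(len(pool))]


def generate_embryo_annotations(
    catalog: GeneCatalog, anatomy: SlimAnatomy, config: SimulationConfig
) -> tuple[StageTissueMatrix, GroundTruth]:
    """Assign each gene a temporal class, a support consistent with it, and
    per-stage term sets; TF inclusion odds are multiplied for the planted
    (term, stage) cells of ``enrichment_spec``.

    Planted co-expression groups (if configured) are forced to the
    maternal_continuous class and share identical term sets, carried over to
    the next stage with probability ``conservation_spec``.
    """
    rng = config.rng("annotations")
    genes = catalog.gene_ids
    n = len(genes)
    classes = list(TEMPORAL_CLASSES)
    mix = np.array([config.class_mixture[c] for c in classes])
    draws = rng.choice(len(classes), size=n, p=mix)
    labels = {g: classes[draws[i]] for i, g in enumerate(genes)}

    # planted co-expression groups claim the first TFs, forced continuous
    group_members: list[list[str]] = []
    if config.n_coexpression_groups > 0:
        tf_pool = [g for g in genes if catalog.is_tf(g)]
        need = config.n_coexpression_groups * config.coexpression_group_size
        if need > len(tf_pool):
            raise ValueError("not enough TFs for the planted co-expression groups")
        for c in range(config.n_coexpression_groups):
            members = tf_pool[c * config.coexpression_group_size:
                              (c + 1) * config.coexpression_group_size]
            group_members.append(members)
            for g in members:
                labels[g] = "maternal_continuous"

    supports = {g: _draw_support(labels[g], rng, config.early_cutoff) for g in genes}

    terms = list(anatomy.terms)
    t_idx = {t: i for i, t in enumerate(terms)}
    base = np.full(len(terms), config.term_prob)
    base[t_idx[UBIQUITOUS]] = config.ubiquitous_prob
    # per-stage TF probability vectors with planted odds multipliers
    tf_probs = [base.copy() for _ in range(N_STAGES)]
    for term, stage, mult in config.enrichment_spec:
        j = t_idx[term]
        s = STAGE_INDEX[stage]
        odds = mult * base[j] / (1 - base[j])
        tf_probs[s][j] = odds / (1 + odds)

    is_tf = np.array([catalog.is_tf(g) for g in genes])
    entries: dict[str, list[frozenset[str]]] = {g: [] for g in genes}
    term_arr = np.array(terms, dtype=object)
    for s in range(N_STAGES):
        expressed = np.array([supports[g][s] for g in genes])
        probs = np.where(is_tf[:, None], tf_probs[s][None, :], base[None, :])
        hits = rng.random((n, len(terms))) < probs
        # guarantee a nonempty set for every expressed gene
        empty = expressed & ~hits.any(axis=1)
        if empty.any():
            forced = rng.integers(len(terms), size=int(empty.sum()))
            hits[np.flatnonzero(empty), forced] = True
        for i, g in enumerate(genes):
            entries[g].append(
                frozenset(term_arr[hits[i]]) if expressed[i] else frozenset()
            )

    gt = GroundTruth(
        temporal_class=dict(labels),
        enriched_cells=[tuple(c) for c in config.enrichment_spec],
    )

    # overwrite planted groups with shared, possibly conserved term sets
    if group_members:
        non_ubiq = [t for t in terms if t != UBIQUITOUS]
        for (a, b) in zip(STAGE_LABELS, STAGE_LABELS[1:]):
            gt.conserved_groups[(a, b)] = []
        for gidx, members in enumerate(group_members):
            # a group-specific pair of terms keeps group vectors distinct
            shared = frozenset(rng.choice(len(non_ubiq), size=2, replace=False))
            current = frozenset(non_ubiq[j] for j in shared)
            for g in members:
                entries[g][0] = current
            for s in range(1, N_STAGES):
                if rng.random() < config.conservation_spec:
                    gt.conserved_groups[(STAGE_LABELS[s - 1], STAGE_LABELS[s])].append(
                        len(members)
                    )
                else:
                    pick = rng.choice(len(non_ubiq), size=2, replace=False)
                    current = frozenset(non_ubiq[j] for j in pick)
                for g in members:
                    entries[g][s] = current

    return StageTissueMatrix(entries), gt


# ---------------------------------------------------------------------------
# time course

def default_timepoints(n: int = 12, hours: float = 24.0) -> tuple[tuple[float, float], ...]:
    step = hours / n
    return tuple((i * step, (i + 1) * step) for i in range(n))


def window_label(tp: tuple[float, float]) -> str:
    return f"{tp[0]:g}-{tp[1]:g}"


def generate_timecourse(
    catalog: GeneCatalog,
    timepoints: Sequence[tuple[float, float]],
    config: SimulationConfig,
    expressed: pd.DataFrame | None = None,
) -> tuple[TimeCourse, pd.DataFrame]:
    """Gaussian log-ratios centred on 0.72 where a gene is expressed and 0.14
    where it is not, with sd ``noise_sd``.

    If ``expressed`` (gene × timepoint booleans) is not supplied, flags are
    derived from freshly drawn temporal classes by mapping each timepoint to
    a stage range proportionally along the axis.  Returns the time course and
    the expressed-flag frame (the ground truth for recovery tests).
    """
    if len(timepoints) == 0:
        raise ValueError("timepoint list must be nonempty")
    if config.noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    rng = config.rng("timecourse")
    genes = catalog.gene_ids
    labels = [window_label(tp) for tp in timepoints]
    if expressed is None:
        classes = list(TEMPORAL_CLASSES)
        mix = np.array([config.class_mixture[c] for c in classes])
        draws = rng.choice(len(classes), size=len(genes), p=mix)
        stage_of_tp = [min(N_STAGES - 1, i * N_STAGES // len(timepoints))
                       for i in range(len(timepoints))]
        flags = np.zeros((len(genes), len(timepoints)), dtype=bool)
        for i, g in enumerate(genes):
            sup = _draw_support(classes[draws[i]], rng, config.early_cutoff)
            flags[i] = [sup[s] for s in stage_of_tp]
        expressed = pd.DataFrame(flags, index=genes, columns=labels)
    else:
        expressed = expressed.loc[genes, labels].astype(bool)
    centre = np.where(expressed.to_numpy(), MEDIAN_EXPRESSED, MEDIAN_UNEXPRESSED)
    values = centre + rng.normal(0.0, config.noise_sd, size=centre.shape)
    tc = TimeCourse(
        timepoints=tuple(tuple(tp) for tp in timepoints),
        values=pd.DataFrame(values, index=genes, columns=labels),
    )
    return tc, expressed


# ---------------------------------------------------------------------------
# adult call table

def generate_call_table(
    catalog: GeneCatalog,
    tissues: Sequence[str] = DEFAULT_TISSUES,
    config: SimulationConfig | None = None,
) -> tuple[CallTable, GroundTruth]:
    """Bernoulli present calls per replicate plus planted 'up'-call clusters.

    Each of the ``n_up_clusters`` clusters is tied to a distinct pair of
    tissues; TF genes are assigned to clusters round-robin and receive 'up'
    calls in their cluster's tissues, with per-cell flip noise
    ``up_flip_prob``.
    """
    if config is None:
        raise ValueError("config is required")
    if config.n_replicates < 1:
        raise ValueError("replicate count must be >= 1")
    if config.n_up_clusters > 0 and len(tissues) < 2 * config.n_up_clusters:
        raise ValueError("need at least 2 tissues per planted up-call cluster")
    rng = config.rng("calls")
    genes = catalog.gene_ids
    present = rng.random((len(genes), len(tissues), config.n_replicates)) < config.present_prob
    direction = np.full((len(genes), len(tissues)), "none", dtype=object)
    down = rng.random((len(genes), len(tissues))) < config.down_prob
    direction[down] = "down"

    gt = GroundTruth()
    if config.n_up_clusters > 0:
        tf_genes = [g for g in genes if catalog.is_tf(g)]
        g_idx = {g: i for i, g in enumerate(genes)}
        signatures = [
            (2 * c, 2 * c + 1) for c in range(config.n_up_clusters)
        ]
        for k, g in enumerate(tf_genes):
            c = k % config.n_up_clusters
            gt.up_clusters[g] = c
            for j in signatures[c]:
                direction[g_idx[g], j] = "up"
        flips = rng.random((len(genes), len(tissues))) < config.up_flip_prob
        for i, j in zip(*np.nonzero(flips)):
            direction[i, j] = "none" if direction[i, j] == "up" else "up"
    table = CallTable(genes=list(genes), tissues=list(tissues),
                      present=present, direction=direction)
    return table, gt


# ---------------------------------------------------------------------------
# ChIP experiment

def generate_chip_experiment(
    config: SimulationConfig,
) -> tuple[dict[tuple[str, str], PeakSet], GroundTruth]:
    """Disjoint anchor sites with occupancy states drawn from the planted
    initial distribution at t1 and the transition matrix at t2; a factor
    occupies a site via a peak interval overlapping it.

    Returns peak sets keyed by (factor, timepoint) with factor in {A, B} and
    timepoint in {t1, t2}.
    """
    spec = config.chip_spec
    rng = config.rng("chip")
    init = np.array([spec.initial.get(s, 0.0) for s in CHIP_STATES])
    trans = np.array(
        [[spec.transitions[s].get(t, 0.0) for t in CHIP_STATES] for s in CHIP_STATES]
    )
    s1 = rng.choice(len(CHIP_STATES), size=spec.n_sites, p=init)
    s2 = np.empty(spec.n_sites, dtype=int)
    for i, row in enumerate(trans):
        mask = s1 == i
        s2[mask] = rng.choice(len(CHIP_STATES), size=int(mask.sum()), p=row)

    peaks: dict[tuple[str, str], list[GenomicInterval]] = {
        (f, t): [] for f in "AB" for t in ("t1", "t2")
    }
    gt = GroundTruth()
    L = spec.site_length
    for i in range(spec.n_sites):
        start = i * spec.spacing
        a_iv = GenomicInterval(spec.contig, start + L // 20, start + 11 * L // 20)
        b_iv = GenomicInterval(spec.contig, start + 8 * L // 20, start + 18 * L // 20)
        for t, s in (("t1", s1[i]), ("t2", s2[i])):
            state = CHIP_STATES[s]
            if state in ("A_only", "double"):
                peaks[("A", t)].append(a_iv)
            if state in ("B_only", "double"):
                peaks[("B", t)].append(b_iv)
        gt.chip_states.append((CHIP_STATES[s1[i]], CHIP_STATES[s2[i]]))
    return {k: PeakSet(v) for k, v in peaks.items()}, gt


# ---------------------------------------------------------------------------
# everything at once

@dataclass
class SimulatedData:
    config: SimulationConfig
    catalog: GeneCatalog
    anatomy: SlimAnatomy
    matrix: StageTissueMatrix
    timecourse: TimeCourse
    expressed: pd.DataFrame
    calls: CallTable
    peaks: dict[tuple[str, str], PeakSet]
    ground_truth: GroundTruth


def simulate_all(
    config: SimulationConfig,
    tissues: Sequence[str] = DEFAULT_TISSUES,
    timepoints: Sequence[tuple[float, float]] | None = None,
) -> SimulatedData:
    """Generate all five modalities from one config and merge the ground
    truth records."""
    anatomy = default_anatomy(config.n_terms)
    catalog = generate_catalog(config)
    matrix, gt_ann = generate_embryo_annotations(catalog, anatomy, config)
    tc, expressed = generate_timecourse(
        catalog, timepoints or default_timepoints(), config
    )
    calls, gt_calls = generate_call_table(catalog, tissues, config)
    peaks, gt_chip = generate_chip_experiment(config)
    gt = GroundTruth(
        temporal_class=gt_ann.temporal_class,
        enriched_cells=gt_ann.enriched_cells,
        chip_states=gt_chip.chip_states,
        up_clusters=gt_calls.up_clusters,
        conserved_groups=gt_ann.conserved_groups,
    )
    return SimulatedData(
        config=config, catalog=catalog, anatomy=anatomy, matrix=matrix,
        timecourse=tc, expressed=expressed, calls=calls, peaks=peaks,
        ground_truth=gt,
    )
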