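"""Domain types shared across the pipeline.

The central object is the binary stage × tissue expression matrix derived from
in situ annotation: per gene, one set of slim-anatomy terms for each of the six
embryonic stage ranges (1-3, 4-6, 7-8, 9-10, 11-12, 13-16).  A gene counts as
expressed at a stage range iff its term set there is nonempty.  Everything else
— time-course log-ratios, replicate present/absent call tables, ChIP peak
intervals — is carried in thin validated containers around numpy/pandas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The six embryonic stage-range windows of the in situ annotation, in
#: developmental order (index 1..6 in 1-based terms).
STAGE_LABELS: tuple[str, ...] = ("1-3", "4-6", "7-8", "9-10", "11-12", "13-16")

N_STAGES = len(STAGE_LABELS)

STAGE_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(STAGE_LABELS)}

#: Distinguished anatomy term for staining of the whole embryo.
UBIQUITOUS = "ubiquitous"

#: DNA-binding-domain family vocabulary: the families with more than five
#: members in the fly TF repertoire, the zinc-finger-associated-domain
#: subfamily of zf-C2H2, a catch-all "other", and "none" for non-TFs or
#: literature-curated TFs without a recognized DBD.
DBD_FAMILIES: tuple[str, ...] = (
    "zf-C2H2",
    "zf-C2H2+zf-AD",
    "Homeobox",
    "HLH",
    "zf-C4",
    "BESS",
    "Forkhead",
    "bZIP",
    "Ets",
    "T-box",
    "GATA",
    "HMG",
    "MADF",
    "HTH",
    "other",
    "none",
)


class ValidationError(ValueError):
    """Input data violates a documented invariant (duplicate ids, unknown
    vocabulary, malformed coordinates...)."""


class FormatError(ValueError):
    """A file does not conform to the documented tabular format."""


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    symbol: str
    is_tf: bool
    dbd_family: str = "none"


class GeneCatalog:
    """The gene universe: TF flag and DBD-family label per gene.

    Family-level analyses skip TFs with family "none" (curated TFs without a
    recognized DNA-binding domain).
    """

    def __init__(self, records: Iterable[GeneRecord]):
        self.records: list[GeneRecord] = list(records)
        ids = [r.gene_id for r in self.records]
        dup = {g for g in ids if ids.count(g) > 1} if len(set(ids)) != len(ids) else set()
        if dup:
            raise ValidationError(f"duplicate gene_id(s) in catalog: {sorted(dup)}")
        self._by_id = {r.gene_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]

    @property
    def tf_ids(self) -> set[str]:
        return {r.gene_id for r in self.records if r.is_tf}

    @property
    def nontf_ids(self) -> set[str]:
        return {r.gene_id for r in self.records if not r.is_tf}

    def is_tf(self, gene_id: str) -> bool:
        return self._by_id[gene_id].is_tf

    def family_of(self, gene_id: str) -> str:
        return self._by_id[gene_id].dbd_family


@dataclass(frozen=True)
class SlimAnatomy:
    """Reduced anatomical vocabulary with a distinguished 'ubiquitous' term
    and a total term → lineage mapping."""

    terms: tuple[str, ...]
    lineage_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if list(self.terms).count(UBIQUITOUS) != 1:
            raise ValidationError(
                f"anatomy must contain the term {UBIQUITOUS!r} exactly once"
            )
        if len(set(self.terms)) != len(self.terms):
            raise ValidationError("anatomy terms must be unique")
        if self.lineage_map:
            missing = [t for t in self.terms if t not in self.lineage_map]
            if missing:
                raise ValidationError(f"lineage_map missing terms: {missing}")

    def __contains__(self, term: str) -> bool:
        return term in self.terms


class StageTissueMatrix:
    """Binary spatio-temporal expression: per gene, a frozenset of anatomy
    terms at each of the six stage ranges.

    ``entries[gene]`` is a tuple of six frozensets; an empty set means the
    gene is not annotated as expressed in that window.
    """

    def __init__(self, entries: Mapping[str, Sequence[frozenset[str]]]):
        self.entries: dict[str, tuple[frozenset[str], ...]] = {}
        for g, sets in entries.items():
            sets = tuple(frozenset(s) for s in sets)
            if len(sets) != N_STAGES:
                raise ValidationError(
                    f"gene {g!r}: expected {N_STAGES} stage term sets, got {len(sets)}"
                )
            self.entries[g] = sets

    @property
    def genes(self) -> list[str]:
        return list(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.entries

    def terms_at(self, gene_id: str, stage: int) -> frozenset[str]:
        """Term set of ``gene_id`` at 0-based stage-range index ``stage``."""
        return self.entries[gene_id][stage]

    def support(self, gene_id: str) -> tuple[bool, ...]:
        """Expressed / not-expressed over the six stage ranges."""
        return tuple(len(s) > 0 for s in self.entries[gene_id])

    def expressed_at(self, stage: int) -> set[str]:
        return {g for g, sets in self.entries.items() if sets[stage]}

    def expressed_anywhere(self) -> set[str]:
        return {g for g, sets in self.entries.items() if any(sets)}

    def restrict(self, genes: Iterable[str]) -> "StageTissueMatrix":
        keep = set(genes)
        return StageTissueMatrix({g: s for g, s in self.entries.items() if g in keep})

    def validate(self, anatomy: SlimAnatomy) -> None:
        for g, sets in self.entries.items():
            for s_idx, terms in enumerate(sets):
                bad = [t for t in terms if t not in anatomy]
                if bad:
                    raise ValidationError(
                        f"gene {g!r}, stage {STAGE_LABELS[s_idx]!r}: "
                        f"unknown term(s) {bad}"
                    )


@dataclass
class TimeCourse:
    """Gene × timepoint log-ratio matrix relative to a pooled-stage reference.

    ``timepoints`` are (start, end) hour-AEL windows in strictly increasing
    order; ``values`` is a DataFrame indexed by gene with one column per
    window label, NaN marking an explicitly missing measurement.
    """

    timepoints: tuple[tuple[float, float], ...]
    values: pd.DataFrame

    def __post_init__(self):
        starts = [a for a, _ in self.timepoints]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValidationError("timepoints must be strictly increasing")
        if self.values.shape[1] != len(self.timepoints):
            raise ValidationError("value columns must match timepoints")


@dataclass
class CallTable:
    """Replicate-level present/absent calls plus per-tissue up/down calls.

    ``present`` has shape (n_genes, n_tissues, n_replicates) with boolean
    entries (True = present call); ``direction`` is an object array of
    "up" / "down" / "none" per gene × tissue.
    """

    genes: list[str]
    tissues: list[str]
    present: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        if self.present.shape[:2] != (len(self.genes), len(self.tissues)):
            raise ValidationError("present array shape mismatch")
        if self.direction.shape != (len(self.genes), len(self.tissues)):
            raise ValidationError("direction array shape mismatch")
        bad = set(np.unique(self.direction)) - {"up", "down", "none"}
        if bad:
            raise ValidationError(f"invalid direction values: {sorted(bad)}")

    @property
    def n_replicates(self) -> int:
        return self.present.shape[2]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic interval; strand-free."""

    contig: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.contig}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


class PeakSet:
    """A set of genomic intervals (ChIP peaks or transfrags), kept sorted by
    (contig, start, end).  Overlapping intervals are retained as-is; merging
    is a downstream operation."""

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        self.intervals: list[GenomicInterval] = sorted(intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def by_contig(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.contig, []).append(iv)
        return out


@dataclass
class EnrichmentResult:
    """TF over-representation in one (stage range × anatomy term) cell.

    ``z = (n_tf - expected_tf) / null_sd`` against random draws of
    ``n_tf + n_nontf`` genes from the universe; significant iff
    ``z >= z_threshold`` (default 3).  ``degenerate`` flags a null with zero
    spread (z undefined, reported as NaN).
    """

    stage_range: str
    term: str
    n_tf: int
    n_nontf: int
    expected_tf: float
    null_sd: float
    z: float
    significant: bool
    degenerate: bool = False


@dataclass
class ModuleStats:
    """Conserved co-expression modules between two consecutive stage ranges
    with a label-permutation null."""

    from_stage: str
    to_stage: str
    k: int
    observed: int
    null_mean: float
    null_sd: float
    z: float
    n_iterations: int
    degenerate: bool = False
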