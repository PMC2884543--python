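"""Readers and writers for the pipeline's tabular and interval formats.

All tables are plain TSV with a header row; peaks and coding regions are BED3
(0-based half-open).  Formats:

* gene catalog:   gene_id, symbol, is_tf (0/1), dbd_family
* annotations:    gene_id, stage_range, term   (long format, one term per row)
* gene universe:  one gene_id per line (distinguishes "never annotated" from
                  "annotated as unexpressed" — both files are required inputs)
* time course:    gene_id + one column per hour-AEL window labelled "a-b"
* call table:     gene_id, tissue, present (string of P/A, one char per
                  replicate), direction (up/down/none)
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .core import (
    CallTable,
    FormatError,
    GeneCatalog,
    GeneRecord,
    GenomicInterval,
    PeakSet,
    SlimAnatomy,
    StageTissueMatrix,
    STAGE_INDEX,
    STAGE_LABELS,
    N_STAGES,
    TimeCourse,
    ValidationError,
)

_TRUTHY = {"1", "true", "True", "TRUE", "yes"}
_FALSY = {"0", "false", "False", "FALSE", "no"}


def _require_columns(header: list[str], required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_gene_catalog(path) -> GeneCatalog:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(list(df.columns), ["gene_id", "is_tf", "dbd_family"], path)
    records = []
    for row in df.itertuples(index=False):
        raw = str(row.is_tf)
        if raw in _TRUTHY:
            is_tf = True
        elif raw in _FALSY:
            is_tf = False
        else:
            raise FormatError(f"{path}: unparseable is_tf value {raw!r}")
        records.append(
            GeneRecord(
                gene_id=row.gene_id,
                symbol=getattr(row, "symbol", row.gene_id) or row.gene_id,
                is_tf=is_tf,
                dbd_family=row.dbd_family,
            )
        )
    return GeneCatalog(records)


def write_gene_catalog(catalog: GeneCatalog, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "symbol", "is_tf", "dbd_family"])
        for r in catalog.records:
            w.writerow([r.gene_id, r.symbol, int(r.is_tf), r.dbd_family])


def read_anatomy(path) -> SlimAnatomy:
    """TSV with columns term, lineage."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(list(df.columns), ["term", "lineage"], path)
    return SlimAnatomy(
        terms=tuple(df["term"]),
        lineage_map=dict(zip(df["term"], df["lineage"])),
    )


def write_anatomy(anatomy: SlimAnatomy, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["term", "lineage"])
        for t in anatomy.terms:
            w.writerow([t, anatomy.lineage_map.get(t, "other")])


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_annotations(
    path, anatomy: SlimAnatomy, gene_universe: Iterable[str]
) -> StageTissueMatrix:
    """Read long-format (gene_id, stage_range, term) rows into a stage ×
    tissue matrix over ``gene_universe``.

    Genes in the universe that never appear in the file get all-empty term
    sets (temporal class "no expression").  Unknown terms or stage labels are
    validation errors reported with their line number.
    """
    universe = list(dict.fromkeys(gene_universe))
    entries: dict[str, list[set[str]]] = {
        g: [set() for _ in range(N_STAGES)] for g in universe
    }
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return StageTissueMatrix(entries)
        _require_columns(header, ["gene_id", "stage_range", "term"], path)
        gi, si, ti = (header.index(c) for c in ("gene_id", "stage_range", "term"))
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            gene, stage, term = row[gi], row[si], row[ti]
            if stage not in STAGE_INDEX:
                raise ValidationError(
                    f"{path}:{lineno}: unknown stage range {stage!r}"
                )
            if term not in anatomy:
                raise ValidationError(f"{path}:{lineno}: unknown term {term!r}")
            if gene not in entries:
                raise ValidationError(
                    f"{path}:{lineno}: gene {gene!r} not in the gene universe"
                )
            entries[gene][STAGE_INDEX[stage]].add(term)
    return StageTissueMatrix(entries)


def write_annotations(matrix: StageTissueMatrix, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "stage_range", "term"])
        for g in matrix.genes:
            for s_idx, terms in enumerate(matrix.entries[g]):
                for t in sorted(terms):
                    w.writerow([g, STAGE_LABELS[s_idx], t])


def _parse_window(label: str) -> tuple[float, float]:
    try:
        a, b = label.split("-")
        return float(a), float(b)
    except ValueError as exc:
        raise FormatError(f"unparseable timepoint column {label!r}") from exc


def read_timecourse(path) -> TimeCourse:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    timepoints = tuple(_parse_window(c) for c in df.columns)
    return TimeCourse(timepoints=timepoints, values=df.astype(float))


def write_timecourse(tc: TimeCourse, path) -> None:
    tc.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.4f")


def read_call_table(path) -> CallTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(list(df.columns), ["gene_id", "tissue", "present", "direction"], path)
    genes = list(dict.fromkeys(df["gene_id"]))
    tissues = list(dict.fromkeys(df["tissue"]))
    reps = {len(p) for p in df["present"]}
    if len(reps) != 1:
        raise ValidationError(f"{path}: inconsistent replicate counts {sorted(reps)}")
    n_rep = reps.pop()
    present = np.zeros((len(genes), len(tissues), n_rep), dtype=bool)
    direction = np.full((len(genes), len(tissues)), "none", dtype=object)
    g_idx = {g: i for i, g in enumerate(genes)}
    t_idx = {t: i for i, t in enumerate(tissues)}
    for row in df.itertuples(index=False):
        bad = set(row.present) - {"P", "A"}
        if bad:
            raise ValidationError(f"{path}: invalid present-call chars {sorted(bad)}")
        present[g_idx[row.gene_id], t_idx[row.tissue]] = [c == "P" for c in row.present]
        direction[g_idx[row.gene_id], t_idx[row.tissue]] = row.direction
    return CallTable(genes=genes, tissues=tissues, present=present, direction=direction)


def write_call_table(table: CallTable, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "tissue", "present", "direction"])
        for i, g in enumerate(table.genes):
            for j, t in enumerate(table.tissues):
                calls = "".join("P" if p else "A" for p in table.present[i, j])
                w.writerow([g, t, calls, table.direction[i, j]])


def read_peaks(path) -> PeakSet:
    """Read a BED3+ file; zero-length or inverted intervals are rejected with
    their line number."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED fields")
            contig, start, end = fields[0], fields[1], fields[2]
            try:
                start, end = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValidationError(
                    f"{path}:{lineno}: empty or inverted interval "
                    f"{contig}:{start}-{end}"
                )
            intervals.append(GenomicInterval(contig, start, end))
    return PeakSet(intervals)


def write_peaks(peaks: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for iv in peaks:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\n")
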