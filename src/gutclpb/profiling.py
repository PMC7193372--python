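"""Functional read-count profiling of annotated metagenomic ORFs.

Reproduces the annotation-counting pipeline applied to shotgun
metagenomes: pick the best homology annotation per ORF, assign mapped
reads to ORFs by overlap, count reads per KEGG annotation and per
functional category (an annotation may belong to several categories),
roll the counts into a sample x annotation contingency table with
relative abundances, and filter low-abundance taxa.

Conventions (fixed so the pipeline is fully deterministic):

* best hit per ORF = minimal e-value, then maximal bitscore, then
  lexicographically smallest KO;
* a read belongs to the ORF on its contig covering >= 50% of the read's
  aligned length; ties go to the ORF with the smaller start, then the
  smaller orf_id; coordinates are 1-based inclusive and strand-agnostic;
* the taxa filter keeps a taxon with strictly more than 10 reads in at
  least two samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HIT_COLUMNS = ("orf_id", "ko", "evalue", "bitscore")
LOCATION_COLUMNS = ("contig", "start", "end", "strand", "orf_id")
READ_COLUMNS = ("read_id", "contig", "start", "end")


@dataclass(frozen=True)
class HmmerHit:
    orf_id: str
    ko: str
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative e-value for {self.orf_id}")


@dataclass(frozen=True)
class OrfLocation:
    contig: str
    start: int
    end: int
    strand: str
    orf_id: str

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid span [{self.start}, {self.end}] for {self.orf_id}")


@dataclass(frozen=True)
class ReadAlignment:
    read_id: str
    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"invalid span for read {self.read_id}")


@dataclass
class FunctionTable:
    """Sample x annotation contingency table with roll-ups.

    ``counts``: integer read counts per sample (rows) and KO (columns).
    ``category_counts``: per-category sums; a KO contributes its full
    count to every category it belongs to, so category totals may exceed
    annotation totals.  ``relative``: per-sample fractions over all
    annotated reads (rows with a nonzero total sum to 1).
    """

    counts: pd.DataFrame
    category_counts: pd.DataFrame
    relative: pd.DataFrame
    descriptions: Dict[str, str] = field(default_factory=dict)
    dropped_reads: Dict[str, int] = field(default_factory=dict)


class FormatError(ValueError):
    pass


def _read_tsv(path, required: Sequence[str], numeric: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing required column {col!r}")
    for col in numeric:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based file line, counting the header
            raise FormatError(f"{path.name}: unparsable value in column {col!r} at row {row}")
        if parsed.isna().any():
            row = int(parsed.isna().idxmax()) + 2
            raise FormatError(f"{path.name}: missing value in column {col!r} at row {row}")
        df[col] = parsed
    return df


def parse_hits(path) -> List[HmmerHit]:
    """Read a tblout-style homology hit table (TSV with header)."""
    df = _read_tsv(path, HIT_COLUMNS, numeric=("evalue", "bitscore"))
    return [
        HmmerHit(str(r.orf_id), str(r.ko), float(r.evalue), float(r.bitscore))
        for r in df.itertuples(index=False)
    ]


def parse_orf_locations(path) -> List[OrfLocation]:
    """Read ORF genomic locations (1-based inclusive coordinates)."""
    df = _read_tsv(path, LOCATION_COLUMNS, numeric=("start", "end"))
    return [
        OrfLocation(str(r.contig), int(r.start), int(r.end), str(r.strand), str(r.orf_id))
        for r in df.itertuples(index=False)
    ]


def parse_read_alignments(path) -> pd.DataFrame:
    """Read read-to-contig alignments; keeps a ``sample`` column if present."""
    return _read_tsv(path, READ_COLUMNS, numeric=("start", "end"))


def reads_from_frame(df: pd.DataFrame) -> List[ReadAlignment]:
    return [
        ReadAlignment(str(r.read_id), str(r.contig), int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]


def best_annotation_per_orf(hits: Iterable[HmmerHit]) -> Dict[str, str]:
    """Best KO per ORF: min e-value, then max bitscore, then smallest KO."""
    best: Dict[str, HmmerHit] = {}
    for hit in hits:
        cur = best.get(hit.orf_id)
        if cur is None or (hit.evalue, -hit.bitscore, hit.ko) < (cur.evalue, -cur.bitscore, cur.ko):
            best[hit.orf_id] = hit
    return {orf: h.ko for orf, h in best.items()}


def assign_reads_to_orfs(
    reads: Iterable[ReadAlignment],
    orfs: Iterable[OrfLocation],
) -> Dict[str, int]:
    """Count reads per ORF; a read needs >= 50% overlap to be assigned.

    The overlap fraction is relative to the read's aligned length.  When
    two ORFs tie on overlap, the smaller start (then smaller orf_id)
    wins.  Reads overlapping no ORF at >= 50% stay unassigned.
    """
    by_contig: Dict[str, List[OrfLocation]] = {}
    for orf in orfs:
        by_contig.setdefault(orf.contig, []).append(orf)
    for lst in by_contig.values():
        lst.sort(key=lambda o: (o.start, o.orf_id))

    counts: Dict[str, int] = {}
    for read in reads:
        read_len = read.end - read.start + 1
        best_orf, best_overlap = None, 0
        for orf in by_contig.get(read.contig, ()):
            overlap = min(read.end, orf.end) - max(read.start, orf.start) + 1
            if overlap > best_overlap:  # sorted order makes ties keep the smaller start
                best_orf, best_overlap = orf, overlap
        if best_orf is not None and 2 * best_overlap >= read_len:
            counts[best_orf.orf_id] = counts.get(best_orf.orf_id, 0) + 1
    return counts


def build_function_table(
    orf2ko: Mapping[str, str],
    orf_read_counts: Mapping,
    ko2categories: Optional[Mapping[str, Set[str]]] = None,
    descriptions: Optional[Mapping[str, str]] = None,
) -> FunctionTable:
    """Contingency table of reads per annotation and per category.

    ``orf_read_counts`` maps sample -> {orf_id: reads}; a flat
    {orf_id: reads} mapping is treated as a single sample "S1".  Reads
    on ORFs without an annotation are dropped and logged per sample.
    KOs absent from ``ko2categories`` count under category "unmapped".
    """
    first = next(iter(orf_read_counts.values()), None)
    if first is not None and not isinstance(first, Mapping):
        orf_read_counts = {"S1": orf_read_counts}

    samples = list(orf_read_counts)
    kos = sorted(set(orf2ko.values()))
    counts = pd.DataFrame(0, index=samples, columns=kos, dtype=int)
    dropped: Dict[str, int] = {}
    for sample, per_orf in orf_read_counts.items():
        lost = 0
        for orf, n in per_orf.items():
            ko = orf2ko.get(orf)
            if ko is None:
                lost += int(n)
            else:
                counts.loc[sample, ko] += int(n)
        dropped[sample] = lost
        if lost:
            logger.info("sample %s: dropped %d reads on unannotated ORFs", sample, lost)

    ko2categories = ko2categories or {}
    categories = sorted({c for cats in ko2categories.values() for c in cats} | {"unmapped"})
    category_counts = pd.DataFrame(0, index=samples, columns=categories, dtype=int)
    for ko in kos:
        cats = ko2categories.get(ko) or {"unmapped"}
        for cat in cats:
            category_counts[cat] += counts[ko]

    totals = counts.sum(axis=1)
    relative = counts.div(totals.where(totals > 0, 1), axis=0).astype(float)

    counts.index.name = relative.index.name = category_counts.index.name = "sample"
    return FunctionTable(
        counts=counts,
        category_counts=category_counts,
        relative=relative,
        descriptions=dict(descriptions or {}),
        dropped_reads=dropped,
    )


def filter_taxa(count_matrix: pd.DataFrame) -> pd.DataFrame:
    """Keep taxa (rows) with > 10 reads (strict) in at least two samples."""
    values = count_matrix.to_numpy()
    if (values < 0).any():
        raise ValueError("count matrix must be non-negative")
    keep = (count_matrix > 10).sum(axis=1) >= 2
    return count_matrix.loc[keep]
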