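"""Molecular-mimicry screen of metagenomic ORFs against an epitope motif.

The screen asks whether predicted bacterial ORFs carry a region mimicking
a host peptide epitope (by default the alpha-MSH-mimetic hexapeptide
RWGKPV of the E. coli disaggregase chaperone ClpB).  The procedure:

1. locate the motif in a reference protein;
2. align each ORF to the reference region around the epitope
   (deterministic semi-global alignment, see :mod:`gutclpb.alignment`);
3. keep only ORFs whose alignment covers the epitope columns, trimming
   everything beyond a 30-residue flank on either side of the motif;
4. score percent identity over the motif columns (motif identity) and
   over the whole trimmed window (window identity);
5. aggregate by bacterial family: how many sequences carry the motif at
   100% identity, and the family's mean window identity.

Motif identity and window identity are deliberately both reported: a
family can carry a perfect epitope copy inside an otherwise diverged
protein, and the two numbers answer different questions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .alignment import PairwiseAlignment, align_pair, identity, validate_protein

#: Hexapeptide mimicking the alpha-MSH anorexigenic peptide in E. coli ClpB.
DEFAULT_MOTIF = "RWGKPV"
#: Residues kept on either side of the aligned motif before scoring.
DEFAULT_FLANK = 30


@dataclass(frozen=True)
class EpitopeMotif:
    """A short amino-acid motif to screen for."""

    sequence: str = DEFAULT_MOTIF
    name: str = "alpha-MSH-like epitope"

    def __post_init__(self) -> None:
        if len(self.sequence) < 3:
            raise ValueError("motif must be at least 3 residues long")
        validate_protein(self.sequence, "motif")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReferenceProtein:
    """Reference carrying the epitope, with the located motif span (1-based)."""

    id: str
    accession: str
    sequence: str
    motif_start: int = 0
    motif_end: int = 0

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MimicryHit:
    orf_id: str
    family: str
    covers_epitope: bool
    motif_identity: float
    window_identity: float
    trimmed_ref: str
    trimmed_query: str


@dataclass(frozen=True)
class FamilyMimicrySummary:
    family: str
    n_sequences: int
    n_full_motif: int
    mean_window_identity: float


@dataclass(frozen=True)
class DiscardRecord:
    orf_id: str
    family: str
    reason: str


class MotifNotFoundError(ValueError):
    pass


def locate_motif(
    sequence: str, motif: EpitopeMotif | str, *, fuzzy: bool = False
) -> Tuple[int, int]:
    """First exact occurrence of the motif, 1-based inclusive span.

    With ``fuzzy=True`` an absent motif falls back to the best ungapped
    placement (maximal residue matches, earliest on ties); otherwise it
    raises :class:`MotifNotFoundError`.  Multiple exact occurrences emit
    a warning and the first is used.
    """
    pat = motif.sequence if isinstance(motif, EpitopeMotif) else motif
    k = len(pat)
    occurrences = []
    start = sequence.find(pat)
    while start != -1:
        occurrences.append(start)
        start = sequence.find(pat, start + 1)
    if occurrences:
        if len(occurrences) > 1:
            warnings.warn(
                f"motif {pat!r} occurs {len(occurrences)} times; using the first "
                f"occurrence at position {occurrences[0] + 1}",
                stacklevel=2,
            )
        s = occurrences[0]
        return s + 1, s + k
    if not fuzzy:
        raise MotifNotFoundError(f"motif {pat!r} not found in reference sequence")
    if len(sequence) < k:
        raise MotifNotFoundError("reference shorter than the motif")
    best_s, best_matches = 0, -1
    for s in range(len(sequence) - k + 1):
        matches = sum(1 for a, b in zip(sequence[s : s + k], pat) if a == b)
        if matches > best_matches:
            best_s, best_matches = s, matches
    return best_s + 1, best_s + k


def _column_ref_positions(alignment: PairwiseAlignment) -> List[Optional[int]]:
    """Reference position (1-based) carried by each alignment column."""
    out: List[Optional[int]] = []
    pos = alignment.ref_start - 1
    for ch in alignment.aligned_ref:
        if ch == "-":
            out.append(None)
        else:
            pos += 1
            out.append(pos)
    return out


def epitope_window(
    alignment: PairwiseAlignment,
    motif_span: Tuple[int, int],
    flank: int = DEFAULT_FLANK,
    ref_length: Optional[int] = None,
) -> Optional[Tuple[str, str]]:
    """Trim an alignment to the epitope region, or ``None`` if uncovered.

    The window spans reference positions ``[motif_start - flank,
    motif_end + flank]`` clipped to the reference ends; returned strings
    are the alignment columns between the first and last reference
    position inside that range (so query insertions interior to the
    window are retained).  ``None`` is returned when the query has no
    residue in any motif column — the ORF does not cover the epitope.
    """
    details = _window_details(alignment, motif_span, flank, ref_length)
    if details is None:
        return None
    return details[0], details[1]


def _window_details(
    alignment: PairwiseAlignment,
    motif_span: Tuple[int, int],
    flank: int,
    ref_length: Optional[int],
) -> Optional[Tuple[str, str, List[int], int]]:
    """Trimmed strings, motif column indices (window-relative) and motif coverage."""
    ms, me = motif_span
    positions = _column_ref_positions(alignment)
    lo = max(1, ms - flank)
    hi = me + flank
    if ref_length is not None:
        hi = min(hi, ref_length)

    window_cols = [c for c, p in enumerate(positions) if p is not None and lo <= p <= hi]
    if not window_cols:
        return None
    first, last = window_cols[0], window_cols[-1]

    motif_cols_abs = [c for c, p in enumerate(positions) if p is not None and ms <= p <= me]
    covered = sum(1 for c in motif_cols_abs if alignment.aligned_query[c] != "-")
    if covered == 0:
        return None

    trimmed_ref = alignment.aligned_ref[first : last + 1]
    trimmed_query = alignment.aligned_query[first : last + 1]
    motif_cols = [c - first for c in motif_cols_abs if first <= c <= last]
    return trimmed_ref, trimmed_query, motif_cols, covered


def screen_orfs(
    orfs: Iterable,
    taxonomy: Mapping[str, str],
    reference: ReferenceProtein,
    motif: EpitopeMotif | str = DEFAULT_MOTIF,
    flank: int = DEFAULT_FLANK,
    *,
    region_pad: int = 10,
    min_motif_cols: Optional[int] = None,
) -> Tuple[List[MimicryHit], List[DiscardRecord]]:
    """Screen ORFs for the epitope; returns (hits, discard log).

    ``orfs`` may be Biopython SeqRecords or ``(orf_id, sequence)``
    pairs.  ORFs missing from ``taxonomy`` fall into family
    "unassigned".  Each ORF is aligned to the reference region spanning
    the motif plus ``flank + region_pad`` residues on each side.
    Coverage requires query residues in at least ``min_motif_cols`` of
    the motif columns (default: all of them); ORFs failing coverage are
    logged with a reason code instead of scored.
    """
    motif = motif if isinstance(motif, EpitopeMotif) else EpitopeMotif(motif)
    if min_motif_cols is None:
        min_motif_cols = len(motif)

    orf_list = [_as_pair(o) for o in orfs]
    if not orf_list:
        raise ValueError("empty ORF input: nothing to screen")

    ms, me = locate_motif(reference.sequence, motif)
    reference.motif_start, reference.motif_end = ms, me
    region_lo = max(1, ms - flank - region_pad)
    region_hi = min(len(reference.sequence), me + flank + region_pad)
    region = reference.sequence[region_lo - 1 : region_hi]
    ms_rel, me_rel = ms - region_lo + 1, me - region_lo + 1

    hits: List[MimicryHit] = []
    discards: List[DiscardRecord] = []
    for orf_id, seq in orf_list:
        family = taxonomy.get(orf_id, "unassigned")
        aln = align_pair(seq, region)
        details = _window_details(aln, (ms_rel, me_rel), flank, len(region))
        if details is None:
            discards.append(DiscardRecord(orf_id, family, "no_epitope_coverage"))
            continue
        trimmed_ref, trimmed_query, motif_cols, covered = details
        if covered < min_motif_cols:
            discards.append(DiscardRecord(orf_id, family, "partial_motif_coverage"))
            continue
        hits.append(
            MimicryHit(
                orf_id=orf_id,
                family=family,
                covers_epitope=True,
                motif_identity=identity(trimmed_ref, trimmed_query, motif_cols),
                window_identity=identity(trimmed_ref, trimmed_query),
                trimmed_ref=trimmed_ref,
                trimmed_query=trimmed_query,
            )
        )
    return hits, discards


def _as_pair(orf) -> Tuple[str, str]:
    if isinstance(orf, tuple):
        return orf[0], str(orf[1])
    return orf.id, str(orf.seq)  # Biopython SeqRecord


def summarize_families(hits: Sequence[MimicryHit]) -> List[FamilyMimicrySummary]:
    """Per-family sequence counts, perfect-motif counts and mean identity.

    ``n_full_motif`` counts hits whose motif identity is 100% (within
    1e-9).  Families are ordered by descending sequence count, then
    name.
    """
    if not hits:
        return []
    by_family: Dict[str, List[MimicryHit]] = {}
    for h in hits:
        by_family.setdefault(h.family, []).append(h)
    summaries = [
        FamilyMimicrySummary(
            family=fam,
            n_sequences=len(fam_hits),
            n_full_motif=sum(1 for h in fam_hits if abs(h.motif_identity - 100.0) <= 1e-9),
            mean_window_identity=float(np.mean([h.window_identity for h in fam_hits])),
        )
        for fam, fam_hits in by_family.items()
    ]
    summaries.sort(key=lambda s: (-s.n_sequences, s.family))
    return summaries


def homology_distribution(
    hits: Sequence[MimicryHit],
    bin_edges: Sequence[float],
    *,
    which: str = "window",
) -> pd.DataFrame:
    """Family x identity-bin counts; bins half-open [a, b), last closed.

    ``which`` selects the identity scored ("window" or "motif").
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing")
    if edges[0] > 0 or edges[-1] < 100:
        raise ValueError("bin edges must cover [0, 100]")
    attr = {"window": "window_identity", "motif": "motif_identity"}[which]

    labels = [f"[{edges[i]:g},{edges[i + 1]:g})" for i in range(len(edges) - 2)]
    labels.append(f"[{edges[-2]:g},{edges[-1]:g}]")
    families = sorted({h.family for h in hits})
    table = pd.DataFrame(0, index=families, columns=labels, dtype=int)
    for fam in families:
        vals = [getattr(h, attr) for h in hits if h.family == fam]
        counts, _ = np.histogram(vals, bins=edges)
        table.loc[fam] = counts
    table.index.name = "family"
    return table
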