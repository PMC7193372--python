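"""Deterministic pairwise protein alignment for epitope screening.

Implements semi-global ("glocal") alignment of a query ORF against a
reference window: reference overhang at either end of the query (gap
columns at the query's ends) is free, while every internal gap is
affine-penalised.  This placement model suits dropping a short predicted
ORF fragment onto a longer reference region around an epitope.

Scoring is BLOSUM62 with affine gaps, open 11 / extend 1, so a gap of
length k costs 11 + k.  A gap "opens" whenever the previous alignment
column is of a different type, which keeps the model identical between
the iterative Gotoh implementation here and exhaustive recursions used
to validate it.  Traceback ties are broken in a fixed order (diagonal,
then up, then left), making every alignment byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from Bio.Align import substitution_matrices

#: The 20 standard amino-acid one-letter codes accepted everywhere.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_B62 = substitution_matrices.load("BLOSUM62")
#: BLOSUM62 as a plain ``{(a, b): score}`` dict for fast lookup.
BLOSUM62: Mapping[tuple, float] = {
    (a, b): float(_B62[a][b]) for a in _B62.alphabet for b in _B62.alphabet
}

GAP_OPEN = 11.0
GAP_EXTEND = 1.0

_NEG = float("-inf")
# state codes; numeric order doubles as tie-break preference
_M, _UP, _LEFT = 0, 1, 2  # diagonal / gap-in-reference / gap-in-query


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped pairwise alignment between a reference and a query.

    ``aligned_ref`` / ``aligned_query`` are equal-length gapped strings
    covering only the aligned region; free reference overhang is not
    included, its extent is recoverable from ``ref_start``.  Coordinates
    are 1-based.  Degapping ``aligned_ref`` reproduces the reference
    substring starting at ``ref_start``; degapping ``aligned_query``
    reproduces the full query (``query_start`` is always 1 under the
    semi-global model).
    """

    aligned_ref: str
    aligned_query: str
    ref_start: int
    query_start: int
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_ref) != len(self.aligned_query):
            raise ValueError("gapped strings must have equal length")


def validate_protein(seq: str, name: str = "sequence") -> None:
    """Reject sequences containing anything but the 20 standard residues."""
    for ch in seq:
        if ch not in AMINO_ACIDS:
            raise ValueError(
                f"invalid residue {ch!r} in {name}: only the 20 standard "
                f"amino acids are accepted"
            )


def align_pair(
    query: str,
    reference: str,
    *,
    matrix: Optional[Mapping[tuple, float]] = None,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
) -> PairwiseAlignment:
    """Optimal semi-global alignment of ``query`` against ``reference``.

    End gaps on the query (unaligned reference overhang) carry no
    penalty; internal gaps and query overhang cost
    ``gap_open + k * gap_extend`` for length ``k``.  Ties during
    traceback prefer diagonal, then up (query residue vs gap), then left
    (reference residue vs gap), and among equally scoring end columns
    the leftmost placement on the reference wins.
    """
    if not query or not reference:
        raise ValueError("both sequences must be non-empty")
    validate_protein(query, "query")
    validate_protein(reference, "reference")
    sub = BLOSUM62 if matrix is None else matrix

    n, m = len(query), len(reference)
    opening = gap_open + gap_extend

    # score + predecessor-state matrices per alignment state
    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    U = [[_NEG] * (m + 1) for _ in range(n + 1)]  # up: query residue vs gap
    L = [[_NEG] * (m + 1) for _ in range(n + 1)]  # left: reference residue vs gap
    pM = [[0] * (m + 1) for _ in range(n + 1)]
    pU = [[0] * (m + 1) for _ in range(n + 1)]
    pL = [[0] * (m + 1) for _ in range(n + 1)]

    M[0][0] = 0.0
    for j in range(1, m + 1):
        L[0][j] = 0.0  # free leading reference overhang
        pL[0][j] = _LEFT
    for i in range(1, n + 1):
        # query overhang before any reference residue: always penalised
        cand = (M[i - 1][0] - opening, U[i - 1][0] - gap_extend, L[i - 1][0] - opening)
        best = max(cand)
        U[i][0] = best
        pU[i][0] = cand.index(best)

    for i in range(1, n + 1):
        qi = query[i - 1]
        Mi, Ui, Li = M[i], U[i], L[i]
        Mp, Up, Lp = M[i - 1], U[i - 1], L[i - 1]
        pMi, pUi, pLi = pM[i], pU[i], pL[i]
        for j in range(1, m + 1):
            # diagonal
            cand = (Mp[j - 1], Up[j - 1], Lp[j - 1])
            best = max(cand)
            Mi[j] = best + sub[(qi, reference[j - 1])]
            pMi[j] = cand.index(best)
            # up: consume query residue, gap in reference
            cand = (Mp[j] - opening, Up[j] - gap_extend, Lp[j] - opening)
            best = max(cand)
            Ui[j] = best
            pUi[j] = cand.index(best)
            # left: consume reference residue, gap in query
            cand = (Mi[j - 1] - opening, Ui[j - 1] - opening, Li[j - 1] - gap_extend)
            best = max(cand)
            Li[j] = best
            pLi[j] = cand.index(best)

    # free trailing reference overhang: best cell anywhere in the last row;
    # strict comparisons keep the leftmost (smallest j) maximal placement
    score, end_state, end_j = _NEG, _M, 0
    for j in range(m + 1):
        for state, row in ((_M, M), (_UP, U), (_LEFT, L)):
            if row[n][j] > score:
                score, end_state, end_j = row[n][j], state, j
    if score == _NEG:  # pragma: no cover - unreachable for non-empty inputs
        raise RuntimeError("alignment failed")

    # traceback
    ref_cols: list = []
    qry_cols: list = []
    i, j, state = n, end_j, end_state
    while i > 0:
        if state == _M:
            ref_cols.append(reference[j - 1])
            qry_cols.append(query[i - 1])
            state = pM[i][j]
            i -= 1
            j -= 1
        elif state == _UP:
            ref_cols.append("-")
            qry_cols.append(query[i - 1])
            state = pU[i][j]
            i -= 1
        else:  # _LEFT: internal reference-vs-gap column
            ref_cols.append(reference[j - 1])
            qry_cols.append("-")
            state = pL[i][j]
            j -= 1
    # any remaining j belongs to the free leading overhang
    ref_cols.reverse()
    qry_cols.reverse()
    return PairwiseAlignment(
        aligned_ref="".join(ref_cols),
        aligned_query="".join(qry_cols),
        ref_start=j + 1,
        query_start=1,
        score=score,
    )


def identity(
    aligned_a: str,
    aligned_b: str,
    columns: Optional[Sequence[int]] = None,
) -> float:
    """Percent identity between two gapped strings.

    ``aligned_a`` is treated as the reference.  Over the full strings
    the denominator counts the columns where the reference carries a
    residue, and a gap in the other string counts as a mismatch.  When
    an explicit ``columns`` subset is given (0-based indices, e.g. the
    motif columns) every listed column enters the denominator and a gap
    in either string counts as a mismatch.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError(
            f"gapped strings differ in length ({len(aligned_a)} vs {len(aligned_b)})"
        )
    if columns is None:
        denom = sum(1 for ch in aligned_a if ch != "-")
        match = sum(1 for a, b in zip(aligned_a, aligned_b) if a == b and a != "-")
    else:
        denom = len(columns)
        match = sum(1 for c in columns if aligned_a[c] == aligned_b[c] and aligned_a[c] != "-")
    if denom == 0:
        raise ValueError("identity undefined: reference has no residue in the evaluated columns")
    return 100.0 * match / denom
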