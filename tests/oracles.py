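"""Independent reference implementations used as test oracles.

Each oracle recomputes a quantity by the most transparent route
available (exhaustive recursion, brute-force scanning, literal formula
transcription) and stays independent of the library code paths it
checks.
"""

from __future__ import annotations

import sys
from functools import lru_cache
from typing import Dict, List, Sequence

import numpy as np

from gutclpb.alignment import BLOSUM62, GAP_EXTEND, GAP_OPEN


def semiglobal_score(query: str, reference: str) -> float:
    """Exhaustive-recursion optimum of the semi-global alignment score.

    Top-down recursion over (query suffix, reference suffix, previous
    column type): reference overhang before the chosen start and after
    query exhaustion is free; a gap charges open+extend when the
    previous column is of a different type, extend otherwise.
    """
    n, m = len(query), len(reference)
    opening = GAP_OPEN + GAP_EXTEND
    sys.setrecursionlimit(10000)

    @lru_cache(maxsize=None)
    def best(i: int, j: int, prev: str) -> float:
        if i == n:
            return 0.0  # trailing reference overhang is free
        options = [-(GAP_EXTEND if prev == "Y" else opening) + best(i + 1, j, "Y")]
        if j < m:
            options.append(BLOSUM62[(query[i], reference[j])] + best(i + 1, j + 1, "M"))
            options.append(-(GAP_EXTEND if prev == "X" else opening) + best(i, j + 1, "X"))
        return max(options)

    result = max(best(0, j0, "S") for j0 in range(m + 1))
    best.cache_clear()
    return result


def bh_stepup(p_values: Sequence[float]) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up: q_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running_min = np.inf
    for rank in range(m, 0, -1):
        running_min = min(running_min, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = min(running_min, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def recount_reads_per_ko(
    hits_df, locations_df, reads_df
) -> Dict[str, Dict[str, int]]:
    """Brute-force recount of reads per KO per sample from the raw tables.

    Re-derives best hits, read-ORF assignment (>= 50% overlap, smaller
    start then smaller orf_id on ties) and the per-KO sums with plain
    Python loops, independent of the profiling module.
    """
    best: Dict[str, tuple] = {}
    for row in hits_df.itertuples(index=False):
        key = (row.evalue, -row.bitscore, row.ko)
        if row.orf_id not in best or key < best[row.orf_id]:
            best[row.orf_id] = key
    orf2ko = {orf: key[2] for orf, key in best.items()}

    orfs = [tuple(r) for r in locations_df.itertuples(index=False)]
    out: Dict[str, Dict[str, int]] = {}
    for row in reads_df.itertuples(index=False):
        sample = getattr(row, "sample", "S1")
        out.setdefault(sample, {})
        read_len = row.end - row.start + 1
        candidates = []
        for contig, start, end, strand, orf_id in orfs:
            if contig != row.contig:
                continue
            overlap = min(row.end, end) - max(row.start, start) + 1
            if 2 * overlap >= read_len and overlap > 0:
                candidates.append((-overlap, start, orf_id))
        if not candidates:
            continue
        orf_id = min(candidates)[2]
        ko = orf2ko.get(orf_id)
        if ko is None:
            continue
        out[sample][ko] = out[sample].get(ko, 0) + 1
    return out


def pqn_by_hand(X: np.ndarray) -> np.ndarray:
    """PQN written as plain loops straight from the definition."""
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    reference = [sorted(X[:, j])[n // 2] if n % 2 else
                 0.5 * (sorted(X[:, j])[n // 2 - 1] + sorted(X[:, j])[n // 2])
                 for j in range(m)]
    out = np.empty_like(X)
    for i in range(n):
        quotients = sorted(
            X[i, j] / reference[j] for j in range(m) if X[i, j] > 0 and reference[j] > 0
        )
        k = len(quotients)
        factor = quotients[k // 2] if k % 2 else 0.5 * (quotients[k // 2 - 1] + quotients[k // 2])
        out[i] = X[i] / factor
    return out
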