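"""Independent brute-force oracles used to cross-check the implementations.

These deliberately avoid the production code paths: the classifier oracle
re-evaluates the written selection rules with a per-base coverage set, and
the repeat oracle scans every diagonal of the sequence-vs-reverse-
complement comparison with numpy.
"""

from __future__ import annotations

import numpy as np

from cpkit.read_classifier import ClassifierParams
from cpkit.seq_io import reverse_complement


def brute_force_long_read(read_length, alns, params: ClassifierParams) -> bool:
    """Literal re-evaluation of the long-read rule with a base set union."""
    kept = [a for a in alns if (a.query_end - a.query_start) >= params.min_record_query_bp]
    if not kept:
        return False
    covered: set[int] = set()
    for a in kept:
        covered.update(range(a.query_start, a.query_end))
    total = len(covered)
    return (
        total >= params.min_total_query_bp
        and read_length > 0
        and total / read_length >= params.min_query_fraction
    )


def brute_force_pair(alns1, alns2, params: ClassifierParams) -> bool:
    ok1 = any((a.query_end - a.query_start) >= params.pair_min_block_bp for a in alns1)
    ok2 = any((a.query_end - a.query_start) >= params.pair_min_block_bp for a in alns2)
    return ok1 and ok2


def brute_force_max_inverted_repeat(s: str) -> tuple[int, int, int]:
    """Longest exact inverted repeat: (i, j, L) with s[i:i+L] equal to the
    reverse complement of s[j:j+L] and the two copies disjoint (i + L <= j).

    Equivalent to the longest common substring between s and revcomp(s)
    under the disjointness constraint, scanned per diagonal with numpy.
    """
    n = len(s)
    a = np.frombuffer(s.encode(), dtype=np.uint8)
    t = np.frombuffer(reverse_complement(s).encode(), dtype=np.uint8)
    best = (0, 0, 0)  # (L, i, j)
    for shift in range(-(n - 1), n):  # shift = i - p, comparing a[i] with t[p]
        i0 = max(0, shift)
        p0 = i0 - shift
        m = n - max(i0, p0)
        eq = (a[i0 : i0 + m] == t[p0 : p0 + m]).astype(np.int8)
        bounds = np.flatnonzero(np.diff(np.concatenate(([0], eq, [0]))))
        for start, stop in bounds.reshape(-1, 2):
            L = int(stop - start)
            i = i0 + int(start)
            p = p0 + int(start)
            j = n - p - L  # the partner copy's start on s
            if j < 0:
                continue
            lo, hi = (i, j) if i <= j else (j, i)
            if lo + L <= hi and L > best[0]:
                best = (L, lo, hi)
    L, i, j = best
    return i, j, L
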