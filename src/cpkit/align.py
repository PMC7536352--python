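"""Seed-and-extend alignment helpers built on exact k-mer anchoring plus
edit-distance verification (edlib).

These primitives back three stages: suffix-prefix overlap detection for
contig merging and circularization, contig placement on a reference for
scaffolding, and read placement on a draft for pileup polishing. They are
deliberately simple: exact k-mer seeds vote for diagonals, each candidate
is verified with banded edit distance, and ties are broken
deterministically (longest overlap, then smallest coordinate).
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass

import edlib

from .seq_io import reverse_complement

__all__ = ["Hit", "kmer_index", "suffix_prefix_overlap", "map_query", "cigar_ops"]

_CIGAR_RE = re.compile(r"(\d+)([MIDX=])")


def cigar_ops(cigar: str) -> list[tuple[int, str]]:
    """Parse a CIGAR string into (length, op) pairs; ops in {M,=,X,I,D}."""
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if sum(n for n, _ in ops) == 0 or "".join(
        f"{n}{op}" for n, op in ops
    ) != cigar:
        raise ValueError(f"unparseable CIGAR {cigar!r}")
    return ops


def kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i : i + k]].append(i)
    return dict(index)


@dataclass(frozen=True)
class Hit:
    """A verified placement of (an interval of) a query on a target.

    Query coordinates refer to the oriented query: when ``strand`` is "-",
    they index into reverse_complement(query).
    """

    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str
    edit_distance: int
    identity: float
    cigar: str | None = None

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start

    @property
    def t_span(self) -> int:
        return self.t_end - self.t_start


def _nw(query: str, target: str, max_ed: int, task: str = "distance"):
    res = edlib.align(query, target, mode="NW", task=task, k=max_ed)
    return res


def suffix_prefix_overlap(
    a: str,
    b: str,
    *,
    min_overlap: int,
    min_identity: float,
    k: int = 21,
    max_overlap: int | None = None,
) -> tuple[int, float] | None:
    """Longest suffix of ``a`` matching a prefix of ``b``.

    Candidate overlap lengths come from shared k-mer diagonals; each is
    verified by global edit distance with a band of twice the tolerated
    error. Returns (overlap_bp, identity) for the longest verified overlap,
    or None. ``max_overlap`` caps the candidate length (used to exclude the
    trivial full-length self match when a == b).
    """
    cap = min(len(a), len(b))
    if max_overlap is not None:
        cap = min(cap, max_overlap)
    if cap < min_overlap or cap < k:
        return None
    index = kmer_index(b[:cap], k)
    diagonals: Counter[int] = Counter()
    lo = len(a) - cap
    for i in range(lo, len(a) - k + 1):
        for j in index.get(a[i : i + k], ()):
            ov = len(a) - (i - j)
            if min_overlap <= ov <= cap:
                diagonals[ov] += 1
    for ov in sorted(diagonals, reverse=True):
        band = max(2, int(2 * (1.0 - min_identity) * ov))
        res = _nw(a[len(a) - ov :], b[:ov], band)
        if res["editDistance"] < 0:
            continue
        identity = 1.0 - res["editDistance"] / ov
        if identity >= min_identity:
            return ov, identity
    return None


def _cluster_anchors(
    anchors: list[tuple[int, int]], k: int, band: int, max_q_gap: int
) -> list[tuple[int, int, int, int]]:
    """Group (qpos, tpos) anchors into diagonal clusters.

    Returns (q_start, q_end, t_start, t_end) per cluster, half-open.
    """
    if not anchors:
        return []
    anchors = sorted(anchors, key=lambda a: (a[1] - a[0], a[0]))
    clusters = []
    cur = [anchors[0]]
    for anc in anchors[1:]:
        prev = cur[-1]
        if abs((anc[1] - anc[0]) - (prev[1] - prev[0])) <= band:
            cur.append(anc)
        else:
            clusters.append(cur)
            cur = [anc]
    clusters.append(cur)
    out = []
    for cl in clusters:
        cl.sort()
        qmin = min(q for q, _ in cl)
        qmax = max(q for q, _ in cl) + k
        tmin = min(t for _, t in cl)
        tmax = max(t for _, t in cl) + k
        out.append((qmin, qmax, tmin, tmax))
    return out


def map_query(
    query: str,
    target: str,
    *,
    k: int = 17,
    min_span: int = 50,
    min_identity: float = 0.8,
    both_strands: bool = True,
    with_cigar: bool = False,
    index: dict[str, list[int]] | None = None,
    anchor_stride: int = 1,
) -> list[Hit]:
    """Place a query (or intervals of it) on a target sequence.

    Anchoring: exact shared k-mers, clustered by diagonal. Each cluster is
    extended to the full query where the target allows, and verified with
    edit distance; if full-query identity fails, the cluster span alone is
    reported (a partial placement). Hits below ``min_span`` or
    ``min_identity`` are dropped. Sorted by (descending score, t_start)
    where score = identity x aligned target span.
    """
    if index is None:
        index = kmer_index(target, k)
    task = "path" if with_cigar else "locations"
    hits: list[Hit] = []
    strands = ("+", "-") if both_strands else ("+",)
    for strand in strands:
        q = query if strand == "+" else reverse_complement(query)
        if len(q) < k:
            continue
        anchors = []
        for i in range(0, len(q) - k + 1, anchor_stride):
            for t in index.get(q[i : i + k], ()):
                anchors.append((i, t))
        band = max(16, int(2 * (1.0 - min_identity) * len(q)))
        max_ed_frac = 1.0 - min_identity
        seen_spans = set()
        for qmin, qmax, tmin, tmax in _cluster_anchors(anchors, k, band, len(q)):
            # project the cluster to the full query where the target allows
            ext_t_lo = tmin - qmin
            ext_t_hi = tmax + (len(q) - qmax)
            pad = band

            def _try(qs: int, qe: int, ts: int, te: int) -> Hit | None:
                sub = q[qs:qe]
                if len(sub) < min_span:
                    return None
                max_ed = max(2, int(max_ed_frac * len(sub) * 2))
                res = edlib.align(sub, target[ts:te], mode="HW", task=task, k=max_ed)
                if res["editDistance"] < 0 or not res["locations"]:
                    return None
                loc = min(res["locations"])
                t_start = ts + loc[0]
                t_end = ts + loc[1] + 1
                alnlen = max(len(sub), t_end - t_start)
                identity = 1.0 - res["editDistance"] / alnlen
                if identity < min_identity:
                    return None
                return Hit(
                    q_start=qs,
                    q_end=qe,
                    t_start=t_start,
                    t_end=t_end,
                    strand=strand,
                    edit_distance=res["editDistance"],
                    identity=identity,
                    cigar=res.get("cigar") if with_cigar else None,
                )

            cluster_hit = _try(
                qmin, qmax, max(0, tmin - pad), min(len(target), tmax + pad)
            )
            placed = cluster_hit
            extra = (len(q) - (qmax - qmin))
            if extra > 0 and ext_t_lo >= -pad and ext_t_hi <= len(target) + pad:
                full_hit = _try(
                    0,
                    len(q),
                    max(0, ext_t_lo - pad),
                    min(len(target), ext_t_hi + pad),
                )
                if full_hit is not None:
                    # accept the full-query extension only when the flanks
                    # added beyond the anchored cluster align well themselves
                    base_ed = cluster_hit.edit_distance if cluster_hit else 0
                    budget = max(2, int(max_ed_frac * extra))
                    if full_hit.edit_distance - base_ed <= budget:
                        placed = full_hit
            if placed is None:
                continue
            key = (placed.strand, placed.t_start // 32, placed.q_start // 32)
            if key in seen_spans:
                continue
            seen_spans.add(key)
            hits.append(placed)
    # deduplicate near-identical placements, keep the better one
    hits.sort(key=lambda h: (-h.identity * h.t_span, h.t_start, h.strand))
    kept: list[Hit] = []
    for h in hits:
        dup = False
        for other in kept:
            if (
                h.strand == other.strand
                and abs(h.t_start - other.t_start) < 32
                and abs(h.t_end - other.t_end) < 32
            ):
                dup = True
                break
        if not dup:
            kept.append(h)
    return [h for h in kept if h.q_span >= min_span]
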