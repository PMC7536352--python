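"""Classify whole-genome sequencing reads as chloroplast-derived.

Long reads: alignment records with at least ``min_record_query_bp`` (default
500 bp) of the query aligned are kept; the read is accepted when the union
of the kept query intervals reaches ``min_total_query_bp`` (default 1 kb)
AND ``min_query_fraction`` (default 80 %) of the read length. Records
aligned to any of several chloroplast reference genomes count toward the
same union, overlaps counted once; strand is ignored.

Short read pairs: both mates must be aligned, each with at least one
alignment block of ``pair_min_block_bp`` (default 100 bp). Quality trimming
(every base >= Q20, length >= 100) is applied to short reads first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .seq_io import AlignmentRecord, ReadRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierParams",
    "ClassificationResult",
    "BatchSummary",
    "alignment_identity",
    "trim_by_quality",
    "classify_long_read",
    "classify_read_pair",
    "classify_batch",
    "interval_union_length",
]


@dataclass(frozen=True)
class ClassifierParams:
    min_record_query_bp: int = 500
    min_total_query_bp: int = 1000
    min_query_fraction: float = 0.8
    pair_min_block_bp: int = 100
    trim_min_quality: int = 20
    trim_min_length: int = 100

    def __post_init__(self):
        for name in (
            "min_record_query_bp",
            "min_total_query_bp",
            "pair_min_block_bp",
            "trim_min_quality",
            "trim_min_length",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.min_query_fraction <= 1.0:
            raise ValueError("min_query_fraction must lie in [0,1]")


@dataclass(frozen=True)
class ClassificationResult:
    read_id: str
    is_chloroplast: bool
    aligned_bp: int
    aligned_fraction: float
    n_records_used: int


@dataclass(frozen=True)
class BatchSummary:
    n_input: int
    n_accepted: int
    total_retained_bp: int


def alignment_identity(aln: AlignmentRecord) -> float:
    """Alignment identity I = M/L: exact-match bases over reference span."""
    if aln.ref_span <= 0:
        raise ValueError("alignment identity undefined for zero reference span")
    return aln.match_bp / aln.ref_span


def interval_union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length covered by a set of half-open intervals, overlaps once."""
    total = 0
    cur_start = cur_end = None
    for start, end in sorted(intervals):
        if cur_start is None:
            cur_start, cur_end = start, end
        elif start <= cur_end:
            cur_end = max(cur_end, end)
        else:
            total += cur_end - cur_start
            cur_start, cur_end = start, end
    if cur_start is not None:
        total += cur_end - cur_start
    return total


def trim_by_quality(read: ReadRecord, params: ClassifierParams = ClassifierParams()):
    """Quality-trim a short read; returns the trimmed read or None (rejected).

    Leading and trailing bases below ``trim_min_quality`` are removed; if a
    failing base remains internally, the read is cut at the first such base
    and the longer fragment kept (ties keep the left fragment). Reads
    shorter than ``trim_min_length`` after trimming are rejected.
    """
    if read.qualities is None:
        raise ValueError(f"read {read.id!r} has no qualities; cannot quality-trim")
    q = read.qualities
    lo, hi = 0, len(q)
    while lo < hi and q[lo] < params.trim_min_quality:
        lo += 1
    while hi > lo and q[hi - 1] < params.trim_min_quality:
        hi -= 1
    cut = next((i for i in range(lo, hi) if q[i] < params.trim_min_quality), None)
    if cut is not None:
        left = (lo, cut)
        right = (cut + 1, hi)
        lo, hi = left if left[1] - left[0] >= right[1] - right[0] else right
    if hi - lo < params.trim_min_length:
        return None
    return replace(
        read, bases=read.bases[lo:hi], qualities=tuple(q[lo:hi])
    )


def _check_query_lengths(alns: Sequence[AlignmentRecord]):
    ids = {a.query_id for a in alns}
    if len(ids) > 1:
        raise ValueError(f"alignments from multiple queries: {sorted(ids)!r}")
    lengths = {a.query_length for a in alns}
    if len(lengths) > 1:
        raise ValueError(
            f"inconsistent query_length for {ids.pop()!r}: {sorted(lengths)!r}"
        )


def classify_long_read(
    read_length: int,
    alns: Sequence[AlignmentRecord],
    params: ClassifierParams = ClassifierParams(),
) -> ClassificationResult:
    """Apply the long-read rule: >= 1 kb and >= 80 % of the read aligned,
    counting only alignment records with >= 500 bp of query aligned."""
    if alns:
        _check_query_lengths(alns)
        if alns[0].query_length != read_length:
            raise ValueError(
                f"read length {read_length} != alignment query_length "
                f"{alns[0].query_length}"
            )
    read_id = alns[0].query_id if alns else ""
    used = [a for a in alns if a.query_span >= params.min_record_query_bp]
    aligned = interval_union_length((a.query_start, a.query_end) for a in used)
    fraction = aligned / read_length if read_length else 0.0
    accepted = (
        bool(used)
        and aligned >= params.min_total_query_bp
        and fraction >= params.min_query_fraction
    )
    return ClassificationResult(
        read_id=read_id,
        is_chloroplast=accepted,
        aligned_bp=aligned,
        aligned_fraction=fraction,
        n_records_used=len(used),
    )


def classify_read_pair(
    alns_mate1: Sequence[AlignmentRecord],
    alns_mate2: Sequence[AlignmentRecord],
    params: ClassifierParams = ClassifierParams(),
) -> ClassificationResult:
    """Apply the pair rule: both mates aligned with a block >= 100 bp."""
    blocks1 = [a.query_span for a in alns_mate1]
    blocks2 = [a.query_span for a in alns_mate2]
    ok1 = any(b >= params.pair_min_block_bp for b in blocks1)
    ok2 = any(b >= params.pair_min_block_bp for b in blocks2)
    aligned = max(blocks1, default=0) + max(blocks2, default=0)
    read_id = (
        alns_mate1[0].query_id
        if alns_mate1
        else (alns_mate2[0].query_id if alns_mate2 else "")
    )
    return ClassificationResult(
        read_id=read_id,
        is_chloroplast=ok1 and ok2,
        aligned_bp=aligned,
        aligned_fraction=0.0,
        n_records_used=len(alns_mate1) + len(alns_mate2),
    )


def classify_batch(
    reads: Sequence[ReadRecord],
    alignments: Sequence[AlignmentRecord],
    params: ClassifierParams = ClassifierParams(),
) -> tuple[list[ClassificationResult], BatchSummary]:
    """Classify a batch of reads against an alignment table.

    Long reads are classified individually; short reads are classified as
    pairs grouped by read id. Alignments whose query id matches no read are
    skipped with a warning.
    """
    known = {r.id for r in reads}
    # mate alignments are keyed "<id>/1" and "<id>/2"; group them per pair
    by_query: dict[str, list[AlignmentRecord]] = {}
    by_mate: dict[str, tuple[list[AlignmentRecord], list[AlignmentRecord]]] = {}
    for aln in alignments:
        qid = aln.query_id
        if qid in known:
            by_query.setdefault(qid, []).append(aln)
        elif qid.endswith(("/1", "/2")) and qid[:-2] in known:
            slot = by_mate.setdefault(qid[:-2], ([], []))
            slot[int(qid[-1]) - 1].append(aln)
        else:
            logger.warning("alignment for unknown read %r skipped", qid)

    results: list[ClassificationResult] = []
    seen_pairs: set[str] = set()
    for read in reads:
        if read.platform == "long":
            alns = by_query.get(read.id, [])
            res = classify_long_read(len(read), alns, params)
            results.append(replace(res, read_id=read.id))
        else:
            if read.id in seen_pairs:
                continue
            seen_pairs.add(read.id)
            m1, m2 = by_mate.get(read.id, ([], []))
            unkeyed = by_query.get(read.id, [])
            res = classify_read_pair(m1 + unkeyed, m2, params)
            results.append(replace(res, read_id=read.id))

    lengths: dict[str, int] = {}
    for r in reads:
        lengths[r.id] = lengths.get(r.id, 0) + len(r)
    accepted = [r for r in results if r.is_chloroplast]
    summary = BatchSummary(
        n_input=len(results),
        n_accepted=len(accepted),
        total_retained_bp=sum(lengths.get(r.read_id, 0) for r in accepted),
    )
    logger.info(
        "classified %d reads: %d accepted, %d bp retained",
        summary.n_input,
        summary.n_accepted,
        summary.total_retained_bp,
    )
    return results, summary
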