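"""Merge draft contigs through suffix-prefix overlaps and circularize.

Long-read assemblers typically emit a chloroplast genome as a few linear
contigs broken at the inverted-repeat boundaries, with duplicated sequence
at the junctions. This module rebuilds the single circular molecule:
pairwise end-overlap detection, greedy longest-overlap-first path layout
with containment removal, and terminal-redundancy trimming to close the
circle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import edlib

from .align import suffix_prefix_overlap
from .seq_io import NucSequence, reverse_complement

__all__ = [
    "Contig",
    "OverlapEdge",
    "MergeParams",
    "MergeResult",
    "CircularizationResult",
    "find_overlaps",
    "merge_layout",
    "circularize",
    "assemble_draft",
]


@dataclass(frozen=True)
class Contig:
    seq: NucSequence
    mean_coverage: float | None = None

    def __post_init__(self):
        if len(self.seq) == 0:
            raise ValueError(f"contig {self.seq.id!r} is empty")
        if self.seq.circular:
            raise ValueError(f"contig {self.seq.id!r} must be linear")

    @property
    def id(self) -> str:
        return self.seq.id

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class OverlapEdge:
    """Suffix of oriented ``from`` contig matches prefix of oriented ``to``."""

    from_id: str
    to_id: str
    from_orientation: str
    to_orientation: str
    overlap_bp: int
    identity: float

    def __post_init__(self):
        if self.overlap_bp < 1:
            raise ValueError("overlap_bp must be >= 1")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must lie in [0,1]")

    def mirrored(self) -> "OverlapEdge":
        flip = {"+": "-", "-": "+"}
        return OverlapEdge(
            from_id=self.to_id,
            to_id=self.from_id,
            from_orientation=flip[self.to_orientation],
            to_orientation=flip[self.from_orientation],
            overlap_bp=self.overlap_bp,
            identity=self.identity,
        )


@dataclass(frozen=True)
class MergeParams:
    min_overlap_bp: int = 500
    min_identity: float = 0.95
    kmer_size: int = 21

    def __post_init__(self):
        if self.min_overlap_bp < self.kmer_size:
            raise ValueError("min_overlap_bp must be >= kmer_size")
        if not 0.0 < self.min_identity <= 1.0:
            raise ValueError("min_identity must lie in (0,1]")


@dataclass
class MergeResult:
    contigs: list[Contig]
    layout: list[list[tuple[str, str, int]]]  # per path: (contig id, orientation, overlap-into-next)
    dropped_contained: list[str] = field(default_factory=list)
    broken_cycles: list[OverlapEdge] = field(default_factory=list)


@dataclass(frozen=True)
class CircularizationResult:
    seq: NucSequence
    circularized: bool
    overlap_bp: int = 0
    identity: float = 0.0


def _oriented(seq: NucSequence, orientation: str) -> str:
    return seq.bases if orientation == "+" else reverse_complement(seq.bases)


def find_overlaps(contigs: list[Contig], params: MergeParams = MergeParams()) -> list[OverlapEdge]:
    """Report the longest verified suffix-prefix overlap for each oriented
    contig pair. Mirror-image edges (B- -> A- for A+ -> B+) are implied and
    not duplicated."""
    by_id = {c.id: c for c in contigs}
    if len(by_id) != len(contigs):
        raise ValueError("duplicate contig ids")
    edges: list[OverlapEdge] = []
    ids = sorted(by_id)
    # the four orientation classes per unordered pair, with the first contig
    # as the "from" side; mirror-image edges are implied by OverlapEdge.mirrored
    for i, a_id in enumerate(ids):
        for b_id in ids[i + 1 :]:
            for o1 in ("+", "-"):
                a = _oriented(by_id[a_id].seq, o1)
                for o2 in ("+", "-"):
                    b = _oriented(by_id[b_id].seq, o2)
                    found = suffix_prefix_overlap(
                        a,
                        b,
                        min_overlap=params.min_overlap_bp,
                        min_identity=params.min_identity,
                        k=params.kmer_size,
                    )
                    if found:
                        edges.append(
                            OverlapEdge(a_id, b_id, o1, o2, found[0], found[1])
                        )
    return edges


def find_contained(contigs: list[Contig], params: MergeParams = MergeParams()) -> list[str]:
    """Ids of contigs wholly contained in a longer contig (either strand)."""
    contained = []
    by_len = sorted(contigs, key=lambda c: (-len(c), c.id))
    for c in contigs:
        max_ed = int((1.0 - params.min_identity) * len(c))
        for other in by_len:
            if other.id == c.id or len(other) < len(c):
                continue
            if len(other) == len(c) and other.id >= c.id:
                continue
            for bases in (c.seq.bases, reverse_complement(c.seq.bases)):
                res = edlib.align(bases, other.seq.bases, mode="HW", k=max_ed)
                if res["editDistance"] >= 0:
                    contained.append(c.id)
                    break
            else:
                continue
            break
    return contained


def merge_layout(
    contigs: list[Contig],
    edges: list[OverlapEdge],
    params: MergeParams = MergeParams(),
) -> MergeResult:
    """Greedy longest-overlap-first path layout.

    Each contig is consumed at most once; contained contigs are dropped
    first; an edge that would close a cycle is skipped (the cycle is broken
    at its weakest link since edges are taken in descending overlap order)
    and reported.
    """
    dropped = set(find_contained(contigs, params))
    live = {c.id: c for c in contigs if c.id not in dropped}
    usable = [
        e
        for e in edges
        if e.from_id in live and e.to_id in live and e.from_id != e.to_id
    ]
    # both directed interpretations of every edge
    directed = []
    for e in usable:
        directed.append(e)
        directed.append(e.mirrored())
    directed.sort(key=lambda e: (-e.overlap_bp, -e.identity, e.from_id, e.to_id))

    orientation: dict[str, str] = {}
    succ: dict[str, OverlapEdge] = {}
    pred: dict[str, OverlapEdge] = {}
    comp: dict[str, str] = {cid: cid for cid in live}

    def find(x: str) -> str:
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    broken: list[OverlapEdge] = []
    for e in directed:
        of = orientation.get(e.from_id)
        ot = orientation.get(e.to_id)
        if (of is not None and of != e.from_orientation) or (
            ot is not None and ot != e.to_orientation
        ):
            continue
        if e.from_id in succ or e.to_id in pred:
            continue
        if find(e.from_id) == find(e.to_id):
            broken.append(e)
            continue
        succ[e.from_id] = e
        pred[e.to_id] = e
        orientation[e.from_id] = e.from_orientation
        orientation[e.to_id] = e.to_orientation
        comp[find(e.from_id)] = find(e.to_id)

    merged: list[Contig] = []
    layout: list[list[tuple[str, str, int]]] = []
    heads = [cid for cid in sorted(live) if cid not in pred]
    for head in heads:
        path = []
        cid = head
        while True:
            orient = orientation.get(cid, "+")
            nxt = succ.get(cid)
            path.append((cid, orient, nxt.overlap_bp if nxt else 0))
            if nxt is None:
                break
            cid = nxt.to_id
        layout.append(path)
        bases = _oriented(live[path[0][0]].seq, path[0][1])
        prev_len = len(live[path[0][0]])
        for idx in range(1, len(path)):
            cid, orient, _ = path[idx]
            ov = path[idx - 1][2]
            nxt_bases = _oriented(live[cid].seq, orient)
            # overlap bases come from the longer of the two contigs
            if len(live[cid]) >= prev_len:
                bases = bases[: len(bases) - ov] + nxt_bases
            else:
                bases = bases + nxt_bases[ov:]
            prev_len = len(live[cid])
        name = path[0][0] if len(path) == 1 else "merged_" + "_".join(p[0] for p in path)
        merged.append(
            Contig(
                seq=NucSequence(id=name, bases=bases),
                mean_coverage=live[path[0][0]].mean_coverage,
            )
        )
    return MergeResult(
        contigs=merged,
        layout=layout,
        dropped_contained=sorted(dropped),
        broken_cycles=broken,
    )


def circularize(
    contig: Contig | NucSequence, params: MergeParams = MergeParams()
) -> CircularizationResult:
    """Trim the terminal self-overlap of a linear contig and close the circle.

    The longest prefix/suffix match passing the overlap thresholds is
    found; the suffix copy is discarded and the prefix copy kept. Without a
    terminal overlap the input is returned unchanged (not circularizable).
    An overlap longer than half the contig is a degenerate (likely tandem)
    case and raises.
    """
    seq = contig.seq if isinstance(contig, Contig) else contig
    if seq.circular:
        return CircularizationResult(seq=seq, circularized=True)
    found = suffix_prefix_overlap(
        seq.bases,
        seq.bases,
        min_overlap=params.min_overlap_bp,
        min_identity=params.min_identity,
        k=params.kmer_size,
        max_overlap=len(seq) - 1,
    )
    if found is None:
        return CircularizationResult(seq=seq, circularized=False)
    ov, identity = found
    if ov > len(seq) // 2:
        raise ValueError(
            f"terminal overlap {ov} bp exceeds half the contig length "
            f"({len(seq)} bp); degenerate tandem artifact"
        )
    trimmed = replace(seq, bases=seq.bases[: len(seq) - ov], circular=True)
    return CircularizationResult(
        seq=trimmed, circularized=True, overlap_bp=ov, identity=identity
    )


def assemble_draft(
    contigs: list[Contig], params: MergeParams = MergeParams()
) -> tuple[NucSequence, MergeResult, CircularizationResult]:
    """find_overlaps -> merge_layout -> circularize; the full draft stage.

    Fails when the overlap graph leaves more than one merged contig
    (disconnected components, e.g. contigs from different molecules).
    """
    edges = find_overlaps(contigs, params)
    result = merge_layout(contigs, edges, params)
    if len(result.contigs) != 1:
        names = [c.id for c in result.contigs]
        raise ValueError(
            f"overlap graph is disconnected: {len(names)} components remain "
            f"({', '.join(names)})"
        )
    circ = circularize(result.contigs[0], params)
    return circ.seq, result, circ
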