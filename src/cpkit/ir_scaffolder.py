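"""Reference-guided scaffolding of short-read contigs into a circular
chloroplast genome, with inverted-repeat restoration.

Short-read assemblers usually collapse the two near-identical inverted
repeats into a single contig. Guided by a complete reference genome whose
quadripartite structure (LSC, IRA, SSC, IRB) is known, contigs are
anchored on the reference, ordered, and contigs homologous to the IR are
instantiated at BOTH repeat placements — the second reverse-complemented —
so the assembled circle carries both copies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib

from .align import kmer_index, map_query
from .seq_io import NucSequence, reverse_complement
from .structure_tools import QuadripartiteStructure

logger = logging.getLogger(__name__)

__all__ = [
    "Placement",
    "ScaffoldLayout",
    "ScaffoldParams",
    "anchor_contigs",
    "select_and_order",
    "join_layout",
    "scaffold",
]


@dataclass(frozen=True)
class Placement:
    contig_id: str
    ref_start: int
    ref_end: int
    strand: str
    identity: float
    query_coverage: float
    q_start: int = 0  # interval of the ORIENTED contig that is placed
    q_end: int = 0

    def __post_init__(self):
        if self.ref_start >= self.ref_end:
            raise ValueError("ref_start must be < ref_end")
        if not (0.0 <= self.identity <= 1.0 and 0.0 <= self.query_coverage <= 1.0):
            raise ValueError("identity and query_coverage must lie in [0,1]")

    @property
    def score(self) -> float:
        return self.identity * (self.ref_end - self.ref_start)


@dataclass
class ScaffoldLayout:
    reference_id: str
    placements: list[Placement]
    joins: list[tuple[str, int]]  # between consecutive placements (+ closure last): ("overlap"|"gap"|"abut", bp)
    is_complete: bool
    uncovered: list[tuple[int, int]] = field(default_factory=list)


@dataclass(frozen=True)
class ScaffoldParams:
    min_anchor_bp: int = 500
    min_identity: float = 0.95
    min_join_overlap_bp: int = 30
    max_gap_bp: int = 5000
    kmer_size: int = 21
    ir_span_fraction: float = 0.8  # span fraction inside an IR to call a contig IR-homologous


def anchor_contigs(
    contigs: list[NucSequence],
    reference: NucSequence,
    params: ScaffoldParams = ScaffoldParams(),
) -> tuple[list[Placement], list[str]]:
    """Place every contig on the reference; returns (placements, unplaced ids).

    A contig homologous to the inverted repeat yields two placements, one
    per IR copy on opposite strands. Placements may cover only part of a
    contig (query_coverage < 1) when the rest of the contig belongs
    elsewhere on the circle.
    """
    index = kmer_index(reference.bases, params.kmer_size)
    placements: list[Placement] = []
    unplaced: list[str] = []
    for contig in contigs:
        hits = map_query(
            contig.bases,
            reference.bases,
            k=params.kmer_size,
            min_span=max(30, params.min_join_overlap_bp),
            min_identity=params.min_identity,
            index=index,
        )
        # a contig is anchored when at least one placement is substantial;
        # its shorter verified placements (e.g. the partial mirror of an
        # IR-boundary-spanning contig) are then trusted as well
        strong = min(
            params.min_anchor_bp,
            max(len(contig) // 2, params.min_join_overlap_bp),
        )
        if not any(h.t_span >= strong for h in hits):
            unplaced.append(contig.id)
            continue
        for h in hits:
            placements.append(
                Placement(
                    contig_id=contig.id,
                    ref_start=h.t_start,
                    ref_end=h.t_end,
                    strand=h.strand,
                    identity=h.identity,
                    query_coverage=h.q_span / len(contig),
                    q_start=h.q_start,
                    q_end=h.q_end,
                )
            )
    return placements, unplaced


def _ir_overlap_fraction(p: Placement, structure: QuadripartiteStructure) -> float:
    span = p.ref_end - p.ref_start
    inside = 0
    for lo, hi in (structure.ira, structure.irb):
        inside += max(0, min(p.ref_end, hi) - max(p.ref_start, lo))
    return inside / span if span else 0.0


def select_and_order(
    placements: list[Placement],
    structure: QuadripartiteStructure,
    params: ScaffoldParams = ScaffoldParams(),
    ref_length: int | None = None,
) -> ScaffoldLayout:
    """Choose the best placement per reference region and order the tiling.

    Placements are taken greedily by descending identity x length (ties by
    contig id, then coordinate); one is kept only if it covers reference
    bases not yet covered. A contig id may appear twice when both its
    placements lie in the two IR intervals (the IR-collapse resolution);
    elsewhere each contig is used once.
    """
    n = ref_length if ref_length is not None else structure.genome_length
    order = sorted(
        placements, key=lambda p: (-p.score, p.contig_id, p.ref_start, p.strand)
    )
    covered: list[tuple[int, int]] = []
    chosen: list[Placement] = []
    used_outside_ir: set[str] = set()

    def novel(p: Placement) -> int:
        new = p.ref_end - p.ref_start
        for lo, hi in covered:
            new -= max(0, min(p.ref_end, hi) - max(p.ref_start, lo))
        return new

    for p in order:
        in_ir = _ir_overlap_fraction(p, structure) >= params.ir_span_fraction
        if not in_ir and p.contig_id in used_outside_ir:
            continue
        if novel(p) < max(1, (p.ref_end - p.ref_start) // 20):
            continue
        # near-containment by an already-chosen placement on the other
        # strand is a discordant claim on the region; junction-scale
        # overlaps between neighbours are expected and pass through
        conflict = False
        for q in chosen:
            ov = min(p.ref_end, q.ref_end) - max(p.ref_start, q.ref_start)
            if (
                ov >= 0.95 * (p.ref_end - p.ref_start)
                and q.strand != p.strand
                and q.contig_id != p.contig_id
            ):
                conflict = True
                logger.warning(
                    "placement %s [%d,%d) conflicts with %s; dropped",
                    p.contig_id, p.ref_start, p.ref_end, q.contig_id,
                )
                break
        if conflict:
            continue
        chosen.append(p)
        covered.append((p.ref_start, p.ref_end))
        if not in_ir:
            used_outside_ir.add(p.contig_id)

    chosen.sort(key=lambda p: (p.ref_start, p.ref_end))
    joins: list[tuple[str, int]] = []
    uncovered: list[tuple[int, int]] = []
    complete = bool(chosen)
    for i, p in enumerate(chosen):
        if i + 1 < len(chosen):
            delta = chosen[i + 1].ref_start - p.ref_end
        else:  # circular closure back to the first placement
            delta = (n - p.ref_end) + chosen[0].ref_start
        if delta > 0:
            joins.append(("gap", delta))
            if delta > params.max_gap_bp:
                complete = False
                nxt = chosen[(i + 1) % len(chosen)].ref_start
                uncovered.append((p.ref_end, nxt if i + 1 < len(chosen) else n + nxt))
        elif delta < 0:
            joins.append(("overlap", -delta))
        else:
            joins.append(("abut", 0))
    if not chosen:
        complete = False
        uncovered.append((0, n))
    return ScaffoldLayout(
        reference_id="",
        placements=chosen,
        joins=joins,
        is_complete=complete,
        uncovered=uncovered,
    )


def join_layout(
    layout: ScaffoldLayout,
    contigs: dict[str, NucSequence],
    params: ScaffoldParams = ScaffoldParams(),
) -> NucSequence:
    """Concatenate the placed contig intervals into one circular sequence.

    Neighbours joined through an overlap have the overlap emitted once,
    after verifying the junction sequences agree within the identity
    threshold; gap joins are filled with N. The last placement closes the
    circle onto the first by the same rule.
    """
    if not layout.is_complete:
        raise ValueError(f"layout incomplete; uncovered intervals: {layout.uncovered}")
    pieces: list[str] = []
    n = len(layout.placements)
    segs = []
    for p in layout.placements:
        bases = contigs[p.contig_id].bases
        oriented = bases if p.strand == "+" else reverse_complement(bases)
        q_end = p.q_end if p.q_end else len(oriented)
        segs.append(oriented[p.q_start : q_end])
    for i, p in enumerate(layout.placements):
        seg = segs[i]
        kind, bp = layout.joins[i]
        nxt = (i + 1) % n
        if kind == "overlap":
            tail = seg[-bp:]
            head = segs[nxt][:bp]
            max_ed = max(2, int(2 * (1.0 - params.min_identity) * bp))
            res = edlib.align(tail, head, mode="NW", k=max_ed)
            if res["editDistance"] < 0:
                raise ValueError(
                    f"join between {p.contig_id} and "
                    f"{layout.placements[nxt].contig_id}: claimed {bp} bp overlap "
                    f"failed identity verification"
                )
            seg = seg[:-bp] if i + 1 < n else seg
            if i + 1 == n:  # closure: trim the first piece's head instead
                pieces[0] = pieces[0][bp:]
            pieces.append(seg)
        elif kind == "gap":
            pieces.append(seg + "N" * bp)
        else:
            pieces.append(seg)
    bases = "".join(pieces)
    return NucSequence(id="scaffold", bases=bases, circular=True)


def scaffold(
    contigs: list[NucSequence],
    reference: NucSequence,
    ref_structure: QuadripartiteStructure,
    params: ScaffoldParams = ScaffoldParams(),
) -> tuple[NucSequence, ScaffoldLayout]:
    """anchor -> select_and_order -> join_layout; deterministic."""
    placements, unplaced = anchor_contigs(contigs, reference, params)
    if unplaced:
        logger.info("%d contigs unplaced: %s", len(unplaced), ", ".join(unplaced))
    layout = select_and_order(
        placements, ref_structure, params, ref_length=len(reference)
    )
    layout.reference_id = reference.id
    genome = join_layout(layout, {c.id: c for c in contigs}, params)
    return genome, layout
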