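"""Quadripartite structure of a circular chloroplast genome.

A plastome is canonically a large single-copy region (LSC) and a small
single-copy region (SSC) separated by two near-identical inverted repeats
(IRA, IRB). This module detects that structure from sequence alone,
canonicalizes a genome to start at the LSC on a deterministic strand,
computes per-region length and GC statistics, and tallies a gene
annotation table into copy-number censuses.

Intervals are 0-based half-open on the circle; an interval whose ``end``
exceeds the genome length wraps around the origin. IRA is, by convention,
the repeat copy immediately following the LSC in canonical order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from collections import Counter

from .seq_io import AnnotationRow, NucSequence, gc_fraction, reverse_complement, rotate

__all__ = [
    "QuadripartiteStructure",
    "RegionStats",
    "AnnotationCensus",
    "StructureError",
    "detect_quadripartite",
    "canonicalize",
    "region_stats",
    "annotation_census",
    "gene_totals",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": None}


class StructureError(ValueError):
    """No valid quadripartite structure could be found."""


def _ilen(iv: tuple[int, int]) -> int:
    return iv[1] - iv[0]


@dataclass(frozen=True)
class QuadripartiteStructure:
    """The four intervals partitioning a circular genome.

    Cyclic order around the molecule is LSC, IRA, SSC, IRB. On a canonical
    linearization no interval wraps; on an arbitrary rotation one interval
    may have ``end > genome_length`` (coordinates taken modulo length).
    """

    lsc: tuple[int, int]
    ira: tuple[int, int]
    ssc: tuple[int, int]
    irb: tuple[int, int]
    ir_mismatches: int = 0

    def __post_init__(self):
        for name in ("lsc", "ira", "ssc", "irb"):
            lo, hi = getattr(self, name)
            if hi <= lo:
                raise ValueError(f"{name}: empty or inverted interval ({lo},{hi})")
        if _ilen(self.lsc) <= _ilen(self.ssc):
            raise ValueError("LSC must be longer than SSC")
        n = self.genome_length
        order = [self.lsc, self.ira, self.ssc, self.irb]
        for cur, nxt in zip(order, order[1:] + order[:1]):
            if nxt[0] % n != cur[1] % n:
                raise ValueError("regions must be contiguous in order LSC, IRA, SSC, IRB")

    @property
    def genome_length(self) -> int:
        return _ilen(self.lsc) + _ilen(self.ira) + _ilen(self.ssc) + _ilen(self.irb)

    @property
    def region_lengths(self) -> dict[str, int]:
        return {
            "LSC": _ilen(self.lsc),
            "IRA": _ilen(self.ira),
            "SSC": _ilen(self.ssc),
            "IRB": _ilen(self.irb),
        }


@dataclass(frozen=True)
class RegionStats:
    lengths: dict[str, int]
    gc: dict[str, float]          # per region, plus "IR" (both copies) and "overall"
    total_length: int


@dataclass(frozen=True)
class AnnotationCensus:
    per_system: dict[str, int]    # gene-copy count per functional system
    distinct_genes: int
    total_copies: int
    n_single: int
    n_double: int
    n_triple: int


# ---------------------------------------------------------------------------
# detection


def _extract(bases: str, iv: tuple[int, int]) -> str:
    n = len(bases)
    lo, hi = iv
    if hi <= n:
        return bases[lo:hi]
    return bases[lo:] + bases[: hi - n]


def _extend_repeat(s: str, n: int, c: int, seed_i: int, k: int, max_rate: float):
    """Extend an inverted-repeat seed outward in both directions.

    Positions p (forward copy) pair with q(p) = (c + k - 1 - p) mod n.
    A mismatch is crossed only when the next window is match-dense (the
    hallmark of isolated divergence between the two copies, as opposed to
    having run off the repeat into single-copy sequence) and the overall
    mismatch rate stays within budget. Returns (a1, a2, mismatches) with
    a2 - a1 the repeat length; a1 may be negative (wraps).
    """
    window = 30

    def partner(p: int) -> int:
        return (c + k - 1 - p) % n

    def match(p: int) -> bool:
        comp = _COMP[s[partner(p)]]
        return comp is not None and s[p % n] == comp

    a1, a2 = seed_i, seed_i + k
    mm = 0

    def arcs_ok(na1: int, na2: int) -> bool:
        # the two copies plus both single-copy arcs must stay disjoint
        length = na2 - na1
        b1 = partner(na2 - 1)
        b2 = (partner(na1) + 1) % n
        g1 = (b1 - (na2 % n)) % n
        g2 = ((na1 % n) - b2) % n
        return 2 * length + g1 + g2 == n and g1 > 0 and g2 > 0

    def try_extend(direction: int) -> None:
        nonlocal a1, a2, mm
        while True:
            p = a2 if direction > 0 else a1 - 1
            na1, na2 = (a1, a2 + 1) if direction > 0 else (a1 - 1, a2)
            if na2 - na1 > n // 2 or not arcs_ok(na1, na2):
                return
            if match(p):
                a1, a2 = na1, na2
                continue
            # mismatch: peek ahead for a match-dense continuation
            dense = sum(
                1 for x in (p + direction * t for t in range(1, window + 1)) if match(x)
            )
            if dense < 0.8 * window:
                return
            if (mm + 1) > max_rate * (a2 - a1 + window):
                return
            mm += 1
            a1, a2 = na1, na2

    try_extend(+1)
    try_extend(-1)
    # boundaries end on the outermost matching base
    while a2 > a1 and not match(a2 - 1):
        a2 -= 1
        mm -= 1
    while a2 > a1 and not match(a1):
        a1 += 1
        mm -= 1
    return a1, a2, mm


def detect_quadripartite(
    genome: NucSequence,
    min_ir_bp: int = 1000,
    max_mismatch_rate: float = 0.01,
    kmer_size: int = 15,
) -> QuadripartiteStructure:
    """Find the inverted-repeat pair of a circular genome and name regions.

    Seeds are exact k-mers shared between the sequence and its reverse
    complement; an inverted-repeat pair places all its seeds on one
    anti-diagonal (i + j) mod n, which is invariant under rotation. The
    best-scoring extension wins; single-copy arcs are named by size
    (larger = LSC) and IRA is the copy following the LSC.
    """
    if not genome.circular:
        raise ValueError("quadripartite detection requires a circular genome")
    n = len(genome)
    if n <= 4 * kmer_size:
        raise StructureError("genome too short for detection")
    s = genome.bases
    d = s + s[: kmer_size - 1]
    k = kmer_size

    index: dict[str, list[int]] = {}
    for i in range(n):
        index.setdefault(d[i : i + k], []).append(i)
    votes: Counter[int] = Counter()
    anchors: dict[int, list[int]] = {}
    for i in range(n):
        rc = reverse_complement(d[i : i + k])
        for j in index.get(rc, ()):
            c = (i + j) % n
            votes[c] += 1
            anchors.setdefault(c, []).append(i)

    best = None  # (length, -a1, a1, a2, mm, c)
    for c, _count in votes.most_common(8):
        seeds = sorted(anchors[c])
        for seed in {seeds[0], seeds[len(seeds) // 2], seeds[-1]}:
            a1, a2, mm = _extend_repeat(s, n, c, seed, k, max_mismatch_rate)
            length = a2 - a1
            if length < max(min_ir_bp, k):
                continue
            cand = (length, -(a1 % n), a1, a2, mm, c)
            if best is None or cand > best:
                best = cand
    if best is None:
        raise StructureError(
            f"no inverted repeat of at least {min_ir_bp} bp found: "
            "no quadripartite structure"
        )
    length, _, a1, a2, mm, c = best

    def partner(p: int) -> int:
        return (c + k - 1 - p) % n

    a1m = a1 % n
    b1 = partner(a2 - 1)
    b2m = (partner(a1) + 1) % n
    copy_a = (a1m, a1m + length)
    copy_b = (b1, b1 + length)
    arc1 = ((a1m + length) % n, b1)      # between A end and B start
    arc2 = (b2m, a1m)                     # between B end and A start
    arc1 = (arc1[0], arc1[1] if arc1[1] > arc1[0] else arc1[1] + n)
    arc2 = (arc2[0], arc2[1] if arc2[1] > arc2[0] else arc2[1] + n)
    if _ilen(arc1) >= _ilen(arc2):
        lsc, ssc = arc1, arc2
        ira, irb = copy_b, copy_a   # IRA follows the LSC
    else:
        lsc, ssc = arc2, arc1
        ira, irb = copy_a, copy_b
    return QuadripartiteStructure(
        lsc=lsc, ira=ira, ssc=ssc, irb=irb, ir_mismatches=mm
    )


# ---------------------------------------------------------------------------
# canonical form


def canonicalize(
    genome: NucSequence, structure: QuadripartiteStructure
) -> tuple[NucSequence, QuadripartiteStructure]:
    """Rotate (and possibly flip) the genome so the LSC starts at 0.

    Of the two strand choices, each rotated to its own LSC start, the
    lexicographically smaller sequence is emitted: a deterministic,
    data-free orientation convention, so that any rotation or reverse
    complement of the same molecule canonicalizes identically.
    """
    n = len(genome)
    circ = genome if genome.circular else replace(genome, circular=True)
    fwd = rotate(circ, structure.lsc[0] % n)
    rc_start = (n - (structure.lsc[1] % n)) % n
    rev = rotate(reverse_complement(circ), rc_start)
    lengths = structure.region_lengths
    if fwd.bases <= rev.bases:
        chosen = fwd
        l_ira, l_irb = lengths["IRA"], lengths["IRB"]
    else:
        chosen = rev
        l_ira, l_irb = lengths["IRB"], lengths["IRA"]
    l_lsc, l_ssc = lengths["LSC"], lengths["SSC"]
    remapped = QuadripartiteStructure(
        lsc=(0, l_lsc),
        ira=(l_lsc, l_lsc + l_ira),
        ssc=(l_lsc + l_ira, l_lsc + l_ira + l_ssc),
        irb=(l_lsc + l_ira + l_ssc, n),
        ir_mismatches=structure.ir_mismatches,
    )
    return chosen, remapped


# ---------------------------------------------------------------------------
# statistics and census


def region_stats(genome: NucSequence, structure: QuadripartiteStructure) -> RegionStats:
    """Per-region lengths and GC content; combined-IR GC as one figure."""
    if structure.genome_length != len(genome):
        raise ValueError(
            f"structure length {structure.genome_length} != genome length {len(genome)}"
        )
    regions = {
        "LSC": _extract(genome.bases, structure.lsc),
        "IRA": _extract(genome.bases, structure.ira),
        "SSC": _extract(genome.bases, structure.ssc),
        "IRB": _extract(genome.bases, structure.irb),
    }
    lengths = {name: len(seq) for name, seq in regions.items()}
    assert sum(lengths.values()) == len(genome)
    gc = {name: gc_fraction(seq) for name, seq in regions.items()}
    gc["IR"] = gc_fraction(regions["IRA"] + regions["IRB"])
    gc["overall"] = gc_fraction(genome.bases)
    return RegionStats(lengths=lengths, gc=gc, total_length=len(genome))


def annotation_census(rows: list[AnnotationRow]) -> AnnotationCensus:
    """Tally an annotation table into per-system and copy-number counts."""
    seen: set[str] = set()
    per_system: dict[str, int] = {}
    by_copy: Counter[int] = Counter()
    total = 0
    for row in rows:
        if row.gene in seen:
            raise ValueError(f"duplicate gene {row.gene!r} in annotation table")
        seen.add(row.gene)
        per_system[row.functional_system] = (
            per_system.get(row.functional_system, 0) + row.copies
        )
        by_copy[row.copies] += 1
        total += row.copies
    return AnnotationCensus(
        per_system=per_system,
        distinct_genes=len(rows),
        total_copies=total,
        n_single=by_copy.get(1, 0),
        n_double=by_copy.get(2, 0),
        n_triple=by_copy.get(3, 0),
    )


def gene_totals(census: AnnotationCensus, n_rrna: int, n_trna: int) -> int:
    """Total gene count: protein-coding copies plus rRNA and tRNA genes."""
    if n_rrna < 0 or n_trna < 0:
        raise ValueError("rRNA/tRNA counts must be >= 0")
    return census.total_copies + n_rrna + n_trna
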