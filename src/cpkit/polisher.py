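"""Pileup-consensus polishing of a draft circular genome with short reads.

Reads are placed on the draft with an exact k-mer seed / banded-extension
aligner (or supplied as an alignment table with CIGARs), stacked into a
per-column pileup, and the draft is corrected wherever a plurality allele
(base, deletion, or inserted string) reaches the support threshold. This
reproduces the role short-read polishers play in hybrid organelle
assembly: fixing residual SNPs and small indels left by long-read drafts.

Reads that map equally well to both inverted-repeat copies are assigned to
the best-scoring placement (ties to the smaller coordinate); variants that
distinguish the copies therefore stay resolvable as long as reads overlap
a distinguishing site.

Indel placements are canonicalized per read by re-aligning each indel
neighbourhood against a fixed draft window, so that reads covering the
same variant pool their support on identical columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from collections import Counter

import edlib

from .align import cigar_ops, kmer_index
from .seq_io import AlignmentRecord, NucSequence, ReadRecord, reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "PileupColumn",
    "Edit",
    "PolishParams",
    "build_pileup",
    "call_edits",
    "apply_edits",
    "align_reads",
    "polish",
]

_BASES = "ACGTN"


@dataclass
class PileupColumn:
    position: int
    base_counts: Counter = field(default_factory=Counter)
    deletion_count: int = 0
    insertion_multiset: Counter = field(default_factory=Counter)

    @property
    def depth(self) -> int:
        return sum(self.base_counts.values()) + self.deletion_count


@dataclass(frozen=True)
class Edit:
    position: int
    kind: str  # {"snp", "ins", "del"}
    ref_allele: str
    alt_allele: str
    support_fraction: float
    depth: int

    def __post_init__(self):
        if self.kind == "snp" and not (len(self.ref_allele) == len(self.alt_allele) == 1):
            raise ValueError("snp edit must have single-base alleles")
        if self.kind == "ins" and self.ref_allele != "":
            raise ValueError("ins edit must have empty ref allele")
        if self.kind == "del" and self.alt_allele != "":
            raise ValueError("del edit must have empty alt allele")


@dataclass(frozen=True)
class PolishParams:
    min_depth: int = 5
    min_support_fraction: float = 0.7
    max_indel_bp: int = 10
    kmer_size: int = 17

    def __post_init__(self):
        if not 0.5 < self.min_support_fraction <= 1.0:
            raise ValueError("min_support_fraction must lie in (0.5, 1]")


def _read_ops(cigar: str, read_bases: str, ref_start: int):
    """Expand a CIGAR into per-column events: (ref_pos, kind, payload).

    kinds: 'base' (payload = read base), 'del' (payload None, one per
    deleted ref base), 'ins' (payload = inserted string, attached before
    ref_pos).
    """
    events = []
    rp = ref_start
    qp = 0
    for n, op in cigar_ops(cigar):
        if op in "M=X":
            for i in range(n):
                events.append((rp + i, "base", read_bases[qp + i]))
            rp += n
            qp += n
        elif op == "D":
            for i in range(n):
                events.append((rp + i, "del", None))
            rp += n
        elif op == "I":
            events.append((rp, "ins", read_bases[qp : qp + n]))
            qp += n
    return events


def _canonicalize_indel_clusters(events, draft2: str, ref_lo: int, ref_hi: int, margin: int = 8):
    """Re-derive events around indels from a fixed draft window.

    Edit-distance alignments place the same insertion or deletion at
    slightly different offsets depending on where a read happens to start;
    votes for one variant would then scatter over neighbouring columns.
    For every cluster of indel events the read's alternate sequence over a
    padded draft window is extracted and re-aligned against that window,
    so every read fully covering the window emits byte-identical events.
    Clusters whose window is not fully covered by the read keep their
    original events.
    """
    indel_pos = sorted({e[0] for e in events if e[1] != "base"})
    if not indel_pos:
        return events
    clusters = []
    cur = [indel_pos[0]]
    for p in indel_pos[1:]:
        if p - cur[-1] <= 6:
            cur.append(p)
        else:
            clusters.append(cur)
            cur = [p]
    clusters.append(cur)
    out = list(events)
    for cl in clusters:
        w0, w1 = cl[0] - margin, cl[-1] + margin + 1
        if w0 < ref_lo or w1 > ref_hi or w0 < 0 or w1 > len(draft2):
            continue
        inside = []
        keep = []
        for e in out:
            pos, kind, payload = e
            if kind == "ins":
                (inside if w0 < pos < w1 else keep).append(e)
            else:
                (inside if w0 <= pos < w1 else keep).append(e)
        alt = []
        for pos, kind, payload in inside:  # events stay in alignment order
            if kind == "ins":
                alt.append(payload)
            elif kind == "base":
                alt.append(payload)
        alt = "".join(alt)
        window = draft2[w0:w1]
        res = edlib.align(alt, window, mode="NW", task="path")
        out = keep + _read_ops(res["cigar"], alt, w0)
        out.sort(key=lambda e: (e[0], e[1] != "ins"))
    return out


def align_reads(
    draft: NucSequence,
    reads: list[ReadRecord],
    params: PolishParams = PolishParams(),
) -> list[AlignmentRecord]:
    """Place each read on the draft with seed-and-verify alignment.

    A circular draft is indexed doubled so reads may span the origin. Each
    candidate diagonal (from exact k-mer seeds, both strands) is verified
    with global edit distance over a padded window; the placement with the
    smallest edit distance wins, ties going to the smaller draft
    coordinate. Unalignable reads are skipped.
    """
    n = len(draft)
    target = draft.bases + (draft.bases if draft.circular else "")
    k = params.kmer_size
    index = kmer_index(target, k)
    out = []
    for read in reads:
        best = None  # (edit_distance, offset_mod, strand, cigar, span)
        for strand in "+-":
            q = read.bases if strand == "+" else reverse_complement(read.bases)
            if len(q) < k:
                continue
            votes = Counter()
            for i in range(0, len(q) - k + 1, 4):
                for t in index.get(q[i : i + k], ()):
                    votes[t - i] += 1
            pad = max(8, len(q) // 10)
            seen = set()
            for off, _cnt in votes.most_common(8):
                key = off if not draft.circular else off % n
                if key in seen:
                    continue
                seen.add(key)
                lo = max(0, off - pad)
                hi = min(len(target), off + len(q) + pad)
                res = edlib.align(q, target[lo:hi], mode="HW", task="path", k=pad)
                if res["editDistance"] < 0 or not res["locations"]:
                    continue
                loc = min(res["locations"])
                start = lo + loc[0]
                cand = (res["editDistance"], start % n if draft.circular else start,
                        strand, res["cigar"], loc[1] + 1 - loc[0])
                if best is None or cand[:2] < best[:2]:
                    best = cand
        if best is None:
            continue
        ed, start, strand, cigar, span = best
        out.append(
            AlignmentRecord(
                query_id=read.id + (f"/{read.mate}" if read.mate else ""),
                query_length=len(read),
                query_start=0,
                query_end=len(read),
                ref_id=draft.id,
                ref_start=start,
                ref_end=start + span,
                strand=strand,
                match_bp=max(0, min(len(read), span) - ed),
                cigar=cigar,
            )
        )
    return out


def build_pileup(
    draft: NucSequence,
    alns: list[AlignmentRecord],
    reads: dict[str, str] | None = None,
) -> dict[int, PileupColumn]:
    """Stack aligned reads into per-column counts.

    ``reads`` maps query id to the read bases; when omitted the alignments
    must have been produced by :func:`align_reads` against reads whose
    bases are supplied there. Positions wrap modulo the draft length on a
    circular draft.
    """
    n = len(draft)
    columns: dict[int, PileupColumn] = {}

    def col(p: int) -> PileupColumn:
        if p not in columns:
            columns[p] = PileupColumn(position=p)
        return columns[p]

    for aln in alns:
        if aln.cigar is None:
            raise ValueError(f"alignment {aln.query_id!r} carries no CIGAR")
        if reads is None:
            raise ValueError("read bases required to build a pileup")
        bases = reads[aln.query_id]
        if aln.strand == "-":
            bases = reverse_complement(bases)
        if not draft.circular and aln.ref_end > n:
            raise ValueError(
                f"alignment {aln.query_id!r} extends past the end of a linear draft"
            )
        events = _read_ops(aln.cigar, bases, aln.ref_start)
        draft2 = draft.bases + (draft.bases if draft.circular else "")
        events = _canonicalize_indel_clusters(
            events, draft2, aln.ref_start, aln.ref_end
        )
        for pos, kind, payload in events:
            p = pos % n if draft.circular else pos
            c = col(p)
            if kind == "base":
                c.base_counts[payload] += 1
            elif kind == "del":
                c.deletion_count += 1
            else:
                c.insertion_multiset[payload] += 1
    return columns


def call_edits(
    pileup: dict[int, PileupColumn],
    draft: NucSequence,
    params: PolishParams = PolishParams(),
) -> list[Edit]:
    """Plurality-with-threshold consensus calls against the draft.

    At each column with depth >= min_depth the plurality allele among
    {A,C,G,T,N, deletion} is compared with the draft base; a disagreement
    supported by >= min_support_fraction of the depth becomes a SNP or
    1-bp deletion edit. Insertions are called per junction the same way.
    Ties at exactly the threshold are accepted. Indels longer than
    max_indel_bp are ignored.
    """
    edits = []
    for pos in sorted(pileup):
        c = pileup[pos]
        depth = c.depth
        if depth < params.min_depth:
            continue
        alleles = list(c.base_counts.items()) + [("-", c.deletion_count)]
        allele, count = max(alleles, key=lambda kv: (kv[1], kv[0] != "-"))
        draft_base = draft.bases[pos]
        if allele != draft_base and count / depth >= params.min_support_fraction:
            if allele == "-":
                edits.append(
                    Edit(pos, "del", draft_base, "", count / depth, depth)
                )
            else:
                edits.append(
                    Edit(pos, "snp", draft_base, allele, count / depth, depth)
                )
        if c.insertion_multiset:
            ins, icount = max(c.insertion_multiset.items(), key=lambda kv: (kv[1], kv[0]))
            if len(ins) <= params.max_indel_bp and icount / depth >= params.min_support_fraction:
                edits.append(Edit(pos, "ins", "", ins, icount / depth, depth))
    return edits


def apply_edits(draft: NucSequence, edits: list[Edit]) -> NucSequence:
    """Apply edits in descending position order so coordinates stay valid.

    Edits touching the same position (other than an insertion next to a
    substitution/deletion) are rejected as overlapping.
    """
    by_pos = sorted(edits, key=lambda e: (e.position, e.kind))
    seen: dict[tuple[int, bool], Edit] = {}
    for e in by_pos:
        key = (e.position, e.kind == "ins")
        if key in seen:
            raise ValueError(
                f"overlapping edits at position {e.position}: {seen[key]} vs {e}"
            )
        seen[key] = e
    bases = draft.bases
    for e in sorted(edits, key=lambda e: (-e.position, e.kind != "ins")):
        if e.kind == "snp":
            bases = bases[: e.position] + e.alt_allele + bases[e.position + 1 :]
        elif e.kind == "del":
            bases = bases[: e.position] + bases[e.position + 1 :]
        else:
            bases = bases[: e.position] + e.alt_allele + bases[e.position :]
    return NucSequence(
        id=draft.id, bases=bases, circular=draft.circular, description=draft.description
    )


def polish(
    draft: NucSequence,
    reads: list[ReadRecord],
    params: PolishParams = PolishParams(),
    rounds: int = 1,
    alignments: list[AlignmentRecord] | None = None,
) -> tuple[NucSequence, list[Edit]]:
    """Full polishing: align -> pileup -> call -> apply, optionally iterated.

    Deterministic for fixed inputs. Raises when no read aligns.
    """
    current = draft
    all_edits: list[Edit] = []
    for rnd in range(rounds):
        if alignments is not None and rnd == 0:
            alns = alignments
        else:
            alns = align_reads(current, reads, params)
        if not alns:
            raise ValueError("no reads aligned to the draft; cannot polish")
        read_bases = {}
        for r in reads:
            read_bases[r.id + (f"/{r.mate}" if r.mate else "")] = r.bases
        pileup = build_pileup(current, alns, read_bases)
        edits = call_edits(pileup, current, params)
        logger.info("polish round %d: %d edits", rnd + 1, len(edits))
        if not edits:
            break
        current = apply_edits(current, edits)
        all_edits.extend(edits)
    return current, all_edits
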