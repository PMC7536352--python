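"""Seeded generators for quadripartite genomes, reads and assembler-like
contig sets, so every pipeline stage is testable without any download.

The default genome is a scaled-down plastome: LSC 20 kb, IR 6 kb, SSC
3 kb (the real molecule is ~87/31/12 kb), with region GC targets set to
the values typical of plastomes (single-copy regions in the mid 30s %,
IRs noticeably higher). Long reads carry indel-dominated errors and no
quality strings; short reads come as error-free Q40 pairs by default,
with an optional 3' quality decay to exercise trimming. All generators
are pure functions of their spec (byte-identical output per seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .contig_merger import Contig
from .seq_io import AlignmentRecord, NucSequence, ReadRecord, reverse_complement
from .structure_tools import QuadripartiteStructure

__all__ = [
    "GenomeSpec",
    "ReadSimSpec",
    "ContigSimSpec",
    "WgsMixture",
    "simulate_genome",
    "simulate_long_reads",
    "simulate_short_pairs",
    "simulate_draft_contigs",
    "simulate_collapsed_contigs",
    "simulate_wgs_mixture",
    "inject_variants",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class GenomeSpec:
    lsc_bp: int = 20_000
    ir_bp: int = 6_000
    ssc_bp: int = 3_000
    gc_lsc: float = 0.36
    gc_ir: float = 0.41
    gc_ssc: float = 0.32
    ir_divergence_sites: int = 0
    seed: int = 0

    def __post_init__(self):
        if not self.lsc_bp > self.ssc_bp > 0:
            raise ValueError("need lsc_bp > ssc_bp > 0")
        if self.ir_bp < 100:
            raise ValueError("ir_bp must be >= 100")
        for gc in (self.gc_lsc, self.gc_ir, self.gc_ssc):
            if not 0.0 < gc < 1.0:
                raise ValueError("GC targets must lie in (0,1)")
        if self.ir_divergence_sites < 0:
            raise ValueError("ir_divergence_sites must be >= 0")


@dataclass(frozen=True)
class ReadSimSpec:
    coverage: float = 30.0
    # long-read fields
    length_mean: int = 3_000
    length_sd: int = 1_000
    min_length: int = 200
    # short-read fields
    read_bp: int = 150
    insert_mean: int = 400
    insert_sd: int = 40
    # per-base error rates
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    three_prime_decay_bp: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0.0 <= r <= 0.2:
                raise ValueError("error rates must lie in [0, 0.2]")


@dataclass(frozen=True)
class ContigSimSpec:
    mode: str = "ir_boundary_break"  # {"ir_boundary_break", "random_break", "ir_collapsed"}
    n_breaks: int = 12
    terminal_overlap_bp: int = 2_000
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("ir_boundary_break", "random_break", "ir_collapsed"):
            raise ValueError(f"unknown contig simulation mode {self.mode!r}")
        if self.terminal_overlap_bp < 0:
            raise ValueError("terminal_overlap_bp must be >= 0")


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p).tobytes().decode()


def simulate_genome(spec: GenomeSpec = GenomeSpec()) -> tuple[NucSequence, QuadripartiteStructure]:
    """A circular quadripartite genome in canonical order LSC-IRA-SSC-IRB.

    IRB is the reverse complement of IRA with ``ir_divergence_sites``
    substitutions placed away from the copy ends. The bases flanking the
    repeat copies are adjusted so the truth boundaries are maximal: the
    repeat cannot be extended by a chance complementary base, which makes
    the truth structure the unique answer a detector should find.
    """
    rng = np.random.default_rng(spec.seed)
    lsc = list(_random_bases(rng, spec.lsc_bp, spec.gc_lsc))
    ira = _random_bases(rng, spec.ir_bp, spec.gc_ir)
    ssc = list(_random_bases(rng, spec.ssc_bp, spec.gc_ssc))
    irb = list(reverse_complement(ira))
    if spec.ir_divergence_sites:
        margin = min(50, spec.ir_bp // 10)
        positions = rng.choice(
            np.arange(margin, spec.ir_bp - margin),
            size=spec.ir_divergence_sites,
            replace=False,
        )
        for pos in sorted(int(p) for p in positions):
            old = irb[pos]
            choices = [b for b in "ACGT" if b != old]
            irb[pos] = choices[int(rng.integers(len(choices)))]
    # enforce maximality of the repeat boundaries:
    # extending IRA leftward pairs the last LSC base with the first LSC base;
    # extending IRA rightward pairs the first SSC base with the last SSC base
    if lsc[-1] == _COMP[lsc[0]]:
        lsc[-1] = next(b for b in "ACGT" if b != _COMP[lsc[0]] and b != lsc[-1])
    if ssc[0] == _COMP[ssc[-1]]:
        ssc[0] = next(b for b in "ACGT" if b != _COMP[ssc[-1]] and b != ssc[0])
    bases = "".join(lsc) + ira + "".join(ssc) + "".join(irb)
    genome = NucSequence(id=f"sim_cp_{spec.seed}", bases=bases, circular=True)
    n_lsc, n_ir, n_ssc = spec.lsc_bp, spec.ir_bp, spec.ssc_bp
    structure = QuadripartiteStructure(
        lsc=(0, n_lsc),
        ira=(n_lsc, n_lsc + n_ir),
        ssc=(n_lsc + n_ir, n_lsc + n_ir + n_ssc),
        irb=(n_lsc + n_ir + n_ssc, n_lsc + 2 * n_ir + n_ssc),
        ir_mismatches=spec.ir_divergence_sites,
    )
    return genome, structure


def _inject_errors(bases: str, rng: np.random.Generator, spec: ReadSimSpec) -> str:
    if spec.sub_rate == spec.ins_rate == spec.del_rate == 0.0:
        return bases
    out = []
    for b in bases:
        r = rng.random()
        if r < spec.del_rate:
            continue
        if r < spec.del_rate + spec.sub_rate:
            choices = [c for c in "ACGT" if c != b]
            out.append(choices[int(rng.integers(len(choices)))])
            continue
        out.append(b)
        if rng.random() < spec.ins_rate:
            out.append("ACGT"[int(rng.integers(4))])
    return "".join(out)


def simulate_long_reads(
    genome: NucSequence, spec: ReadSimSpec = ReadSimSpec()
) -> tuple[list[ReadRecord], list[tuple[str, int, int, str]]]:
    """Long reads with uniform circular starts and truncated-normal lengths.

    Returns (reads, truth) where truth rows are (read id, origin start,
    origin end on the doubled circle, strand). Long reads carry no
    quality strings.
    """
    rng = np.random.default_rng(spec.seed)
    n = len(genome)
    doubled = genome.bases + genome.bases if genome.circular else genome.bases
    target_bp = spec.coverage * n
    reads: list[ReadRecord] = []
    truth: list[tuple[str, int, int, str]] = []
    total = 0
    i = 0
    while total < target_bp:
        length = int(rng.normal(spec.length_mean, spec.length_sd))
        length = max(spec.min_length, min(length, n))
        start = int(rng.integers(n)) if genome.circular else int(rng.integers(max(1, n - length + 1)))
        fragment = doubled[start : start + length]
        strand = "+" if rng.random() < 0.5 else "-"
        bases = fragment if strand == "+" else reverse_complement(fragment)
        bases = _inject_errors(bases, rng, spec)
        rid = f"lr{i}"
        reads.append(ReadRecord(id=rid, bases=bases, platform="long"))
        truth.append((rid, start, start + length, strand))
        total += length
        i += 1
    return reads, truth


def _pair_qualities(spec: ReadSimSpec) -> tuple[int, ...]:
    q = [40] * spec.read_bp
    if spec.three_prime_decay_bp:
        d = min(spec.three_prime_decay_bp, spec.read_bp)
        for i in range(d):
            q[spec.read_bp - d + i] = max(2, 40 - (i + 1) * 40 // d)
    return tuple(q)


def simulate_short_pairs(
    genome: NucSequence, spec: ReadSimSpec = ReadSimSpec()
) -> tuple[list[ReadRecord], list[tuple[str, int, int, str]]]:
    """Error-free-by-default paired short reads from random inserts.

    Mate 1 is the fragment 5' end, mate 2 the reverse complement of its
    3' end; the fragment itself sits on a random strand. Truth rows are
    (pair id, fragment start, fragment end, fragment strand).
    """
    rng = np.random.default_rng(spec.seed)
    n = len(genome)
    doubled = genome.bases + genome.bases if genome.circular else genome.bases
    n_pairs = int(np.ceil(spec.coverage * n / (2 * spec.read_bp)))
    quals = _pair_qualities(spec)
    reads: list[ReadRecord] = []
    truth: list[tuple[str, int, int, str]] = []
    for i in range(n_pairs):
        insert = int(rng.normal(spec.insert_mean, spec.insert_sd))
        insert = max(spec.read_bp, min(insert, n))
        start = int(rng.integers(n)) if genome.circular else int(rng.integers(max(1, n - insert + 1)))
        fragment = doubled[start : start + insert]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            fragment = reverse_complement(fragment)
        m1 = _inject_errors(fragment[: spec.read_bp], rng, spec)
        m2 = _inject_errors(reverse_complement(fragment[-spec.read_bp :]), rng, spec)
        pid = f"sr{i}"
        reads.append(ReadRecord(id=pid, bases=m1, qualities=quals, platform="short", mate=1))
        reads.append(ReadRecord(id=pid, bases=m2, qualities=quals, platform="short", mate=2))
        truth.append((pid, start, start + insert, strand))
    return reads, truth


def simulate_draft_contigs(
    genome: NucSequence,
    structure: QuadripartiteStructure,
    spec: ContigSimSpec = ContigSimSpec(),
) -> tuple[list[Contig], list[tuple[str, str]]]:
    """Three linear contigs broken at the IR boundaries, each carrying
    ``terminal_overlap_bp`` of duplicated sequence into its successor
    (the long-read assembler output pattern the merger must resolve).

    Contig orientations are randomized per seed; the truth layout returns
    (contig id, orientation applied).
    """
    ov = spec.terminal_overlap_bp
    b = genome.bases
    lsc, ira, ssc, irb = structure.lsc, structure.ira, structure.ssc, structure.irb
    for name, iv in (("LSC", lsc), ("IRA", ira), ("SSC", ssc), ("IRB", irb)):
        if ov >= iv[1] - iv[0]:
            raise ValueError(
                f"terminal overlap {ov} must be smaller than region {name}"
            )
    pieces = {
        "tig1": b[lsc[0] : lsc[1]] + b[ira[0] : ira[0] + ov],
        "tig2": b[ira[0] : ira[1]] + b[ssc[0] : ssc[0] + ov],
        "tig3": b[ssc[0] : irb[1]] + b[lsc[0] : lsc[0] + ov],
    }
    rng = np.random.default_rng(spec.seed)
    contigs = []
    layout = []
    for name, bases in pieces.items():
        orient = "+" if rng.random() < 0.5 else "-"
        if orient == "-":
            bases = reverse_complement(bases)
        contigs.append(Contig(seq=NucSequence(id=name, bases=bases)))
        layout.append((name, orient))
    return contigs, layout


def simulate_collapsed_contigs(
    genome: NucSequence,
    structure: QuadripartiteStructure,
    spec: ContigSimSpec = ContigSimSpec(mode="ir_collapsed", terminal_overlap_bp=50),
) -> tuple[list[Contig], list[tuple[str, int, int]]]:
    """Fragments of the genome with one IR copy deleted (short-read
    assembler pattern): the IR survives as single-copy sequence.

    The IR-collapsed circle (LSC + IRA + SSC) is cut at ``n_breaks``
    seeded positions, one of them fixed at the LSC start; every fragment
    carries ``terminal_overlap_bp`` of duplicated sequence into its
    successor (the last wraps into the first). Truth rows are
    (contig id, start, end) on the collapsed circle.
    """
    b = genome.bases
    collapsed = (
        b[structure.lsc[0] : structure.lsc[1]]
        + b[structure.ira[0] : structure.ira[1]]
        + b[structure.ssc[0] : structure.ssc[1]]
    )
    nc = len(collapsed)
    ov = spec.terminal_overlap_bp
    if spec.n_breaks < 1 or spec.n_breaks * (ov + 50) > nc:
        raise ValueError(f"n_breaks {spec.n_breaks} too large for genome of {nc} bp")
    rng = np.random.default_rng(spec.seed)
    if spec.n_breaks == 1:
        breaks = [0]
    else:
        while True:
            inner = sorted(int(x) for x in rng.integers(1, nc, size=spec.n_breaks - 1))
            breaks = [0] + inner
            gaps = [breaks[i + 1] - breaks[i] for i in range(len(breaks) - 1)]
            gaps.append(nc - breaks[-1])
            if min(gaps) > ov + 50:
                break
    doubled = collapsed + collapsed
    contigs = []
    truth = []
    for i, start in enumerate(breaks):
        end = breaks[i + 1] if i + 1 < len(breaks) else nc
        bases = doubled[start : end + ov]
        name = f"ctg{i:02d}"
        contigs.append(Contig(seq=NucSequence(id=name, bases=bases)))
        truth.append((name, start, end + ov))
    return contigs, truth


@dataclass(frozen=True)
class WgsMixture:
    reads: list[ReadRecord]
    labels: dict[str, bool]  # read id -> is chloroplast
    alignments: list[AlignmentRecord]


def simulate_wgs_mixture(
    cp_genome: NucSequence,
    background_bp: int,
    cp_read_fraction: float,
    spec: ReadSimSpec = ReadSimSpec(),
    n_reads: int = 100,
) -> WgsMixture:
    """Long-read WGS mixture: chloroplast reads plus nuclear background.

    Background reads come from a seeded random genome with no chloroplast
    homology. The idealized alignment table holds one exact full-length
    record per chloroplast read (reference coordinates on the circle,
    wrapping past the origin allowed) and nothing for background reads.
    """
    if not 0.0 < cp_read_fraction < 1.0:
        raise ValueError("cp_read_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(spec.seed)
    background = _random_bases(rng, background_bp, 0.35)
    n = len(cp_genome)
    doubled = cp_genome.bases + cp_genome.bases
    reads: list[ReadRecord] = []
    labels: dict[str, bool] = {}
    alns: list[AlignmentRecord] = []
    for i in range(n_reads):
        length = int(rng.normal(spec.length_mean, spec.length_sd))
        length = max(spec.min_length, min(length, n, background_bp))
        is_cp = bool(rng.random() < cp_read_fraction)
        rid = f"wgs{i}"
        if is_cp:
            start = int(rng.integers(n))
            bases = doubled[start : start + length]
            alns.append(
                AlignmentRecord(
                    query_id=rid,
                    query_length=length,
                    query_start=0,
                    query_end=length,
                    ref_id=cp_genome.id,
                    ref_start=start,
                    ref_end=start + length,
                    strand="+",
                    match_bp=length,
                )
            )
        else:
            start = int(rng.integers(max(1, background_bp - length + 1)))
            bases = background[start : start + length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            bases = reverse_complement(bases)
        reads.append(ReadRecord(id=rid, bases=bases, platform="long"))
        labels[rid] = is_cp
    return WgsMixture(reads=reads, labels=labels, alignments=alns)


def inject_variants(
    genome: NucSequence,
    n_snps: int,
    n_indels: int,
    seed: int,
    regions: list[tuple[int, int]] | None = None,
    max_indel_bp: int = 3,
    min_spacing: int = 25,
) -> tuple[NucSequence, list[tuple[int, str, str]]]:
    """Corrupt a genome with seeded SNPs and short indels (for testing
    variant-recovery by the polisher).

    Variants are placed at least ``min_spacing`` apart, optionally
    restricted to the given intervals (e.g. the single-copy regions:
    variants inside a repeat copy are not uniquely correctable by any
    pileup-based polisher, since reads from the two copies are
    interchangeable). Returns (corrupted genome, list of (position on the
    TRUTH genome, truth allele, corrupted allele)), insertions/deletions
    encoded with empty strings.
    """
    rng = np.random.default_rng(seed)
    n = len(genome)
    candidates = regions if regions is not None else [(0, n)]
    positions: list[int] = []
    spans = np.concatenate([np.arange(lo + 5, hi - 5) for lo, hi in candidates])
    while len(positions) < n_snps + n_indels:
        p = int(spans[int(rng.integers(len(spans)))])
        if all(abs(p - q) >= min_spacing for q in positions):
            positions.append(p)
    kinds = ["snp"] * n_snps + ["indel"] * n_indels
    plan = sorted(zip(positions, kinds), reverse=True)
    bases = genome.bases
    variants = []
    for pos, kind in plan:
        if kind == "snp":
            old = bases[pos]
            new = "ACGT"[("ACGT".index(old) + 1 + int(rng.integers(3))) % 4]
            if new == old:
                new = "ACGT"[("ACGT".index(old) + 1) % 4]
            bases = bases[:pos] + new + bases[pos + 1 :]
            variants.append((pos, old, new))
        else:
            size = 1 + int(rng.integers(max_indel_bp))
            if rng.random() < 0.5:  # delete truth bases from the draft
                old = bases[pos : pos + size]
                bases = bases[:pos] + bases[pos + size :]
                variants.append((pos, old, ""))
            else:  # insert spurious bases into the draft
                ins = "".join("ACGT"[int(rng.integers(4))] for _ in range(size))
                bases = bases[:pos] + ins + bases[pos:]
                variants.append((pos, "", ins))
    corrupted = replace(genome, bases=bases, id=genome.id + "_corrupt")
    return corrupted, sorted(variants)
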