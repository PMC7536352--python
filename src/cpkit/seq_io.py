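"""Sequence and table I/O plus the core domain types shared by every stage.

All coordinates inside the toolkit are 0-based half-open; conversion to the
1-based inclusive convention used in report files happens only at the I/O
boundary. Circularity of a sequence is carried as a ``circular=true`` token
in the FASTA description, since FASTA itself has no standard for it.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import dendropy

__all__ = [
    "NucSequence",
    "ReadRecord",
    "AlignmentRecord",
    "AnnotationRow",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_alignment_table",
    "write_alignment_table",
    "read_annotation_table",
    "write_annotation_table",
    "read_newick",
    "write_newick",
    "reverse_complement",
    "rotate",
]

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass(frozen=True)
class NucSequence:
    """A named nucleotide sequence over {A,C,G,T,N} with a circular flag."""

    id: str
    bases: str
    circular: bool = False
    description: str | None = None

    def __post_init__(self):
        bad = set(self.bases) - ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: illegal characters {sorted(bad)!r}"
            )
        if self.circular and len(self.bases) == 0:
            raise ValueError(f"sequence {self.id!r}: circular sequence may not be empty")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read; long (Nanopore-like) or short (Illumina-like)."""

    id: str
    bases: str
    qualities: tuple[int, ...] | None = None
    platform: str = "long"  # {"long", "short"}
    mate: int = 0  # 1 or 2 for short-read mates, 0 for none

    def __post_init__(self):
        bad = set(self.bases) - ALPHABET
        if bad:
            raise ValueError(f"read {self.id!r}: illegal characters {sorted(bad)!r}")
        if self.platform not in ("long", "short"):
            raise ValueError(f"read {self.id!r}: unknown platform {self.platform!r}")
        if self.qualities is not None and len(self.qualities) != len(self.bases):
            raise ValueError(
                f"read {self.id!r}: {len(self.qualities)} qualities for "
                f"{len(self.bases)} bases"
            )
        if self.mate not in (0, 1, 2):
            raise ValueError(f"read {self.id!r}: mate must be 0, 1 or 2")
        if self.mate and self.platform != "short":
            raise ValueError(f"read {self.id!r}: mate set on a non-paired platform")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class AlignmentRecord:
    """One mapping of a query interval onto a reference interval.

    ``match_bp`` is the number of exactly matching base pairs (M) and
    ``ref_span`` the number of reference bases spanned (L); the alignment
    identity of the record is M/L.
    """

    query_id: str
    query_length: int
    query_start: int
    query_end: int
    ref_id: str
    ref_start: int
    ref_end: int
    strand: str  # "+" or "-"
    match_bp: int
    cigar: str | None = None

    def __post_init__(self):
        if not (0 <= self.query_start < self.query_end <= self.query_length):
            raise ValueError(
                f"alignment {self.query_id!r}: bad query interval "
                f"[{self.query_start},{self.query_end}) on length {self.query_length}"
            )
        if not (0 <= self.ref_start < self.ref_end):
            raise ValueError(
                f"alignment {self.query_id!r}: bad reference interval "
                f"[{self.ref_start},{self.ref_end})"
            )
        if self.strand not in "+-":
            raise ValueError(f"alignment {self.query_id!r}: strand must be + or -")
        limit = min(self.query_end - self.query_start, self.ref_span)
        if not (0 <= self.match_bp <= limit):
            raise ValueError(
                f"alignment {self.query_id!r}: match_bp {self.match_bp} outside "
                f"[0,{limit}]"
            )

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start


@dataclass(frozen=True)
class AnnotationRow:
    """One annotated gene: name, functional system, copy number."""

    gene: str
    functional_system: str
    copies: int

    def __post_init__(self):
        if self.copies < 1:
            raise ValueError(f"gene {self.gene!r}: copies must be >= 1")


# ---------------------------------------------------------------------------
# sequence primitives


def reverse_complement(seq: NucSequence | str) -> NucSequence | str:
    """Reverse complement; N maps to N. Involution: rc(rc(x)) == x."""
    if isinstance(seq, str):
        return seq.translate(_COMPLEMENT)[::-1]
    return replace(seq, bases=seq.bases.translate(_COMPLEMENT)[::-1])


def rotate(seq: NucSequence, offset: int) -> NucSequence:
    """Rotate a circular sequence so that position ``offset`` becomes position 0."""
    if not seq.circular:
        raise ValueError(f"sequence {seq.id!r} is not circular; cannot rotate")
    n = len(seq)
    if not 0 <= offset < n:
        raise ValueError(f"rotation offset {offset} outside [0,{n})")
    return replace(seq, bases=seq.bases[offset:] + seq.bases[:offset])


def gc_fraction(bases: str) -> float:
    """G+C over A+C+G+T; N excluded from the denominator."""
    acgt = sum(bases.count(b) for b in "ACGT")
    if acgt == 0:
        return math.nan
    return (bases.count("G") + bases.count("C")) / acgt


# ---------------------------------------------------------------------------
# FASTA

_CIRCULAR_TOKEN = "circular=true"


def read_fasta(path) -> list[NucSequence]:
    """Read a (possibly gzipped) FASTA file into NucSequence records.

    Bases are uppercased and U is mapped to T. A record is flagged circular
    when its description carries the token ``circular=true``. Characters
    outside {A,C,G,T,N} raise a FormatError naming the offending line.
    """
    out: list[NucSequence] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def _flush():
        if header is None:
            return
        name, _, desc = header.partition(" ")
        if not name:
            raise FormatError(f"{path}:{header_line}: empty FASTA header")
        bases = "".join(chunks)
        try:
            seq = NucSequence(
                id=name,
                bases=bases,
                circular=_CIRCULAR_TOKEN in desc.lower().split(),
                description=desc or None,
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{header_line}: {exc}") from exc
        out.append(seq)

    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].strip()
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FormatError(f"{path}:{lineno}: sequence before any header")
                cleaned = line.upper().replace("U", "T")
                bad = set(cleaned) - ALPHABET
                if bad:
                    raise FormatError(
                        f"{path}:{lineno}: illegal characters {sorted(bad)!r}"
                    )
                chunks.append(cleaned)
        _flush()
    return out


def write_fasta(seqs: Iterable[NucSequence], path, line_width: int = 70):
    """Write FASTA; the circular flag round-trips through the description."""
    with _open_text(path, "wt") as fh:
        for seq in seqs:
            desc_parts = []
            if seq.description:
                desc_parts.append(seq.description)
            if seq.circular and _CIRCULAR_TOKEN not in " ".join(desc_parts).lower():
                desc_parts.append(_CIRCULAR_TOKEN)
            desc = (" " + " ".join(desc_parts)) if desc_parts else ""
            fh.write(f">{seq.id}{desc}\n")
            for i in range(0, len(seq.bases), line_width):
                fh.write(seq.bases[i : i + line_width] + "\n")
    return path


# ---------------------------------------------------------------------------
# FASTQ (Phred+33)


def read_fastq(path, platform: str = "long") -> list[ReadRecord]:
    """Read a (possibly gzipped) FASTQ file.

    Mate numbers are recovered from ``/1``, ``/2`` id suffixes for short
    reads. Qualities are Phred+33.
    """
    out: list[ReadRecord] = []
    with _open_text(path) as fh:
        lineno = 0
        while True:
            head = fh.readline()
            lineno += 1
            if not head:
                break
            head = head.rstrip("\n")
            if not head.strip():
                continue
            if not head.startswith("@"):
                raise FormatError(f"{path}:{lineno}: expected '@' header, got {head[:20]!r}")
            bases = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            quals = fh.readline().rstrip("\n")
            lineno += 3
            if not plus.startswith("+"):
                raise FormatError(f"{path}:{lineno - 1}: expected '+' separator")
            if len(quals) != len(bases):
                raise FormatError(
                    f"{path}:{lineno}: quality length {len(quals)} != "
                    f"sequence length {len(bases)}"
                )
            name = head[1:].split()[0]
            mate = 0
            if platform == "short" and name.endswith(("/1", "/2")):
                mate = int(name[-1])
                name = name[:-2]
            try:
                out.append(
                    ReadRecord(
                        id=name,
                        bases=bases.upper().replace("U", "T"),
                        qualities=tuple(ord(c) - 33 for c in quals),
                        platform=platform,
                        mate=mate,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno - 3}: {exc}") from exc
    return out


def write_fastq(reads: Iterable[ReadRecord], path):
    with _open_text(path, "wt") as fh:
        for read in reads:
            name = read.id
            if read.mate:
                name = f"{name}/{read.mate}"
            quals = read.qualities
            if quals is None:
                quals = (40,) * len(read.bases)
            fh.write(f"@{name}\n{read.bases}\n+\n")
            fh.write("".join(chr(q + 33) for q in quals) + "\n")
    return path


# ---------------------------------------------------------------------------
# PAF-style alignment TSV
#
# Columns (PAF layout): query_id, query_length, query_start, query_end,
# strand, ref_id, ref_length, ref_start, ref_end, match_bp, ref_span, mapq.
# An optional 13th column carries a cg:Z: CIGAR for pileup construction.


def read_alignment_table(path) -> list[AlignmentRecord]:
    out: list[AlignmentRecord] = []
    with _open_text(path) as fh:
        for idx, raw in enumerate(fh):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(
                    f"{path}: record {idx}: expected >= 12 columns, got {len(cols)}"
                )
            try:
                qlen, qs, qe = int(cols[1]), int(cols[2]), int(cols[3])
                rs, re_ = int(cols[7]), int(cols[8])
                match_bp, span = int(cols[9]), int(cols[10])
            except ValueError as exc:
                raise FormatError(f"{path}: record {idx}: non-numeric field") from exc
            if span != re_ - rs:
                raise FormatError(
                    f"{path}: record {idx}: ref_span {span} != ref_end - ref_start "
                    f"{re_ - rs}"
                )
            cigar = None
            for extra in cols[12:]:
                if extra.startswith("cg:Z:"):
                    cigar = extra[5:]
            try:
                out.append(
                    AlignmentRecord(
                        query_id=cols[0],
                        query_length=qlen,
                        query_start=qs,
                        query_end=qe,
                        ref_id=cols[5],
                        ref_start=rs,
                        ref_end=re_,
                        strand=cols[4],
                        match_bp=match_bp,
                        cigar=cigar,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}: record {idx}: {exc}") from exc
    return out


def write_alignment_table(alns: Iterable[AlignmentRecord], path, ref_lengths=None):
    ref_lengths = ref_lengths or {}
    with _open_text(path, "wt") as fh:
        for aln in alns:
            cols = [
                aln.query_id,
                str(aln.query_length),
                str(aln.query_start),
                str(aln.query_end),
                aln.strand,
                aln.ref_id,
                str(ref_lengths.get(aln.ref_id, 0)),
                str(aln.ref_start),
                str(aln.ref_end),
                str(aln.match_bp),
                str(aln.ref_span),
                "255",
            ]
            if aln.cigar:
                cols.append(f"cg:Z:{aln.cigar}")
            fh.write("\t".join(cols) + "\n")
    return path


# ---------------------------------------------------------------------------
# annotation TSV (gene, functional system, copies)


def read_annotation_table(path) -> list[AnnotationRow]:
    out: list[AnnotationRow] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for idx, raw in enumerate(fh):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise FormatError(
                    f"{path}: record {idx}: expected 3 columns, got {len(cols)}"
                )
            gene, system, copies = cols
            if gene in seen:
                raise FormatError(f"{path}: record {idx}: duplicate gene {gene!r}")
            seen.add(gene)
            try:
                row = AnnotationRow(gene=gene, functional_system=system, copies=int(copies))
            except ValueError as exc:
                raise FormatError(f"{path}: record {idx}: {exc}") from exc
            out.append(row)
    return out


def write_annotation_table(rows: Iterable[AnnotationRow], path):
    with _open_text(path, "wt") as fh:
        for row in rows:
            fh.write(f"{row.gene}\t{row.functional_system}\t{row.copies}\n")
    return path


# ---------------------------------------------------------------------------
# newick trees (dendropy-backed)


def read_newick(path) -> dendropy.Tree:
    with _open_text(path) as fh:
        text = fh.read()
    try:
        return dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several error types
        raise FormatError(f"{path}: invalid newick: {exc}") from exc


def write_newick(tree: dendropy.Tree, path):
    with _open_text(path, "wt") as fh:
        fh.write(tree.as_string(schema="newick", suppress_rooting=True))
    return path
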