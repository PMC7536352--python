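# Methods

This note documents the models, algorithms and numerical choices behind
`cpkit`, in the order the pipeline uses them, together with what the
synthetic data does and does not establish about real data.

## Coordinate and sequence conventions

All coordinates are 0-based half-open; report files (structure TSV,
edits TSV, layout TSV) convert to 1-based inclusive at the I/O boundary
only. Sequences are uppercase over {A,C,G,T,N}; U is mapped to T on
read and other IUPAC ambiguity codes are rejected rather than silently
mapped, so downstream exact-match seeding never sees wildcards.
Circularity is carried as a `circular=true` token in the FASTA
description, since FASTA has no standard for it; the flag round-trips
through read/write.

## Alignment primitives

Three stages (merging, polishing, scaffolding) share one seed-and-verify
engine: exact k-mer anchors vote for diagonals, each candidate is
verified with banded edit distance (edlib), and ties break
deterministically (longest overlap, then smallest coordinate, then
strand). k defaults to 21 for contig-scale comparisons and 17 for reads;
at those sizes a chance exact anchor in a ~10⁴–10⁵ bp target is
vanishingly rare (≈ n·4⁻ᵏ), so identity verification, not seeding, is
the effective filter. The edit-distance band is twice the tolerated
error of the interval under test. When a placement can be extended from
its anchored cluster to the full query, the extension is accepted only
if the *added* flanks align at the identity threshold on their own;
otherwise the cluster span is reported as a partial placement. This
matters for fragments of a circular molecule whose tail wraps the
origin: the tail maps elsewhere on the reference and must not be
absorbed into the main placement.

## Read classification

The long-read rule: records with < 500 bp of the read aligned are
ignored; the remaining query intervals are merged to an interval union
(overlaps counted once — the conservative reading of "total aligned
length", which prevents repeat-region double-counting from inflating
coverage); the read is accepted iff the union is ≥ 1 kb and ≥ 80 % of
the read length, and at least one record survived the filter. Alignments
to any reference genome of a panel count toward the same union, and
strand is ignored. The pair rule: both mates aligned, each with at least
one block ≥ 100 bp. Quality trimming (short reads first): leading and
trailing bases below Q20 are removed; if an internal base still fails,
the read is cut at the first such base and the longer fragment kept
(ties keep the left fragment); results shorter than 100 bp are
discarded. The trimming semantics beyond the two thresholds are a pinned
design choice, exposed as parameters.

The read length used for the 80 % fraction is the length of the read as
given; no post-trimming length is substituted.

## Contig merging and circularization

Overlap detection reports, for each unordered contig pair and each of
the four orientation classes, the longest suffix–prefix match ≥ 500 bp
at ≥ 95 % identity (candidates from shared-k-mer diagonals, verified by
global edit distance over the candidate length). Mirror-image edges are
implied, not duplicated. Layout is greedy longest-overlap-first: each
contig is consumed once with a single orientation; contigs wholly
contained in a longer contig (either strand) are dropped as redundancy
first; an edge that would close a cycle is skipped — because edges are
taken in descending overlap order this breaks the cycle at its weakest
link — and reported. Concatenation emits each overlap once; when
identities are below 1 the overlap bases come from the longer contig
(deterministic; the polisher is the error-fixing stage).

Circularization finds the longest prefix/suffix self-match (the trivial
full-length match excluded), trims the suffix copy, keeps the prefix
copy, and marks the sequence circular. An overlap longer than half the
contig is refused as a degenerate tandem artifact. Without a terminal
overlap the input is returned unchanged with a not-circularizable
status.

One boundary case is worth naming: when draft contigs abut with *zero*
junction redundancy, the contig holding one complete IR copy is still a
genuine full-length suffix–prefix overlap of the reverse complement of
the contig holding the other copy. That edge is real sequence homology,
not an artifact, and the merger reports it; "no junction overlaps"
therefore means "no sub-IR-length edges", not "no edges".

## Polishing

Reads are placed on the draft by the shared aligner; a circular draft is
indexed doubled so reads may span the origin, and positions wrap modulo
the length. A read that maps equally well to both IR copies is assigned
to the best-scoring placement with ties to the smaller coordinate, so
copy-distinguishing variants remain resolvable when reads overlap a
distinguishing site.

Each read's CIGAR is expanded to per-column events. Because
edit-distance alignment places the same indel at slightly different
offsets depending on where a read starts, every indel neighbourhood is
re-aligned against a fixed ±8 bp draft window, so all reads fully
covering the window emit byte-identical events and pool their votes on
the same columns (reads only partially covering a window keep their
original events and are a small minority at any locus). Per-event VCF
style left-normalization was deliberately *not* used: shifting adjacent
insertions independently is only sequence-preserving in isolation and
corrupted compound variants.

Calling is plurality-with-threshold: at each column with depth ≥ 5, a
plurality allele (base or deletion) differing from the draft with
support ≥ 0.7 becomes an edit; insertions are called per junction the
same way; indels longer than 10 bp are ignored; support exactly at the
threshold is accepted (≥, not >). Edits are applied in descending
position order. Polishing the truth genome with reads simulated from the
truth yields zero edits (fixed point), and a second round after full
recovery yields zero edits (convergence).

Known limitation: a variant *inside* a repeat copy is not uniquely
correctable by any pileup consensus, because reads from the two copies
are interchangeable wherever they cover no distinguishing site; the
recovery guarantees are therefore stated for single-copy regions, which
is where the variant-recovery suites inject their variants.

## Reference-guided scaffolding

Contigs are anchored on a canonical reference with known structure. A
contig counts as anchored when some placement reaches
min(500 bp, max(half the contig, 30 bp)); all its identity-verified
placements are then trusted, including short partial ones such as the
mirror image of an IR-boundary-spanning fragment. A contig homologous to
the IR (≥ 80 % of its placed span inside an IR interval) naturally
receives two placements on opposite strands, one per copy, and may be
used at both — the resolution of IR collapse. Selection is greedy by
identity × placed length with deterministic tie-breaks; a placement is
kept only if it covers reference bases not yet covered (≥ 5 % of its
span); a placement nearly contained (≥ 95 %) in an opposite-strand
placement of another contig is dropped as discordant with a logged
warning.

Joining concatenates the *placed query intervals* in reference order:
neighbouring intervals that overlap on the reference are joined through
that overlap after verifying the junction sequences agree within the
identity band; abutting intervals concatenate directly; gaps are filled
with N at reference-estimated size (transparent and reported; gaps above
5 kb mark the layout incomplete and joining refuses). The last placement
closes the circle onto the first by the same rule. Joining placed
intervals rather than whole contigs is what keeps wrap-around tails and
IR-boundary dangles out of the assembled sequence.

When the input contains exactly one IR copy, the rebuilt second copy is
by construction the reverse complement of the first; any real divergence
between the copies of the source molecule is thereby erased. That is an
inherent property of IR-collapse resolution (shared with the manual
pipelines this emulates), and the round-trip guarantees are accordingly
stated for genomes with identical copies.

## Quadripartite structure detection

Seeds are exact k-mers (k = 15) shared between the circular sequence and
its reverse complement. A pair of positions (i, j) such that the k-mer
at i equals the reverse complement of the k-mer at j lies, for a true
inverted repeat, on one anti-diagonal c = (i + j) mod n — a quantity
invariant under rotation of the circle, which is what makes detection
rotation-proof without trying rotations. The top anti-diagonals by seed
count are extended outward from three of their seeds (first, median,
last). Extension crosses a mismatch only when the next 30 pairings are
≥ 80 % matches — the signature of isolated divergence between copies, as
opposed to having run off the repeat into single-copy sequence (where
pairings match ~25 % by chance) — and only while the cumulative mismatch
count stays within the 1 % budget; boundaries end on the outermost
matching base, and the copies plus both single-copy arcs must stay
disjoint. The longest extension wins (ties to the smaller start). The
larger single-copy arc is the LSC; IRA is, by convention, the copy
immediately following the LSC — a positional convention that makes
reports reproducible. Both copies get equal lengths from the pairwise
extension; diverged trailing bases are implicitly assigned to the
single-copy neighbours. If no repeat reaches 1 kb (configurable), a
"no quadripartite structure" error is raised.

Canonicalization rotates the genome so the LSC starts at 0 and, of the
two strand choices (each rotated to its own LSC start), emits the
lexicographically smaller sequence — deterministic and data-free, so any
rotation or reverse complement of one molecule canonicalizes
identically. Homology to a published genome would fix the strand
biologically but requires external data; the lexicographic rule is the
default.

Region statistics: lengths must sum to the genome length (asserted); GC
is G+C over A+C+G+T with N excluded from the denominator, reported per
region, for both IR copies combined (one figure, as plastome reports
conventionally print), and overall.

The annotation census tallies a (gene, functional system, copies) table:
per-system copy sums, distinct genes, total copies, and single-, double-
and triple-copy gene counts, with `copies = n₁ + 2n₂ + 3n₃` holding by
construction. Annotation *generation* is out of scope; the bundled
`sweetpotato_cp_genes.tsv` (83 genes, 16 functional systems) is a
transcription of a published sweetpotato plastome gene table used as a
census fixture.

## Phylogeny summaries

p-distance is the proportion of differing columns among columns where
both symbols are in {A,C,G,T}; gap and N columns are excluded from
numerator and denominator; zero comparable columns is an error. Branch
collapse contracts internal branches strictly shorter than the threshold
(default 2×10⁻⁴ substitutions/bp; "shorter than" is strict, so threshold
0 is the identity); terminal branches are never contracted and the leaf
set is preserved. Clade reports group the leaf children of each polytomy
of the collapsed tree into one cluster; leaves at fully resolved binary
nodes stay singletons. An optional stricter mode also requires each
leaf's own branch to be below the threshold before it joins a cluster.

## Synthetic data: what it emulates and what it does not

`simulate_genome` draws LSC, IRA and SSC i.i.d. per base at region GC
targets (defaults 0.36/0.41/0.32 — single-copy regions in the mid-30s %,
IRs higher, as in real plastomes) and sets IRB to the reverse complement
of IRA with a configurable number of substitutions placed ≥ 50 bp from
the copy ends. The default toy scale is LSC 20 kb, IR 6 kb, SSC 3 kb
(35 kb total) — the real molecule's ~87/31/12 kb layout scaled down
~4.6× so every suite runs in seconds on one CPU. The bases flanking the
repeat are adjusted so the truth boundaries are maximal (the repeat
cannot be extended by a chance complementary base); without this the
recorded truth would disagree with any correct maximal-extension
detector at ~25 % of boundaries. IR divergence defaults to 0 because the
exact reference round trip is only well-defined for identical copies
(see scaffolding above); detector suites set it explicitly.

Long reads: uniform circular starts, truncated-normal lengths (mean
3 kb, sd 1 kb, floor 200 bp), indel-biased errors when enabled, no
quality strings. Short reads: error-free 150-bp pairs at Q40 from
~400-bp inserts, with an optional 3' quality decay to exercise trimming.
Draft contigs: the three-contig IR-boundary break with configurable
terminal redundancy (default 2 kb) and randomized orientations.
Collapsed contigs: the genome minus one IR copy, cut at n seeded
positions (one fixed at the LSC start), each fragment carrying a small
(default 50 bp) overlap into its successor, the last wrapping into the
first. WGS mixtures: cp reads plus reads from a seeded random background
genome, with truth labels and an idealized alignment table (one exact
full-length record per cp read, coordinates allowed to wrap the circle;
none for background).

Because background reads are random sequence and cp alignments are
idealized, classifier suites establish that the *selection rules* are
implemented exactly (oracle equivalence, monotonicity, perfect
sensitivity/specificity under full-length alignments) — not how the
rules perform against real nuclear genomes with organelle-derived
insertions, divergent reference panels, or a real mapper's split and
soft-clipped records. Likewise error-free reads make polisher recovery a
test of consensus logic, not of error-model robustness; and i.i.d.
sequence contains none of the local repeats, homopolymer runs or gene
content of real plastomes, so exact round trips demonstrate algorithmic
correctness, not field performance.

## Problem sizes used by the verification suites

The standing suites use the 35-kb toy genome for round trips (≥ 5 seeds
each for the hybrid and reference pipelines), 30× error-free 150-bp
pairs for polishing, 20 replicate seeds × (20 SNPs + 5 indels of 1–3 bp)
for variant recovery, 50-read batches for classifier oracle checks,
≤ 2.3-kb genomes for the exhaustive inverted-repeat oracle (the oracle
scans all ~2n diagonals of the sequence against its reverse complement,
O(n²)), and 100 random rotation/strand transformations for canonical
invariance. These sizes were chosen so the whole verification runs in
about a minute while every property is exercised at its full strength.
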