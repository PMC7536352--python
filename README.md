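# cpkit

A toolkit for hybrid assembly of chloroplast (cp) genomes from
whole-genome sequencing data.

Plastomes are circular molecules of roughly 107–218 kb with a
quadripartite layout: a large single-copy region (LSC) and a small
single-copy region (SSC) separated by two near-identical inverted
repeats (IRA and IRB) of tens of kilobases. The IRs defeat short-read
assemblers (they usually emit a single collapsed copy), while long WGS
reads span them but carry high error rates. `cpkit` implements the
bespoke computational stages of a long+short read plastome pipeline for
people assembling organelle genomes from ordinary WGS data:

- **read_classifier** — select cp-derived reads from WGS alignments.
  A long read is kept when, over alignment records with ≥ 500 bp of the
  read aligned, the union of aligned intervals reaches ≥ 1 kb and ≥ 80 %
  of the read length; a short-read pair is kept when both mates align
  with a block ≥ 100 bp (after trimming every base to Q ≥ 20 and reads
  to ≥ 100 bp). Per-record alignment identity is `I = M/L`, exact-match
  bases over the reference span.
- **contig_merger** — merge the few linear contigs a long-read assembler
  emits (typically broken at the IR boundaries) through verified
  suffix–prefix overlaps, drop contained redundancy, and circularize by
  trimming the duplicated terminal sequence.
- **polisher** — pileup-consensus correction of SNPs and small indels in
  the circular draft from accurate short reads (plurality allele with
  ≥ 70 % support at ≥ 5× depth, indels ≤ 10 bp).
- **ir_scaffolder** — reference-guided scaffolding of fragmented
  short-read contigs; contigs homologous to the IR are placed at *both*
  repeat positions (the second reverse-complemented) so the assembled
  circle regains both copies.
- **structure_tools** — detect the quadripartite structure from sequence
  alone (inverted-repeat seed pairs on rotation-invariant anti-diagonals,
  mismatch-tolerant extension), canonicalize to an LSC-first
  linearization on a deterministic strand, compute per-region length and
  GC statistics, and census gene-annotation tables by functional system
  and copy number.
- **phylo_summary** — p-distances on aligned genomes and collapsing of
  tree branches shorter than a threshold (default 2×10⁻⁴
  substitutions/bp) into polytomies, with clade reports.
- **synthetic_data** — seeded generators for quadripartite genomes,
  long/short reads, IR-boundary-broken draft contigs and IR-collapsed
  contig sets, so the whole pipeline is testable offline.

## Worked example

Simulate a 35-kb quadripartite genome (LSC 20 kb, IRs 6 kb, SSC 3 kb),
break it into three draft contigs at the IR boundaries with 2 kb of
terminal redundancy, then rebuild and inspect it:

```sh
cpkit simulate genome --seed 11 -o sim
cpkit simulate draft-contigs --seed 11 -o sim
cpkit merge --contigs sim/draft_contigs.fasta -o merged.fasta --layout layout.tsv
cpkit circularize --in merged.fasta -o circle.fasta
cpkit structure --in circle.fasta -o structure.tsv --stats stats.tsv
```

which prints

```
merge: 3 contigs in, 1 out, 0 contained dropped
circularize: trimmed 2000 bp terminal overlap
structure: LSC=20000 IRA=6000 SSC=3000 IRB=6000 total=35000
```

The three contigs chained into one ~39-kb linear sequence whose 2-kb
duplicated ends were trimmed to close the 35,000-bp circle; the detector
then recovered the simulated region sizes exactly, and `stats.tsv`
reports the per-region GC (IR ≈ 41.6 %, LSC ≈ 35.7 %, SSC ≈ 32.6 % here
— IRs are GC-rich because they carry the rRNA operon).

Censusing the bundled sweetpotato cp gene table:

```sh
cpkit census --table src/cpkit/data/sweetpotato_cp_genes.tsv --rrna 8 --trna 48
```

```
distinct_genes  83
total_copies    96
single_copy     71
double_copy     11
triple_copy     1
total_with_rrna_trna    152
```

83 distinct protein-coding genes make 96 gene copies (71 single-copy, 11
double-copy, one triple-copy), and adding 8 rRNA and 48 tRNA genes gives
the 152 genes of the genome.

`cpkit demo --seed 11 -o demo_out` runs both end-to-end pipelines
(hybrid: merge → circularize → polish → canonicalize; reference:
scaffold IR-collapsed fragments → canonicalize) and verifies both
reconstructions against the simulated truth:

```
demo: hybrid exact=True, reference exact=True
```

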