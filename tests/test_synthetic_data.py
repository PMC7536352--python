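import pytest

from cpkit.seq_io import reverse_complement
from cpkit.synthetic_data import (
    ContigSimSpec,
    GenomeSpec,
    ReadSimSpec,
    simulate_collapsed_contigs,
    simulate_draft_contigs,
    simulate_genome,
    simulate_long_reads,
    simulate_short_pairs,
    simulate_wgs_mixture,
)


class TestGenome:
    def test_lengths_and_structure(self):
        genome, st = simulate_genome(GenomeSpec(seed=1))
        assert len(genome) == 35_000
        assert st.region_lengths == {"LSC": 20_000, "IRA": 6_000, "SSC": 3_000, "IRB": 6_000}

    def test_irb_is_revcomp_of_ira(self):
        genome, st = simulate_genome(GenomeSpec(seed=2))
        ira = genome.bases[st.ira[0] : st.ira[1]]
        irb = genome.bases[st.irb[0] : st.irb[1]]
        assert irb == reverse_complement(ira)

    def test_divergence_site_count(self):
        genome, st = simulate_genome(GenomeSpec(seed=3, ir_divergence_sites=7))
        ira = genome.bases[st.ira[0] : st.ira[1]]
        irb = genome.bases[st.irb[0] : st.irb[1]]
        diffs = sum(a != b for a, b in zip(reverse_complement(irb), ira))
        assert diffs == 7

    def test_deterministic_per_seed(self):
        g1, _ = simulate_genome(GenomeSpec(seed=9))
        g2, _ = simulate_genome(GenomeSpec(seed=9))
        g3, _ = simulate_genome(GenomeSpec(seed=10))
        assert g1.bases == g2.bases and g1.bases != g3.bases

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            GenomeSpec(lsc_bp=1000, ssc_bp=2000)


class TestReads:
    def test_long_read_coverage_close_to_target(self, toy_genome):
        genome, _ = toy_genome
        reads, truth = simulate_long_reads(genome, ReadSimSpec(coverage=30, seed=4))
        realized = sum(len(r) for r in reads) / len(genome)
        assert abs(realized - 30) / 30 < 0.1

    def test_error_free_long_reads_are_substrings(self, toy_genome):
        genome, _ = toy_genome
        reads, truth = simulate_long_reads(genome, ReadSimSpec(coverage=2, seed=5))
        doubled = genome.bases + genome.bases
        for read, (rid, start, end, strand) in zip(reads[:50], truth[:50]):
            expected = doubled[start:end]
            if strand == "-":
                expected = reverse_complement(expected)
            assert read.bases == expected

    def test_error_free_pairs_are_substrings(self, toy_genome):
        genome, _ = toy_genome
        reads, truth = simulate_short_pairs(genome, ReadSimSpec(coverage=1, seed=6))
        doubled = genome.bases + genome.bases
        rc = reverse_complement(doubled)
        for r in reads[:100]:
            assert r.bases in doubled or r.bases in rc

    def test_pair_qualities_pass_trimming_by_default(self, toy_genome):
        from cpkit.read_classifier import ClassifierParams, trim_by_quality
        genome, _ = toy_genome
        reads, _ = simulate_short_pairs(genome, ReadSimSpec(coverage=0.1, seed=7))
        for r in reads:
            assert trim_by_quality(r, ClassifierParams()).bases == r.bases

    def test_three_prime_decay_exercises_trimming(self, toy_genome):
        from cpkit.read_classifier import ClassifierParams, trim_by_quality
        genome, _ = toy_genome
        reads, _ = simulate_short_pairs(
            genome, ReadSimSpec(coverage=0.1, seed=8, three_prime_decay_bp=40)
        )
        trimmed = trim_by_quality(reads[0], ClassifierParams())
        assert trimmed is None or len(trimmed) < len(reads[0])

    def test_indel_biased_errors_change_length(self, toy_genome):
        genome, _ = toy_genome
        reads, truth = simulate_long_reads(
            genome,
            ReadSimSpec(coverage=1, seed=9, sub_rate=0.02, ins_rate=0.04, del_rate=0.04),
        )
        lengths_differ = sum(
            1 for r, (_, s, e, _) in zip(reads, truth) if len(r) != e - s
        )
        assert lengths_differ > len(reads) * 0.5


class TestContigSets:
    def test_draft_contigs_zero_overlap_abut(self, toy_genome):
        genome, st = toy_genome
        contigs, _ = simulate_draft_contigs(
            genome, st, ContigSimSpec(terminal_overlap_bp=0, seed=1)
        )
        assert sum(len(c) for c in contigs) == len(genome)
        from cpkit.contig_merger import find_overlaps
        # junction overlaps vanish; only the genuine IR-homology overlap
        # (the IRA contig against the reverse complement of the SSC+IRB
        # contig) can remain, and it spans the full repeat
        ir_len = st.ira[1] - st.ira[0]
        assert all(e.overlap_bp >= ir_len for e in find_overlaps(contigs))

    def test_draft_contig_overlap_too_large_rejected(self, toy_genome):
        genome, st = toy_genome
        with pytest.raises(ValueError, match="smaller than region"):
            simulate_draft_contigs(genome, st, ContigSimSpec(terminal_overlap_bp=4000))

    def test_collapsed_contigs_lack_second_ir(self, toy_genome):
        genome, st = toy_genome
        contigs, truth = simulate_collapsed_contigs(
            genome, st, ContigSimSpec(mode="ir_collapsed", n_breaks=5, terminal_overlap_bp=50, seed=2)
        )
        total = sum(len(c) for c in contigs)
        collapsed_len = len(genome) - (st.irb[1] - st.irb[0])
        assert total == collapsed_len + 5 * 50

    def test_too_many_breaks_rejected(self, toy_genome):
        genome, st = toy_genome
        with pytest.raises(ValueError, match="too large"):
            simulate_collapsed_contigs(
                genome, st, ContigSimSpec(mode="ir_collapsed", n_breaks=1000, terminal_overlap_bp=50)
            )

    def test_deterministic_per_seed(self, toy_genome):
        genome, st = toy_genome
        a, _ = simulate_collapsed_contigs(
            genome, st, ContigSimSpec(mode="ir_collapsed", n_breaks=8, terminal_overlap_bp=50, seed=3)
        )
        b, _ = simulate_collapsed_contigs(
            genome, st, ContigSimSpec(mode="ir_collapsed", n_breaks=8, terminal_overlap_bp=50, seed=3)
        )
        assert [c.seq.bases for c in a] == [c.seq.bases for c in b]


class TestWgsMixture:
    def test_label_fraction_binomial(self, toy_genome):
        genome, _ = toy_genome
        mix = simulate_wgs_mixture(
            genome, background_bp=50_000, cp_read_fraction=0.4,
            spec=ReadSimSpec(seed=10), n_reads=1000,
        )
        n_cp = sum(mix.labels.values())
        # 3 sigma of Binomial(1000, 0.4)
        assert abs(n_cp - 400) < 3 * (1000 * 0.4 * 0.6) ** 0.5

    def test_alignments_only_for_cp_reads(self, toy_genome):
        genome, _ = toy_genome
        mix = simulate_wgs_mixture(
            genome, background_bp=50_000, cp_read_fraction=0.5,
            spec=ReadSimSpec(seed=11), n_reads=100,
        )
        aligned_ids = {a.query_id for a in mix.alignments}
        assert aligned_ids == {rid for rid, is_cp in mix.labels.items() if is_cp}

    def test_fraction_one_rejected(self, toy_genome):
        genome, _ = toy_genome
        with pytest.raises(ValueError):
            simulate_wgs_mixture(genome, 1000, 1.0)
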