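import pytest

from cpkit.polisher import (
    Edit,
    PolishParams,
    align_reads,
    apply_edits,
    build_pileup,
    call_edits,
    polish,
)
from cpkit.seq_io import NucSequence, ReadRecord
from cpkit.synthetic_data import (
    GenomeSpec,
    ReadSimSpec,
    inject_variants,
    simulate_genome,
    simulate_short_pairs,
)

P = PolishParams()


def _reads_from(draft_bases, coverage, read_len=30, circular=True):
    """Tile error-free reads over a (possibly circular) template."""
    doubled = draft_bases + (draft_bases if circular else "")
    n = len(draft_bases)
    reads = []
    step = max(1, read_len * len(draft_bases) // (coverage * len(draft_bases)))
    i = 0
    pos = 0
    limit = n if circular else n - read_len + 1
    while len(reads) * read_len < coverage * n:
        start = pos % limit
        reads.append(ReadRecord(id=f"t{i}", bases=doubled[start : start + read_len], platform="long"))
        pos += step
        i += 1
    return reads


class TestPileup:
    def test_uniform_coverage_consensus_equals_draft(self):
        draft = NucSequence("d", "ACGTTGCA" * 20, circular=False)
        reads = [ReadRecord(id=f"r{i}", bases=draft.bases, platform="long") for i in range(10)]
        alns = align_reads(draft, reads, P)
        pileup = build_pileup(draft, alns, {r.id: r.bases for r in reads})
        assert all(col.depth == 10 for col in pileup.values())
        assert call_edits(pileup, draft, P) == []

    def test_substitution_shows_nine_one_split(self):
        draft = NucSequence("d", "ACGT" * 30, circular=False)
        alt = draft.bases[:50] + ("G" if draft.bases[50] != "G" else "C") + draft.bases[51:]
        reads = [ReadRecord(id=f"r{i}", bases=draft.bases, platform="long") for i in range(9)]
        reads.append(ReadRecord(id="rx", bases=alt, platform="long"))
        alns = align_reads(draft, reads, P)
        pileup = build_pileup(draft, alns, {r.id: r.bases for r in reads})
        col = pileup[50]
        assert sorted(col.base_counts.values()) == [1, 9]

    def test_read_spanning_circular_origin(self):
        genome, _ = simulate_genome(GenomeSpec(lsc_bp=300, ir_bp=120, ssc_bp=150, seed=3))
        wrap = genome.bases[-40:] + genome.bases[:40]
        reads = [ReadRecord(id="w", bases=wrap, platform="long")]
        alns = align_reads(genome, reads, P)
        pileup = build_pileup(genome, alns, {"w": wrap})
        assert 0 in pileup and (len(genome) - 1) in pileup


class TestCallEdits:
    def _col_pileup(self, draft, pos, counts, deletions=0):
        from cpkit.polisher import PileupColumn
        from collections import Counter
        col = PileupColumn(position=pos, base_counts=Counter(counts), deletion_count=deletions)
        return {pos: col}

    def test_plurality_snp_called(self):
        draft = NucSequence("d", "A" * 100)
        pileup = self._col_pileup(draft, 9, {"G": 9})
        (edit,) = call_edits(pileup, draft, P)
        assert (edit.kind, edit.ref_allele, edit.alt_allele) == ("snp", "A", "G")

    def test_draft_plurality_no_edit(self):
        draft = NucSequence("d", "A" * 100)
        pileup = self._col_pileup(draft, 9, {"A": 6, "G": 4})
        assert call_edits(pileup, draft, P) == []

    def test_below_min_depth_no_edit(self):
        draft = NucSequence("d", "A" * 100)
        pileup = self._col_pileup(draft, 9, {"G": 3})
        assert call_edits(pileup, draft, P) == []

    def test_support_exactly_at_threshold_accepted(self):
        draft = NucSequence("d", "A" * 100)
        pileup = self._col_pileup(draft, 9, {"G": 7, "A": 3})
        (edit,) = call_edits(pileup, draft, P)
        assert edit.support_fraction == pytest.approx(0.7)


class TestApplyEdits:
    def test_snp_keeps_length(self):
        draft = NucSequence("d", "AAAA")
        out = apply_edits(draft, [Edit(1, "snp", "A", "G", 1.0, 10)])
        assert out.bases == "AGAA"

    def test_deletion_shortens(self):
        draft = NucSequence("d", "AACGT")
        out = apply_edits(draft, [Edit(1, "del", "A", "", 1.0, 10), Edit(2, "del", "C", "", 1.0, 10)])
        assert out.bases == "AGT"

    def test_empty_list_is_identity(self):
        draft = NucSequence("d", "ACGT")
        assert apply_edits(draft, []).bases == "ACGT"

    def test_overlapping_edits_rejected(self):
        draft = NucSequence("d", "ACGT")
        with pytest.raises(ValueError, match="overlapping"):
            apply_edits(draft, [Edit(1, "snp", "C", "G", 1.0, 9), Edit(1, "del", "C", "", 1.0, 9)])


class TestPolish:
    def test_exact_draft_zero_edits(self, toy_genome):
        genome, _ = toy_genome
        reads, _ = simulate_short_pairs(genome, ReadSimSpec(coverage=10, seed=1))
        polished, edits = polish(genome, reads, P)
        assert edits == [] and polished.bases == genome.bases

    def test_three_bp_deletion_restored(self):
        genome, structure = simulate_genome(GenomeSpec(seed=9))
        pos = 5000
        draft = NucSequence(genome.id, genome.bases[:pos] + genome.bases[pos + 3 :], circular=True)
        reads, _ = simulate_short_pairs(genome, ReadSimSpec(coverage=30, seed=9))
        polished, edits = polish(draft, reads, P)
        assert polished.bases == genome.bases
        kinds = {e.kind for e in edits}
        assert kinds == {"ins"}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_variant_recovery(self, seed):
        """20 SNPs + 5 short indels in single-copy regions, fully recovered."""
        genome, structure = simulate_genome(GenomeSpec(seed=seed))
        draft, variants = inject_variants(
            genome, 20, 5, seed=500 + seed, regions=[structure.lsc, structure.ssc]
        )
        reads, _ = simulate_short_pairs(genome, ReadSimSpec(coverage=30, seed=700 + seed))
        polished, edits = polish(draft, reads, P, rounds=3)
        assert polished.bases == genome.bases

    def test_second_round_converges(self):
        genome, structure = simulate_genome(GenomeSpec(seed=4))
        draft, _ = inject_variants(genome, 5, 2, seed=44, regions=[structure.lsc])
        reads, _ = simulate_short_pairs(genome, ReadSimSpec(coverage=30, seed=45))
        once, edits1 = polish(draft, reads, P)
        again, edits2 = polish(once, reads, P)
        assert edits2 == [] and again.bases == once.bases == genome.bases

    def test_no_aligned_reads_raises(self):
        draft = NucSequence("d", "ACGT" * 100, circular=True)
        foreign = [ReadRecord(id="f", bases="TTAAGGCCTTAAGGCC" * 10, platform="long")]
        with pytest.raises(ValueError, match="no reads aligned"):
            polish(draft, foreign, P)
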