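import pytest

from cpkit.read_classifier import (
    ClassifierParams,
    alignment_identity,
    classify_batch,
    classify_long_read,
    classify_read_pair,
    interval_union_length,
    trim_by_quality,
)
from cpkit.seq_io import AlignmentRecord, ReadRecord
from cpkit.synthetic_data import GenomeSpec, ReadSimSpec, simulate_genome, simulate_wgs_mixture

from oracles import brute_force_long_read

P = ClassifierParams()


def aln(qid="q", qlen=2000, qs=0, qe=1000, rs=0, re=1000, m=None):
    return AlignmentRecord(
        query_id=qid, query_length=qlen, query_start=qs, query_end=qe,
        ref_id="cp", ref_start=rs, ref_end=re, strand="+",
        match_bp=m if m is not None else (qe - qs),
    )


class TestAlignmentIdentity:
    @pytest.mark.parametrize("m,span,expected", [(900, 1000, 0.9), (0, 500, 0.0), (750, 750, 1.0)])
    def test_formula(self, m, span, expected):
        a = aln(qe=span, re=span, m=m)
        assert alignment_identity(a) == pytest.approx(expected)


class TestTrimByQuality:
    def test_high_quality_read_unchanged(self):
        r = ReadRecord("r", "A" * 150, (30,) * 150, "short", 1)
        assert trim_by_quality(r, P).bases == r.bases

    def test_leading_low_quality_then_too_short(self):
        # 150 bp with the first 60 bases Q10: end-trim leaves 90 bp < 100
        r = ReadRecord("r", "A" * 150, (10,) * 60 + (30,) * 90, "short", 1)
        assert trim_by_quality(r, P) is None

    def test_short_read_rejected_at_boundary(self):
        r = ReadRecord("r", "A" * 99, (40,) * 99, "short", 1)
        assert trim_by_quality(r, P) is None

    def test_internal_cut_keeps_longer_fragment(self):
        # Q30 x 120, one Q5, Q30 x 30: cut keeps the left 120 bp
        r = ReadRecord("r", "A" * 151, (30,) * 120 + (5,) + (30,) * 30, "short", 1)
        trimmed = trim_by_quality(r, P)
        assert len(trimmed) == 120

    def test_missing_qualities_raise(self):
        with pytest.raises(ValueError, match="no qualities"):
            trim_by_quality(ReadRecord("r", "ACGT", None, "long"), P)


class TestClassifyLongRead:
    def test_short_record_discarded_then_accept(self):
        # 1200 bp read: [0,1000) kept, a 400-bp record discarded (< 500)
        alns = [aln(qlen=1200, qs=0, qe=1000, re=1000),
                aln(qlen=1200, qs=800, qe=1200, rs=2000, re=2400)]
        res = classify_long_read(1200, alns, P)
        assert res.aligned_bp == 1000
        assert res.aligned_fraction == pytest.approx(1000 / 1200)
        assert res.is_chloroplast

    def test_fraction_below_threshold_rejected(self):
        alns = [aln(qs=0, qe=600, re=600), aln(qs=1000, qe=1600, rs=1000, re=1600)]
        res = classify_long_read(2000, alns, P)
        assert res.aligned_bp == 1200 and not res.is_chloroplast

    def test_no_alignments_rejected(self):
        res = classify_long_read(5000, [], P)
        assert res.aligned_bp == 0 and not res.is_chloroplast

    def test_duplicate_records_do_not_inflate_union(self):
        a = aln(qs=0, qe=1600, qlen=2000, re=1600)
        r1 = classify_long_read(2000, [a], P)
        r2 = classify_long_read(2000, [a, a, a], P)
        assert r1.aligned_bp == r2.aligned_bp == 1600

    def test_inconsistent_query_length_raises(self):
        bad = [aln(qlen=2000), aln(qlen=3000, qs=0, qe=1000)]
        with pytest.raises(ValueError, match="inconsistent"):
            classify_long_read(2000, bad, P)


class TestClassifyReadPair:
    @pytest.mark.parametrize(
        "b1,b2,expected",
        [(150, 120, True), (150, 80, False), (150, None, False)],
    )
    def test_block_rule(self, b1, b2, expected):
        a1 = [aln(qid="p/1", qlen=250, qs=0, qe=b1, re=b1)]
        a2 = [] if b2 is None else [aln(qid="p/2", qlen=250, qs=0, qe=b2, re=b2)]
        assert classify_read_pair(a1, a2, P).is_chloroplast is expected


class TestBatchAndOracle:
    def _mixture(self, seed, n_reads=50):
        genome, _ = simulate_genome(GenomeSpec(seed=seed))
        return simulate_wgs_mixture(
            genome, background_bp=50_000, cp_read_fraction=0.4,
            spec=ReadSimSpec(seed=seed, length_mean=3000, length_sd=1500, min_length=300),
            n_reads=n_reads,
        )

    def test_simulated_truth_recovered_for_long_reads(self):
        mix = self._mixture(seed=5, n_reads=100)
        results, summary = classify_batch(mix.reads, mix.alignments, P)
        by_id = {r.read_id: r for r in results}
        for read in mix.reads:
            if mix.labels[read.id] and len(read) >= 1250:
                assert by_id[read.id].is_chloroplast, read.id
            if not mix.labels[read.id]:
                assert not by_id[read.id].is_chloroplast, read.id
        assert summary.n_accepted == sum(1 for r in results if r.is_chloroplast)

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_oracle_equivalence_on_small_batches(self, seed):
        """Decisions equal a brute-force base-set evaluation of the rules."""
        mix = self._mixture(seed=seed)
        by_query = {}
        for a in mix.alignments:
            by_query.setdefault(a.query_id, []).append(a)
        results, _ = classify_batch(mix.reads, mix.alignments, P)
        by_id = {r.read_id: r for r in results}
        for read in mix.reads:
            expected = brute_force_long_read(len(read), by_query.get(read.id, []), P)
            assert by_id[read.id].is_chloroplast == expected

    def test_threshold_monotonicity(self):
        """Raising any threshold never grows the accepted set."""
        mix = self._mixture(seed=21)

        def accepted(params):
            results, _ = classify_batch(mix.reads, mix.alignments, params)
            return {r.read_id for r in results if r.is_chloroplast}

        base = accepted(ClassifierParams(min_record_query_bp=0, min_total_query_bp=0,
                                         min_query_fraction=0.0))
        assert base == {r.id for r in mix.reads if any(
            a.query_id == r.id for a in mix.alignments)}
        prev = base
        for frac in (0.2, 0.5, 0.8, 0.95):
            cur = accepted(ClassifierParams(min_query_fraction=frac))
            assert cur <= prev
            prev = cur
        prev = accepted(ClassifierParams(min_total_query_bp=0))
        for total in (500, 1000, 2000, 4000):
            cur = accepted(ClassifierParams(min_total_query_bp=total))
            assert cur <= prev
            prev = cur

    def test_empty_alignment_table(self):
        mix = self._mixture(seed=31)
        results, summary = classify_batch(mix.reads, [], P)
        assert summary.n_accepted == 0


def test_interval_union_counts_overlaps_once():
    assert interval_union_length([(0, 100), (50, 150), (200, 300)]) == 250
    assert interval_union_length([]) == 0
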