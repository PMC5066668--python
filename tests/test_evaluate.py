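"""Misassembly classification, genome fraction, k-mer masking, overlap curves."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from bacplex.evaluate import (
    MaskedIntervals,
    build_kmer_index,
    canonical_kmer,
    classify_misassemblies,
    genome_fraction,
    kmer_mask,
    merge_intervals,
    repeat_overlap_fraction,
)
from bacplex.fixtures import random_dna
from bacplex.seqio_core import Alignment, revcomp


def _aln(qid, qstart, qend, tstart, tend, strand="+", identity=1.0):
    span = qend - qstart
    return Alignment(query_id=qid, target_id="ref", qstart=qstart, qend=qend,
                     tstart=tstart, tend=tend, strand=strand,
                     matches=int(identity * span), aln_len=span,
                     identity=identity, mapq=60, score=float(span))


def classifier_oracle(alns, min_aln=100, dist_thresh=1000):
    """Independent re-statement of the breakpoint rules, pair by pair."""
    calls = []
    per_query = {}
    for a in alns:
        if a.qend - a.qstart >= min_aln:
            per_query.setdefault(a.query_id, []).append(a)
    for qid in sorted(per_query):
        srt = sorted(per_query[qid], key=lambda a: (a.qstart, a.qend))
        for left, right in zip(srt, srt[1:]):
            if left.strand != right.strand:
                calls.append((qid, "global", "strand"))
                continue
            if left.strand == "+":
                sep = right.tstart - left.tend
            else:
                sep = left.tstart - right.tend
            if sep > dist_thresh:
                calls.append((qid, "global", "distance"))
            elif sep < -dist_thresh:
                calls.append((qid, "global", "overlap"))
            else:
                calls.append((qid, "local",
                              "distance" if sep >= 0 else "overlap"))
    return calls


class TestClassifyMisassemblies:
    def test_strand_flip_is_global(self):
        alns = [_aln("q", 0, 5000, 0, 5000, "+"),
                _aln("q", 5000, 10000, 5000, 10000, "-")]
        calls, summary = classify_misassemblies(alns)
        assert summary == {"n_global": 1, "n_local": 0}
        assert calls[0].reason == "strand"

    def test_long_range_relocation_is_global_distance(self):
        alns = [_aln("q", 0, 5000, 0, 5000),
                _aln("q", 5000, 10000, 45000, 50000)]
        calls, _ = classify_misassemblies(alns)
        assert (calls[0].klass, calls[0].reason) == ("global", "distance")

    def test_short_gap_is_local(self):
        alns = [_aln("q", 0, 5000, 0, 5000),
                _aln("q", 5000, 10000, 5200, 10200)]
        calls, _ = classify_misassemblies(alns)
        assert calls[0].klass == "local"

    def test_separation_exactly_threshold_is_local(self):
        alns = [_aln("q", 0, 5000, 0, 5000),
                _aln("q", 5000, 10000, 6000, 11000)]
        calls, _ = classify_misassemblies(alns)
        assert calls[0].klass == "local"

    def test_large_overlap_is_global(self):
        alns = [_aln("q", 0, 5000, 0, 5000),
                _aln("q", 5000, 10000, 3000, 8000)]
        calls, _ = classify_misassemblies(alns)
        assert (calls[0].klass, calls[0].reason) == ("global", "overlap")

    def test_single_alignment_yields_no_calls(self):
        calls, summary = classify_misassemblies([_aln("q", 0, 10000, 0, 10000)])
        assert calls == [] and summary == {"n_global": 0, "n_local": 0}

    def test_short_alignments_filtered_before_classification(self):
        alns = [_aln("q", 0, 5000, 0, 5000),
                _aln("q", 5000, 5050, 40000, 40050),  # below min_aln
                _aln("q", 5100, 10000, 5100, 10000)]
        calls, summary = classify_misassemblies(alns)
        assert summary == {"n_global": 0, "n_local": 1}

    def test_matches_oracle_on_random_configurations(self, rng):
        for _ in range(1000):
            n_aln = int(rng.integers(1, 6))
            qpos = 0
            alns = []
            for _ in range(n_aln):
                span = int(rng.integers(100, 3000))
                tstart = int(rng.integers(0, 50000))
                strand = "+" if rng.random() < 0.5 else "-"
                alns.append(_aln("q", qpos, qpos + span, tstart, tstart + span,
                                 strand))
                qpos += span + int(rng.integers(0, 50))
            calls, _ = classify_misassemblies(alns)
            got = [(c.query_id, c.klass, c.reason) for c in calls]
            assert got == classifier_oracle(alns)


class TestGenomeFraction:
    def test_full_coverage(self):
        assert genome_fraction([_aln("q", 0, 1000, 0, 1000)], 1000) == 100.0

    def test_overlapping_intervals_union(self):
        alns = [_aln("q", 0, 600, 0, 600), _aln("q", 0, 600, 400, 1000)]
        assert genome_fraction(alns, 1000) == pytest.approx(100.0)

    def test_partial_coverage(self):
        assert genome_fraction([_aln("q", 0, 990, 0, 990)], 1000) == pytest.approx(99.0)

    def test_zero_reference_is_error(self):
        with pytest.raises(ValueError):
            genome_fraction([], 0)

    def test_matches_per_base_count_on_random_instances(self, rng):
        for _ in range(50):
            ref_len = int(rng.integers(100, 2000))
            alns = []
            covered = np.zeros(ref_len, dtype=bool)
            for _ in range(int(rng.integers(0, 8))):
                s = int(rng.integers(0, ref_len - 1))
                e = int(rng.integers(s + 1, ref_len + 1))
                alns.append(_aln("q", 0, e - s, s, e))
                covered[s:e] = True
            expected = 100.0 * covered.sum() / ref_len
            assert genome_fraction(alns, ref_len) == pytest.approx(expected)


class TestKmerMask:
    def test_unique_sequence_unmasked(self, rng):
        seq = random_dna(500, rng)
        index = build_kmer_index([seq])
        m = kmer_mask(seq, index, min_count=5)
        assert m.masked_fraction == 0.0

    def test_tandem_repeat_fully_masked(self, rng):
        unit = random_dna(50, rng)
        seq = unit * 30
        index = build_kmer_index([seq])
        m = kmer_mask(seq, index, min_count=10)
        assert m.masked_fraction == 1.0

    def test_single_abundant_kmer_masks_exactly_k_bases(self, rng):
        seq = random_dna(200, rng)
        kmer = seq[90:111]
        index = {canonical_kmer(kmer): 50}
        m = kmer_mask(seq, index, min_count=10)
        assert m.intervals == [(90, 111)]

    def test_reverse_complement_counted_as_same_kmer(self, rng):
        seq = random_dna(100, rng)
        index = build_kmer_index([seq, seq])
        assert kmer_mask(revcomp(seq), index, min_count=2).masked_fraction == 1.0

    def test_sequence_shorter_than_k(self):
        m = kmer_mask("ACGT", {}, k=21, min_count=1)
        assert m.intervals == [] and m.masked_fraction == 0.0

    def test_interval_invariants(self):
        with pytest.raises(ValueError):
            MaskedIntervals("s", 100, intervals=[(10, 5)])
        with pytest.raises(ValueError):
            MaskedIntervals("s", 100, intervals=[(0, 20), (10, 30)])


class TestRepeatOverlapFraction:
    def _mask(self):
        return MaskedIntervals("ref", 1000, intervals=[(100, 600)])

    def _cover(self, identity):
        a = _aln("w", 0, 500, 100, 600, identity=identity)
        return a

    def test_threshold_semantics(self):
        frac = repeat_overlap_fraction(self._mask(), [self._cover(0.85)],
                                       thresholds=(80, 99))
        assert frac[80] == pytest.approx(1.0)
        assert frac[99] == 0.0

    def test_no_alignments(self):
        frac = repeat_overlap_fraction(self._mask(), [])
        assert all(v == 0.0 for v in frac.values())

    def test_perfect_identity_everywhere(self):
        frac = repeat_overlap_fraction(self._mask(), [self._cover(1.0)])
        assert all(v == pytest.approx(1.0) for v in frac.values())

    def test_zero_masked_bases_reported_as_zero(self):
        m = MaskedIntervals("ref", 1000, intervals=[])
        assert repeat_overlap_fraction(m, [self._cover(1.0)])[80] == 0.0

    def test_monotone_non_increasing(self, rng):
        m = MaskedIntervals("ref", 5000, intervals=[(0, 2000), (3000, 4000)])
        alns = [self._cover(float(rng.uniform(0.8, 1.0))) for _ in range(10)]
        for a in alns:
            a.tstart = int(rng.integers(0, 4000))
            a.tend = a.tstart + 500
        frac = repeat_overlap_fraction(m, alns)
        values = [frac[t] for t in sorted(frac)]
        assert all(x >= y - 1e-12 for x, y in zip(values, values[1:]))


class TestMergeIntervals:
    def test_merges_overlaps_and_sorts(self):
        assert merge_intervals([(5, 10), (0, 6), (20, 30)]) == [(0, 10), (20, 30)]

    @given(hst.lists(hst.tuples(hst.integers(0, 500), hst.integers(1, 200)),
                     max_size=20))
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_union_matches_per_base_marking(self, raw):
        intervals = [(s, s + l) for s, l in raw]
        merged = merge_intervals(intervals)
        marked = np.zeros(800, dtype=bool)
        for s, e in intervals:
            marked[s:e] = True
        assert sum(e - s for s, e in merged) == int(marked.sum())
        assert all(e1 < s2 for (_, e1), (s2, _) in zip(merged, merged[1:]))
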