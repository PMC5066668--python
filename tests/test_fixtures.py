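"""The synthetic-data generator: determinism, truth bookkeeping, self-checks."""

import numpy as np
import pytest

from bacplex.evaluate import classify_misassemblies
from bacplex.fixtures import (
    InducedEvent,
    SimulationConfig,
    copy_mutation_rate,
    fragment_assembly,
    make_reference_set,
    simulate_matepairs,
    simulate_pe_reads,
)
from bacplex.pipeline import segment_align
from bacplex.seqio_core import SequenceRecord, revcomp

SMALL = dict(genome_len=300_000, n_bacs=2, insert_len_mean=30_000)


class TestReferenceSet:
    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=42, **SMALL)
        a = make_reference_set(cfg)
        b = make_reference_set(cfg)
        assert a.genome.bases == b.genome.bases
        assert a.vector.bases == b.vector.bases
        assert [i.bases for i in a.bac_inserts] == [i.bases for i in b.bac_inserts]

    def test_no_bacs_empty_insert_list(self):
        cfg = SimulationConfig(seed=1, genome_len=100_000, n_bacs=0,
                               insert_len_mean=10_000)
        assert make_reference_set(cfg).bac_inserts == []

    def test_inserts_are_genome_substrings_at_recorded_positions(self):
        cfg = SimulationConfig(seed=2, **SMALL)
        ref = make_reference_set(cfg)
        for rec, (s, e) in zip(ref.bac_inserts, ref.insert_positions):
            assert rec.bases == ref.genome.bases[s:e]

    def test_planted_repeat_pairwise_identity(self):
        """Copies planted at 90% pairwise identity measure 90% +- 1%."""
        cfg = SimulationConfig(seed=3, genome_len=400_000, n_bacs=4,
                               insert_len_mean=30_000,
                               repeat_identity_insert=0.90)
        ref = make_reference_set(cfg)
        copies = [ref.genome.bases[s:e]
                  for s, e, fam in ref.repeat_annotations if fam == "rep1"]
        assert len(copies) == 4
        idents = []
        for i in range(len(copies)):
            for j in range(i + 1, len(copies)):
                match = sum(a == b for a, b in zip(copies[i], copies[j]))
                idents.append(match / len(copies[i]))
        assert np.mean(idents) == pytest.approx(0.90, abs=0.01)

    def test_mutation_rate_solver(self):
        for target in (0.85, 0.95, 0.999):
            r = copy_mutation_rate(target)
            assert (1 - r) ** 2 + r ** 2 / 3 == pytest.approx(target)


class TestSimulatePeReads:
    def test_error_free_reads_are_exact_substrings(self):
        cfg = SimulationConfig(seed=4, error_rate=0.0, contamination_rate=0.0,
                               lowq_tail_frac=0.0, **SMALL)
        rng = np.random.default_rng(cfg.seed)
        ref = make_reference_set(cfg, rng)
        pairs, truths = simulate_pe_reads(0, ref, cfg, 200, rng)
        sources = {"insert": ref.bac_inserts[0].bases,
                   "vector_near": ref.vector.bases,
                   "vector_far": ref.vector.bases,
                   "host": ref.host_decoy.bases}
        for p, t in zip(pairs, truths):
            src = sources[t.source]
            frag = src[t.start:t.start + t.insert_size]
            assert p.read1.bases == frag[:100]
            assert p.read2.bases == revcomp(frag[-100:])

    def test_contamination_fraction_recovered(self):
        cfg = SimulationConfig(seed=5, contamination_rate=0.05, **SMALL)
        rng = np.random.default_rng(cfg.seed)
        ref = make_reference_set(cfg, rng)
        contam = [(ref.bac_inserts[1].bases[:10_000], 1)]
        _, truths = simulate_pe_reads(0, ref, cfg, 10_000, rng,
                                      contam_source=contam)
        frac = sum(t.source == "cross" for t in truths) / len(truths)
        assert frac == pytest.approx(0.05, abs=0.01)

    def test_insert_size_mean_matches_configuration(self):
        cfg = SimulationConfig(seed=6, **SMALL)
        rng = np.random.default_rng(cfg.seed)
        ref = make_reference_set(cfg, rng)
        _, truths = simulate_pe_reads(0, ref, cfg, 10_000, rng)
        spans = [t.insert_size for t in truths if t.source == "insert"]
        assert np.mean(spans) == pytest.approx(500, abs=2)

    def test_vector_near_reads_fall_in_window(self):
        cfg = SimulationConfig(seed=7, vector_read_frac=0.5, **SMALL)
        rng = np.random.default_rng(cfg.seed)
        ref = make_reference_set(cfg, rng)
        _, truths = simulate_pe_reads(0, ref, cfg, 500, rng)
        for t in truths:
            if t.source == "vector_near":
                assert t.start + t.insert_size >= ref.cloning_site - 2000
                assert t.start <= ref.cloning_site + 2000


class TestSimulateMatepairs:
    def test_no_readthrough_means_no_adapter(self):
        cfg = SimulationConfig(seed=8, adapter_readthrough_frac=0.0, **SMALL)
        rng = np.random.default_rng(cfg.seed)
        ref = make_reference_set(cfg, rng)
        pairs, truths = simulate_matepairs(ref.bac_inserts, cfg, 300, rng)
        adapter = cfg.junction_adapter
        for p, t in zip(pairs, truths):
            assert not t.adapter_in_read1 and not t.adapter_in_read2
            assert adapter not in p.read1.bases
            assert adapter not in p.read2.bases

    def test_duplicate_injection_marked_in_truth(self):
        cfg = SimulationConfig(seed=9, dup_rate=0.2, **SMALL)
        rng = np.random.default_rng(cfg.seed)
        ref = make_reference_set(cfg, rng)
        _, truths = simulate_matepairs(ref.bac_inserts, cfg, 10_000, rng)
        frac = sum(t.is_duplicate for t in truths) / len(truths)
        assert frac == pytest.approx(0.2, abs=0.01)

    def test_fragment_recorded_in_truth(self):
        cfg = SimulationConfig(seed=10, error_rate=0.0,
                               adapter_readthrough_frac=0.0, dup_rate=0.0, **SMALL)
        rng = np.random.default_rng(cfg.seed)
        ref = make_reference_set(cfg, rng)
        pairs, truths = simulate_matepairs(ref.bac_inserts, cfg, 100, rng)
        for p, t in zip(pairs, truths):
            insert = ref.bac_inserts[t.source_bac].bases
            frag = insert[t.start:t.start + t.insert_size]
            assert p.read1.bases == frag[:100]
            assert p.read2.bases == revcomp(frag[-100:])


class TestFragmentAssembly:
    def _insert(self, seed=11, n=30_000):
        rng = np.random.default_rng(seed)
        from bacplex.fixtures import random_dna
        return SequenceRecord("bac0_insert", random_dna(n, rng)), rng

    def test_single_fragment_no_events_equals_insert(self):
        insert, rng = self._insert()
        contigs, truths = fragment_assembly(insert, 1, rng)
        assert len(contigs) == 1 and contigs[0].bases == insert.bases
        assert truths[0].gap_after is None

    def test_fragments_reconstruct_insert_with_true_gaps(self):
        insert, rng = self._insert()
        contigs, truths = fragment_assembly(insert, 5, rng)
        assert len(contigs) == 5
        rebuilt = ""
        for c, t in zip(contigs, truths):
            assert c.bases == insert.bases[t.source_start:t.source_end]
            rebuilt += insert.bases[t.source_start:t.source_end]
            if t.gap_after is not None:
                rebuilt += insert.bases[t.source_end:t.source_end + t.gap_after]
        assert rebuilt == insert.bases

    def test_induced_inversion_detected_downstream(self):
        """Cross-module truth check: a planted inversion yields a
        global(strand) breakpoint when the contig is aligned back."""
        insert, rng = self._insert()
        contigs, truths = fragment_assembly(
            insert, 1, rng,
            induced_events=[InducedEvent("inversion", 0, 10_000, 2000)])
        alns = segment_align(SequenceRecord("c", contigs[0].bases), insert)
        calls, summary = classify_misassemblies(alns)
        assert any(c.klass == "global" and c.reason == "strand" for c in calls)

    def test_induced_relocation_shifts_flanks(self):
        insert, rng = self._insert()
        contigs, _ = fragment_assembly(
            insert, 1, rng,
            induced_events=[InducedEvent("relocation", 0, 10_000, 3000)])
        assert len(contigs[0].bases) == len(insert.bases) - 3000
        alns = segment_align(SequenceRecord("c", contigs[0].bases), insert)
        calls, _ = classify_misassemblies(alns)
        assert any(c.klass == "global" and c.reason == "distance" for c in calls)

    def test_overlap_event_duplicates_sequence(self):
        insert, rng = self._insert()
        contigs, _ = fragment_assembly(
            insert, 1, rng,
            induced_events=[InducedEvent("overlap", 0, 10_000, 1500)])
        assert len(contigs[0].bases) == len(insert.bases) + 1500
        alns = segment_align(SequenceRecord("c", contigs[0].bases), insert)
        calls, _ = classify_misassemblies(alns)
        assert any(c.klass == "global" and c.reason == "overlap" for c in calls)

    def test_overlapping_event_definitions_rejected(self):
        insert, rng = self._insert()
        with pytest.raises(ValueError, match="overlapping"):
            fragment_assembly(insert, 2, rng, induced_events=[
                InducedEvent("inversion", 0, 1000, 2000),
                InducedEvent("relocation", 0, 2500, 1000)])

    def test_out_of_range_event_rejected(self):
        insert, rng = self._insert()
        with pytest.raises(ValueError):
            fragment_assembly(insert, 2, rng, induced_events=[
                InducedEvent("inversion", 5, 0, 100)])
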