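"""End-to-end orchestration on synthetic multiplex BAC data.

Builds a complete study-shaped dataset (reference set, fabricated draft
contigs with vector ends, cross-contamination and phage spike-in contigs,
paired-end and two mate-pair libraries) and runs the full pipeline over it:
read QC -> contig post-processing -> mate-pair prep -> insert estimation ->
iterative scaffolding -> evaluation (misassemblies, genome fraction, k-mer
masking, repeat-overlap curve). Every stage calls the same library functions
the CLI exposes; this module only wires them together and collects metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import evaluate, read_qc
from .contig_post import CoverageFilterParams, PostprocessResult, postprocess_assembly
from .deconvolve import LibraryStats, estimate_insert
from .fixtures import (
    ContigTruth,
    InducedEvent,
    ReadTruth,
    ReferenceSet,
    SimulationConfig,
    fragment_assembly,
    make_reference_set,
    mutate,
    random_dna,
    simulate_matepairs,
    simulate_pe_reads,
)
from .matepair_prep import MatePrepReport, prep_matepairs
from .scaffolder import ScaffoldLayout, iterative_scaffold
from .seqio_core import (
    Alignment,
    AssemblyStats,
    BacAssembly,
    Contig,
    ReadPair,
    SequenceRecord,
    TargetIndex,
    assembly_stats,
    map_reads,
)

# ---------------------------------------------------------------------------
# Tile-based alignment helpers (vector/contaminant detection, reference eval)
# ---------------------------------------------------------------------------


def tile_hits(query_seq: str, query_id: str, targets: Sequence[Contig | SequenceRecord],
              tile: int = 150, stride: int = 75,
              min_identity: float = 0.9) -> List[Alignment]:
    """Locate a long query on a contig set by mapping overlapping tiles and
    merging per-target hit intervals. Used to find vector or contaminant
    stretches on contigs; the merged hits carry identity 1.0 and the interval
    length as both matches and alignment length."""
    records = [t if isinstance(t, SequenceRecord) else SequenceRecord(t.id, t.bases)
               for t in targets]
    if not records:
        return []
    idx = TargetIndex(records)
    tiles = [SequenceRecord(f"{query_id}_t{p}", query_seq[p:p + tile])
             for p in range(0, max(len(query_seq) - tile, 0) + 1, stride)]
    tiles = [t for t in tiles if len(t) >= idx.seed_len]
    per_target: Dict[str, List[Tuple[int, int]]] = {}
    for a in map_reads(tiles, idx, min_identity=min_identity):
        per_target.setdefault(a.target_id, []).append((a.tstart, a.tend))
    out: List[Alignment] = []
    for tid in sorted(per_target):
        for s, e in evaluate.merge_intervals(per_target[tid]):
            out.append(Alignment(
                query_id=query_id, target_id=tid, qstart=0, qend=e - s,
                tstart=s, tend=e, strand="+", matches=e - s, aln_len=e - s,
                identity=1.0, mapq=60, score=float(e - s)))
    return out


def segment_align(query: SequenceRecord, reference: SequenceRecord,
                  tile: int = 300, stride: int = 100,
                  min_identity: float = 0.85) -> List[Alignment]:
    """Split a query into tiles, map each to the reference and chain tiles
    that share a strand and diagonal into segment alignments.

    This is the internal stand-in for a genome-to-genome aligner: structural
    differences (inversions, relocations, scaffold gaps) break the chain, so
    the resulting segments are exactly the flanks the misassembly classifier
    reasons about.
    """
    idx = TargetIndex([reference])
    n = len(query.bases)
    tiles = []
    starts = list(range(0, max(n - tile, 0) + 1, stride))
    if starts and starts[-1] + tile < n:
        starts.append(n - tile)
    for p in starts:
        tiles.append((p, SequenceRecord(f"{query.id}__{p}", query.bases[p:p + tile])))
    placed = []  # (qstart, strand, diag, tstart, tend, matches)
    for p, t in tiles:
        if len(t) < idx.seed_len:
            continue
        hits = map_reads([t], idx, min_identity=min_identity)
        if not hits:
            continue
        a = max(hits, key=lambda h: h.score)
        diag = (a.tstart - (p + a.qstart)) if a.strand == "+" else (a.tend + (p + a.qstart))
        placed.append((p + a.qstart, p + a.qend, a.strand, diag,
                       a.tstart, a.tend, a.matches))
    segments: List[Alignment] = []
    cur: Optional[List] = None
    for qs, qe, strand, diag, ts, te, m in sorted(placed):
        if cur is not None and strand == cur[2] and diag == cur[3] and qs <= cur[1] + stride:
            cur[1] = max(cur[1], qe)
            cur[4] = min(cur[4], ts)
            cur[5] = max(cur[5], te)
        else:
            if cur is not None:
                segments.append(_segment_to_alignment(query, reference, cur))
            cur = [qs, qe, strand, diag, ts, te, m]
    if cur is not None:
        segments.append(_segment_to_alignment(query, reference, cur))
    return segments


def _segment_to_alignment(query: SequenceRecord, reference: SequenceRecord,
                          seg: List) -> Alignment:
    from .seqio_core import revcomp

    qs, qe, strand, _diag, ts, te, _m = seg
    span = qe - qs
    qseg = query.bases[qs:qe]
    tseg = reference.bases[ts:te]
    if strand == "-":
        qseg = revcomp(qseg)
    matches = sum(a == b for a, b in zip(qseg, tseg))
    return Alignment(query_id=query.id, target_id=reference.id,
                     qstart=qs, qend=qe, tstart=ts, tend=te, strand=strand,
                     matches=matches, aln_len=span,
                     identity=matches / span, mapq=60, score=float(matches))


# ---------------------------------------------------------------------------
# Dataset construction
# ---------------------------------------------------------------------------


@dataclass
class MpLibrary:
    tag: str
    pairs: List[ReadPair]
    truths: List[ReadTruth]
    k_min: int
    read_len: int
    sim_insert_mean: float


@dataclass
class PipelineDataset:
    """A full synthetic study with ground truth for every artifact."""

    config: SimulationConfig
    reference: ReferenceSet
    raw_assemblies: List[BacAssembly]
    contig_truths: Dict[str, List[ContigTruth]]
    pe_pairs: Dict[str, List[ReadPair]]
    pe_truths: Dict[str, List[ReadTruth]]
    mp_libraries: List[MpLibrary]
    phage: SequenceRecord
    wgs_contigs: List[SequenceRecord]
    vector_flank: int

    def true_contig_ids(self, bac_id: str) -> List[str]:
        return [t.contig_id for t in self.contig_truths[bac_id] if not t.is_contaminant]


def default_study_config(seed: int = 7) -> SimulationConfig:
    """The desk-scale study conditions: 8 BACs from a 2 Mb genome, genomic
    inserts scaled down proportionally to 20 kb, two mate-pair libraries."""
    return SimulationConfig(seed=seed, insert_len_mean=20_000)


def make_pipeline_dataset(config: Optional[SimulationConfig] = None,
                          seed: int = 7,
                          pe_pairs_per_bac: int = 600,
                          mp_pairs_per_library: int = 2400,
                          n_fragments: int = 3) -> PipelineDataset:
    """Build the synthetic study the end-to-end pipeline consumes.

    Per BAC: ``n_fragments`` true draft contigs with vector sequence attached
    at the two outermost ends, two contamination-only contigs copied from a
    neighbouring BAC's insert (the regions its cross-contaminating reads are
    drawn from, at well below native depth), and for two BACs a phage spike-in
    contig that attracts no reads at all. Three BACs carry planted
    misassemblies: a 1 kb inversion, a 500 bp relocation (local class) and a
    3 kb relocation (global class), all mid-contig so true adjacencies stay
    link-supported. Mate pairs are pooled across BACs, MiSeq-style (2 x 250,
    ~5.5 kb) and HiSeq-style (2 x 100, ~6.2 kb).
    """
    config = config if config is not None else default_study_config(seed)
    rng = np.random.default_rng(config.seed)
    reference = make_reference_set(config, rng)
    L = config.insert_len_mean
    site = config.cloning_site
    vec = reference.vector.bases
    flank = 400

    event_plan: Dict[int, List[InducedEvent]] = {}
    if config.n_bacs > 3:
        mid = 1 if n_fragments > 1 else 0
        frag_len = L // n_fragments
        event_plan = {
            1: [InducedEvent("inversion", mid, frag_len // 2 - 500, 1000)],
            2: [InducedEvent("relocation", mid, frag_len // 2 - 250, 500)],
            3: [InducedEvent("relocation", mid, frag_len // 2 - 1500, 3000)],
        }

    phage = SequenceRecord("phage", random_dna(3000, rng))
    assemblies: List[BacAssembly] = []
    contig_truths: Dict[str, List[ContigTruth]] = {}
    contam_regions: Dict[int, List[Tuple[str, int]]] = {}
    for i in range(config.n_bacs):
        bac_id = f"bac{i}"
        insert = reference.bac_inserts[i]
        contigs, truths = fragment_assembly(
            insert, n_fragments, rng, bac_index=i,
            induced_events=event_plan.get(i, ()))
        # vector backbone flanks the insert around the cloning site
        first, last = contigs[0], contigs[-1]
        contigs[0] = Contig(first.id, vec[site - flank:site] + first.bases,
                            bac_id=bac_id)
        contigs[-1] = Contig(last.id, contigs[-1].bases + vec[site:site + flank],
                             bac_id=bac_id)
        # contamination-only contigs: neighbour-insert regions around (not
        # including) the neighbour's central repeat copy
        nb = (i + 1) % config.n_bacs
        nb_seq = reference.bac_inserts[nb].bases
        reg_a = nb_seq[: int(0.45 * L) - config.repeat_copy_len // 2]
        reg_b = nb_seq[int(0.55 * L) + config.repeat_copy_len // 2:]
        contam_regions[i] = [(reg_a, nb), (reg_b, nb)]
        for suffix, reg in (("xcA", reg_a), ("xcB", reg_b)):
            cid = f"{bac_id}_{suffix}"
            contigs.append(Contig(cid, reg, bac_id=bac_id))
            truths.append(ContigTruth(cid, i, 0, len(reg), is_contaminant=True))
        if i in (0, config.n_bacs // 2):
            cid = f"{bac_id}_phiX"
            contigs.append(Contig(cid, phage.bases[100:1600], bac_id=bac_id))
            truths.append(ContigTruth(cid, i, 0, 1500, is_contaminant=True))
        assemblies.append(BacAssembly(bac_id, contigs, stage="raw"))
        contig_truths[bac_id] = truths

    pe_pairs: Dict[str, List[ReadPair]] = {}
    pe_truths: Dict[str, List[ReadTruth]] = {}
    for i in range(config.n_bacs):
        pairs, truths_r = simulate_pe_reads(
            i, reference, config, pe_pairs_per_bac, rng,
            contam_source=contam_regions[i])
        pe_pairs[f"bac{i}"] = pairs
        pe_truths[f"bac{i}"] = truths_r

    mp_libraries: List[MpLibrary] = []
    lib_specs = [
        ("mp_miseq", 250, config.mp_insert_mean, config.mp_insert_sd, 10),
        ("mp_hiseq", 100, config.mp_insert_mean + 700,
         (config.mp_insert_mean + 700) * 0.05, 20),
    ]
    for tag, rl, mean, sd, k_min in lib_specs:
        lib_cfg = replace(config, mp_insert_mean=mean, mp_insert_sd=sd)
        pairs, truths_m = simulate_matepairs(
            reference.bac_inserts, lib_cfg, mp_pairs_per_library, rng,
            library_tag=tag, read_len=rl)
        mp_libraries.append(MpLibrary(tag, pairs, truths_m, k_min, rl, mean))

    wgs_identities = [0.999, 0.97, 0.92, 0.85]
    wgs_contigs: List[SequenceRecord] = []
    for i in range(config.n_bacs):
        lo = int(0.5 * L) - config.repeat_copy_len // 2 - 250
        hi = int(0.5 * L) + config.repeat_copy_len // 2 + 250
        region = reference.bac_inserts[i].bases[lo:hi]
        ident = wgs_identities[i % len(wgs_identities)]
        wgs_contigs.append(SequenceRecord(
            f"wgs_rep{i}", mutate(region, 1.0 - ident, rng)))

    return PipelineDataset(
        config=config, reference=reference, raw_assemblies=assemblies,
        contig_truths=contig_truths, pe_pairs=pe_pairs, pe_truths=pe_truths,
        mp_libraries=mp_libraries, phage=phage, wgs_contigs=wgs_contigs,
        vector_flank=flank)


# ---------------------------------------------------------------------------
# End-to-end run
# ---------------------------------------------------------------------------


@dataclass
class BacEvaluation:
    bac_id: str
    n_global: int = 0
    n_local: int = 0
    global_reasons: List[str] = field(default_factory=list)
    genome_fraction: float = 0.0


@dataclass
class PipelineResult:
    dataset: PipelineDataset
    qc_counts: Dict[str, Dict[str, int]]
    post: Dict[str, PostprocessResult]
    mp_reports: Dict[str, MatePrepReport]
    lib_stats: Dict[str, LibraryStats]
    scaffolded: List[BacAssembly]
    layouts: List[ScaffoldLayout]
    evaluations: Dict[str, BacEvaluation]
    stats_before: Dict[str, AssemblyStats]
    stats_after: Dict[str, AssemblyStats]
    masked_fraction: float = 0.0
    overlap_curve: Dict[int, float] = field(default_factory=dict)

    def postprocessed(self) -> List[BacAssembly]:
        return [self.post[a.bac_id].assembly for a in self.dataset.raw_assemblies]


def run_pipeline(dataset: PipelineDataset,
                 params: CoverageFilterParams = CoverageFilterParams(),
                 ratio: float = 0.7,
                 kmer_min_count: int = 4,
                 kmer_k: int = 21,
                 run_repeat_analysis: bool = True) -> PipelineResult:
    """Run QC, post-processing, mate-pair scaffolding and evaluation."""
    cfg = dataset.config
    ref = dataset.reference

    # 1) paired-end read QC per BAC
    qc_counts: Dict[str, Dict[str, int]] = {}
    clean_pe: Dict[str, List[ReadPair]] = {}
    for asm in dataset.raw_assemblies:
        pairs = dataset.pe_pairs[asm.bac_id]
        clean, counts = read_qc.qc_pipeline(
            pairs, ref.vector, ref.host_decoy, ref.cloning_site)
        clean_pe[asm.bac_id] = clean
        qc_counts[asm.bac_id] = counts

    # 2) contig post-processing per BAC
    post: Dict[str, PostprocessResult] = {}
    for asm in dataset.raw_assemblies:
        vec_hits = tile_hits(ref.vector.bases, "vector", asm.contigs)
        contam_hits = tile_hits(dataset.phage.bases, "phage", asm.contigs)
        reads = [r for p in clean_pe[asm.bac_id] for r in (p.read1, p.read2)]
        post[asm.bac_id] = postprocess_assembly(
            asm, reads, vec_hits, contam_hits, params=params)
    post_assemblies = [post[a.bac_id].assembly for a in dataset.raw_assemblies]
    stats_before = {a.bac_id: assembly_stats(a.contigs) for a in post_assemblies}

    # 3) mate-pair prep, insert estimation, iterative scaffolding
    mp_reports: Dict[str, MatePrepReport] = {}
    lib_stats: Dict[str, LibraryStats] = {}
    libraries = []
    all_contigs = [SequenceRecord(c.id, c.bases)
                   for a in post_assemblies for c in a.contigs]
    idx = TargetIndex(all_contigs)
    for lib in dataset.mp_libraries:
        clean, report = prep_matepairs(lib.pairs, cfg.junction_adapter)
        mp_reports[lib.tag] = report
        reads = [r for p in clean for r in (p.read1, p.read2)
                 if len(r) >= idx.seed_len]
        alns = map_reads(reads, idx)
        stats = estimate_insert(clean, alns, library_tag=lib.tag)
        lib_stats[lib.tag] = stats
        libraries.append((clean, stats, lib.k_min))
    scaffolded, layouts = iterative_scaffold(post_assemblies, libraries, ratio=ratio)
    stats_after = {a.bac_id: assembly_stats(a.contigs) for a in scaffolded}

    # 4) evaluation against the true inserts
    evaluations: Dict[str, BacEvaluation] = {}
    for i, asm in enumerate(scaffolded):
        insert = ref.bac_inserts[i]
        alns: List[Alignment] = []
        for c in asm.contigs:
            alns.extend(segment_align(SequenceRecord(c.id, c.bases), insert))
        calls, summary = evaluate.classify_misassemblies(alns)
        gf = evaluate.genome_fraction(alns, len(insert.bases))
        evaluations[asm.bac_id] = BacEvaluation(
            bac_id=asm.bac_id,
            n_global=summary["n_global"], n_local=summary["n_local"],
            global_reasons=[c.reason for c in calls if c.klass == "global"],
            genome_fraction=gf)

    # 5) repeat masking and identity-stratified WGS overlap
    masked_fraction = 0.0
    overlap_curve: Dict[int, float] = {}
    if run_repeat_analysis:
        kidx = evaluate.build_kmer_index([ref.kmer_index_source], k=kmer_k)
        total_len = 0
        total_masked = 0
        covered: Dict[int, int] = {t: 0 for t in range(80, 100)}
        for asm in scaffolded:
            for c in asm.contigs:
                masked = evaluate.kmer_mask(c.bases, kidx, k=kmer_k,
                                            min_count=kmer_min_count, seq_id=c.id)
                total_len += len(c.bases)
                total_masked += masked.masked_bases
                if masked.masked_bases == 0:
                    continue
                walns: List[Alignment] = []
                for w in dataset.wgs_contigs:
                    for a in segment_align(w, SequenceRecord(c.id, c.bases),
                                           min_identity=0.75):
                        walns.append(a)
                frac = evaluate.repeat_overlap_fraction(masked, walns)
                for t, f in frac.items():
                    covered[t] += int(round(f * masked.masked_bases))
        masked_fraction = total_masked / total_len if total_len else 0.0
        overlap_curve = {
            t: (covered[t] / total_masked if total_masked else 0.0)
            for t in sorted(covered)}

    return PipelineResult(
        dataset=dataset, qc_counts=qc_counts, post=post,
        mp_reports=mp_reports, lib_stats=lib_stats,
        scaffolded=scaffolded, layouts=layouts, evaluations=evaluations,
        stats_before=stats_before, stats_after=stats_after,
        masked_fraction=masked_fraction, overlap_curve=overlap_curve)


# ---------------------------------------------------------------------------
# Truth-conditioned audits used by tests and the acceptance report
# ---------------------------------------------------------------------------


def spanning_pair_support(dataset: PipelineDataset, lib: MpLibrary,
                          bac_index: int) -> List[int]:
    """Per true adjacency, the number of library pairs whose fragment places
    one full mate on each neighbouring contig (from truth, not mapping)."""
    truths = [t for t in dataset.contig_truths[f"bac{bac_index}"]
              if not t.is_contaminant]
    rl = lib.read_len
    support = [0] * (len(truths) - 1)
    for t in lib.truths:
        if t.source_bac != bac_index or t.is_duplicate:
            continue
        r1_end = t.start + rl
        r2_start = t.start + t.insert_size - rl
        for j in range(len(truths) - 1):
            left, right = truths[j], truths[j + 1]
            if t.start >= left.source_start and r1_end <= left.source_end \
                    and r2_start >= right.source_start \
                    and t.start + t.insert_size <= right.source_end:
                support[j] += 1
    return support
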