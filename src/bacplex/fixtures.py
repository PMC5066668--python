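"""Deterministic synthetic BAC sequencing data with full ground truth.

The generator emulates the substrate of a multiplex BAC sequencing study:
a genome with planted repeat families and unique regions, a cloning vector
with a known cloning site, an E. coli-like host decoy, BAC inserts sampled
from the genome, fragmented draft "contigs" with recorded true adjacencies
(standing in for an external assembler), paired-end reads with vector/host
carryover and cross-contamination, and Nextera-style mate pairs with junction
adapters and injected duplicates. Every read and contig carries a truth
record, so pipeline properties are audited against known provenance rather
than re-inference. All sampling flows through one numpy Generator: the same
seed reproduces every byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .seqio_core import Contig, ReadPair, SequenceRecord, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Nextera transposase junction sequence
NEXTERA_JUNCTION = "CTGTCTCTTATACACATCT"


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic data.

    Insert-size and read-length defaults mirror the sequencing design the
    pipeline targets: 500 bp paired-end inserts read as 2 x 100 cycles,
    ~5.5 kb mate-pair fragments, 145 kb genomic inserts in a ~7.5 kb vector.
    ``insert_len_mean`` may be scaled down proportionally for desk-scale runs.
    """

    seed: int = 7
    genome_len: int = 2_000_000
    n_bacs: int = 8
    insert_len_mean: int = 145_000
    vector_len: int = 7_500
    cloning_site: int = 3_750
    host_len: int = 20_000
    pe_insert_mean: float = 500.0
    pe_insert_sd: float = 50.0
    mp_insert_mean: float = 5_500.0
    mp_insert_sd: float = 275.0
    read_len_pe: int = 100
    read_len_mp: int = 100
    error_rate: float = 0.001
    dup_rate: float = 0.05
    contamination_rate: float = 0.05
    vector_read_frac: float = 0.03
    host_read_frac: float = 0.02
    lowq_tail_frac: float = 0.10
    adapter_readthrough_frac: float = 0.30
    junction_adapter: str = NEXTERA_JUNCTION
    repeat_copy_len: int = 2_000
    repeat_identity_insert: float = 0.99
    repeat_identity_tail: float = 0.95
    repeat_tail_copies: int = 4

    def __post_init__(self) -> None:
        for name in ("genome_len", "insert_len_mean", "vector_len", "host_len",
                     "read_len_pe", "read_len_mp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("error_rate", "dup_rate", "contamination_rate",
                     "vector_read_frac", "host_read_frac", "lowq_tail_frac",
                     "adapter_readthrough_frac"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.insert_len_mean > self.genome_len:
            raise ValueError("insert longer than genome")
        if not (0 <= self.cloning_site < self.vector_len):
            raise ValueError("cloning site outside vector")


@dataclass
class ReadTruth:
    """Provenance of one simulated read pair."""

    pair_id: str
    source: str  # insert | vector_near | vector_far | host | cross
    source_bac: Optional[int] = None
    start: int = 0
    insert_size: int = 0
    is_duplicate: bool = False
    adapter_in_read1: bool = False
    adapter_in_read2: bool = False


@dataclass
class ContigTruth:
    """Provenance of one fabricated contig."""

    contig_id: str
    bac_index: int
    source_start: int  # on the BAC insert, 0-based half-open
    source_end: int
    gap_after: Optional[int] = None  # true gap to the next contig, bp
    event: str = "none"  # none | inversion | relocation | overlap
    event_position: int = 0
    event_length: int = 0
    is_contaminant: bool = False


@dataclass
class ReferenceSet:
    genome: SequenceRecord
    vector: SequenceRecord
    host_decoy: SequenceRecord
    bac_inserts: List[SequenceRecord]
    insert_positions: List[Tuple[int, int]]
    repeat_annotations: List[Tuple[int, int, str]]
    cloning_site: int

    @property
    def kmer_index_source(self) -> str:
        """The sequence the repeat k-mer index is built from."""
        return self.genome.bases


# ---------------------------------------------------------------------------
# Low-level sequence sampling
# ---------------------------------------------------------------------------


def random_dna(n: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute bases independently at the given per-base rate."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def copy_mutation_rate(pairwise_identity: float) -> float:
    """Per-copy substitution rate from consensus that yields the requested
    expected pairwise identity between two independently mutated copies.

    Two copies mutated at rate r agree at a site with probability
    (1-r)^2 + r^2/3; solving that quadratic for r gives the rate.
    """
    if not (0 < pairwise_identity <= 1):
        raise ValueError("pairwise identity must be in (0, 1]")
    d = pairwise_identity
    # (4/3) r^2 - 2 r + (1 - d) = 0, smaller root
    disc = 4.0 - 4.0 * (4.0 / 3.0) * (1.0 - d)
    return (2.0 - disc ** 0.5) / (8.0 / 3.0)


def _normal_length(mean: float, sd: float, lo: int, hi: int,
                   rng: np.random.Generator, retries: int = 100) -> int:
    """A normal draw rejected outside [lo, hi]."""
    for _ in range(retries):
        x = int(round(rng.normal(mean, sd)))
        if lo <= x <= hi:
            return x
    raise ValueError(f"could not draw length in [{lo},{hi}] from N({mean},{sd})")


# ---------------------------------------------------------------------------
# Reference set
# ---------------------------------------------------------------------------


def make_reference_set(config: SimulationConfig,
                       rng: Optional[np.random.Generator] = None) -> ReferenceSet:
    """Genome with planted repeats, vector, host decoy and BAC inserts.

    Inserts occupy evenly spaced, non-overlapping slots in the first part of
    the genome; each carries one centred copy of repeat family ``rep1``
    (mutated to the configured identity), and extra ``rep2`` copies are
    planted in the genome tail beyond the insert slots so that unique regions
    remain unique. Deterministic under the seed.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    genome = bytearray(random_dna(config.genome_len, rng).encode())
    annotations: List[Tuple[int, int, str]] = []

    inserts: List[SequenceRecord] = []
    positions: List[Tuple[int, int]] = []
    if config.n_bacs > 0:
        slot = config.genome_len // (config.n_bacs + 1)
        if config.insert_len_mean > slot:
            raise ValueError("insert does not fit the per-BAC genome slot")
        rep1 = random_dna(config.repeat_copy_len, rng)
        for i in range(config.n_bacs):
            jitter = int(rng.integers(0, max(slot - config.insert_len_mean, 1)))
            start = i * slot + jitter
            end = start + config.insert_len_mean
            if config.repeat_copy_len < config.insert_len_mean // 2:
                mid = start + (config.insert_len_mean - config.repeat_copy_len) // 2
                copy = mutate(rep1, copy_mutation_rate(config.repeat_identity_insert), rng)
                genome[mid:mid + config.repeat_copy_len] = copy.encode()
                annotations.append((mid, mid + config.repeat_copy_len, "rep1"))
            positions.append((start, end))
        # tail repeats, outside every insert slot
        tail_start = config.n_bacs * slot
        rep2 = random_dna(config.repeat_copy_len, rng)
        span = config.genome_len - tail_start
        for j in range(config.repeat_tail_copies):
            pos = tail_start + (j * span) // max(config.repeat_tail_copies, 1)
            pos = min(pos, config.genome_len - config.repeat_copy_len)
            copy = mutate(rep2, copy_mutation_rate(config.repeat_identity_tail), rng)
            genome[pos:pos + config.repeat_copy_len] = copy.encode()
            annotations.append((pos, pos + config.repeat_copy_len, "rep2"))
        for i, (start, end) in enumerate(positions):
            inserts.append(SequenceRecord(
                id=f"bac{i}_insert", bases=genome[start:end].decode()))

    vector = SequenceRecord("vector", random_dna(config.vector_len, rng))
    host = SequenceRecord("host_decoy", random_dna(config.host_len, rng))
    return ReferenceSet(
        genome=SequenceRecord("genome", genome.decode()),
        vector=vector,
        host_decoy=host,
        bac_inserts=inserts,
        insert_positions=positions,
        repeat_annotations=annotations,
        cloning_site=config.cloning_site,
    )


# ---------------------------------------------------------------------------
# Paired-end reads
# ---------------------------------------------------------------------------


def _draw_pe_pair(source: str, pair_id: str, lib: str, insert_size: int, start: int,
                  read_len: int, error_rate: float, lowq_tail: bool,
                  rng: np.random.Generator) -> ReadPair:
    frag = source[start:start + insert_size]
    r1 = mutate(frag[:read_len], error_rate, rng)
    r2 = mutate(revcomp(frag[-read_len:]), error_rate, rng)
    q1 = [40] * read_len
    q2 = [40] * read_len
    if lowq_tail:
        q2[-15:] = [2] * 15
    return ReadPair(
        pair_id,
        SequenceRecord(f"{pair_id}/1", r1, q1),
        SequenceRecord(f"{pair_id}/2", r2, q2),
        library_tag=lib,
    )


def simulate_pe_reads(bac_index: int,
                      reference: ReferenceSet,
                      config: SimulationConfig,
                      n_pairs: int,
                      rng: np.random.Generator,
                      contam_source: Optional[Sequence[Tuple[str, int]]] = None,
                      ) -> Tuple[List[ReadPair], List[ReadTruth]]:
    """Inward paired-end reads of one BAC library.

    The mix contains insert reads, vector carryover (half within the 2 kb
    cloning-site window, half elsewhere on the backbone), host reads and
    cross-contamination drawn from ``contam_source`` — (sequence, source BAC
    index) tuples, typically regions of a neighbouring BAC's insert, chosen
    uniformly per contaminating pair.
    """
    insert = reference.bac_inserts[bac_index].bases
    vector = reference.vector.bases
    host = reference.host_decoy.bases
    site, window = reference.cloning_site, 2000
    rl = config.read_len_pe

    pairs: List[ReadPair] = []
    truths: List[ReadTruth] = []
    p_contam = config.contamination_rate if contam_source is not None else 0.0
    for i in range(n_pairs):
        pid = f"bac{bac_index}_pe{i}"
        u = rng.random()
        lowq = rng.random() < config.lowq_tail_frac
        size = _normal_length(config.pe_insert_mean, config.pe_insert_sd,
                              2 * rl, 10 ** 9, rng)
        if u < p_contam and contam_source is not None:
            seq, src_bac = contam_source[int(rng.integers(0, len(contam_source)))]
            size = min(size, len(seq))
            start = int(rng.integers(0, len(seq) - size + 1))
            pairs.append(_draw_pe_pair(seq, pid, "pe", size, start, rl,
                                       config.error_rate, lowq, rng))
            truths.append(ReadTruth(pid, "cross", src_bac, start, size))
            continue
        u -= p_contam
        if u < config.host_read_frac:
            size = min(size, len(host))
            start = int(rng.integers(0, len(host) - size + 1))
            pairs.append(_draw_pe_pair(host, pid, "pe", size, start, rl,
                                       config.error_rate, lowq, rng))
            truths.append(ReadTruth(pid, "host", None, start, size))
            continue
        u -= config.host_read_frac
        if u < config.vector_read_frac:
            near = rng.random() < 0.5
            if near:
                lo = max(site - window + 1, 0)
                hi = min(site + window, len(vector)) - size
                hi = max(hi, lo + 1)
            else:
                lo, hi = 0, max(site - window - size, 1)
            start = int(rng.integers(lo, hi))
            pairs.append(_draw_pe_pair(vector, pid, "pe", size, start, rl,
                                       config.error_rate, lowq, rng))
            label = "vector_near" if near else "vector_far"
            truths.append(ReadTruth(pid, label, None, start, size))
            continue
        start = int(rng.integers(0, len(insert) - size + 1))
        pairs.append(_draw_pe_pair(insert, pid, "pe", size, start, rl,
                                   config.error_rate, lowq, rng))
        truths.append(ReadTruth(pid, "insert", bac_index, start, size))
    return pairs, truths


# ---------------------------------------------------------------------------
# Mate pairs
# ---------------------------------------------------------------------------


def simulate_matepairs(bac_inserts: Sequence[SequenceRecord],
                       config: SimulationConfig,
                       n_pairs: int,
                       rng: np.random.Generator,
                       library_tag: str = "mp",
                       read_len: Optional[int] = None,
                       ) -> Tuple[List[ReadPair], List[ReadTruth]]:
    """Nextera-style mate pairs pooled over all BACs.

    A fragment of ~``mp_insert_mean`` bp is drawn from a uniformly chosen BAC
    insert; the two reads face inward across the fragment. With probability
    ``adapter_readthrough_frac`` a read crosses the circularization point: its
    tail is replaced by the junction adapter followed by distal-end filler,
    which correct clipping removes. Duplicate pairs are injected at
    ``dup_rate``; truth marks duplicates and adapter carriers.
    """
    rl = read_len if read_len is not None else config.read_len_mp
    adapter = config.junction_adapter
    pairs: List[ReadPair] = []
    truths: List[ReadTruth] = []
    originals: List[Tuple[ReadPair, ReadTruth]] = []
    for i in range(n_pairs):
        pid = f"{library_tag}{i}"
        if originals and rng.random() < config.dup_rate:
            src_pair, src_truth = originals[int(rng.integers(0, len(originals)))]
            dup = ReadPair(
                pid,
                SequenceRecord(f"{pid}/1", src_pair.read1.bases,
                               list(src_pair.read1.quals or []) or None),
                SequenceRecord(f"{pid}/2", src_pair.read2.bases,
                               list(src_pair.read2.quals or []) or None),
                library_tag,
            )
            pairs.append(dup)
            truths.append(ReadTruth(
                pid, src_truth.source, src_truth.source_bac, src_truth.start,
                src_truth.insert_size, is_duplicate=True,
                adapter_in_read1=src_truth.adapter_in_read1,
                adapter_in_read2=src_truth.adapter_in_read2))
            continue
        bac = int(rng.integers(0, len(bac_inserts)))
        insert = bac_inserts[bac].bases
        frag_len = _normal_length(config.mp_insert_mean, config.mp_insert_sd,
                                  2 * rl + 10, len(insert), rng)
        start = int(rng.integers(0, len(insert) - frag_len + 1))
        frag = insert[start:start + frag_len]
        r1 = frag[:rl]
        r2 = revcomp(frag[-rl:])
        ad1 = ad2 = False
        if rng.random() < config.adapter_readthrough_frac:
            keep = int(rng.integers(20, max(rl - len(adapter), 21)))
            filler = revcomp(frag[-(rl):])  # distal-end bases beyond the junction
            r1 = (r1[:keep] + adapter + filler)[:rl]
            ad1 = True
        if rng.random() < config.adapter_readthrough_frac:
            keep = int(rng.integers(20, max(rl - len(adapter), 21)))
            filler = frag[:rl]
            r2 = (r2[:keep] + adapter + filler)[:rl]
            ad2 = True
        r1 = mutate(r1, config.error_rate, rng)
        r2 = mutate(r2, config.error_rate, rng)
        pair = ReadPair(
            pid,
            SequenceRecord(f"{pid}/1", r1, [40] * len(r1)),
            SequenceRecord(f"{pid}/2", r2, [40] * len(r2)),
            library_tag,
        )
        truth = ReadTruth(pid, "insert", bac, start, frag_len,
                          adapter_in_read1=ad1, adapter_in_read2=ad2)
        pairs.append(pair)
        truths.append(truth)
        originals.append((pair, truth))
    return pairs, truths


# ---------------------------------------------------------------------------
# Fabricated draft contigs
# ---------------------------------------------------------------------------


@dataclass
class InducedEvent:
    """A misassembly planted into one fabricated contig."""

    kind: str  # inversion | relocation | overlap
    contig_index: int
    position: int  # within the contig
    length: int  # inverted block / relocation distance / overlap size

    def __post_init__(self) -> None:
        if self.kind not in ("inversion", "relocation", "overlap"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.position < 0 or self.length <= 0:
            raise ValueError("event coordinates must be positive")


def fragment_assembly(bac_insert: SequenceRecord,
                      n_fragments: int,
                      rng: np.random.Generator,
                      bac_index: int = 0,
                      induced_events: Sequence[InducedEvent] = (),
                      gap_range: Tuple[int, int] = (50, 200),
                      contig_prefix: str = "c",
                      ) -> Tuple[List[Contig], List[ContigTruth]]:
    """Cut an insert into draft contigs with recorded true gaps and events.

    Contigs are substrings of the insert separated by gaps drawn from
    ``gap_range``; their concatenation with the true gaps reconstructs the
    insert (up to planted events). An inversion reverse-complements an
    internal block; a relocation omits the ``length`` bases at ``position`` so
    the flanking sequences align that far apart on the reference; an overlap
    duplicates the ``length`` bases preceding ``position`` so the flanks
    overlap on the reference. Two events on one contig must not touch
    overlapping base ranges.
    """
    if n_fragments < 1:
        raise ValueError("need at least one fragment")
    by_contig: Dict[int, List[InducedEvent]] = {}
    for ev in induced_events:
        if not (0 <= ev.contig_index < n_fragments):
            raise ValueError(f"event contig index {ev.contig_index} out of range")
        for other in by_contig.get(ev.contig_index, []):
            if ev.position < other.position + other.length and \
                    other.position < ev.position + ev.length:
                raise ValueError("overlapping event definitions")
        by_contig.setdefault(ev.contig_index, []).append(ev)

    insert = bac_insert.bases
    gaps = [int(rng.integers(gap_range[0], gap_range[1] + 1))
            for _ in range(n_fragments - 1)]
    usable = len(insert) - sum(gaps)
    if usable < n_fragments:
        raise ValueError("insert too short for the requested fragmentation")
    base_len = usable // n_fragments

    contigs: List[Contig] = []
    truths: List[ContigTruth] = []
    pos = 0
    bac_id = f"bac{bac_index}"
    for j in range(n_fragments):
        length = base_len if j < n_fragments - 1 else usable - base_len * (n_fragments - 1)
        start, end = pos, pos + length
        seq = insert[start:end]
        events = sorted(by_contig.get(j, []), key=lambda e: e.position)
        ev_kind, ev_pos, ev_len = "none", 0, 0
        for ev in events:
            if ev.kind == "inversion":
                if ev.position + ev.length > len(seq):
                    raise ValueError("inversion block outside contig")
                seq = (seq[:ev.position]
                       + revcomp(seq[ev.position:ev.position + ev.length])
                       + seq[ev.position + ev.length:])
            elif ev.kind == "relocation":
                if ev.position + ev.length > len(seq):
                    raise ValueError("relocation block outside contig")
                seq = seq[:ev.position] + seq[ev.position + ev.length:]
            else:  # overlap
                if ev.position - ev.length < 0 or ev.position > len(seq):
                    raise ValueError("overlap block outside contig")
                seq = seq[:ev.position] + seq[ev.position - ev.length:]
            ev_kind, ev_pos, ev_len = ev.kind, ev.position, ev.length
        cid = f"{bac_id}_{contig_prefix}{j + 1}"
        contigs.append(Contig(id=cid, bases=seq, bac_id=bac_id))
        truths.append(ContigTruth(
            contig_id=cid, bac_index=bac_index,
            source_start=start, source_end=end,
            gap_after=gaps[j] if j < n_fragments - 1 else None,
            event=ev_kind, event_position=ev_pos, event_length=ev_len))
        pos = end + (gaps[j] if j < n_fragments - 1 else 0)
    return contigs, truths
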