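"""Domain types, sequence/alignment I/O, internal read mapper and assembly statistics.

All coordinates in this package are 0-based half-open. Strand ``-`` means the
query aligns reverse-complemented relative to the target. Mapping quality is
synthetic: 60 for a unique best hit, 0 for hits tied at the best score —
downstream filters only ever ask "unique or not" and "mapq >= 40".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SequenceRecord:
    """A named DNA sequence with optional Phred qualities (one per base)."""

    id: str
    bases: str
    quals: Optional[List[int]] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if self.quals is not None and len(self.quals) != len(self.bases):
            raise ValueError(
                f"record {self.id!r}: {len(self.quals)} quality scores "
                f"for {len(self.bases)} bases"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class ReadPair:
    """Two mates of one sequenced fragment, tagged with their library of origin."""

    pair_id: str
    read1: SequenceRecord
    read2: SequenceRecord
    library_tag: str = "pe"


@dataclass
class Alignment:
    """A coordinate-level hit of a query against a target.

    ``qstart``/``qend`` are on the query's forward strand regardless of
    ``strand``; ``aln_len`` counts aligned columns so it can exceed
    ``qend - qstart`` when indels are present.
    """

    query_id: str
    target_id: str
    qstart: int
    qend: int
    tstart: int
    tend: int
    strand: str
    matches: int
    aln_len: int
    identity: float
    mapq: int = 0
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not (0 <= self.qstart < self.qend):
            raise ValueError(f"bad query interval [{self.qstart},{self.qend})")
        if not (0 <= self.tstart < self.tend):
            raise ValueError(f"bad target interval [{self.tstart},{self.tend})")
        if self.aln_len < self.matches:
            raise ValueError("aln_len < matches")

    @property
    def qspan(self) -> int:
        return self.qend - self.qstart

    @property
    def tspan(self) -> int:
        return self.tend - self.tstart


@dataclass
class Contig:
    """A contig of one BAC assembly, with BAC-end flags set by vector clipping."""

    id: str
    bases: str
    bac_id: str = ""
    bac_end_left: bool = False
    bac_end_right: bool = False
    coverage: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise ValueError(f"contig {self.id!r} is empty")
        if self.coverage is not None and self.coverage < 0:
            raise ValueError("coverage must be non-negative")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class BacAssembly:
    """The contig set of a single BAC at a given pipeline stage."""

    bac_id: str
    contigs: List[Contig] = field(default_factory=list)
    stage: str = "raw"

    def __post_init__(self) -> None:
        ids = [c.id for c in self.contigs]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate contig ids in BAC {self.bac_id}")

    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)


@dataclass
class AssemblyStats:
    """Summary statistics of one sequence set (contigs or scaffolds)."""

    n_sequences: int
    total_len: int
    l50: int
    largest: int
    len_ge_1kb: int
    len_ge_10kb: int


# ---------------------------------------------------------------------------
# FASTA / FASTQ I/O
# ---------------------------------------------------------------------------


def load_sequences(path: str | Path, format: str = "fasta") -> List[SequenceRecord]:
    """Load FASTA or FASTQ (Phred+33) into :class:`SequenceRecord` objects.

    Record order is preserved; an empty file yields an empty list.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    records: List[SequenceRecord] = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), format)):
            quals = None
            if format == "fastq":
                quals = list(rec.letter_annotations["phred_quality"])
            records.append(SequenceRecord(id=rec.id, bases=str(rec.seq).upper(), quals=quals))
    except ValueError as exc:
        raise ValueError(f"malformed {format} record #{len(records)}: {exc}") from exc
    return records


def write_sequences(records: Iterable[SequenceRecord], path: str | Path,
                    format: str = "fasta") -> None:
    """Write records as FASTA or FASTQ (Phred+33)."""
    bio_records = []
    for rec in records:
        bio = _BioSeqRecord(Seq(rec.bases), id=rec.id, description="")
        if format == "fastq":
            if rec.quals is None:
                raise ValueError(f"record {rec.id!r} has no qualities for FASTQ output")
            bio.letter_annotations["phred_quality"] = rec.quals
        bio_records.append(bio)
    SeqIO.write(bio_records, str(path), format)


# ---------------------------------------------------------------------------
# SAM / PAF alignment input
# ---------------------------------------------------------------------------


def _sam_identity(aln: pysam.AlignedSegment) -> Tuple[int, int]:
    """(matches, aligned columns) from NM tag and CIGAR; assumes NM when present."""
    cols = 0
    qcols = 0
    for op, ln in aln.cigartuples or []:
        if op in (0, 7, 8):  # M, =, X
            cols += ln
            qcols += ln
        elif op == 1:  # I
            cols += ln
            qcols += ln
        elif op == 2:  # D
            cols += ln
    nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
    matches = max(qcols - nm, 0)
    return matches, max(cols, 1)


def load_alignments(path: str | Path, dialect: str = "paf") -> List[Alignment]:
    """Load external alignments from SAM (text) or PAF.

    Coordinates are normalized to 0-based half-open; unmapped records are
    skipped. A coordinate outside the stated target length is an error.
    """
    if dialect == "sam":
        return _load_sam(path)
    if dialect == "paf":
        return _load_paf(path)
    raise ValueError(f"unsupported alignment dialect {dialect!r}")


def _load_sam(path: str | Path) -> List[Alignment]:
    out: List[Alignment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        tlens = dict(zip(sam.references, sam.lengths))
        for aln in sam:
            if aln.is_unmapped or aln.query_name is None:
                continue
            tname = aln.reference_name
            tlen = tlens.get(tname, 0)
            if tlen and aln.reference_end is not None and aln.reference_end > tlen:
                raise ValueError(
                    f"SAM record {aln.query_name}: end {aln.reference_end} "
                    f"outside target {tname} (len {tlen})"
                )
            matches, cols = _sam_identity(aln)
            qstart = aln.query_alignment_start
            qend = aln.query_alignment_end
            qlen = aln.query_length or (qend - qstart)
            if aln.is_reverse:
                # report on the forward strand of the original read
                qstart, qend = qlen - qend, qlen - qstart
            out.append(Alignment(
                query_id=aln.query_name,
                target_id=tname,
                qstart=qstart, qend=qend,
                tstart=aln.reference_start, tend=aln.reference_end,
                strand="-" if aln.is_reverse else "+",
                matches=matches, aln_len=cols,
                identity=matches / cols,
                mapq=aln.mapping_quality,
                score=float(matches),
            ))
    return out


def _load_paf(path: str | Path) -> List[Alignment]:
    out: List[Alignment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"PAF line {lineno}: expected >=12 columns, got {len(f)}")
            tlen = int(f[6])
            tstart, tend = int(f[7]), int(f[8])
            if tend > tlen:
                raise ValueError(
                    f"PAF line {lineno} ({f[0]}): target end {tend} outside "
                    f"target {f[5]} (len {tlen})"
                )
            matches = int(f[9])
            cols = int(f[10])
            out.append(Alignment(
                query_id=f[0], target_id=f[5],
                qstart=int(f[2]), qend=int(f[3]),
                tstart=tstart, tend=tend,
                strand=f[4],
                matches=matches, aln_len=cols,
                identity=matches / cols if cols else 0.0,
                mapq=int(f[11]),
                score=float(matches),
            ))
    return out


def write_paf(alignments: Iterable[Alignment], path: str | Path,
              query_lengths: Mapping[str, int], target_lengths: Mapping[str, int]) -> None:
    """Write alignments as minimal 12-column PAF."""
    with open(path, "w") as fh:
        for a in alignments:
            fh.write("\t".join(map(str, [
                a.query_id, query_lengths[a.query_id], a.qstart, a.qend, a.strand,
                a.target_id, target_lengths[a.target_id], a.tstart, a.tend,
                a.matches, a.aln_len, a.mapq,
            ])) + "\n")


# ---------------------------------------------------------------------------
# Internal read mapper (seed-and-extend)
# ---------------------------------------------------------------------------


class TargetIndex:
    """Exact k-mer index over a target set, reusable across map_reads calls."""

    def __init__(self, targets: Sequence[SequenceRecord], seed_len: int = 21,
                 max_seed_hits: int = 500):
        self.seed_len = seed_len
        self.max_seed_hits = max_seed_hits
        self.targets = list(targets)
        self.index: Dict[str, List[Tuple[int, int]]] = {}
        for ti, t in enumerate(self.targets):
            seq = t.bases
            for pos in range(len(seq) - seed_len + 1):
                kmer = seq[pos:pos + seed_len]
                self.index.setdefault(kmer, []).append((ti, pos))


def _extend_on_diagonal(query: str, target: str, diag: int) -> Optional[Tuple[int, int, int]]:
    """Ungapped alignment of the whole query placed at target offset ``diag``.

    Returns (q_lo, q_hi, matches) for the window of the query that fits on the
    target, or None if the window is empty.
    """
    q_lo = max(0, -diag)
    q_hi = min(len(query), len(target) - diag)
    if q_hi - q_lo < 1:
        return None
    qseg = query[q_lo:q_hi]
    tseg = target[q_lo + diag:q_hi + diag]
    if qseg == tseg:
        return q_lo, q_hi, q_hi - q_lo
    matches = sum(a == b for a, b in zip(qseg, tseg))
    return q_lo, q_hi, matches


def map_reads(queries: Sequence[SequenceRecord],
              targets: Sequence[SequenceRecord] | TargetIndex,
              seed_len: int = 21, min_identity: float = 0.9) -> List[Alignment]:
    """Map reads to targets by exact-k-mer seeding and ungapped extension.

    Contract: an exact substring of exactly one target location yields one
    alignment with identity 1.0 and mapq 60; a query whose best score ties
    across two or more target locations gets mapq 0 on all tied hits; hits
    below ``min_identity`` are suppressed; score equals the match count.
    Substitutions are modeled, indels are not.
    """
    if isinstance(targets, TargetIndex):
        idx = targets
        if idx.seed_len != seed_len:
            raise ValueError("TargetIndex built with a different seed_len")
    else:
        if not targets:
            raise ValueError("no targets to map against")
        idx = TargetIndex(targets, seed_len=seed_len)

    out: List[Alignment] = []
    for q in queries:
        hits = _map_one(q, idx, seed_len, min_identity)
        out.extend(hits)
    return out


def _map_one(q: SequenceRecord, idx: TargetIndex, seed_len: int,
             min_identity: float) -> List[Alignment]:
    qlen = len(q.bases)
    if qlen < seed_len:
        return []
    candidates: List[Tuple[str, int, int, int, int, int]] = []
    seen: set = set()
    for strand, seq in (("+", q.bases), ("-", revcomp(q.bases))):
        # seed at a stride of seed_len plus the final k-mer: any exact stretch
        # of >= 2*seed_len-1 bases is guaranteed to contain a sampled seed
        positions = list(range(0, qlen - seed_len + 1, seed_len))
        if positions[-1] != qlen - seed_len:
            positions.append(qlen - seed_len)
        diags: set = set()
        for qpos in positions:
            for ti, tpos in idx.index.get(seq[qpos:qpos + seed_len], ())[:idx.max_seed_hits]:
                diags.add((ti, tpos - qpos))
        for ti, diag in diags:
            key = (strand, ti, diag)
            if key in seen:
                continue
            seen.add(key)
            ext = _extend_on_diagonal(seq, idx.targets[ti].bases, diag)
            if ext is None:
                continue
            lo, hi, matches = ext
            if matches / (hi - lo) < min_identity:
                continue
            candidates.append((strand, ti, diag, lo, hi, matches))
    if not candidates:
        return []

    best = max(c[5] for c in candidates)
    n_best = sum(1 for c in candidates if c[5] == best)
    out = []
    for strand, ti, diag, lo, hi, matches in candidates:
        target = idx.targets[ti]
        if strand == "+":
            qstart, qend = lo, hi
        else:
            qstart, qend = qlen - hi, qlen - lo
        out.append(Alignment(
            query_id=q.id, target_id=target.id,
            qstart=qstart, qend=qend,
            tstart=lo + diag, tend=hi + diag,
            strand=strand,
            matches=matches, aln_len=hi - lo,
            identity=matches / (hi - lo),
            mapq=60 if (matches == best and n_best == 1) else 0,
            score=float(matches),
        ))
    return out


def best_hit(alignments: Iterable[Alignment]) -> Dict[str, Alignment]:
    """Best alignment per query: maximal score, ties broken by lexicographic
    target id then smallest target start."""
    best: Dict[str, Alignment] = {}
    for a in alignments:
        cur = best.get(a.query_id)
        if cur is None:
            best[a.query_id] = a
            continue
        if (-a.score, a.target_id, a.tstart) < (-cur.score, cur.target_id, cur.tstart):
            best[a.query_id] = a
    return best


# ---------------------------------------------------------------------------
# Assembly statistics
# ---------------------------------------------------------------------------


def assembly_stats(sequences: Iterable[SequenceRecord | Contig | str | int]) -> AssemblyStats:
    """Summary statistics of a sequence set.

    L50 is the maximum length L such that sequences of length >= L together
    contain at least half the total assembly length. Accepts records, raw
    strings or plain lengths. An empty set reports zeros.
    """
    lengths = sorted(
        (s if isinstance(s, int) else len(s)) for s in sequences
    )
    n = len(lengths)
    total = sum(lengths)
    if n == 0:
        return AssemblyStats(0, 0, 0, 0, 0, 0)
    l50 = 0
    # scan candidates from largest down, accumulating the tail sum
    acc = 0
    for length in sorted(set(lengths), reverse=True):
        acc = sum(x for x in lengths if x >= length)
        if 2 * acc >= total:
            l50 = length
            break
    return AssemblyStats(
        n_sequences=n,
        total_len=total,
        l50=l50,
        largest=lengths[-1],
        len_ge_1kb=sum(x for x in lengths if x >= 1000),
        len_ge_10kb=sum(x for x in lengths if x >= 10000),
    )


def stats_table(assemblies: Iterable[BacAssembly]):
    """Per-BAC stats as a pandas DataFrame matching the report TSV layout."""
    import pandas as pd

    rows = []
    for asm in assemblies:
        st = assembly_stats(asm.contigs)
        rows.append({
            "bac_id": asm.bac_id, "stage": asm.stage,
            "n_sequences": st.n_sequences, "total_len": st.total_len,
            "l50": st.l50, "largest": st.largest,
            "len_ge_1kb": st.len_ge_1kb, "len_ge_10kb": st.len_ge_10kb,
        })
    return pd.DataFrame(rows)
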