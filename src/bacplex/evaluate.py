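"""Assembly evaluation: misassembly classification, genome fraction, repeat masking.

Misassembly breakpoints follow the Plantagora-style rules: every boundary
between consecutive alignments of one query is a breakpoint; flanks on
different reference strands, or separated by more than 1 kb, or overlapping by
more than 1 kb, are *global* misassemblies; flanks on the same strand within
1 kb are *local*. Genome fraction is the percentage of the reference covered
by the union of alignment intervals. Repeat masking flags every base covered
by a k-mer that is highly abundant in a reference k-mer index, and the
identity-stratified overlap curve asks what fraction of masked sequence is
matched by whole-genome-shotgun alignments at increasing identity thresholds.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .seqio_core import Alignment, revcomp


@dataclass
class BreakpointCall:
    query_id: str
    query_position: int
    klass: str  # global | local
    reason: str  # distance | overlap | strand

    def __post_init__(self) -> None:
        if self.reason == "strand" and self.klass != "global":
            raise ValueError("strand breakpoints are always global")


@dataclass
class MaskedIntervals:
    """Sorted, disjoint masked intervals of one sequence."""

    seq_id: str
    seq_len: int
    intervals: List[Tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = -1
        for s, e in self.intervals:
            if s >= e or s < prev_end:
                raise ValueError("intervals must be sorted and disjoint")
            prev_end = e

    @property
    def masked_bases(self) -> int:
        return sum(e - s for s, e in self.intervals)

    @property
    def masked_fraction(self) -> float:
        return self.masked_bases / self.seq_len if self.seq_len else 0.0


# ---------------------------------------------------------------------------
# Misassembly classification
# ---------------------------------------------------------------------------


def _flank_separation(left: Alignment, right: Alignment) -> int:
    """Signed reference-coordinate separation between consecutive flanks
    (positive = gap, negative = overlap), measured between the inner
    boundaries facing each other on the reference."""
    if left.strand == "+":
        return right.tstart - left.tend
    # on the minus strand, later query positions map to smaller ref coords
    return left.tstart - right.tend


def classify_breakpoint(left: Alignment, right: Alignment,
                        dist_thresh: int = 1000) -> Tuple[str, str]:
    """(class, reason) for the boundary between two consecutive alignments."""
    if left.strand != right.strand:
        return "global", "strand"
    sep = _flank_separation(left, right)
    if sep > dist_thresh:
        return "global", "distance"
    if -sep > dist_thresh:
        return "global", "overlap"
    return "local", "distance" if sep >= 0 else "overlap"


def classify_misassemblies(alignments: Iterable[Alignment],
                           min_aln: int = 100,
                           dist_thresh: int = 1000,
                           ) -> Tuple[List[BreakpointCall], Dict[str, int]]:
    """Classify every breakpoint of every query against the reference.

    Alignments shorter than ``min_aln`` query bases are ignored; the remaining
    alignments of each query are sorted by query start, and each boundary
    between consecutive alignments yields one call. Queries with a single
    alignment yield none.
    """
    per_query: Dict[str, List[Alignment]] = {}
    for a in alignments:
        if a.qspan >= min_aln:
            per_query.setdefault(a.query_id, []).append(a)
    calls: List[BreakpointCall] = []
    for qid in sorted(per_query):
        alns = sorted(per_query[qid], key=lambda a: (a.qstart, a.qend))
        for left, right in zip(alns, alns[1:]):
            klass, reason = classify_breakpoint(left, right, dist_thresh)
            calls.append(BreakpointCall(
                query_id=qid, query_position=left.qend, klass=klass, reason=reason))
    summary = {
        "n_global": sum(1 for c in calls if c.klass == "global"),
        "n_local": sum(1 for c in calls if c.klass == "local"),
    }
    return calls, summary


# ---------------------------------------------------------------------------
# Genome fraction
# ---------------------------------------------------------------------------


def merge_intervals(intervals: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Union of half-open intervals as a sorted disjoint list."""
    merged: List[Tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def genome_fraction(alignments: Iterable[Alignment], reference_length: int) -> float:
    """Percentage of the reference covered by at least one alignment."""
    if reference_length <= 0:
        raise ValueError("reference length must be positive")
    covered = sum(e - s for s, e in
                  merge_intervals((a.tstart, a.tend) for a in alignments))
    return 100.0 * covered / reference_length


# ---------------------------------------------------------------------------
# K-mer repeat masking
# ---------------------------------------------------------------------------


def canonical_kmer(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def build_kmer_index(sequences: Iterable[str], k: int = 21) -> Counter:
    """Canonical k-mer occurrence counts over a sequence set."""
    counts: Counter = Counter()
    for seq in sequences:
        for i in range(len(seq) - k + 1):
            counts[canonical_kmer(seq[i:i + k])] += 1
    return counts


def kmer_mask(sequence: str, kmer_index: Mapping[str, int],
              k: int = 21, min_count: int = 10,
              seq_id: str = "seq") -> MaskedIntervals:
    """Mask every base covered by a k-mer with index count >= min_count.

    Maximal masked runs are merged into intervals; a sequence shorter than k
    yields no intervals.
    """
    n = len(sequence)
    if n < k:
        return MaskedIntervals(seq_id=seq_id, seq_len=n, intervals=[])
    masked = bytearray(n)
    for i in range(n - k + 1):
        if kmer_index.get(canonical_kmer(sequence[i:i + k]), 0) >= min_count:
            for j in range(i, i + k):
                masked[j] = 1
    intervals: List[Tuple[int, int]] = []
    start: Optional[int] = None
    for i, m in enumerate(masked):
        if m and start is None:
            start = i
        elif not m and start is not None:
            intervals.append((start, i))
            start = None
    if start is not None:
        intervals.append((start, n))
    return MaskedIntervals(seq_id=seq_id, seq_len=n, intervals=intervals)


# ---------------------------------------------------------------------------
# Identity-stratified repeat overlap
# ---------------------------------------------------------------------------


def repeat_overlap_fraction(masked: MaskedIntervals,
                            alignments: Sequence[Alignment],
                            thresholds: Sequence[int] = tuple(range(80, 100)),
                            ) -> Dict[int, float]:
    """Fraction of masked bases covered by alignments of at least each
    identity threshold (percent). Non-increasing in the threshold; with zero
    masked bases every fraction is reported as 0."""
    total = masked.masked_bases
    out: Dict[int, float] = {}
    relevant = [a for a in alignments if a.target_id == masked.seq_id]
    for t in thresholds:
        if total == 0:
            out[t] = 0.0
            continue
        cover = merge_intervals(
            (a.tstart, a.tend) for a in relevant if a.identity >= t / 100.0)
        covered = 0
        ci = 0
        for ms, me in masked.intervals:
            for cs, ce in cover:
                lo, hi = max(ms, cs), min(me, ce)
                if lo < hi:
                    covered += hi - lo
        out[t] = covered / total
    return out


def write_bed(masked_sets: Iterable[MaskedIntervals], path) -> None:
    """Masked intervals as 3-column BED."""
    with open(path, "w") as fh:
        for m in masked_sets:
            for s, e in m.intervals:
                fh.write(f"{m.seq_id}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# Table-level bookkeeping helpers
# ---------------------------------------------------------------------------


def mean_reads_per_unit(total_reads: int, n_units: int) -> float:
    """Average read count per BAC from lane totals."""
    if n_units <= 0:
        raise ValueError("n_units must be positive")
    return total_reads / n_units


def mean_read_depth(reads_per_unit: float, read_len: int, insert_len: int) -> float:
    """Mean depth = reads per BAC x read length / genomic insert length."""
    if insert_len <= 0:
        raise ValueError("insert length must be positive")
    return reads_per_unit * read_len / insert_len


def removed_fraction(n_removed: int, n_total: int) -> float:
    """Percentage of items removed (e.g. low-coverage contigs)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * n_removed / n_total
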