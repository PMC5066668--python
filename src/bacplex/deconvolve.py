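"""Deconvolution of unbarcoded mate pairs onto individual BAC assemblies.

Mate-pair libraries are prepared from BAC pools without per-clone barcodes;
a pair is traced back to its clone by mapping both mates against the
concatenated set of per-BAC draft assemblies and requiring a unique best hit
for each mate on contigs of one and the same BAC. Insert-size statistics are
estimated from high-mapq pairs whose mates land on a single contig.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .seqio_core import Alignment, ReadPair


@dataclass
class LibraryStats:
    """Insert-size model of one mate-pair library (sd pinned at half the mean)."""

    library_tag: str
    insert_mean: float
    n_pairs_used: int = 0
    orientation: str = "inward"

    def __post_init__(self) -> None:
        if self.insert_mean <= 0:
            raise ValueError("insert_mean must be positive")

    @property
    def insert_sd(self) -> float:
        return 0.5 * self.insert_mean


@dataclass
class PairAssignment:
    pair_id: str
    bac_id: Optional[str]
    reason: str  # unique | ambiguous | cross_bac | unmapped

    def __post_init__(self) -> None:
        if (self.reason == "unique") != (self.bac_id is not None):
            raise ValueError("bac_id must be set iff reason is 'unique'")


def _mate_best(alignments: Sequence[Alignment]) -> Tuple[List[Alignment], int]:
    """Best-scoring alignments of one mate and the max mapq among them."""
    top = max(a.score for a in alignments)
    best = [a for a in alignments if a.score == top]
    return best, max(a.mapq for a in best)


def assign_pairs(pairs: Sequence[ReadPair],
                 alignments: Iterable[Alignment],
                 contig_to_bac: Mapping[str, str]) -> List[PairAssignment]:
    """Assign each pair to a BAC, or record why it could not be assigned.

    A pair is assigned to BAC ``b`` iff every best-scoring alignment of each
    mate lies on contigs of ``b`` and both mates are uniquely placed
    (mapq >= 1). Mates whose best hits disagree on the BAC are ``cross_bac``;
    a mate tied across locations is ``ambiguous``; a mate with no alignment is
    ``unmapped``.
    """
    by_query: Dict[str, List[Alignment]] = {}
    for a in alignments:
        if a.target_id not in contig_to_bac:
            raise KeyError(f"alignment target {a.target_id!r} missing from contig->BAC map")
        by_query.setdefault(a.query_id, []).append(a)

    out: List[PairAssignment] = []
    for pair in pairs:
        mates = [by_query.get(pair.read1.id), by_query.get(pair.read2.id)]
        if any(m is None for m in mates):
            out.append(PairAssignment(pair.pair_id, None, "unmapped"))
            continue
        bacs: List[str] = []
        ambiguous = False
        for alns in mates:
            best, top_mapq = _mate_best(alns)
            mate_bacs = {contig_to_bac[a.target_id] for a in best}
            if len(mate_bacs) > 1 or top_mapq < 1:
                ambiguous = True
                break
            bacs.append(next(iter(mate_bacs)))
        if ambiguous:
            out.append(PairAssignment(pair.pair_id, None, "ambiguous"))
        elif bacs[0] != bacs[1]:
            out.append(PairAssignment(pair.pair_id, None, "cross_bac"))
        else:
            out.append(PairAssignment(pair.pair_id, bacs[0], "unique"))
    return out


def estimate_insert(pairs: Sequence[ReadPair],
                    alignments: Iterable[Alignment],
                    min_mapq: int = 40,
                    library_tag: Optional[str] = None) -> LibraryStats:
    """Estimate insert size from pairs whose mates map to the same contig at
    high mapping quality.

    The span of a pair is the outer-coordinate distance of its two mate
    alignments on the shared contig; the library sd is fixed at 50% of the
    estimated mean.
    """
    from .seqio_core import best_hit

    best = best_hit(alignments)
    spans: List[int] = []
    tag = library_tag
    for pair in pairs:
        if tag is None:
            tag = pair.library_tag
        a1 = best.get(pair.read1.id)
        a2 = best.get(pair.read2.id)
        if a1 is None or a2 is None:
            continue
        if a1.mapq < min_mapq or a2.mapq < min_mapq:
            continue
        if a1.target_id != a2.target_id:
            continue
        spans.append(max(a1.tend, a2.tend) - min(a1.tstart, a2.tstart))
    if not spans:
        raise ValueError("no qualifying pairs: cannot estimate insert size")
    mean = sum(spans) / len(spans)
    return LibraryStats(library_tag=tag or "mp", insert_mean=mean,
                        n_pairs_used=len(spans))


def assignment_summary(assignments: Sequence[PairAssignment]) -> Dict[str, int]:
    """Counts per reason; the values sum to the number of input pairs."""
    counts: Dict[str, int] = {"unique": 0, "ambiguous": 0, "cross_bac": 0, "unmapped": 0}
    for a in assignments:
        counts[a.reason] += 1
    return counts
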