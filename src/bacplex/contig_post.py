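"""Post-processing of raw per-BAC contigs.

Fixed stage order: vector clipping (flagging BAC-end contigs) -> length filter
-> read-back coverage -> trimmed-mean coverage filter -> contaminant screen ->
final length filter. The coverage filter is the cross-contamination defence:
contigs assembled from reads that leaked in from neighbouring wells sit far
below the native read depth and are removed wholesale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .seqio_core import (
    Alignment,
    BacAssembly,
    Contig,
    SequenceRecord,
    TargetIndex,
    best_hit,
    map_reads,
)

logger = logging.getLogger(__name__)


@dataclass
class CoverageFilterParams:
    """Knobs of the trimmed-mean coverage threshold.

    The threshold is ``safety * half_factor * mean`` where the mean is taken
    after dropping the ``trim_frac`` lowest-coverage contigs. ``safety=1.0``
    reproduces the printed worked example (threshold = 50% of the trimmed
    average); ``safety=0.9`` gives the softer variant (90% of half the
    average).
    """

    trim_frac: float = 0.10
    half_factor: float = 0.5
    safety: float = 1.0
    min_contig_len: int = 500

    def __post_init__(self) -> None:
        if not (0 <= self.trim_frac < 1):
            raise ValueError("trim_frac must be in [0, 1)")
        if self.half_factor <= 0 or self.safety <= 0:
            raise ValueError("factors must be positive")


@dataclass
class ContigAction:
    """Bookkeeping row for the post-processing report."""

    contig_id: str
    len_before: int
    len_after: int
    coverage: Optional[float] = None
    threshold: Optional[float] = None
    action: str = "kept"  # kept | clipped | low_coverage | contaminant | short


# ---------------------------------------------------------------------------
# Vector clipping
# ---------------------------------------------------------------------------


def clip_vector(contig: Contig, vector_alignments: Sequence[Alignment],
                end_zone: int = 1000) -> Optional[Contig]:
    """Clip vector hits off contig ends and flag the contig as a BAC end.

    A hit whose target interval (on the contig) intersects the first or last
    ``end_zone`` bp is removed together with everything between it and that
    end. Internal vector hits are logged but leave the sequence untouched.
    Returns None when clipping consumes the whole contig.
    """
    n = len(contig)
    left_cut = 0
    right_cut = n
    left_flag = False
    right_flag = False
    for hit in vector_alignments:
        if hit.target_id != contig.id:
            continue
        in_left = hit.tstart < end_zone
        in_right = hit.tend > n - end_zone
        if in_left:
            left_cut = max(left_cut, hit.tend)
            left_flag = True
        if in_right:
            right_cut = min(right_cut, hit.tstart)
            right_flag = True
        if not in_left and not in_right:
            logger.warning(
                "internal vector hit on %s at [%d,%d) left unclipped",
                contig.id, hit.tstart, hit.tend,
            )
    if left_cut >= right_cut:
        return None
    return Contig(
        id=contig.id,
        bases=contig.bases[left_cut:right_cut],
        bac_id=contig.bac_id,
        bac_end_left=left_flag,
        bac_end_right=right_flag,
        coverage=contig.coverage,
    )


def filter_length(contigs: Iterable[Contig], min_len: int = 500) -> List[Contig]:
    """Contigs with length >= min_len, order preserved."""
    return [c for c in contigs if len(c) >= min_len]


# ---------------------------------------------------------------------------
# Read-back coverage
# ---------------------------------------------------------------------------


def contig_coverage(contigs: Sequence[Contig],
                    read_best_hits: Mapping[str, Alignment],
                    read_lengths: Mapping[str, int]) -> Dict[str, float]:
    """Coverage of each contig: summed full length of its best-hit reads
    divided by contig length. Contigs with no assigned reads get 0."""
    totals: Dict[str, int] = {c.id: 0 for c in contigs}
    for read_id, aln in read_best_hits.items():
        if aln.target_id in totals:
            totals[aln.target_id] += read_lengths[read_id]
    return {c.id: totals[c.id] / len(c) for c in contigs}


def annotate_coverage(contigs: Sequence[Contig],
                      reads: Sequence[SequenceRecord],
                      seed_len: int = 21) -> List[Contig]:
    """Map reads back to the contig set and set each contig's coverage."""
    if not contigs:
        return []
    idx = TargetIndex([SequenceRecord(c.id, c.bases) for c in contigs], seed_len=seed_len)
    hits = map_reads([r for r in reads if len(r) >= seed_len], idx)
    best = best_hit(hits)
    lengths = {r.id: len(r) for r in reads}
    cov = contig_coverage(contigs, best, lengths)
    out = []
    for c in contigs:
        out.append(Contig(c.id, c.bases, c.bac_id, c.bac_end_left,
                          c.bac_end_right, coverage=cov[c.id]))
    return out


# ---------------------------------------------------------------------------
# Trimmed-mean coverage filter
# ---------------------------------------------------------------------------


def coverage_filter(assembly: BacAssembly,
                    params: CoverageFilterParams = CoverageFilterParams(),
                    ) -> Tuple[List[Contig], float]:
    """Remove contigs whose coverage falls strictly below the threshold.

    The averaging set drops the ``floor(trim_frac * n)`` lowest-coverage
    contigs (coverage ties broken by contig id); the threshold applies to ALL
    contigs, including those excluded from the averaging set.
    """
    contigs = assembly.contigs
    n = len(contigs)
    if n == 0:
        raise ValueError(f"BAC {assembly.bac_id}: no contigs to filter")
    for c in contigs:
        if c.coverage is None:
            raise ValueError(f"contig {c.id} has no coverage annotation")
    n_trim = int(params.trim_frac * n)
    by_cov = sorted(contigs, key=lambda c: (c.coverage, c.id))
    averaging_set = by_cov[n_trim:]
    mean_cov = sum(c.coverage for c in averaging_set) / len(averaging_set)
    threshold = params.safety * params.half_factor * mean_cov
    retained = [c for c in contigs if c.coverage >= threshold]
    return retained, threshold


# ---------------------------------------------------------------------------
# Contaminant screen
# ---------------------------------------------------------------------------


def contaminant_screen(contigs: Sequence[Contig],
                       contaminant_alignments: Sequence[Alignment],
                       min_identity: float = 0.90,
                       min_len: int = 100,
                       min_contig_len: int = 500,
                       end_zone: int = 1000) -> Tuple[List[Contig], List[ContigAction]]:
    """Remove known-contaminant sequence from the contig set.

    A qualifying hit (identity >= min_identity, alignment length >= min_len,
    intervals on the contig) touching a contig end clips the contig to the
    hit's inner boundary; a qualifying internal hit discards the whole contig;
    contigs shorter than ``min_contig_len`` after clipping are discarded.
    """
    by_contig: Dict[str, List[Alignment]] = {}
    for a in contaminant_alignments:
        if a.identity >= min_identity and (a.tend - a.tstart) >= min_len:
            by_contig.setdefault(a.target_id, []).append(a)

    kept: List[Contig] = []
    actions: List[ContigAction] = []
    for c in contigs:
        hits = by_contig.get(c.id, [])
        if not hits:
            kept.append(c)
            actions.append(ContigAction(c.id, len(c), len(c), c.coverage, action="kept"))
            continue
        n = len(c)
        left_cut, right_cut = 0, n
        internal = False
        for h in hits:
            in_left = h.tstart < end_zone
            in_right = h.tend > n - end_zone
            if in_left:
                left_cut = max(left_cut, h.tend)
            elif in_right:
                right_cut = min(right_cut, h.tstart)
            else:
                internal = True
        if internal or left_cut >= right_cut:
            actions.append(ContigAction(c.id, n, 0, c.coverage, action="contaminant"))
            continue
        new_len = right_cut - left_cut
        if new_len < min_contig_len:
            actions.append(ContigAction(c.id, n, new_len, c.coverage, action="contaminant"))
            continue
        if new_len < n:
            kept.append(Contig(c.id, c.bases[left_cut:right_cut], c.bac_id,
                               c.bac_end_left, c.bac_end_right, c.coverage))
            actions.append(ContigAction(c.id, n, new_len, c.coverage, action="clipped"))
        else:
            kept.append(c)
            actions.append(ContigAction(c.id, n, n, c.coverage, action="kept"))
    return kept, actions


# ---------------------------------------------------------------------------
# Full post-processing pipeline for one BAC
# ---------------------------------------------------------------------------


@dataclass
class PostprocessResult:
    assembly: BacAssembly
    threshold: float
    actions: List[ContigAction] = field(default_factory=list)


def postprocess_assembly(assembly: BacAssembly,
                         reads: Sequence[SequenceRecord],
                         vector_alignments: Sequence[Alignment],
                         contaminant_alignments: Sequence[Alignment] = (),
                         params: CoverageFilterParams = CoverageFilterParams(),
                         end_zone: int = 1000,
                         seed_len: int = 21) -> PostprocessResult:
    """Run the fixed post-processing order on one BAC assembly.

    ``vector_alignments`` and ``contaminant_alignments`` are vector/contaminant
    hits on the raw contigs (target = contig). Reads are the cleaned
    paired-end reads of this BAC, used for read-back coverage.
    """
    actions: List[ContigAction] = []

    clipped: List[Contig] = []
    for c in assembly.contigs:
        cc = clip_vector(c, vector_alignments, end_zone=end_zone)
        if cc is None:
            actions.append(ContigAction(c.id, len(c), 0, action="contaminant"))
        else:
            clipped.append(cc)
            if len(cc) < len(c):
                actions.append(ContigAction(c.id, len(c), len(cc), action="clipped"))

    sized = filter_length(clipped, params.min_contig_len)
    for c in clipped:
        if len(c) < params.min_contig_len:
            actions.append(ContigAction(c.id, len(c), len(c), action="short"))

    covered = annotate_coverage(sized, reads, seed_len=seed_len)
    retained, threshold = coverage_filter(
        BacAssembly(assembly.bac_id, covered, stage="raw"), params)
    kept_ids = {c.id for c in retained}
    for c in covered:
        if c.id not in kept_ids:
            actions.append(ContigAction(c.id, len(c), len(c), c.coverage,
                                        threshold, action="low_coverage"))

    cleaned, screen_actions = contaminant_screen(
        retained, contaminant_alignments, min_contig_len=params.min_contig_len,
        end_zone=end_zone)
    actions.extend(a for a in screen_actions if a.action != "kept")

    final = filter_length(cleaned, params.min_contig_len)
    out = BacAssembly(assembly.bac_id, final, stage="postprocessed")
    return PostprocessResult(assembly=out, threshold=threshold, actions=actions)
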