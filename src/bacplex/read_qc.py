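"""Paired-end read preprocessing: quality trimming, host/vector screening, pair integrity.

Screening is presence/absence: a read aligning to the E. coli host decoy is
dropped; a read aligning to the cloning vector is dropped unless its hit falls
within a window around the cloning site (those reads carry the insert boundary
and are kept so the assembler can reach the very ends of the insert). A pair
survives only if both mates survive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .seqio_core import (
    Alignment,
    ReadPair,
    SequenceRecord,
    TargetIndex,
    map_reads,
)

#: alignment thresholds a hit must meet to count in a presence/absence screen
SCREEN_MIN_IDENTITY = 0.90
SCREEN_MIN_LEN = 50

VERDICTS = ("keep", "keep_vector_near_site", "drop_host", "drop_vector", "drop_quality")


@dataclass
class ScreenVerdict:
    verdict: str
    evidence: Optional[Alignment] = None

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")

    @property
    def keeps_read(self) -> bool:
        return self.verdict in ("keep", "keep_vector_near_site")


# ---------------------------------------------------------------------------
# Quality trimming (modified Mott)
# ---------------------------------------------------------------------------


def _phred_error(q: int) -> float:
    return 10.0 ** (-q / 10.0)


def quality_trim(record: SequenceRecord, error_limit: float = 0.05) -> SequenceRecord:
    """Trim a read to the contiguous substring maximizing the running sum of
    ``error_limit - p_error(base)`` (modified Mott trimming).

    Ties are resolved toward the smallest start, then the largest end. If no
    substring has a positive objective the read is trimmed to empty.
    """
    if record.quals is None:
        raise ValueError(f"read {record.id!r} has no quality scores to trim on")
    n = len(record.bases)
    # prefix sums of the objective
    prefix = [0.0] * (n + 1)
    for i, q in enumerate(record.quals):
        prefix[i + 1] = prefix[i] + (error_limit - _phred_error(q))

    best_val = 0.0
    best_i, best_j = 0, 0
    min_idx = 0  # earliest index of the minimal prefix seen so far
    for j in range(1, n + 1):
        val = prefix[j] - prefix[min_idx]
        if val > best_val + 1e-12 or (
            abs(val - best_val) <= 1e-12
            and best_j > best_i
            and (min_idx < best_i or (min_idx == best_i and j > best_j))
        ):
            best_val, best_i, best_j = val, min_idx, j
        if prefix[j] < prefix[min_idx] - 1e-12:
            min_idx = j
    if best_val <= 0 or best_j == best_i:
        return SequenceRecord(id=record.id, bases="", quals=[])
    return SequenceRecord(
        id=record.id,
        bases=record.bases[best_i:best_j],
        quals=record.quals[best_i:best_j],
    )


# ---------------------------------------------------------------------------
# Host / vector screening
# ---------------------------------------------------------------------------


def qualifying_hits(hits: Iterable[Alignment],
                    min_identity: float = SCREEN_MIN_IDENTITY,
                    min_len: int = SCREEN_MIN_LEN) -> List[Alignment]:
    """Hits that qualify for a presence/absence screen."""
    return [h for h in hits
            if h.identity >= min_identity and h.qspan >= min_len]


def screen_read(record: SequenceRecord,
                host_hits: Sequence[Alignment],
                vector_hits: Sequence[Alignment],
                cloning_site: int,
                window: int = 2000) -> ScreenVerdict:
    """Classify a read by its qualifying hits against host and vector.

    Host contamination dominates; vector hits are tolerated when the hit
    interval intersects ``[cloning_site - window, cloning_site + window]``.
    """
    host = qualifying_hits(host_hits)
    if host:
        return ScreenVerdict("drop_host", evidence=host[0])
    vector = qualifying_hits(vector_hits)
    if vector:
        lo, hi = cloning_site - window, cloning_site + window
        for h in vector:
            if h.tstart <= hi and h.tend >= lo:
                return ScreenVerdict("keep_vector_near_site", evidence=h)
        return ScreenVerdict("drop_vector", evidence=vector[0])
    return ScreenVerdict("keep")


def filter_intact_pairs(
    pairs: Iterable[Tuple[ReadPair, bool, bool]],
) -> List[ReadPair]:
    """Keep only pairs whose two mates both survived and are both non-empty."""
    out = []
    for pair, ok1, ok2 in pairs:
        if ok1 and ok2 and len(pair.read1) > 0 and len(pair.read2) > 0:
            out.append(pair)
    return out


# ---------------------------------------------------------------------------
# Whole-library driver
# ---------------------------------------------------------------------------


def qc_pipeline(pairs: Sequence[ReadPair],
                vector: SequenceRecord,
                host: SequenceRecord,
                cloning_site: int,
                window: int = 2000,
                error_limit: float = 0.05,
                trim: bool = True) -> Tuple[List[ReadPair], Dict[str, int]]:
    """Trim and screen every mate, then keep intact pairs.

    Returns the surviving pairs (with trimmed reads) and a count per verdict
    (plus ``pairs_in`` / ``pairs_out``).
    """
    host_idx = TargetIndex([host])
    vec_idx = TargetIndex([vector])
    counts = {v: 0 for v in VERDICTS}
    survived: List[Tuple[ReadPair, bool, bool]] = []
    for pair in pairs:
        processed: List[SequenceRecord] = []
        flags: List[bool] = []
        for mate in (pair.read1, pair.read2):
            read = quality_trim(mate, error_limit) if (trim and mate.quals is not None) else mate
            if len(read) == 0:
                counts["drop_quality"] += 1
                processed.append(read)
                flags.append(False)
                continue
            hh = map_reads([read], host_idx) if len(read) >= host_idx.seed_len else []
            vh = map_reads([read], vec_idx) if len(read) >= vec_idx.seed_len else []
            verdict = screen_read(read, hh, vh, cloning_site, window)
            counts[verdict.verdict] += 1
            processed.append(read)
            flags.append(verdict.keeps_read)
        survived.append((
            ReadPair(pair.pair_id, processed[0], processed[1], pair.library_tag),
            flags[0], flags[1],
        ))
    clean = filter_intact_pairs(survived)
    counts["pairs_in"] = len(list(pairs))
    counts["pairs_out"] = len(clean)
    return clean, counts
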