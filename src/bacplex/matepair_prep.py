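"""Mate-pair library preprocessing: duplicate removal and junction-adapter clipping.

Nextera mate-pair libraries circularize long fragments; the junction adapter
marks the circularization point, and any bases a read carries beyond it belong
to the distal end of the fragment. Clipping therefore keeps only the bases 5'
of the adapter match. Duplicate pairs (PCR/optical) are collapsed on exact
sequence identity of both mates before clipping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .seqio_core import ReadPair, SequenceRecord, revcomp


@dataclass
class DedupReport:
    n_input_pairs: int
    n_unique_pairs: int

    @property
    def duplication_rate(self) -> float:
        if self.n_input_pairs == 0:
            return 0.0
        return 1.0 - self.n_unique_pairs / self.n_input_pairs


def dedup_pairs(pairs: Sequence[ReadPair]) -> Tuple[List[ReadPair], DedupReport]:
    """Collapse pairs with byte-identical (read1, read2) sequences; first
    occurrence wins."""
    seen: set = set()
    unique: List[ReadPair] = []
    for pair in pairs:
        key = (pair.read1.bases, pair.read2.bases)
        if key in seen:
            continue
        seen.add(key)
        unique.append(pair)
    return unique, DedupReport(n_input_pairs=len(pairs), n_unique_pairs=len(unique))


# ---------------------------------------------------------------------------
# Junction-adapter clipping
# ---------------------------------------------------------------------------


def find_adapter(bases: str, adapter: str, max_mismatch: int = 2) -> Optional[int]:
    """Start position of the leftmost occurrence of the adapter or its reverse
    complement with at most ``max_mismatch`` mismatches, or None."""
    patterns = [adapter, revcomp(adapter)]
    m = len(adapter)
    n = len(bases)
    best: Optional[int] = None
    for pat in patterns:
        for start in range(0, n - m + 1):
            if best is not None and start >= best:
                break
            mm = 0
            for a, b in zip(bases[start:start + m], pat):
                if a != b:
                    mm += 1
                    if mm > max_mismatch:
                        break
            if mm <= max_mismatch:
                best = start
                break
    return best


def _clip_read(read: SequenceRecord, adapter: str, max_mismatch: int) -> SequenceRecord:
    pos = find_adapter(read.bases, adapter, max_mismatch)
    if pos is None:
        return read
    return SequenceRecord(
        id=read.id,
        bases=read.bases[:pos],
        quals=read.quals[:pos] if read.quals is not None else None,
    )


def clip_junction(pair: ReadPair, adapter_seq: str,
                  max_mismatch: int = 2,
                  min_survivor_len: int = 16) -> Optional[ReadPair]:
    """Clip both mates at the junction adapter; drop the pair if either mate
    ends up shorter than ``min_survivor_len``.

    Each mate is truncated to the bases 5' of the leftmost adapter match
    (either orientation, <= max_mismatch mismatches); unmatched mates pass
    through unchanged. Returns None when the pair does not survive.
    """
    if not adapter_seq:
        raise ValueError("adapter sequence must be non-empty")
    r1 = _clip_read(pair.read1, adapter_seq, max_mismatch)
    r2 = _clip_read(pair.read2, adapter_seq, max_mismatch)
    if len(r1) < min_survivor_len or len(r2) < min_survivor_len:
        return None
    return ReadPair(pair.pair_id, r1, r2, pair.library_tag)


@dataclass
class MatePrepReport:
    n_pairs_in: int = 0
    n_pairs_out: int = 0
    duplication_rate: float = 0.0
    n_clipped: int = 0
    n_dropped_short: int = 0


def prep_matepairs(pairs: Sequence[ReadPair], adapter_seq: str,
                   max_mismatch: int = 2,
                   min_survivor_len: int = 16) -> Tuple[List[ReadPair], MatePrepReport]:
    """Full mate-pair preprocessing: dedup first, then junction clipping."""
    unique, dedup = dedup_pairs(pairs)
    out: List[ReadPair] = []
    n_clipped = 0
    n_dropped = 0
    for pair in unique:
        clipped = clip_junction(pair, adapter_seq, max_mismatch, min_survivor_len)
        if clipped is None:
            n_dropped += 1
            continue
        if len(clipped.read1) < len(pair.read1) or len(clipped.read2) < len(pair.read2):
            n_clipped += 1
        out.append(clipped)
    report = MatePrepReport(
        n_pairs_in=len(pairs),
        n_pairs_out=len(out),
        duplication_rate=dedup.duplication_rate,
        n_clipped=n_clipped,
        n_dropped_short=n_dropped,
    )
    return out, report
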