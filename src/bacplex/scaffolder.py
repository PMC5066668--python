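"""Mate-pair scaffolding: link graph, greedy joining, iterative two-library scheme.

A mate pair whose clipped mates best-hit two different contigs of the same BAC
is evidence that those contigs are adjacent. Each such pair votes for one
(contig end, contig end) combination — the ends the mates point toward — and
contributes a gap estimate ``insert_mean - d_a - d_b`` where ``d`` is the
distance from the outermost aligned base of a mate to the linked contig end.
Links with enough votes (the minimum-link threshold ``k``) are applied
greedily, strongest first, skipping ends whose second-best link is too close
to the best (the ambiguity ratio). Gaps are written as runs of ``N``; no
sequence is ever created or destroyed, so scaffolding conserves base content.

The iterative scheme re-deconvolves each mate-pair library against the current
assemblies (draft, then once-scaffolded) and scaffolds each BAC independently,
one library at a time, in the order given.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .deconvolve import LibraryStats, PairAssignment, assign_pairs
from .seqio_core import (
    Alignment,
    BacAssembly,
    Contig,
    ReadPair,
    SequenceRecord,
    TargetIndex,
    best_hit,
    map_reads,
    revcomp,
)

logger = logging.getLogger(__name__)

HEAD = "head"  # left end of a contig in its given orientation
TAIL = "tail"  # right end

End = Tuple[str, str]  # (contig_id, HEAD|TAIL)


@dataclass
class ContigLink:
    """Aggregated mate-pair evidence joining two oriented contig ends."""

    contig_a: str
    end_a: str
    contig_b: str
    end_b: str
    gap_estimates: List[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.contig_a, self.end_a) == (self.contig_b, self.end_b):
            raise ValueError("link joins a contig end to itself")

    @property
    def n_links(self) -> int:
        return len(self.gap_estimates)

    @property
    def gap_mean(self) -> float:
        return sum(self.gap_estimates) / len(self.gap_estimates)

    @property
    def ends(self) -> Tuple[End, End]:
        return (self.contig_a, self.end_a), (self.contig_b, self.end_b)


@dataclass
class ScaffoldLayout:
    """Ordered, oriented, gapped contig layout of one scaffold."""

    scaffold_id: str
    parts: List[Tuple[str, str, Optional[int]]]  # (contig_id, +/-, gap_after)


# ---------------------------------------------------------------------------
# Link building
# ---------------------------------------------------------------------------


def _mate_end_and_distance(aln: Alignment, contig_len: int) -> Tuple[str, int]:
    """The contig end a mate points toward, and the distance from the mate's
    outermost aligned base to that end.

    After junction clipping, mates of a spanning pair face inward across the
    gap: a forward-strand mate points at the contig tail, a reverse-strand
    mate at the head.
    """
    if aln.strand == "+":
        return TAIL, contig_len - aln.tstart
    return HEAD, aln.tend


def build_links(contigs: Sequence[Contig],
                pairs: Sequence[ReadPair],
                alignments: Iterable[Alignment],
                lib: LibraryStats) -> List[ContigLink]:
    """Aggregate spanning pairs of one BAC into links between contig ends.

    Only pairs whose mates best-hit two *different* contigs of this BAC are
    informative; each contributes one vote and one gap estimate to the link
    between the contig ends its mates point toward.
    """
    lengths = {c.id: len(c) for c in contigs}
    best = best_hit(a for a in alignments if a.target_id in lengths)
    grouped: Dict[Tuple[str, str, str, str], ContigLink] = {}
    for pair in pairs:
        a1 = best.get(pair.read1.id)
        a2 = best.get(pair.read2.id)
        if a1 is None or a2 is None or a1.target_id == a2.target_id:
            continue
        end1, d1 = _mate_end_and_distance(a1, lengths[a1.target_id])
        end2, d2 = _mate_end_and_distance(a2, lengths[a2.target_id])
        gap = lib.insert_mean - d1 - d2
        ea: End = (a1.target_id, end1)
        eb: End = (a2.target_id, end2)
        if eb < ea:
            ea, eb = eb, ea
        key = (ea[0], ea[1], eb[0], eb[1])
        link = grouped.get(key)
        if link is None:
            link = ContigLink(ea[0], ea[1], eb[0], eb[1])
            grouped[key] = link
        link.gap_estimates.append(gap)
    return [grouped[k] for k in sorted(grouped)]


# ---------------------------------------------------------------------------
# Greedy joining
# ---------------------------------------------------------------------------


class _Chain:
    """A growing scaffold: ordered (contig_id, orient, gap_after) parts."""

    __slots__ = ("parts",)

    def __init__(self, contig_id: str):
        self.parts: List[Tuple[str, str, Optional[float]]] = [(contig_id, "+", None)]

    def left_end(self) -> End:
        cid, orient, _ = self.parts[0]
        return (cid, HEAD if orient == "+" else TAIL)

    def right_end(self) -> End:
        cid, orient, _ = self.parts[-1]
        return (cid, TAIL if orient == "+" else HEAD)

    def flip(self) -> None:
        flipped = []
        gaps = [g for _, _, g in self.parts][:-1]
        for i, (cid, orient, _) in enumerate(reversed(self.parts)):
            gap = gaps[len(self.parts) - 2 - i] if i < len(self.parts) - 1 else None
            flipped.append((cid, "-" if orient == "+" else "+", gap))
        self.parts = flipped


def greedy_scaffold(contigs: Sequence[Contig],
                    links: Sequence[ContigLink],
                    k_min: int,
                    ratio: float = 0.7,
                    min_gap: int = 1,
                    scaffold_prefix: str = "sc",
                    ) -> Tuple[List[ScaffoldLayout], List[Contig]]:
    """Join contigs greedily by their strongest mate-pair links.

    Links with fewer than ``k_min`` votes are discarded. Links are applied in
    order of decreasing vote count; a link is skipped when either of its
    contig ends has a competing remaining link whose vote ratio exceeds
    ``ratio`` (that end is marked ambiguous and never joined), when an end is
    already joined, or when the join would close a cycle. Gap sizes are
    ``max(round(gap_mean), min_gap)`` unknown bases.

    Returns layouts and scaffold sequences (as contigs of the same BAC).
    """
    bac_id = contigs[0].bac_id if contigs else ""
    seqs = {c.id: c.bases for c in contigs}

    usable = sorted(
        (l for l in links if l.n_links >= k_min),
        key=lambda l: (-l.n_links, l.contig_a, l.contig_b, l.end_a, l.end_b),
    )
    # remaining links per contig end, for the ambiguity test
    per_end: Dict[End, List[ContigLink]] = {}
    for link in usable:
        for end in link.ends:
            per_end.setdefault(end, []).append(link)

    chains: Dict[str, _Chain] = {c.id: _Chain(c.id) for c in contigs}
    chain_of: Dict[str, str] = {c.id: c.id for c in contigs}  # contig -> chain key
    used_ends: set = set()
    ambiguous_ends: set = set()

    def find_chain(contig_id: str) -> str:
        key = chain_of[contig_id]
        while chain_of[key] != key:
            key = chain_of[key]
        chain_of[contig_id] = key
        return key

    for link in usable:
        for end in link.ends:
            per_end[end].remove(link)
        ea, eb = link.ends
        competing = False
        for end in (ea, eb):
            for other in per_end[end]:
                if other.n_links / link.n_links > ratio:
                    ambiguous_ends.add(end)
                    competing = True
        if competing:
            logger.info("ambiguous link %s-%s skipped", ea, eb)
            continue
        if ea in used_ends or eb in used_ends:
            continue
        if ea in ambiguous_ends or eb in ambiguous_ends:
            continue
        ka, kb = find_chain(ea[0]), find_chain(eb[0])
        if ka == kb:
            logger.info("cycle-inducing link %s-%s skipped", ea, eb)
            continue
        ca, cb = chains[ka], chains[kb]
        # orient chain A so the linked end is on its right boundary
        if ca.right_end() != ea:
            ca.flip()
        if cb.left_end() != eb:
            cb.flip()
        gap = link.gap_mean
        cid, orient, _ = ca.parts[-1]
        ca.parts[-1] = (cid, orient, gap)
        ca.parts.extend(cb.parts)
        chain_of[kb] = ka
        del chains[kb]
        used_ends.add(ea)
        used_ends.add(eb)

    # deterministic scaffold order: largest first, then by first contig id
    def chain_len(ch: _Chain) -> int:
        return sum(len(seqs[cid]) for cid, _, _ in ch.parts)

    ordered = sorted(chains.values(), key=lambda ch: (-chain_len(ch), ch.parts[0][0]))
    layouts: List[ScaffoldLayout] = []
    out_contigs: List[Contig] = []
    for i, ch in enumerate(ordered, 1):
        sid = f"{bac_id}_{scaffold_prefix}{i}" if bac_id else f"{scaffold_prefix}{i}"
        parts: List[Tuple[str, str, Optional[int]]] = []
        pieces: List[str] = []
        for j, (cid, orient, gap) in enumerate(ch.parts):
            gap_n: Optional[int] = None
            if j < len(ch.parts) - 1:
                gap_n = max(int(round(gap)), min_gap)  # type: ignore[arg-type]
            parts.append((cid, orient, gap_n))
            pieces.append(seqs[cid] if orient == "+" else revcomp(seqs[cid]))
            if gap_n is not None:
                pieces.append("N" * gap_n)
        layouts.append(ScaffoldLayout(scaffold_id=sid, parts=parts))
        out_contigs.append(Contig(id=sid, bases="".join(pieces), bac_id=bac_id))
    return layouts, out_contigs


# ---------------------------------------------------------------------------
# Iterative two-library scheme
# ---------------------------------------------------------------------------


def iterative_scaffold(assemblies: Sequence[BacAssembly],
                       libraries: Sequence[Tuple[Sequence[ReadPair], LibraryStats, int]],
                       ratio: float = 0.7,
                       min_gap: int = 1,
                       seed_len: int = 21,
                       ) -> Tuple[List[BacAssembly], List[ScaffoldLayout]]:
    """Scaffold every BAC with each mate-pair library in turn.

    For each library the pairs are re-deconvolved against the *current*
    assemblies (so pairs unassignable against the draft may resolve after the
    first round), links are built per BAC, and each BAC is scaffolded
    independently. With an empty library list the assemblies pass through
    unchanged.
    """
    current = [BacAssembly(a.bac_id, list(a.contigs), a.stage) for a in assemblies]
    all_layouts: List[ScaffoldLayout] = []
    for round_no, (pairs, lib, k_min) in enumerate(libraries, 1):
        all_contigs = [c for asm in current for c in asm.contigs]
        contig_to_bac = {c.id: c.bac_id for c in all_contigs}
        idx = TargetIndex(
            [SequenceRecord(c.id, c.bases) for c in all_contigs], seed_len=seed_len)
        reads = []
        for p in pairs:
            reads.append(p.read1)
            reads.append(p.read2)
        alns = map_reads([r for r in reads if len(r) >= seed_len], idx)
        assignments = assign_pairs(pairs, alns, contig_to_bac)
        assigned_to: Dict[str, str] = {
            a.pair_id: a.bac_id for a in assignments if a.reason == "unique"}

        all_layouts = []
        nxt: List[BacAssembly] = []
        for asm in current:
            bac_pairs = [p for p in pairs if assigned_to.get(p.pair_id) == asm.bac_id]
            links = build_links(asm.contigs, bac_pairs, alns, lib)
            layouts, scaffolds = greedy_scaffold(
                asm.contigs, links, k_min=k_min, ratio=ratio, min_gap=min_gap,
                scaffold_prefix=f"r{round_no}sc")
            nxt.append(BacAssembly(asm.bac_id, scaffolds, stage="scaffolded"))
            all_layouts.extend(layouts)
        current = nxt
    return current, all_layouts


def write_agp(layouts: Sequence[ScaffoldLayout],
              contig_lengths: Mapping[str, int], path) -> None:
    """Write scaffold layouts as AGP 2.1."""
    with open(path, "w") as fh:
        fh.write("##agp-version 2.1\n")
        for lay in layouts:
            pos = 0
            part_no = 0
            for cid, orient, gap in lay.parts:
                part_no += 1
                clen = contig_lengths[cid]
                fh.write("\t".join(map(str, [
                    lay.scaffold_id, pos + 1, pos + clen, part_no,
                    "W", cid, 1, clen, orient,
                ])) + "\n")
                pos += clen
                if gap is not None:
                    part_no += 1
                    fh.write("\t".join(map(str, [
                        lay.scaffold_id, pos + 1, pos + gap, part_no,
                        "N", gap, "scaffold", "yes", "paired-ends",
                    ])) + "\n")
                    pos += gap
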