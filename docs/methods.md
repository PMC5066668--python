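# Methods

## Problem setting

A multiplexed BAC sequencing experiment produces, per clone, a set of
paired-end reads (barcoded, so clone assignment is known) and, per clone
pool, long-insert Nextera mate-pair reads (unbarcoded). After an external
per-clone assembler produces draft contigs, this package performs everything
downstream: read-level QC, contig-level filtering, mate-pair deconvolution,
scaffolding and quality evaluation. All coordinates are 0-based half-open;
strand `-` means the query aligns reverse-complemented to the target.

## Internal read mapper

External aligners are deliberately not invoked; every mapping step runs
through one internal seed-and-extend mapper with a small, explicit contract:

* exact 21-mer seeding on both strands (a sampled seed every `seed_len`
  bases plus the final k-mer, so any exact stretch of ≥ 2·k−1 bases is hit);
* ungapped extension along the seed diagonal over the whole query, clipped at
  target boundaries; substitutions are scored, indels are not modelled;
* hits below `min_identity` (default 0.9) are suppressed; `score = matches`;
* mapping quality is synthetic: 60 for a unique best score, 0 for hits tied
  at the best score. Downstream rules only ever consume "unique vs tied"
  (deconvolution) and "mapq ≥ 40" (insert estimation), so intermediate
  values are not needed.

Externally produced SAM or PAF alignments can be substituted at every
consuming operation. For locating long references (vector backbone,
contaminants) on contigs, and for aligning assemblies back to their
reference inserts, the mapper is applied to overlapping tiles whose hits are
merged (`pipeline.tile_hits`) or chained by diagonal (`pipeline.segment_align`);
chain breaks at strand flips or diagonal shifts are exactly the flanks the
misassembly classifier consumes. Screens that classical pipelines phrase as
BLAST e-value cut-offs are phrased here as identity ≥ 0.9 with alignment
length ≥ 50 bp, since e-values depend on database size while these screens
are presence/absence tests.

## Quality trimming

The trimmer is modified-Mott: with per-base error probability
`p = 10^(-Q/10)`, keep the contiguous substring maximising
`Σ (limit − p_i)`, `limit = 0.05`. Ties resolve to the smallest start, then
the largest end; a read whose best objective is ≤ 0 becomes empty and its
pair is discarded. The algorithm is checked against an exhaustive O(n²)
oracle over all substrings.

## Coverage filter

Contig read coverage is the summed full length of the reads whose *best* hit
lies on the contig, divided by contig length. For each BAC the
`floor(0.10·n)` lowest-coverage contigs (ties broken by contig id) are
dropped from the averaging set, and the retention threshold is
`T = safety · 0.5 · mean(remaining)`. The threshold applies to all contigs,
including those excluded from the averaging set, and removal is strict
(`coverage < T`). `safety` defaults to 1.0 — the variant that reproduces the
worked threshold example (trimmed mean 306 → T = 153) — with 0.9 available
as the softer variant some descriptions of the procedure imply; the two
cannot be reconciled, so both are exposed and neither is claimed canonical.

## Junction clipping and deconvolution

Nextera mate pairs carry the 19 bp junction adapter at the circularization
point; bases 3′ of it belong to the distal fragment end. Each mate is
truncated at the leftmost occurrence of the adapter or its reverse
complement within ≤ 2 mismatches; mates shorter than 16 bp afterwards
discard the whole pair. Duplicate pairs are removed *before* clipping, keyed
on the exact full-length sequence of both mates (optical duplicates are
subsumed by sequence identity at this scale).

A pair is deconvolved to BAC *b* iff every best-scoring alignment of each
mate lies on contigs of *b* and both mates are uniquely placed (mapq ≥ 1);
otherwise it is recorded as ambiguous, cross-BAC or unmapped, and every
input pair receives exactly one verdict. Insert size is the outer-coordinate
span of same-contig pairs with both mapq ≥ 40; the library sd is pinned at
50 % of the mean. Because estimation only sees pairs that fit inside one
contig, the estimate carries a mild downward truncation bias when contigs
are not much longer than the insert (≈ 4 % at 6.6 kb contigs and 5.5 kb
inserts in the synthetic study); it is reported as measured.

## Scaffolding

Each deconvolved pair whose mates best-hit two different contigs of its BAC
votes for one (contig end, contig end) combination — a forward-strand mate
points at its contig's tail, a reverse-strand mate at the head — with gap
estimate `insert_mean − d_a − d_b`, `d` being the distance from the mate's
outermost aligned base to the linked end. Votes are grouped into links with
canonically ordered ends.

Joining is greedy: links below the minimum-link threshold *k* (10 for the
MiSeq-style library, 20 for HiSeq-style) are discarded; remaining links are
taken strongest-first; a link is refused when either end has a competing
remaining link with vote ratio > 0.7 (that end is marked ambiguous and never
joined — the ratio fills a gap the minimum-link rule leaves open, using the
conventional SSPACE default), when an end is already joined, or when the
join would close a cycle. Gaps are rendered as `max(round(gap_mean), 1)`
`N`s; negative estimates collapse to a single `N` and overlap merging is not
attempted, so the non-`N` base content of a BAC is exactly conserved and
scaffold L50 can never drop below contig L50. Libraries are applied
sequentially (MiSeq first), re-deconvolving against the current assemblies
between rounds; each BAC is scaffolded independently. Equal-vote ties break
lexicographically for determinism.

## Evaluation

Alignments of an assembly to its reference insert shorter than 100 bp are
discarded; the remainder are sorted by query start, and every boundary
between consecutive alignments is a breakpoint. Flanks on different strands
are global (strand); separation is measured between the reference-facing
inner boundaries with positive = gap, negative = overlap, so the distance
and overlap rules become one signed comparison: > +1000 ⇒ global (distance),
< −1000 ⇒ global (overlap), otherwise local. "More than 1 kb" is strict, so
a separation of exactly 1000 is local. Genome fraction is the percentage of
the reference covered by the union of alignment intervals. True scaffold
gaps appear as small-separation local breakpoints, mirroring how
reference-based evaluators count gap-adjacent boundaries.

Repeat masking flags every base covered by at least one canonical 21-mer
whose count in a reference k-mer index reaches `min_count`; maximal runs are
merged into BED-style intervals. The repeat-overlap curve reports, per
identity threshold t ∈ {80..99}, the fraction of masked bases covered by an
alignment of identity ≥ t %, which is non-increasing in t by construction.

## Synthetic study

The generator emulates the experiment rather than any particular dataset.
Study-shaped defaults: 500 bp paired-end inserts read as 2 × 100, mate-pair
fragments ~5.5 kb (MiSeq-style, 2 × 250) and ~6.2 kb (HiSeq-style, 2 × 100),
a ~7.5 kb vector with a recorded cloning site, an E. coli-sized host decoy
stand-in, substitution errors at 0.1 %, 5 % duplicate pairs, 5 %
cross-contamination, and 30 % adapter read-through. The end-to-end study
uses 8 BACs drawn from a 2 Mb genome with inserts scaled down proportionally
to 20 kb, 600 paired-end pairs per BAC and 2 400 pairs per mate-pair
library — sizes chosen once so that native coverage (~5×) comfortably
dominates contamination depth (≤ 10 % of native) and every true adjacency
receives several times the minimum link count, while the whole study runs in
seconds on one CPU.

Per BAC the fabricated draft assembly contains three true contigs (vector
sequence attached at the two outermost ends), two contamination-only contigs
copied from the neighbouring BAC's insert (the same regions its
cross-contaminating reads are drawn from), and for two BACs a phage spike-in
contig that attracts no reads — the latter is removed purely by the coverage
filter, as phage control sequence is in practice. Three BACs carry planted
misassemblies (1 kb inversion, 500 bp relocation, 3 kb relocation), placed
mid-contig so adjacencies stay supported; a relocation is planted as
omission of an internal block, which produces exactly the flank-separation
signature the classifier keys on. One repeat family is planted centred in
every insert at 99 % pairwise identity (mutation rates are solved from the
requested *pairwise* identity, `(1−r)² + r²/3 = d`), a second family lives
in the genome tail outside all inserts. Every read and contig carries a
truth record; all property tests condition on truth, never on re-inference.

What the generator does not model: indels and structured quality profiles
(no downstream rule consumes them), PCR bias, optical duplicate geometry,
chimeric reads, and real repeat landscapes (one family per insert rather
than nested transposon hierarchies). Passing tests therefore demonstrate the
correctness of the decision rules under their stated assumptions, not
performance on real barley-scale repeat content.

## Numerical conventions

Trimmed count uses `floor`; coverage ties break by contig id; link ties
break lexicographically; `N` gaps are at least 1; empty inputs are errors
where a statistic would be undefined (coverage filter on zero contigs,
insert estimation with zero qualifying pairs, genome fraction on a zero-length
reference) and identities elsewhere (empty FASTA, empty library list). The
L50 of an empty set is reported as 0.
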