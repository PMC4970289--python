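# Methods

This note documents the models and algorithms behind `incseq`, the choices
made where the design was genuinely open, and what the simulation-based
tests do and do not demonstrate.

## Input model

A read is assumed to be a rolling-circle amplification (RCA) product: a
long linear sequence of tandem copies of one circular template, observed
through a noisy sequencer. Copies are independent observations of the same
molecule; the read's start point within the template is arbitrary, so all
template-level comparisons in this package are circular (the read or the
reference is self-concatenated before alignment, and either strand may
match).

## Alignment engines

All alignment goes through one module (`incseq.align`) exposing a single
hit type (`LocalAlignment`: 0-based half-open query/target intervals,
strand, score, match/mismatch/insertion/deletion counts, run-length edit
script). Three interchangeable engines implement it:

* **sw** — affine-gap Smith–Waterman (Biopython's `PairwiseAligner` does
  the dynamic programming; this package adds strand handling, edit-script
  and count extraction, and multi-hit recovery by greedy masked
  realignment). Default scoring: match +1, mismatch −2, gap open −3, gap
  extend −1, reporting threshold (min_score) 40. The threshold is the main
  sensitivity knob; 40 corresponds to roughly a 60–80 bp clean overlap and
  is permissive at amplicon scale.
* **seeded** — for long targets: edlib's bit-parallel infix search locates
  candidate spans (edit distance ≤ 45% of the query length), the sw engine
  refines each span in a ±60 bp padded window, the span is masked, and the
  search repeats. Chosen automatically when query×target exceeds 2.5 Mcells.
* **edlib** — pure edit distance, infix mode, counts from the edit script
  and the score derived from the counts. The whole query aligns or nothing
  does; unpaired query bases at a target boundary are reported as clipped.

Engine choice per stage:

* Anchor mapping and all segment-stage alignments use **edlib**. Anchors
  are read subsequences aligned back to the same read, so both sides carry
  sequencing error and the effective divergence is ~30%. At that divergence
  score-based local alignment trims noisy hit ends below the 80%
  anchor-coverage filter and loses a substantial fraction of true repeat
  hits, fragmenting segment runs; the infix engine aligns the whole anchor
  within a distance budget or not at all, which matches the filter's intent
  (a hit must cover ≥80% of the anchor) without the trimming artifact.
* Reference-vs-read operations (chimera region mapping, profiling, error
  assessment) default to sw/seeded, where clipping and local score are
  meaningful. Scores stand in for e-values when competing hits are ranked
  (the score order is the monotone surrogate; ties break to the leftmost
  read start).

The test suite validates the sw engine against an independently written
brute-force Gotoh dynamic program on 200 random short pairs, and the seeded
engine against exact masked realignment on concatemer fixtures.

## Repeat segmentation

Anchors are non-overlapping 500 bp windows at offsets 0, 500, 1000, …
while the offset is below half the read length (a window may extend past
the midpoint; this guarantees at least one anchor for any read at least
one window long). Each anchor is aligned to the whole read on both strands;
hits covering less than 80% of the anchor are discarded. The anchor with
the most retained hits wins (ties: higher mean hit identity, then lower
index — determinism matters more than the specific rule here).

Adjacent hit starts delimit candidate segments; each start is first
extended 5'-ward by the anchor bases clipped at the hit's 5' end (in read
orientation), floored so segments never overlap. n hits yield n−1 segments;
the trailing partial copy after the last hit is deliberately dropped (at
most one copy of coverage is lost). Segments take the strand of their
left-bounding hit and minus-strand segments are stored reverse-complemented
so consensus construction sees one orientation.

Run selection: segments are split into maximal same-strand blocks; within a
block the median length is computed once, segments deviating more than 5%
from it are dropped, and the longest stretch of consecutive survivors is
the block's candidate. The longest candidate overall is the run; fewer than
six segments rejects the read (`too_few_segments`). Recomputing the median
after outlier removal was considered and rejected — the single-pass rule is
the simplest deterministic reading of "consecutive segments within 5% of
the median" and the two differ only in pathological mixtures.

A read with c copies of a unit no shorter than the anchor window yields
c−1 segments, each exactly a rotation of the unit, over the whole tested
grid (unit 500–2000 bp × 3–20 copies, noise-free). Units *shorter* than
the window are a known limitation: the final anchor hit is partial (filtered
at 80% coverage) and periodic overlapping hits cannot all be recovered by
masked search, so one additional boundary is lost. The intended amplicon
scale (~500–730 bp) is unaffected.

## Backbone selection

Every segment of the run is tested as a potential backbone: all other
segments are aligned against it and an alignment is retained when it covers
at least 80% of the aligned segment. The candidate with the most retained
alignments wins; ties break on higher mean alignment identity, then lower
index. This favours a complete, centrally accurate copy as the starting
draft.

## Consensus by edit-distance descent

The consensus is computed as a local optimum of an explicit objective: the
sum over segments of the edit distance to the consensus (the Steiner/center
string objective). Starting from the backbone:

1. all segments are globally aligned to the current draft;
2. the resulting pileup proposes candidate single-site variants — at every
   column the best-supported non-draft base or deletion, at every
   inter-column slot the best-supported inserted string (support ≥ 2
   segments);
3. each candidate is scored by the change in summed edit distance over a
   ±18 bp window of every segment (windows are cut with the segment's own
   alignment to the draft);
4. improving variants are applied most-improving-first, skipping any whose
   window overlaps an already accepted one (they were scored against the
   same draft);
5. rounds repeat until no variant improves the total distance (bounded at
   12 rounds; convergence is typically reached in 4–8).

Ties keep the draft symbol, so the procedure is deterministic and the
backbone wins whenever the evidence is balanced.

A simpler design was tried first and measured before being replaced:
one-shot per-column/per-slot majority voting over the segment-to-backbone
alignments. It leaves a consensus error floor of ~2% at 17 segments and
~4.5% at 6 segments under the default error model — an order of magnitude
above what the copy number supports. The cause is structural, not a bug:
two co-optimal pairwise alignments may represent the same underlying
discrepancy at different columns, so votes for one variant split across
adjacent slots (worst in repeats), and the binary insert-vs-not vote is
biased in homopolymers, where the probability that a segment retains a full
k-base run is below one half for moderate k even though the run length mode
is correct. Scoring candidate variants by total edit distance is invariant
to how any individual alignment chooses to represent a discrepancy, which
removes both failure modes. Measured on simulated segments (error model
below), the descent reaches a median total error of ~0.3% at 17 segments
and ~1.5% at 6.

Final trimming mirrors conventional backbone-consensus settings: two
columns are dropped from each end (draft ends see the least informative
alignment evidence), columns below the minimum coverage (default 1) are
dropped, and a consensus shorter than 5 bases rejects the read.

## Error model of the simulator

Per template base: deletion with probability `p_del`; otherwise
substitution (to a uniformly chosen different base) with probability
`p_mismatch`; after every template base position, insertion of one uniform
random base with probability `p_ins`. Defaults `p_mismatch=0.075`,
`p_ins=0.045`, `p_del=0.045` give raw reads ~84% identity to their
template — the accuracy regime of nanopore 2D reads, with the mismatch
component (7.5%) taken from that regime and the remaining ~9% split evenly
between insertions and deletions because the split is not independently
constrained. All three probabilities are bounded in [0,1] individually;
the deletion and substitution draws are sequential and the insertion draw
is independent, so degenerate settings (e.g. `p_del=1`) are valid.

What the simulator does **not** model: homopolymer-length-dependent errors,
k-mer-dependent error profiles, quality-score structure, read-length
distributions, or chimera formation unless explicitly requested. Errors are
i.i.d. per base, which makes consensus accuracy measured here slightly
optimistic relative to real nanopore data, where errors correlate with
sequence context and copies of one molecule can fail in the same places.
Passing the accuracy benchmarks therefore demonstrates the correctness and
convergence of the algorithms under the stated error regime, not a
guarantee on any particular sequencer.

Reproducibility: every library draws per-read child RNGs from one seed
sequence, so a library is byte-for-byte reproducible and individual reads
are independent of library size and ordering.

## Chimera classification and rates

Two chimera classes with distinct read signatures:

* **Intermolecular ligation** (two templates circularized together): the
  joint template repeats, so reference labels along the read alternate
  A,B,A,B,… The simulator joins the two templates in the same or opposite
  orientation with equal probability.
* **Template switching** (polymerase jump during RCA): a block of copies of
  one template followed by a block of the other; both blocks must exceed 3
  copies to be simulated, since shorter blocks cannot survive the
  segment-count filter anyway.

Classification maps both reference groups onto the read (per-region best
hits, 80% query-coverage filter), collapses consecutive identical labels,
and calls: `alternating` when both groups appear at least twice each
(with two groups, a collapsed sequence is strictly alternating by
construction), `both_no_alt` when both appear but not twice each, `single`,
or `unmapped`. Rates divide the evidence counts by `n_total · 2·p1·p2`,
the expected fraction of chimeric pairs that cross the two groups — only
cross-group chimeras are observable; within-group chimeras between
near-identical templates are not detectable by this (or any
alignment-based) method when orientation and segment length are preserved.
Exactly two groups are supported; the caller pools near-identical
references into one group.

## Profiling

Consensus reads are self-concatenated so that any rotation of a reference
aligns contiguously, then aligned to every labeled database reference on
both strands. Hits must exceed 98% identity and 98% reference coverage
(reference coverage = aligned reference span over reference length — the
denominator is the trimmed amplicon, not the read). The species of the
highest-identity hit is assigned; an exact identity tie between different
species discards the read as ambiguous; references differing by one base
resolve without a tie because the identities differ. Abundances are
proportions over assigned reads only — ambiguous and unassigned reads are
excluded from the denominator, which is the natural reading of
"proportion of corrected reads mapped to that reference" once unusable
reads are discarded.

Classification evaluation sweeps the identity threshold (default 0.80–0.98)
over assignments produced with permissive filters and reports species-set
precision, recall and F1 (= 2PR/(P+R), 0 when P+R = 0).

A primer-trimming helper extracts the amplicon between two degenerate
primers by exact IUPAC-expanded matching (the reverse primer is matched as
its reverse complement downstream of the forward match). It is a
convenience for preparing reference databases, not a general primer
search — one exact site per primer is assumed.

## Numerical and degeneracy conventions

* Coordinates are 0-based half-open everywhere; minus-strand hits are
  stored on the query's forward coordinates with a strand flag.
* IUPAC codes other than N are collapsed to N with a warning; N matches
  nothing (scored as a mismatch).
* Empty sequences are legal in memory (an extreme error model can delete
  every base) but rejected at FASTA/FASTQ boundaries.
* All tie-breaks (anchor choice, backbone choice, variant ordering,
  co-optimal alignments) are deterministic; two runs with the same seed
  produce identical bytes.

## Benchmarks and their problem sizes

`scripts/acceptance.py` and the heavy end of the test suite use 200-read
libraries of a single 700 bp template (18 copies for the high-copy
benchmark, uniform 6–20 copies for the mixed benchmark) — large enough for
stable medians, small enough to run in a few minutes on one CPU. The
chimera-recovery, abundance-recovery and rare-species suites use
classification-level or reduced-size end-to-end simulations sized to keep
each suite within a few minutes; the rare-species check (a 0.1% species in
a 5,000-read community, zero false positives) feeds consensus-grade reads
(rotations with ~0.5% residual error) directly to the classifier, since
correcting 5,000 raw reads is far outside a desk-scale budget and the
property under test is the classifier's.

## Known limitations

* Repeat units shorter than the anchor window lose one segment boundary
  (see above).
* Chimeric reads are rejected, never split into multiple consensus reads —
  informative segments from them are discarded by design.
* The consensus descent optimizes unit-cost edit distance; an
  affine-gap or quality-weighted objective might resolve rare long-indel
  ambiguities better.
* Multi-group (>2) chimera designs and genus-level aggregation are out of
  scope.
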