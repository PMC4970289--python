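"""Tandem-repeat structure detection for concatemer reads.

A rolling-circle amplification product is a long read made of tandem copies
of one template.  The copy boundaries are found without any reference: a
window from the first half of the read (an "anchor") is aligned back to the
whole read; the starts of adjacent anchor hits delimit candidate repeat
segments, and the longest run of consecutive segments with a single
orientation and concordant lengths (within 5% of the run's median) is kept.
Reads yielding fewer than ``min_segments`` (default 6) concordant segments
are rejected — too few copies give an unreliable consensus.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Sequence

from .align import AlignParams, DEFAULT_PARAMS, LocalAlignment, local_align
from .io_formats import SequenceRecord, revcomp

__all__ = [
    "Anchor",
    "Segment",
    "SegmentRun",
    "SegmenterError",
    "extract_anchors",
    "map_anchors",
    "select_anchor",
    "segments_from_hits",
    "longest_concordant_run",
    "segment_read",
    "DEFAULT_WINDOW",
    "DEFAULT_MIN_SEGMENTS",
    "LENGTH_TOLERANCE",
]

DEFAULT_WINDOW = 500
DEFAULT_MIN_SEGMENTS = 6
LENGTH_TOLERANCE = 0.05  # max fractional deviation from the run median length


class SegmenterError(ValueError):
    """Raised when a read cannot be segmented; ``reason`` is machine-readable."""

    def __init__(self, reason: str, message: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {message}" if message else reason)


@dataclass(frozen=True)
class Anchor:
    """A fixed-length window from the first half of a read."""

    index: int
    read_start: int
    read_end: int
    seq: str


@dataclass
class Segment:
    """One putative repeat unit: the stretch between two adjacent anchor hits.

    ``seq`` is oriented: minus-strand segments are stored reverse-complemented
    so that consensus construction sees a single orientation.
    """

    read_start: int
    read_end: int
    strand: str
    seq: str
    anchor_identity: float

    def __len__(self) -> int:
        return self.read_end - self.read_start


@dataclass
class SegmentRun:
    """The accepted run of concordant segments for one read."""

    segments: list[Segment]
    median_len: float
    read_id: str

    def __len__(self) -> int:
        return len(self.segments)


def extract_anchors(read: SequenceRecord, window: int = DEFAULT_WINDOW) -> list[Anchor]:
    """Non-overlapping ``window``-sized anchors at offsets 0, window, 2*window, ...

    Anchors are only taken while the offset is in the first half of the read
    (start < len/2); a window starting before the midpoint may extend past it.
    Reads shorter than one window yield no anchors.
    """
    n = len(read.seq)
    anchors = []
    start = 0
    while start < n / 2 and start + window <= n:
        anchors.append(
            Anchor(
                index=len(anchors),
                read_start=start,
                read_end=start + window,
                seq=read.seq[start : start + window],
            )
        )
        start += window
    return anchors


def map_anchors(
    anchors: Sequence[Anchor],
    read: SequenceRecord,
    params: AlignParams = DEFAULT_PARAMS,
    min_anchor_coverage: float = 0.8,
    engine: str = "edlib",
) -> list[list[LocalAlignment]]:
    """Align each anchor back onto its read; keep hits covering >= 80% of the
    anchor, sorted by read position.

    The edit-distance engine is the default: an anchor either aligns along
    its whole length within the seeding threshold (a genuine repeat copy) or
    not at all, which mirrors the coverage filter while avoiding the end
    trimming of score-based local alignment at read-vs-read divergence."""
    out: list[list[LocalAlignment]] = []
    for anchor in anchors:
        # hits of one anchor may legitimately overlap when the repeat unit is
        # shorter than the anchor window, so allow up to half-window overlap
        hits = [
            h
            for h in local_align(anchor.seq, read, params, both_strands=True,
                                 engine=engine, overlap_tol=len(anchor.seq) // 2)
            if h.query_coverage() >= min_anchor_coverage
        ]
        hits.sort(key=lambda h: h.t_start)
        out.append(hits)
    return out


def select_anchor(per_anchor_hits: Sequence[Sequence[LocalAlignment]]) -> int:
    """Pick the anchor with the most retained hits.

    Ties break on higher mean hit identity, then on lower anchor index, so
    the choice is deterministic.
    """
    best = -1
    best_key = None
    for i, hits in enumerate(per_anchor_hits):
        if not hits:
            continue
        mean_ident = sum(h.identity() for h in hits) / len(hits)
        key = (len(hits), mean_ident, -i)
        if best_key is None or key > best_key:
            best_key = key
            best = i
    if best < 0:
        raise SegmenterError("no_anchor", "no anchor produced any retained alignment")
    return best


def segments_from_hits(
    hits: Sequence[LocalAlignment], read: SequenceRecord
) -> list[Segment]:
    """Candidate repeat segments between adjacent anchor hit starts.

    The start of each hit is extended 5'-ward by the anchor bases clipped at
    the hit's 5' end (in read orientation), so segments are as complete as
    possible; the extension is floored at 0 and at the previous segment's
    start so segments never overlap.  n hits yield n-1 segments, each taking
    the strand of its left-bounding hit.
    """
    if len(hits) < 2:
        raise SegmenterError("single_hit", "need at least two anchor hits")
    starts: list[int] = []
    for hit in sorted(hits, key=lambda h: h.t_start):
        adj = max(0, hit.t_start - hit.clip5())
        if starts:
            adj = max(adj, starts[-1] + 1)
        starts.append(adj)
    segments = []
    hits_sorted = sorted(hits, key=lambda h: h.t_start)
    for i in range(len(starts) - 1):
        s, e = starts[i], starts[i + 1]
        strand = hits_sorted[i].strand
        seq = read.seq[s:e]
        if strand == "-":
            seq = revcomp(seq)
        segments.append(
            Segment(
                read_start=s,
                read_end=e,
                strand=strand,
                seq=seq,
                anchor_identity=hits_sorted[i].identity(),
            )
        )
    return segments


def _trim_to_median(block: list[Segment]) -> list[Segment]:
    """Within one strand-concordant block, drop segments deviating more than
    5% from the block's median length and return the longest stretch of
    consecutive survivors."""
    med = median(len(s) for s in block)
    ok = [abs(len(s) - med) <= LENGTH_TOLERANCE * med for s in block]
    best_start = best_len = 0
    cur_start = cur_len = 0
    for i, flag in enumerate(ok):
        if flag:
            if cur_len == 0:
                cur_start = i
            cur_len += 1
            if cur_len > best_len:
                best_start, best_len = cur_start, cur_len
        else:
            cur_len = 0
    return block[best_start : best_start + best_len]


def longest_concordant_run(
    segments: Sequence[Segment],
    read_id: str = "",
    min_segments: int = DEFAULT_MIN_SEGMENTS,
) -> SegmentRun:
    """Longest run of consecutive segments with one orientation and lengths
    within 5% of the run median.

    The segment list is first split into maximal same-strand blocks; within
    each block the median length is computed once, outliers are dropped and
    the longest consecutive surviving stretch is the block's candidate run.
    The candidate with the most segments wins (ties: earlier on the read).
    A best run shorter than ``min_segments`` rejects the read.
    """
    blocks: list[list[Segment]] = []
    for seg in segments:
        if blocks and blocks[-1][-1].strand == seg.strand:
            blocks[-1].append(seg)
        else:
            blocks.append([seg])

    best: list[Segment] = []
    best_med = 0.0
    for block in blocks:
        med = median(len(s) for s in block)
        run = _trim_to_median(block)
        if len(run) > len(best):
            best = run
            best_med = med
    if len(best) < min_segments:
        raise SegmenterError(
            "too_few_segments",
            f"best concordant run has {len(best)} segments (< {min_segments})",
        )
    return SegmentRun(segments=list(best), median_len=best_med, read_id=read_id)


def segment_read(
    read: SequenceRecord,
    window: int = DEFAULT_WINDOW,
    min_segments: int = DEFAULT_MIN_SEGMENTS,
    params: AlignParams = DEFAULT_PARAMS,
    engine: str = "edlib",
) -> SegmentRun:
    """Full segmentation of one read; raises :class:`SegmenterError` with a
    reason (no_anchor, single_hit, too_few_segments) when the read fails."""
    anchors = extract_anchors(read, window)
    if not anchors:
        raise SegmenterError("no_anchor", f"read shorter than anchor window {window}")
    per_anchor = map_anchors(anchors, read, params, engine=engine)
    chosen = select_anchor(per_anchor)
    segments = segments_from_hits(per_anchor[chosen], read)
    return longest_concordant_run(segments, read_id=read.id, min_segments=min_segments)
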