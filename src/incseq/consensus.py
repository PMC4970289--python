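"""Backbone selection and consensus construction for a segment run.

Each segment of the accepted run is tested as a potential backbone by
aligning every other segment against it; the candidate gathering the most
retained alignments wins (ties: higher mean alignment identity, then lower
index).  The backbone then serves as the initial draft of the consensus.

The consensus itself is computed by steepest descent on the total edit
distance between the draft and the segments.  Each round, all segments are
globally aligned to the draft; the resulting pileup proposes candidate
single-site variants (the best-supported non-draft base, deletion, or
inserted string at every position); each candidate is scored by the change
in summed edit distance over a local window of every segment, and the
improving, non-interacting variants are applied.  Rounds repeat until no
variant improves the total distance.

Plain per-column majority voting is not used as the final step because two
co-optimal alignments can place the same discrepancy at different columns:
in repeats and homopolymers the votes for one underlying variant split
across adjacent slots, which biases a one-shot vote toward deletions and
leaves consensus errors an order of magnitude above what the segment count
supports.  Scoring candidate variants by total edit distance is invariant
to how individual alignments represent a discrepancy, so the descent
converges to a local Steiner-string optimum regardless of gap placement.

The draft's symbol wins all ties (only strictly improving variants are
accepted), two columns are trimmed from each end of the final consensus and
a consensus shorter than five bases is rejected — the conventional trim and
minimum-length settings of backbone-based consensus polishing.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import edlib

from .align import AlignParams, DEFAULT_PARAMS, _parse_edlib_cigar, local_align
from .io_formats import SequenceRecord
from .segmenter import (
    DEFAULT_MIN_SEGMENTS,
    DEFAULT_WINDOW,
    SegmenterError,
    SegmentRun,
    segment_read,
)

__all__ = [
    "ConsensusRead",
    "ConsensusParams",
    "select_backbone",
    "build_consensus",
    "correct_read",
    "correct_library",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConsensusParams:
    """Knobs of the consensus stage.

    end_trim: bases dropped at each end of the final consensus (the draft
        ends see the fewest informative alignments).
    min_coverage: minimum segments aligned across a draft column for the
        column to be emitted; global alignment covers every column, so the
        default keeps all of them.
    min_length: minimum consensus length, else the read is rejected.
    min_segment_coverage: fraction of a segment that must align to a
        backbone candidate for the alignment to count during backbone
        selection.
    window: half-width (bases) of the local window used to score candidate
        variants during polishing.
    min_variant_votes: pileup support needed before a variant is scored.
    max_rounds: upper bound on polishing rounds (descent usually converges
        earlier).
    """

    end_trim: int = 2
    min_coverage: int = 1
    min_length: int = 5
    min_segment_coverage: float = 0.8
    window: int = 18
    min_variant_votes: int = 2
    max_rounds: int = 12


DEFAULT_CONSENSUS = ConsensusParams()


@dataclass
class ConsensusRead:
    """Corrected single-molecule sequence plus provenance metadata."""

    read_id: str
    seq: str
    n_segments: int
    backbone_index: int
    per_segment_identity: list[float] = field(default_factory=list)
    status: str = "ok"

    @property
    def ok(self) -> bool:
        return self.status == "ok"

    @classmethod
    def rejected(cls, read_id: str, reason: str) -> "ConsensusRead":
        return cls(read_id=read_id, seq="", n_segments=0, backbone_index=-1,
                   per_segment_identity=[], status=f"rejected:{reason}")

    def to_record(self) -> SequenceRecord:
        if not self.ok:
            raise ValueError(f"consensus for {self.read_id!r} was {self.status}")
        return SequenceRecord(
            id=self.read_id,
            seq=self.seq,
            description=f"n_segments={self.n_segments}",
        )


def select_backbone(
    run: SegmentRun,
    params: AlignParams = DEFAULT_PARAMS,
    cparams: ConsensusParams = DEFAULT_CONSENSUS,
    engine: str = "edlib",
) -> int:
    """Index of the segment best supported as an alignment backbone.

    For each candidate, count the other segments that produce a retained
    alignment against it (covering >= min_segment_coverage of themselves).
    The edit-distance engine is the default: only counts and identities
    matter here, and the candidate sweep is quadratic in segment number.
    """
    if len(run) < 2:
        raise ValueError("backbone selection needs at least two segments")
    best_idx = 0
    best_key = None
    for i, cand in enumerate(run.segments):
        count = 0
        idents = []
        for j, other in enumerate(run.segments):
            if i == j:
                continue
            hits = local_align(other.seq, cand.seq, params, both_strands=False,
                               engine=engine, max_hits=1)
            if hits and hits[0].query_coverage() >= cparams.min_segment_coverage:
                count += 1
                idents.append(hits[0].identity())
        mean_ident = sum(idents) / len(idents) if idents else 0.0
        key = (count, mean_ident, -i)
        if best_key is None or key > best_key:
            best_key = key
            best_idx = i
    return best_idx


def _pileup(draft: str, segs: Sequence[str]):
    """Global-align every segment to the draft; collect per-column base
    votes, per-slot insertion votes, coverage, and for each segment the
    query offset at every draft position (used to cut scoring windows)."""
    L = len(draft)
    base_votes: list[Counter] = [Counter() for _ in range(L)]
    ins_votes: list[Counter] = [Counter() for _ in range(L + 1)]
    coverage = [0] * L
    qmaps: list[list[int]] = []
    identities: list[float] = []
    for s in segs:
        res = edlib.align(s, draft, mode="NW", task="path")
        ops, nm, nx, ni, nd = _parse_edlib_cigar(res["cigar"])
        identities.append(nm / max(1, nm + nx + ni + nd))
        qmap = [0] * (L + 1)
        t = q = 0
        pending = ""
        for op, n in ops:
            if op in ("M", "X"):
                for _ in range(n):
                    if pending:
                        ins_votes[t][pending] += 1
                        pending = ""
                    qmap[t] = q
                    base_votes[t][s[q]] += 1
                    coverage[t] += 1
                    t += 1
                    q += 1
            elif op == "D":
                for _ in range(n):
                    if pending:
                        ins_votes[t][pending] += 1
                        pending = ""
                    qmap[t] = q
                    base_votes[t]["-"] += 1
                    coverage[t] += 1
                    t += 1
            else:  # I
                pending += s[q : q + n]
                q += n
        if pending:
            ins_votes[L][pending] += 1
        qmap[L] = len(s)
        qmaps.append(qmap)
    return base_votes, ins_votes, coverage, qmaps


def _edit_distance(a: str, b: str) -> int:
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, mode="NW")["editDistance"]


def _polish_round(draft: str, segs: Sequence[str], cparams: ConsensusParams):
    """One descent round: propose variants from the pileup, score each by
    the change in summed edit distance over local windows, apply the
    improving non-interacting ones (most improving first)."""
    L = len(draft)
    W = cparams.window
    base_votes, ins_votes, _, qmaps = _pileup(draft, segs)

    candidates: list[tuple[int, str, str | None]] = []
    for c in range(L):
        others = sorted(
            ((v, b) for b, v in base_votes[c].items() if b != draft[c]),
            key=lambda vb: (-vb[0], vb[1]),
        )
        if others and others[0][0] >= cparams.min_variant_votes:
            _, b = others[0]
            candidates.append((c, "del" if b == "-" else "sub", None if b == "-" else b))
    for c in range(L + 1):
        if ins_votes[c]:
            s, v = sorted(ins_votes[c].items(), key=lambda kv: (-kv[1], kv[0]))[0]
            if v >= cparams.min_variant_votes:
                candidates.append((c, "ins", s))

    scored: list[tuple[int, int, str, str | None]] = []
    for pos, kind, payload in candidates:
        a, b = max(0, pos - W), min(L, pos + W)
        ref_win = draft[a:b]
        if kind == "sub":
            alt_win = draft[a:pos] + payload + draft[pos + 1 : b]
        elif kind == "del":
            alt_win = draft[a:pos] + draft[pos + 1 : b]
        else:
            alt_win = draft[a:pos] + payload + draft[pos:b]
        delta = 0
        for s, qmap in zip(segs, qmaps):
            vwin = s[qmap[a] : qmap[b]]
            delta += _edit_distance(vwin, alt_win) - _edit_distance(vwin, ref_win)
        if delta < 0:
            scored.append((delta, pos, kind, payload))

    scored.sort(key=lambda t: (t[0], t[1], t[2]))
    accepted: list[tuple[int, str, str | None]] = []
    used: list[int] = []
    for delta, pos, kind, payload in scored:
        # variants scored against the same draft must not share windows
        if any(abs(pos - p) < 2 * W for p in used):
            continue
        used.append(pos)
        accepted.append((pos, kind, payload))

    out = list(draft)
    for pos, kind, payload in sorted(accepted, reverse=True):
        if kind == "sub":
            out[pos] = payload
        elif kind == "del":
            del out[pos]
        else:
            out.insert(pos, payload)
    return "".join(out), len(accepted)


def build_consensus(
    run: SegmentRun,
    backbone_index: int,
    params: AlignParams = DEFAULT_PARAMS,
    cparams: ConsensusParams = DEFAULT_CONSENSUS,
    min_segments: int = DEFAULT_MIN_SEGMENTS,
) -> ConsensusRead:
    """Consensus of a segment run, polished from the chosen backbone."""
    if not (0 <= backbone_index < len(run)):
        raise ValueError("backbone index out of range")
    if len(run) < min_segments:
        return ConsensusRead.rejected(run.read_id, "too_few_segments")
    segs = [seg.seq for seg in run.segments]
    draft = segs[backbone_index]
    if not draft:
        return ConsensusRead.rejected(run.read_id, "backbone_alignment_failed")

    best = draft
    best_total = sum(_edit_distance(s, best) for s in segs)
    for _ in range(cparams.max_rounds):
        nxt, n_accepted = _polish_round(best, segs, cparams)
        if n_accepted == 0:
            break
        total = sum(_edit_distance(s, nxt) for s in segs)
        if total >= best_total:
            break
        best, best_total = nxt, total

    base_votes, _, coverage, _ = _pileup(best, segs)
    kept = [
        best[c]
        for c in range(len(best))
        if coverage[c] >= cparams.min_coverage
    ]
    trim = cparams.end_trim
    seq = "".join(kept)[trim : len(kept) - trim if trim else None]
    if len(seq) < cparams.min_length:
        return ConsensusRead.rejected(run.read_id, "consensus_too_short")

    identities = []
    for s in segs:
        res = edlib.align(s, best, mode="NW", task="path")
        _, nm, nx, ni, nd = _parse_edlib_cigar(res["cigar"])
        identities.append(nm / max(1, nm + nx + ni + nd))
    return ConsensusRead(
        read_id=run.read_id,
        seq=seq,
        n_segments=len(run),
        backbone_index=backbone_index,
        per_segment_identity=identities,
    )


def correct_read(
    read: SequenceRecord,
    window: int = DEFAULT_WINDOW,
    min_segments: int = DEFAULT_MIN_SEGMENTS,
    params: AlignParams = DEFAULT_PARAMS,
    cparams: ConsensusParams = DEFAULT_CONSENSUS,
    engine: str = "edlib",
) -> ConsensusRead:
    """Run the whole correction pipeline on one raw read.

    Segmentation failures come back as rejected :class:`ConsensusRead`
    objects with machine-readable reasons rather than exceptions, so
    library-level callers can tally them.
    """
    try:
        run = segment_read(read, window=window, min_segments=min_segments,
                           params=params, engine=engine)
    except SegmenterError as exc:
        return ConsensusRead.rejected(read.id, exc.reason)
    backbone = select_backbone(run, params, cparams)
    return build_consensus(run, backbone, params, cparams, min_segments=min_segments)


def correct_library(
    reads: Sequence[SequenceRecord],
    progress: bool = False,
    **kwargs,
) -> list[ConsensusRead]:
    """Correct a collection of reads, logging summary counters."""
    results = []
    iterator = reads
    if progress:
        try:
            from tqdm import tqdm

            iterator = tqdm(reads, unit="read")
        except ImportError:  # pragma: no cover
            pass
    for read in iterator:
        results.append(correct_read(read, **kwargs))
    n_ok = sum(r.ok for r in results)
    logger.info("corrected %d/%d reads (%d rejected)",
                n_ok, len(results), len(results) - n_ok)
    return results
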