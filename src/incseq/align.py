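"""Local pairwise alignment on both strands.

This is the single alignment engine behind anchor mapping, segment-vs-backbone
alignment, chimera classification, quality assessment and profiling.  The
scoring model is affine-gap Smith-Waterman (Biopython's PairwiseAligner does
the dynamic programming); on top of it this module adds what the pipeline
actually needs:

* multiple non-overlapping hits per query on one target, recovered by greedy
  masked realignment (one anchor occurs many times in a concatemer read);
* a seed-and-refine fast path for long targets, where edlib's bit-parallel
  infix search locates candidate hit spans and the affine aligner refines
  each span (validated against full masked realignment in the test suite);
* a pure edit-distance engine ("edlib") for bulk screening steps where only
  counts and identities are needed.

Coordinates are 0-based half-open throughout.  Minus-strand hits are reported
on the query's forward coordinates with a strand flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import edlib
from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import SequenceRecord, revcomp

__all__ = [
    "AlignParams",
    "LocalAlignment",
    "RegionHit",
    "local_align",
    "map_to_regions",
    "DEFAULT_PARAMS",
]

_ALPHABET = "ACGTN#"  # '#' is the mask character; it matches nothing
_MASK_SCORE = -(10**6)


@dataclass(frozen=True)
class AlignParams:
    """Affine-gap local alignment scoring.

    A gap of length L costs ``gap_open + L * gap_extend``.  ``min_score`` is
    the reporting threshold (hits below it are dropped); with match=+1 it is
    roughly the minimum usable anchor/amplicon overlap length after errors.
    """

    match: int = 1
    mismatch: int = 2
    gap_open: int = 3
    gap_extend: int = 1
    min_score: int = 40

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if min(self.mismatch, self.gap_open, self.gap_extend) < 0:
            raise ValueError("penalties must be non-negative")
        if self.gap_open < self.gap_extend:
            raise ValueError("gap_open must be >= gap_extend")

    def score_of_counts(self, n_match: int, n_mismatch: int, n_ins: int, n_del: int) -> int:
        """Score of an alignment under this model, charging each indel run
        as a single gap opening (lower bound used for edit-distance hits:
        contiguous runs are not tracked there, so every indel base is charged
        an opening).  Exact for gap-free alignments."""
        score = self.match * n_match - self.mismatch * n_mismatch
        for n in (n_ins, n_del):
            if n:
                score -= self.gap_open + self.gap_extend * n
        return score


DEFAULT_PARAMS = AlignParams()


@dataclass
class LocalAlignment:
    """One local alignment of a query onto a target.

    ``ops`` is a run-length encoded edit script over {M, X, I, D} in target
    orientation (I = base present in query, absent from target).  For
    minus-strand hits the script refers to the reverse-complemented query,
    while ``q_start``/``q_end`` are on the query's forward coordinates.
    """

    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str
    score: int
    n_match: int
    n_mismatch: int
    n_ins: int
    n_del: int
    q_len: int
    ops: list[tuple[str, int]] = field(default_factory=list, repr=False)

    def identity(self) -> float:
        denom = self.n_match + self.n_mismatch + self.n_ins + self.n_del
        return self.n_match / denom if denom else 0.0

    def query_coverage(self) -> float:
        return (self.q_end - self.q_start) / self.q_len

    def alignment_length(self) -> int:
        return self.n_match + self.n_mismatch + self.n_ins + self.n_del

    def clip5(self) -> int:
        """Unaligned query bases 5' of the hit, in *target* orientation."""
        return self.q_start if self.strand == "+" else self.q_len - self.q_end

    def _check(self) -> None:
        assert self.q_end - self.q_start == self.n_match + self.n_mismatch + self.n_ins
        assert self.t_end - self.t_start == self.n_match + self.n_mismatch + self.n_del


def _aligner(params: AlignParams) -> Align.PairwiseAligner:
    matrix = substitution_matrices.Array(_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            if a == "#" or b == "#":
                matrix[a, b] = _MASK_SCORE
            elif a == "N" or b == "N":
                matrix[a, b] = -params.mismatch
            elif a == b:
                matrix[a, b] = params.match
            else:
                matrix[a, b] = -params.mismatch
    aligner = Align.PairwiseAligner(mode="local")
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def _ops_and_counts(coords, qseq: str, tseq: str):
    """Run-length edit script and counts from a PairwiseAligner path."""
    t_pts, q_pts = coords[0], coords[1]
    ops: list[tuple[str, int]] = []
    nm = nx = ni = nd = 0

    def push(op: str, n: int) -> None:
        if n == 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    for k in range(len(t_pts) - 1):
        t0, t1 = int(t_pts[k]), int(t_pts[k + 1])
        q0, q1 = int(q_pts[k]), int(q_pts[k + 1])
        if t1 > t0 and q1 > q0:
            for a, b in zip(qseq[q0:q1], tseq[t0:t1]):
                if a == b and a != "N":
                    push("M", 1)
                    nm += 1
                else:
                    push("X", 1)
                    nx += 1
        elif q1 > q0:
            push("I", q1 - q0)
            ni += q1 - q0
        elif t1 > t0:
            push("D", t1 - t0)
            nd += t1 - t0
    return ops, nm, nx, ni, nd


def _sw_best(qseq: str, tseq: str, params: AlignParams) -> LocalAlignment | None:
    """Best affine-gap local alignment (plus strand, raw coordinates)."""
    aligner = _aligner(params)
    alns = aligner.align(tseq, qseq)  # Biopython order: (target, query)
    try:
        best = alns[0]
    except IndexError:
        return None
    if best.score <= 0:
        return None
    coords = best.coordinates
    t_start, t_end = int(coords[0][0]), int(coords[0][-1])
    q_start, q_end = int(coords[1][0]), int(coords[1][-1])
    ops, nm, nx, ni, nd = _ops_and_counts(coords, qseq, tseq)
    hit = LocalAlignment(
        q_start=q_start,
        q_end=q_end,
        t_start=t_start,
        t_end=t_end,
        strand="+",
        score=int(round(best.score)),
        n_match=nm,
        n_mismatch=nx,
        n_ins=ni,
        n_del=nd,
        q_len=len(qseq),
        ops=ops,
    )
    hit._check()
    return hit


def _mask(t: str, start: int, end: int) -> str:
    return t[:start] + "#" * (end - start) + t[end:]


def _sw_multi(qseq: str, tseq: str, params: AlignParams, max_hits: int) -> list[LocalAlignment]:
    """All local hits of one oriented query, by exact masked realignment."""
    hits: list[LocalAlignment] = []
    masked = tseq
    while len(hits) < max_hits:
        hit = _sw_best(qseq, masked, params)
        if hit is None or hit.score < params.min_score:
            break
        hits.append(hit)
        masked = _mask(masked, hit.t_start, hit.t_end)
    return hits


def _seeded_multi(
    qseq: str,
    tseq: str,
    params: AlignParams,
    max_hits: int,
    max_edit_frac: float,
    pad: int,
) -> list[LocalAlignment]:
    """Seed hit spans with edlib infix search, refine each with the affine
    aligner on a padded window.  Partial copies whose edit distance exceeds
    the seeding threshold produce no seed; those are exactly the hits the
    80%-coverage filters downstream would discard."""
    hits: list[LocalAlignment] = []
    masked = tseq
    k = max(1, int(max_edit_frac * len(qseq)))
    for _ in range(3 * max_hits):
        if len(hits) >= max_hits:
            break
        res = edlib.align(qseq, masked, mode="HW", task="locations", k=k)
        if res["editDistance"] == -1:
            break
        s, e = res["locations"][0]
        e += 1  # edlib end is inclusive
        ws, we = max(0, s - pad), min(len(tseq), e + pad)
        hit = _sw_best(qseq, masked[ws:we], params)
        if hit is not None:
            hit.t_start += ws
            hit.t_end += ws
        if hit is not None and hit.score >= params.min_score:
            hits.append(hit)
            lo, hi = min(s, hit.t_start), max(e, hit.t_end)
        else:
            lo, hi = s, e
        masked = _mask(masked, lo, hi)
    return hits


def _edlib_multi(
    qseq: str,
    tseq: str,
    params: AlignParams,
    max_hits: int,
    max_edit_frac: float,
) -> list[LocalAlignment]:
    """Edit-distance engine: whole query aligned into the target (infix mode),
    counts from the edit script, score derived from the counts.  Used for bulk
    counting/screening; end-clipping is not modelled (coverage is always 1)."""
    hits: list[LocalAlignment] = []
    masked = tseq
    k = max(1, int(max_edit_frac * len(qseq)))
    for _ in range(3 * max_hits):
        if len(hits) >= max_hits:
            break
        res = edlib.align(qseq, masked, mode="HW", task="locations", k=k)
        if res["editDistance"] == -1:
            break
        # co-optimal locations (all at the same distance) are processed in one
        # batch: exact tandem repeats yield them all at once
        batch: list[tuple[int, int]] = []
        for s, e in res["locations"]:
            e += 1
            if any(min(e, be) - max(s, bs) > 0 for bs, be in batch):
                continue
            batch.append((s, e))
        for s, e in batch:
            span = edlib.align(qseq, masked[s:e], mode="NW", task="path")
            ops, nm, nx, ni, nd = _parse_edlib_cigar(span["cigar"])
            # unpaired query ends (insertions at the span boundary, e.g. an
            # anchor running off the read end) count as clipped, not aligned
            q0, q1 = 0, len(qseq)
            if ops and ops[0][0] == "I":
                q0 = ops[0][1]
                ni -= ops[0][1]
                ops = ops[1:]
            if ops and ops[-1][0] == "I":
                q1 -= ops[-1][1]
                ni -= ops[-1][1]
                ops = ops[:-1]
            score = params.score_of_counts(nm, nx, ni, nd)
            if score >= params.min_score:
                hit = LocalAlignment(
                    q_start=q0,
                    q_end=q1,
                    t_start=s,
                    t_end=e,
                    strand="+",
                    score=score,
                    n_match=nm,
                    n_mismatch=nx,
                    n_ins=ni,
                    n_del=nd,
                    q_len=len(qseq),
                    ops=ops,
                )
                hit._check()
                hits.append(hit)
            masked = _mask(masked, s, e)
    return hits


def _parse_edlib_cigar(cigar: str):
    """Counts from edlib's extended CIGAR (=, X, I, D; I = extra query base)."""
    ops: list[tuple[str, int]] = []
    nm = nx = ni = nd = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "=":
            ops.append(("M", n))
            nm += n
        elif ch == "X":
            ops.append(("X", n))
            nx += n
        elif ch == "I":
            ops.append(("I", n))
            ni += n
        elif ch == "D":
            ops.append(("D", n))
            nd += n
        else:  # pragma: no cover - edlib emits only =XID
            raise ValueError(f"unexpected CIGAR op {ch!r}")
    return ops, nm, nx, ni, nd


def _flip_to_forward(hit: LocalAlignment) -> LocalAlignment:
    """Convert a hit computed on the reverse-complemented query to forward
    query coordinates with a '-' strand flag."""
    q_start = hit.q_len - hit.q_end
    q_end = hit.q_len - hit.q_start
    hit.q_start, hit.q_end = q_start, q_end
    hit.strand = "-"
    return hit


def _select_nonoverlapping(
    hits: list[LocalAlignment], overlap_tol: int
) -> list[LocalAlignment]:
    """Greedy selection by descending score (ties: leftmost target start),
    discarding hits overlapping an accepted hit by more than ``overlap_tol``
    bases on the target."""
    kept: list[LocalAlignment] = []
    for hit in sorted(hits, key=lambda h: (-h.score, h.t_start, h.strand)):
        ok = True
        for other in kept:
            overlap = min(hit.t_end, other.t_end) - max(hit.t_start, other.t_start)
            if overlap > overlap_tol:
                ok = False
                break
        if ok:
            kept.append(hit)
    kept.sort(key=lambda h: (-h.score, h.t_start))
    return kept


# Targets above this area use the seeded fast path under engine="auto".
_EXACT_AREA_LIMIT = 2_500_000


def local_align(
    query: SequenceRecord | str,
    target: SequenceRecord | str,
    params: AlignParams = DEFAULT_PARAMS,
    both_strands: bool = True,
    engine: str = "auto",
    max_hits: int = 200,
    overlap_tol: int = 20,
    max_edit_frac: float = 0.45,
    seed_pad: int = 60,
) -> list[LocalAlignment]:
    """All non-overlapping local alignments of ``query`` onto ``target``.

    Returns hits sorted by descending score, each with score >= min_score,
    mutually non-overlapping on the target beyond ``overlap_tol`` bases.
    ``engine`` is one of ``sw`` (exact masked realignment), ``seeded``
    (edlib-seeded, affine-refined), ``edlib`` (pure edit distance) or
    ``auto`` (exact for small problems, seeded for long targets).
    """
    qseq = query.seq if isinstance(query, SequenceRecord) else query.upper()
    tseq = target.seq if isinstance(target, SequenceRecord) else target.upper()
    if not qseq or not tseq:
        raise ValueError("query and target must be non-empty")

    if engine == "auto":
        engine = "sw" if len(qseq) * len(tseq) <= _EXACT_AREA_LIMIT else "seeded"

    def run(q: str) -> list[LocalAlignment]:
        if engine == "sw":
            return _sw_multi(q, tseq, params, max_hits)
        if engine == "seeded":
            return _seeded_multi(q, tseq, params, max_hits, max_edit_frac, seed_pad)
        if engine == "edlib":
            return _edlib_multi(q, tseq, params, max_hits, max_edit_frac)
        raise ValueError(f"unknown engine {engine!r}")

    hits = run(qseq)
    if both_strands:
        hits += [_flip_to_forward(h) for h in run(revcomp(qseq))]
    return _select_nonoverlapping(hits, overlap_tol)


@dataclass
class RegionHit:
    """A per-region best hit: which query owns a stretch of the read."""

    query_id: str
    alignment: LocalAlignment

    @property
    def read_start(self) -> int:
        return self.alignment.t_start

    @property
    def read_end(self) -> int:
        return self.alignment.t_end


def map_to_regions(
    queries: Sequence[SequenceRecord],
    read: SequenceRecord,
    params: AlignParams = DEFAULT_PARAMS,
    min_query_coverage: float = 0.8,
    engine: str = "auto",
    overlap_tol: int = 20,
    **kwargs,
) -> list[RegionHit]:
    """Tile a read with the best hit per region among several queries.

    Every query is aligned on both strands; hits covering less than
    ``min_query_coverage`` of their query are discarded, and where hits from
    different queries overlap on the read beyond ``overlap_tol`` only the
    higher-scoring one is kept (score stands in for e-value; ties go to the
    leftmost read start).  Results are sorted by read coordinate.
    """
    tagged: list[RegionHit] = []
    for q in queries:
        for hit in local_align(q, read, params, both_strands=True, engine=engine,
                               overlap_tol=overlap_tol, **kwargs):
            if hit.query_coverage() >= min_query_coverage:
                tagged.append(RegionHit(q.id, hit))

    kept: list[RegionHit] = []
    for rh in sorted(tagged, key=lambda r: (-r.alignment.score, r.read_start)):
        ok = True
        for other in kept:
            overlap = min(rh.read_end, other.read_end) - max(rh.read_start, other.read_start)
            if overlap > overlap_tol:
                ok = False
                break
        if ok:
            kept.append(rh)
    kept.sort(key=lambda r: r.read_start)
    return kept
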