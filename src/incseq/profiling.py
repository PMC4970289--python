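"""Taxonomic assignment, abundance profiles, error decomposition and scoring.

Consensus reads inherit an arbitrary start point from the circularized
template, so before classification each read is self-concatenated: any
rotation of a reference then aligns to it full length.  Classification is
best-hit: the read is aligned to every labeled reference on both strands,
hits are filtered on reference coverage and identity (both > 0.98 in
profiling mode, the stringency needed to separate near-identical 16S
sequences), the species of the highest-identity hit is assigned, and reads
where two or more species tie exactly are discarded as ambiguous.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .align import AlignParams, DEFAULT_PARAMS, LocalAlignment, local_align, map_to_regions
from .consensus import ConsensusRead
from .io_formats import SequenceRecord

__all__ = [
    "AMBIGUOUS",
    "UNASSIGNED",
    "TaxAssignment",
    "ErrorProfile",
    "species_of",
    "self_concatenate",
    "classify",
    "abundance_profile",
    "assess_errors",
    "compare_to_reference_circular",
    "evaluate_classification",
    "trim_primers",
]

AMBIGUOUS = "AMBIGUOUS"
UNASSIGNED = "UNASSIGNED"

_SPECIES_RE = re.compile(r"species=(\S+)")


def species_of(ref: SequenceRecord) -> str:
    """Species label embedded in a reference header as ``species=<label>``."""
    m = _SPECIES_RE.search(ref.description)
    if not m:
        raise ValueError(f"reference {ref.id!r} carries no species=<label> tag")
    return m.group(1)


@dataclass
class TaxAssignment:
    """Best-hit species call for one read."""

    read_id: str
    species: str  # a label, AMBIGUOUS or UNASSIGNED
    identity: float
    ref_coverage: float

    @property
    def labeled(self) -> bool:
        return self.species not in (AMBIGUOUS, UNASSIGNED)


@dataclass
class ErrorProfile:
    """Alignment-based error decomposition for one read.

    Rates are counts over the alignment length (matches + mismatches +
    insertions + deletions), so rate_total = 1 - identity.
    """

    read_id: str
    rate_mismatch: float
    rate_ins: float
    rate_del: float

    @property
    def rate_total(self) -> float:
        return self.rate_mismatch + self.rate_ins + self.rate_del


def self_concatenate(read: ConsensusRead | SequenceRecord) -> SequenceRecord:
    """Duplicate a read head-to-tail so any rotation of its template aligns
    contiguously (recovers the unknown start point of a circular template)."""
    rec = read.to_record() if isinstance(read, ConsensusRead) else read
    if not rec.seq:
        raise ValueError(f"record {rec.id!r} is empty; cannot self-concatenate")
    return SequenceRecord(
        id=rec.id,
        seq=rec.seq + rec.seq,
        description=(rec.description + " self-concatenated").strip(),
    )


def _best_hit_per_ref(
    read: SequenceRecord,
    db: Sequence[SequenceRecord],
    params: AlignParams,
    engine: str,
    **align_kwargs,
) -> list[tuple[SequenceRecord, LocalAlignment]]:
    """Best alignment of each reference onto the self-concatenated read."""
    target = self_concatenate(read)
    out = []
    for ref in db:
        hits = local_align(ref, target, params, both_strands=True,
                           engine=engine, max_hits=1, **align_kwargs)
        if hits:
            out.append((ref, hits[0]))
    return out


def classify(
    reads: Iterable[ConsensusRead | SequenceRecord],
    db: Sequence[SequenceRecord],
    min_identity: float = 0.98,
    min_ref_coverage: float = 0.98,
    params: AlignParams = DEFAULT_PARAMS,
    engine: str = "auto",
    **align_kwargs,
) -> list[TaxAssignment]:
    """Best-hit species assignment for each read.

    Thresholds are strict (identity and reference coverage must exceed
    them).  Reference coverage is the aligned span over the *reference*
    length.  An exact identity tie between different species discards the
    read as AMBIGUOUS; no surviving hit leaves it UNASSIGNED.
    """
    if not db:
        raise ValueError("reference database is empty")
    labels = {ref.id: species_of(ref) for ref in db}

    out: list[TaxAssignment] = []
    for read in reads:
        rec = read.to_record() if isinstance(read, ConsensusRead) else read
        best: list[tuple[str, LocalAlignment]] = []
        for ref, hit in _best_hit_per_ref(rec, db, params, engine, **align_kwargs):
            cov = min(1.0, (hit.q_end - hit.q_start) / len(ref.seq))
            if hit.identity() > min_identity and cov > min_ref_coverage:
                best.append((labels[ref.id], hit))
        if not best:
            out.append(TaxAssignment(rec.id, UNASSIGNED, 0.0, 0.0))
            continue
        top = max(h.identity() for _, h in best)
        winners = {sp for sp, h in best if h.identity() == top}
        hit = next(h for _, h in best if h.identity() == top)
        cov = min(1.0, (hit.q_end - hit.q_start) / hit.q_len)
        if len(winners) > 1:
            out.append(TaxAssignment(rec.id, AMBIGUOUS, top, cov))
        else:
            out.append(TaxAssignment(rec.id, winners.pop(), top, cov))
    return out


def abundance_profile(assignments: Sequence[TaxAssignment]) -> dict[str, float]:
    """Species proportions over labeled reads (ambiguous and unassigned
    reads are excluded from the denominator)."""
    labeled = [a for a in assignments if a.labeled]
    if not labeled:
        return {}
    profile: dict[str, float] = {}
    for a in labeled:
        profile[a.species] = profile.get(a.species, 0.0) + 1.0
    total = sum(profile.values())
    return {sp: n / total for sp, n in sorted(profile.items())}


def _profile_from_hits(read_id: str, hits: Sequence[LocalAlignment]) -> ErrorProfile:
    nm = sum(h.n_match for h in hits)
    nx = sum(h.n_mismatch for h in hits)
    ni = sum(h.n_ins for h in hits)
    nd = sum(h.n_del for h in hits)
    length = nm + nx + ni + nd
    if length == 0:
        return ErrorProfile(read_id, 0.0, 0.0, 0.0)
    return ErrorProfile(read_id, nx / length, ni / length, nd / length)


def assess_errors(
    reads: Iterable[SequenceRecord | ConsensusRead],
    truth_refs: Sequence[SequenceRecord],
    mode: str = "corrected",
    params: AlignParams = DEFAULT_PARAMS,
    engine: str = "auto",
    circular: bool | None = None,
) -> list[ErrorProfile]:
    """Error decomposition of reads against trusted reference amplicons.

    ``raw`` mode tiles each (concatemer) read with per-region reference hits
    and sums the errors over all retained alignments; ``corrected`` mode
    keeps only the single best alignment.  In corrected mode the read is
    self-concatenated first (consensus reads start at an arbitrary rotation);
    pass ``circular=False`` to disable.
    """
    if mode not in ("raw", "corrected"):
        raise ValueError(f"unknown mode {mode!r}")
    if circular is None:
        circular = mode == "corrected"
    out = []
    for read in reads:
        rec = read.to_record() if isinstance(read, ConsensusRead) else read
        if mode == "raw":
            regions = map_to_regions(truth_refs, rec, params, engine=engine)
            out.append(_profile_from_hits(rec.id, [r.alignment for r in regions]))
        else:
            target = self_concatenate(rec) if circular else rec
            best: LocalAlignment | None = None
            for ref in truth_refs:
                hits = local_align(ref, target, params, both_strands=True,
                                   engine=engine, max_hits=1)
                if hits and (best is None or hits[0].score > best.score):
                    best = hits[0]
            out.append(_profile_from_hits(rec.id, [best] if best else []))
    return out


def compare_to_reference_circular(
    read: SequenceRecord | ConsensusRead,
    ref: SequenceRecord,
    params: AlignParams = DEFAULT_PARAMS,
    engine: str = "auto",
) -> tuple[ErrorProfile, float]:
    """Error profile and reference coverage of one read against one known
    template, rotation- and strand-invariant.

    The reference is aligned (both strands) to the self-concatenated read;
    reference coverage is the aligned reference span over the reference
    length, capped at 1.  Returns a zero-coverage profile when nothing
    aligns.
    """
    rec = read.to_record() if isinstance(read, ConsensusRead) else read
    target = self_concatenate(rec)
    hits = local_align(ref, target, params, both_strands=True, engine=engine, max_hits=1)
    if not hits:
        return ErrorProfile(rec.id, 1.0, 0.0, 0.0), 0.0
    hit = hits[0]
    coverage = min(1.0, (hit.q_end - hit.q_start) / len(ref.seq))
    return _profile_from_hits(rec.id, [hit]), coverage


def evaluate_classification(
    assignments: Sequence[TaxAssignment],
    truth_species: Iterable[str],
    thresholds: Sequence[float] = tuple(0.8 + 0.02 * i for i in range(10)),
) -> pd.DataFrame:
    """Species-set precision / recall / F1 across identity thresholds.

    ``assignments`` should come from :func:`classify` run with permissive
    thresholds so the sweep can re-filter on identity.  At each threshold
    the detected species set is compared with the truly present set;
    F1 = 2PR/(P+R), defined as 0 when P+R == 0.
    """
    truth = set(truth_species)
    rows = []
    for thr in thresholds:
        detected = {a.species for a in assignments if a.labeled and a.identity >= thr}
        tp = len(detected & truth)
        precision = tp / len(detected) if detected else 0.0
        recall = tp / len(truth) if truth else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        rows.append({"threshold": thr, "precision": precision, "recall": recall, "f1": f1})
    return pd.DataFrame(rows)


_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT", "U": "T",
}


_IUPAC_COMPLEMENT = str.maketrans(
    "ACGTURYSWKMBDHVN", "TGCAAYRSWMKVHDBN"
)


def _iupac_revcomp(primer: str) -> str:
    return primer.upper().translate(_IUPAC_COMPLEMENT)[::-1]


def _primer_regex(primer: str) -> re.Pattern:
    return re.compile("".join(f"[{_IUPAC[c.upper()]}]" for c in primer))


def trim_primers(
    ref: SequenceRecord,
    forward_primer: str,
    reverse_primer: str,
    include_primers: bool = False,
) -> SequenceRecord:
    """Extract the amplicon between two primers by exact degenerate matching.

    The forward primer is matched on the given strand; the reverse primer is
    matched as its reverse complement downstream of the forward match.  By
    default the primer sites themselves are excluded.
    """
    fwd = _primer_regex(forward_primer).search(ref.seq)
    if not fwd:
        raise ValueError(f"forward primer not found in {ref.id!r}")
    rev = _primer_regex(_iupac_revcomp(reverse_primer)).search(ref.seq, fwd.end())
    if not rev:
        raise ValueError(f"reverse primer not found in {ref.id!r}")
    start, end = (fwd.start(), rev.end()) if include_primers else (fwd.end(), rev.start())
    return SequenceRecord(
        id=ref.id, seq=ref.seq[start:end], description=ref.description
    )
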