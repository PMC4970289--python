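"""Synthetic data generation: references, RCA concatemer reads and chimeras.

Everything the pipeline consumes can be simulated with known truth.  The
error model is a simple per-base substitution/insertion/deletion process,
parameterized so that a raw simulated read has ~84% identity to its template
(mismatch 7.5%, insertion 4.5%, deletion 4.5%) — the accuracy regime of
nanopore 2D reads.  The model draws errors independently per base; it has no
homopolymer-specific structure, so consensus accuracy measured on simulated
data is slightly optimistic relative to real nanopore reads.

Two chimera classes are generated, matching how they arise in the protocol:

* intermolecular ligation — two templates circularized together; after RCA
  the read alternates A,B,A,B,... (the two templates are joined in the same
  or opposite orientation with equal probability);
* template switching — the polymerase jumps between templates during
  amplification, producing a block of copies of one template followed by a
  block of the other (both blocks longer than 3 copies).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import SequenceRecord

__all__ = [
    "ErrorModel",
    "SimTruth",
    "DEFAULT_ERROR_MODEL",
    "make_reference_set",
    "concatemerize",
    "corrupt",
    "simulate_read",
    "simulate_intermolecular_chimera",
    "simulate_template_switch_chimera",
    "simulate_community",
]

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)
_IDX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGTN"):
    _IDX[_b] = _i


@dataclass(frozen=True)
class ErrorModel:
    """Per-base error process of the read simulator.

    Each template base is deleted with probability ``p_del``; a surviving
    base is substituted (to a uniformly chosen different base) with
    probability ``p_mismatch``; after each template base position a uniform
    random base is inserted with probability ``p_ins``.
    """

    p_mismatch: float = 0.075
    p_ins: float = 0.045
    p_del: float = 0.045
    seed: int | None = None

    def __post_init__(self) -> None:
        # deletion and substitution are conditional steps, insertion is
        # independent, so each probability is bounded individually
        for p in (self.p_mismatch, self.p_ins, self.p_del):
            if not 0 <= p <= 1:
                raise ValueError("error probabilities must be in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


DEFAULT_ERROR_MODEL = ErrorModel()


@dataclass
class SimTruth:
    """Ground truth for one simulated read."""

    read_id: str
    source_ids: list[str]
    n_copies: list[int]
    orientations: list[str]
    chimera_type: str = "none"  # none | intermolecular | template_switch

    def __post_init__(self) -> None:
        if self.chimera_type == "none" and len(set(self.source_ids)) != 1:
            raise ValueError("non-chimeric truth must have a single source")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, length)]).decode()


def make_reference_set(
    n: int,
    length: int = 700,
    divergence: float = 0.1,
    seed: int | None = None,
) -> list[SequenceRecord]:
    """``n`` related reference amplicons with species labels.

    One random ancestor is mutated independently into each descendant at the
    given per-base substitution divergence, so two references differ at
    ~2*divergence of their positions (minus coincident hits).
    """
    if not 0 <= divergence < 1:
        raise ValueError("divergence must be in [0, 1)")
    rng = np.random.default_rng(seed)
    ancestor = rng.integers(0, 4, length)
    refs = []
    for i in range(n):
        mask = rng.random(length) < divergence
        shift = rng.integers(1, 4, length)
        derived = np.where(mask, (ancestor + shift) % 4, ancestor)
        refs.append(
            SequenceRecord(
                id=f"ref_{i:03d}",
                seq=bytes(_BASES[derived]).decode(),
                description=f"species=Species_{i:03d}",
            )
        )
    return refs


def concatemerize(ref: SequenceRecord, copies: int = 40) -> SequenceRecord:
    """Exact tandem repetition of a template, as RCA would produce."""
    if copies < 1:
        raise ValueError("copies must be >= 1")
    return SequenceRecord(
        id=f"{ref.id}|x{copies}",
        seq=ref.seq * copies,
        description=ref.description,
    )


def corrupt(
    seq: SequenceRecord | str,
    model: ErrorModel = DEFAULT_ERROR_MODEL,
    rng: np.random.Generator | None = None,
) -> SequenceRecord:
    """Apply the error model to a sequence (vectorized, reproducible)."""
    if rng is None:
        rng = model.rng()
    record = seq if isinstance(seq, SequenceRecord) else SequenceRecord("seq", seq)
    idx = _IDX[np.frombuffer(record.seq.encode(), dtype=np.uint8)].astype(np.int64)
    n = len(idx)

    keep = rng.random(n) >= model.p_del
    sub = keep & (rng.random(n) < model.p_mismatch)
    shift = rng.integers(1, 4, n)
    # N (index 4) substitutes to a uniform ACGT base
    subbed = np.where(idx < 4, (idx + shift) % 4, rng.integers(0, 4, n))
    bases = np.where(sub, subbed, idx)

    ins = rng.random(n) < model.p_ins
    ins_bases = rng.integers(0, 4, n)

    lengths = keep.astype(np.int64) + ins.astype(np.int64)
    total = int(lengths.sum())
    offsets = np.cumsum(lengths) - lengths
    out = np.zeros(total, dtype=np.int64)
    out[offsets[keep]] = bases[keep]
    out[offsets[ins] + keep[ins]] = ins_bases[ins]
    return SequenceRecord(
        id=record.id,
        seq=bytes(_BASES[out]).decode(),
        description=record.description,
    )


def simulate_read(
    ref: SequenceRecord,
    n_copies: int,
    model: ErrorModel = DEFAULT_ERROR_MODEL,
    rng: np.random.Generator | None = None,
    read_id: str = "read_0",
) -> tuple[SequenceRecord, SimTruth]:
    """One RCA read: ``n_copies`` tandem copies of the template, corrupted."""
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    read = corrupt(concatemerize(ref, n_copies), model, rng)
    read.id = read_id
    read.description = ""
    truth = SimTruth(read_id, [ref.id], [n_copies], ["+"])
    return read, truth


def simulate_intermolecular_chimera(
    ref_a: SequenceRecord,
    ref_b: SequenceRecord,
    model: ErrorModel = DEFAULT_ERROR_MODEL,
    n_copies_read: int = 6,
    rng: np.random.Generator | None = None,
    read_id: str = "chimera_0",
) -> tuple[SequenceRecord, SimTruth]:
    """Read from a circle that ligated two templates together.

    The second template joins in the same or opposite orientation with equal
    probability; the joint template then repeats ``n_copies_read`` times.
    """
    if rng is None:
        rng = model.rng()
    same_orientation = bool(rng.random() < 0.5)
    b = ref_b if same_orientation else ref_b.reverse_complement()
    joint = SequenceRecord(
        id=f"{ref_a.id}+{ref_b.id}",
        seq=ref_a.seq + b.seq,
        description="intermolecular joint",
    )
    read = corrupt(concatemerize(joint, n_copies_read), model, rng)
    read.id = read_id
    read.description = ""
    truth = SimTruth(
        read_id,
        [ref_a.id, ref_b.id],
        [n_copies_read, n_copies_read],
        ["+", "+" if same_orientation else "-"],
        chimera_type="intermolecular",
    )
    return read, truth


def simulate_template_switch_chimera(
    ref_a: SequenceRecord,
    ref_b: SequenceRecord,
    model: ErrorModel = DEFAULT_ERROR_MODEL,
    copies_each: int | tuple[int, int] = 4,
    rng: np.random.Generator | None = None,
    read_id: str = "switch_0",
) -> tuple[SequenceRecord, SimTruth]:
    """Read from a template switch: a block of copies of A, then of B.

    Both blocks must exceed 3 copies — with fewer copies neither block can
    pass the segment-count filter, so such reads carry no risk of a chimeric
    consensus and are not simulated.
    """
    if rng is None:
        rng = model.rng()
    ca, cb = (copies_each, copies_each) if isinstance(copies_each, int) else copies_each
    if ca <= 3 or cb <= 3:
        raise ValueError("copies_each must be > 3 on both sides")
    part_a = corrupt(concatemerize(ref_a, ca), model, rng)
    part_b = corrupt(concatemerize(ref_b, cb), model, rng)
    read = SequenceRecord(read_id, part_a.seq + part_b.seq)
    truth = SimTruth(
        read_id,
        [ref_a.id, ref_b.id],
        [ca, cb],
        ["+", "+"],
        chimera_type="template_switch",
    )
    return read, truth


def simulate_community(
    refs: Sequence[SequenceRecord],
    abundances: Sequence[float],
    n_reads: int,
    copy_range: tuple[int, int] = (6, 20),
    model: ErrorModel = DEFAULT_ERROR_MODEL,
    seed: int | None = None,
) -> tuple[list[SequenceRecord], list[SimTruth]]:
    """A read library from a mixed community.

    Sources are drawn from ``abundances`` (must sum to 1) and copy numbers
    uniformly from ``copy_range`` (inclusive).  Each read gets its own child
    RNG spawned from ``seed``, so the library is reproducible and individual
    reads are independent of library size or ordering.
    """
    if len(refs) != len(abundances):
        raise ValueError("need one abundance per reference")
    if abs(sum(abundances) - 1.0) > 1e-9:
        raise ValueError(f"abundances must sum to 1 (got {sum(abundances)})")
    lo, hi = copy_range
    if not 1 <= lo <= hi:
        raise ValueError("invalid copy range")
    if isinstance(seed, np.random.SeedSequence):
        root = seed
    else:
        root = np.random.SeedSequence(seed)
    picker = np.random.default_rng(root.spawn(1)[0])
    sources = picker.choice(len(refs), size=n_reads, p=list(abundances))
    copies = picker.integers(lo, hi + 1, size=n_reads)
    reads, truths = [], []
    for k, child in enumerate(root.spawn(n_reads + 1)[1:]):
        rng = np.random.default_rng(child)
        read, truth = simulate_read(
            refs[int(sources[k])], int(copies[k]), model, rng, read_id=f"read_{k:05d}"
        )
        reads.append(read)
        truths.append(truth)
    return reads, truths
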