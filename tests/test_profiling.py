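import numpy as np
import pytest

from incseq.io_formats import SequenceRecord, revcomp
from incseq.profiling import (
    AMBIGUOUS,
    UNASSIGNED,
    TaxAssignment,
    abundance_profile,
    assess_errors,
    classify,
    compare_to_reference_circular,
    evaluate_classification,
    self_concatenate,
    species_of,
    trim_primers,
)
from incseq.simulate import ErrorModel, corrupt, make_reference_set


def _rotate(seq, k):
    return seq[k:] + seq[:k]


@pytest.fixture(scope="module")
def db():
    return make_reference_set(3, 700, 0.1, seed=70)


class TestSelfConcatenate:
    def test_doubles_length(self):
        rec = SequenceRecord("a", "ACGTAC")
        assert self_concatenate(rec).seq == "ACGTACACGTAC"

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            self_concatenate(SequenceRecord("a", ""))

    def test_rotation_aligns_full_length_after_concatenation(self, db):
        """The operation's purpose: a rotated copy of a reference aligns
        contiguously to the doubled read."""
        from incseq.align import local_align

        ref = db[0]
        rotated = SequenceRecord("rot", _rotate(ref.seq, 250))
        target = self_concatenate(rotated)
        best = local_align(ref, target, max_hits=1)[0]
        assert best.identity() == 1.0
        assert best.q_end - best.q_start == len(ref.seq)


class TestClassify:
    def test_planted_rotation_assigned_to_source(self, db):
        read = SequenceRecord("read", _rotate(db[1].seq, 123))
        (assignment,) = classify([read], db)
        assert assignment.species == species_of(db[1])
        assert assignment.identity == pytest.approx(1.0)
        assert assignment.ref_coverage > 0.99

    def test_one_base_difference_still_resolves(self):
        """Two references differing by a single base: no tie, the exact
        match wins."""
        x = make_reference_set(1, 700, 0.0, seed=71)[0]
        y_seq = x.seq[:350] + ("A" if x.seq[350] != "A" else "C") + x.seq[351:]
        x.description = "species=Species_X"
        y = SequenceRecord("ref_y", y_seq, "species=Species_Y")
        read = SequenceRecord("read", _rotate(x.seq, 77))
        (assignment,) = classify([read], [x, y])
        assert assignment.species == "Species_X"

    def test_distant_read_unassigned(self, db):
        rng = np.random.default_rng(72)
        noisy = corrupt(db[0].seq, ErrorModel(0.05, 0, 0), rng)
        read = SequenceRecord("read", noisy.seq)
        (assignment,) = classify([read], db)
        assert assignment.species == UNASSIGNED

    def test_identical_references_of_two_species_ambiguous(self):
        a = make_reference_set(1, 700, 0.0, seed=73)[0]
        r1 = SequenceRecord("ref_1", a.seq, "species=Species_P")
        r2 = SequenceRecord("ref_2", a.seq, "species=Species_Q")
        read = SequenceRecord("read", _rotate(a.seq, 300))
        (assignment,) = classify([read], [r1, r2])
        assert assignment.species == AMBIGUOUS

    def test_unlabeled_reference_rejected(self, db):
        bad = SequenceRecord("ref_x", db[0].seq, "no label here")
        with pytest.raises(ValueError, match="species"):
            classify([SequenceRecord("r", db[0].seq)], [bad])

    def test_rotation_invariance(self, db):
        """Any rotation of a read yields the same assignment."""
        base = db[2].seq
        reads = [SequenceRecord(f"rot{k}", _rotate(base, k)) for k in (0, 100, 350, 699)]
        assignments = classify(reads, db)
        assert {a.species for a in assignments} == {species_of(db[2])}


class TestAbundanceProfile:
    def test_single_species(self):
        asg = [TaxAssignment(f"r{i}", "Species_A", 1.0, 1.0) for i in range(5)]
        assert abundance_profile(asg) == {"Species_A": 1.0}

    def test_proportions_over_labeled_reads(self):
        asg = (
            [TaxAssignment(f"a{i}", "A", 1.0, 1.0) for i in range(6)]
            + [TaxAssignment(f"b{i}", "B", 1.0, 1.0) for i in range(3)]
            + [TaxAssignment("c0", "C", 1.0, 1.0)]
            + [TaxAssignment("u", UNASSIGNED, 0.0, 0.0),
               TaxAssignment("m", AMBIGUOUS, 1.0, 1.0)]
        )
        profile = abundance_profile(asg)
        assert profile == {"A": 0.6, "B": 0.3, "C": 0.1}
        assert sum(profile.values()) == pytest.approx(1.0)

    def test_no_labeled_reads(self):
        assert abundance_profile([TaxAssignment("u", UNASSIGNED, 0, 0)]) == {}


class TestAssessErrors:
    def test_perfect_read_has_zero_rates(self, db):
        read = SequenceRecord("read", db[0].seq)
        (profile,) = assess_errors([read], db, mode="corrected")
        assert profile.rate_total == 0.0

    def test_five_substitutions_over_700(self, db):
        seq = list(db[0].seq)
        for pos in (100, 200, 300, 400, 500):
            seq[pos] = "A" if seq[pos] != "A" else "C"
        read = SequenceRecord("read", "".join(seq))
        (profile,) = assess_errors([read], db, mode="corrected", circular=False)
        assert profile.rate_mismatch == pytest.approx(5 / 700)
        assert profile.rate_ins == 0.0
        assert profile.rate_del == 0.0

    def test_raw_mode_recovers_model_error_rate(self, db):
        """Per-region error rates on raw concatemers concentrate near the
        simulated total edit rate (16.5%)."""
        from incseq.simulate import simulate_read

        model = ErrorModel(0.075, 0.045, 0.045)
        reads = []
        root = np.random.SeedSequence(74)
        for k, child in enumerate(root.spawn(10)):
            rng = np.random.default_rng(child)
            read, _ = simulate_read(db[0], 6, model, rng, read_id=f"r{k}")
            reads.append(read)
        profiles = assess_errors(reads, [db[0]], mode="raw", engine="edlib")
        med = float(np.median([p.rate_total for p in profiles]))
        assert 0.14 <= med <= 0.19

    def test_unknown_mode_rejected(self, db):
        with pytest.raises(ValueError):
            assess_errors([], db, mode="fancy")


class TestEvaluateClassification:
    def test_perfect_detection(self):
        asg = [TaxAssignment("r", "A", 0.99, 0.99), TaxAssignment("s", "B", 0.99, 0.99)]
        row = evaluate_classification(asg, {"A", "B"}, [0.9]).iloc[0]
        assert row.precision == row.recall == row.f1 == 1.0

    def test_false_positive_species(self):
        asg = [TaxAssignment(s, s, 0.99, 0.99) for s in ("A", "B", "C")]
        row = evaluate_classification(asg, {"A", "B"}, [0.9]).iloc[0]
        assert row.precision == pytest.approx(2 / 3)
        assert row.recall == 1.0
        assert row.f1 == pytest.approx(0.8)

    def test_threshold_filters_low_identity_calls(self):
        asg = [TaxAssignment("r", "A", 0.99, 0.99), TaxAssignment("s", "B", 0.85, 0.99)]
        result = evaluate_classification(asg, {"A", "B"}, [0.8, 0.9])
        assert result.recall.tolist() == [1.0, 0.5]

    def test_zero_division_guard(self):
        row = evaluate_classification([], {"A"}, [0.9]).iloc[0]
        assert row.f1 == 0.0


class TestTrimPrimers:
    FWD = "ACTYCTACGGRAGGCWGC"
    REV = "CRRCACGAGCTGACGAC"

    def test_extracts_between_primers(self):
        rng = np.random.default_rng(75)
        amplicon = "".join(rng.choice(list("ACGT"), 300))
        fwd_site = "ACTCCTACGGAAGGCAGC"   # one expansion of the degenerate fwd
        rev_site_rc = revcomp("CAGCACGAGCTGACGAC")  # expansion of rev, rc'd
        seq = "TTTT" + fwd_site + amplicon + rev_site_rc + "GGGG"
        ref = SequenceRecord("ref", seq, "species=X")
        out = trim_primers(ref, self.FWD, self.REV)
        assert out.seq == amplicon
        full = trim_primers(ref, self.FWD, self.REV, include_primers=True)
        assert full.seq == fwd_site + amplicon + rev_site_rc

    def test_missing_primer_raises(self):
        ref = SequenceRecord("ref", "ACGT" * 100, "species=X")
        with pytest.raises(ValueError, match="primer"):
            trim_primers(ref, self.FWD, self.REV)


def test_circular_comparison_of_rotated_noisy_read(db):
    rng = np.random.default_rng(76)
    noisy = corrupt(_rotate(db[0].seq, 200), ErrorModel(0.01, 0.005, 0.005), rng)
    profile, coverage = compare_to_reference_circular(
        SequenceRecord("read", noisy.seq), db[0])
    assert 0.95 <= 1 - profile.rate_total <= 1.0
    assert coverage > 0.98
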