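import numpy as np
import pytest

from incseq.align import LocalAlignment
from incseq.io_formats import SequenceRecord, revcomp
from incseq.segmenter import (
    Segment,
    SegmenterError,
    extract_anchors,
    longest_concordant_run,
    map_anchors,
    segment_read,
    segments_from_hits,
    select_anchor,
)
from incseq.simulate import ErrorModel, make_reference_set, simulate_read


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def _read(seq):
    return SequenceRecord("read", seq)


class TestExtractAnchors:
    def test_anchors_stop_at_half_read(self):
        anchors = extract_anchors(_read("A" * 3000))
        assert [a.read_start for a in anchors] == [0, 500, 1000]
        assert all(a.read_end - a.read_start == 500 for a in anchors)

    def test_single_anchor_when_window_straddles_midpoint(self):
        # start 0 < 499.5 and the 500 bp window fits in the 999 bp read
        anchors = extract_anchors(_read("A" * 999))
        assert [(a.read_start, a.read_end) for a in anchors] == [(0, 500)]

    def test_read_shorter_than_window_yields_nothing(self):
        assert extract_anchors(_read("A" * 400)) == []


class TestMapAnchors:
    def test_exact_concatemer_hits_at_unit_spacing(self):
        rng = np.random.default_rng(0)
        unit = _rand(rng, 700)
        read = _read(unit * 5)
        anchors = extract_anchors(read)
        hits = map_anchors(anchors, read)[0]
        assert [h.t_start for h in hits] == [0, 700, 1400, 2100, 2800]
        assert all(h.query_coverage() >= 0.8 for h in hits)

    def test_partial_end_hit_discarded_by_coverage_filter(self):
        rng = np.random.default_rng(1)
        unit = _rand(rng, 700)
        # final copy truncated to 300 bp: its anchor hit covers 300/500 < 0.8
        read = _read(unit * 4 + unit[:300])
        anchors = extract_anchors(read)
        hits = map_anchors(anchors, read)[0]
        assert [h.t_start for h in hits] == [0, 700, 1400, 2100]

    def test_noisy_concatemer_recovers_copy_count(self):
        model = ErrorModel(0.075, 0.045, 0.045)
        ref = make_reference_set(1, 700, 0.0, seed=2)[0]
        recovered = 0
        n_reads = 40
        root = np.random.SeedSequence(3)
        for child in root.spawn(n_reads):
            rng = np.random.default_rng(child)
            read, truth = simulate_read(ref, 10, model, rng)
            anchors = extract_anchors(read)
            per_anchor = map_anchors(anchors, read)
            best = max(per_anchor, key=len)
            if len(best) == truth.n_copies[0]:
                recovered += 1
        assert recovered >= 0.95 * n_reads


def _fake_hit(t_start, identity=1.0, q_start=0, q_end=500, strand="+", q_len=500):
    nm = int(round(identity * (q_end - q_start)))
    nx = (q_end - q_start) - nm
    return LocalAlignment(
        q_start=q_start, q_end=q_end, t_start=t_start,
        t_end=t_start + (q_end - q_start), strand=strand,
        score=nm - 2 * nx, n_match=nm, n_mismatch=nx, n_ins=0, n_del=0,
        q_len=q_len,
    )


class TestSelectAnchor:
    def test_most_hits_wins(self):
        a0 = [_fake_hit(i * 700) for i in range(6)]
        a1 = [_fake_hit(i * 700) for i in range(4)]
        assert select_anchor([a0, a1]) == 0

    def test_tie_broken_by_mean_identity(self):
        a0 = [_fake_hit(i * 700, identity=0.88) for i in range(5)]
        a1 = [_fake_hit(i * 700, identity=0.91) for i in range(5)]
        assert select_anchor([a0, a1]) == 1

    def test_full_tie_prefers_lower_index(self):
        a0 = [_fake_hit(i * 700) for i in range(5)]
        a1 = [_fake_hit(i * 700) for i in range(5)]
        assert select_anchor([a0, a1]) == 0

    def test_no_hits_rejects_read(self):
        with pytest.raises(SegmenterError, match="no_anchor"):
            select_anchor([[], []])


class TestSegmentsFromHits:
    def test_exact_hits_delimit_unit_segments(self):
        rng = np.random.default_rng(4)
        read = _read(_rand(rng, 3500))
        hits = [_fake_hit(i * 700) for i in range(5)]
        segments = segments_from_hits(hits, read)
        assert len(segments) == 4
        assert all(len(s) == 700 and s.strand == "+" for s in segments)
        assert segments[0].seq == read.seq[0:700]

    def test_five_prime_clip_extends_segment_start(self):
        rng = np.random.default_rng(5)
        read = _read(_rand(rng, 3000))
        # second hit starts at 705 with 5 query bases clipped at its 5' end
        hits = [_fake_hit(0), _fake_hit(705, q_start=5), _fake_hit(1405, q_start=5)]
        segments = segments_from_hits(hits, read)
        assert segments[0].read_end == 700
        assert segments[1].read_start == 700

    def test_minus_strand_segment_stored_reverse_complemented(self):
        rng = np.random.default_rng(6)
        read = _read(_rand(rng, 2100))
        hits = [_fake_hit(0), _fake_hit(700, strand="-"), _fake_hit(1400)]
        segments = segments_from_hits(hits, read)
        assert segments[1].strand == "-"
        assert segments[1].seq == revcomp(read.seq[700:1400])

    def test_single_hit_rejects(self):
        with pytest.raises(SegmenterError, match="single_hit"):
            segments_from_hits([_fake_hit(0)], _read("A" * 1000))


def _segment(start, length, strand="+"):
    return Segment(read_start=start, read_end=start + length, strand=strand,
                   seq="A" * length, anchor_identity=0.9)


class TestLongestConcordantRun:
    def test_uniform_segments_form_one_run(self):
        segs = [_segment(i * 700, 700 + (i % 3) * 10) for i in range(8)]
        run = longest_concordant_run(segs)
        assert len(run) == 8

    def test_orientation_switch_splits_runs(self):
        strands = ["+"] * 3 + ["-"] + ["+"] * 6
        segs = [_segment(i * 700, 700, s) for i, s in enumerate(strands)]
        run = longest_concordant_run(segs)
        assert len(run) == 6
        assert all(s.strand == "+" for s in run.segments)

    def test_length_outlier_removed_and_six_survive(self):
        # the outlier sits at the run edge, so six consecutive segments survive
        lengths = [900, 700, 700, 700, 700, 700, 700]
        segs = [_segment(i * 700, n) for i, n in enumerate(lengths)]
        run = longest_concordant_run(segs)
        assert len(run) == 6  # exactly at the acceptance threshold
        assert all(abs(len(s) - run.median_len) <= 0.05 * run.median_len
                   for s in run.segments)

    def test_short_best_run_rejects(self):
        segs = [_segment(i * 700, 700) for i in range(5)]
        with pytest.raises(SegmenterError, match="too_few_segments"):
            longest_concordant_run(segs)


@pytest.mark.parametrize("length", [500, 700, 1200, 2000])
@pytest.mark.parametrize("copies", [3, 8, 20])
def test_noise_free_concatemer_recovers_all_segments(length, copies):
    """Exact concatemers yield copies-1 segments, each a rotation of the unit."""
    ref = make_reference_set(1, length, 0.0, seed=length + copies)[0]
    read, _ = simulate_read(ref, copies, ErrorModel(0, 0, 0), read_id="clean")
    run = segment_read(read, min_segments=2)
    assert len(run) == copies - 1
    doubled = ref.seq * 2
    for seg in run.segments:
        assert len(seg) == length
        assert seg.seq in doubled


def test_pass_rate_non_increasing_with_error_rate():
    """The >=6-segment filter passes fewer reads as errors increase."""
    ref = make_reference_set(1, 500, 0.0, seed=77)[0]
    rates = []
    for scale in (0.5, 1.0, 2.2):
        model = ErrorModel(0.075 * scale, 0.045 * scale, 0.045 * scale)
        passed = 0
        root = np.random.SeedSequence(int(scale * 1000))
        for child in root.spawn(12):
            rng = np.random.default_rng(child)
            read, _ = simulate_read(ref, 8, model, rng)
            try:
                segment_read(read)
                passed += 1
            except SegmenterError:
                pass
        rates.append(passed / 12)
    assert rates[0] >= rates[1] >= rates[2]
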