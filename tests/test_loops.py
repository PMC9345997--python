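"""SS segmentation, center-strand location and the loop topology walk."""

import pytest

from pl7loop import (
    SSAnnotation,
    SeqRecord,
    annotate_loops,
    extract_loops,
    locate_center_strand,
    segment_ss,
)
from pl7loop.errors import (
    AnnotationFailedError,
    CenterStrandNotFoundError,
    LoopNotFoundError,
)
from pl7loop.motifs import MotifHit


def seg(labels, min_strand_len=2):
    return segment_ss(SSAnnotation(labels=labels), min_strand_len=min_strand_len)


def spans(segments):
    return [(s.label, s.start, s.end) for s in segments]


class TestSegmentSS:
    def test_simple_runs(self):
        assert spans(seg("CCEEECC")) == [("C", 1, 2), ("E", 3, 5), ("C", 6, 7)]

    def test_short_strand_demoted_and_merged(self):
        assert spans(seg("CEC")) == [("C", 1, 3)]

    def test_helix_runs_preserved(self):
        assert spans(seg("EEECCHHCCEEE")) == [
            ("E", 1, 3), ("C", 4, 5), ("H", 6, 7), ("C", 8, 9), ("E", 10, 12),
        ]

    def test_min_strand_len_configurable(self):
        assert spans(seg("CEEC", min_strand_len=3)) == [("C", 1, 4)]
        assert spans(seg("CEEC", min_strand_len=2)) == [
            ("C", 1, 1), ("E", 2, 3), ("C", 4, 4),
        ]

    def test_segments_partition_sequence(self):
        labels = "CCEEHHCEEEECCHE"
        segments = seg(labels)
        covered = []
        for s in segments:
            covered.extend(range(s.start, s.end + 1))
        assert covered == list(range(1, len(labels) + 1))


class TestLocateCenterStrand:
    def test_anchor_inside_strand(self):
        segments = seg("C" * 119 + "E" * 9 + "C" * 10)  # E(120-128)
        anchor = MotifHit("region_QIVH", 123, 125, "QIH")
        center = locate_center_strand(segments, anchor)
        assert (center.start, center.end) == (120, 128)

    def test_exact_cover(self):
        segments = seg("CCEEECC")
        center = locate_center_strand(segments, MotifHit("region_QIVH", 3, 5, "QVH"))
        assert (center.start, center.end) == (3, 5)

    def test_anchor_outside_any_strand_raises(self):
        segments = seg("C" * 10)
        with pytest.raises(CenterStrandNotFoundError):
            locate_center_strand(segments, MotifHit("region_QIVH", 3, 5, "QIH"))

    def test_straddling_anchor_majority_wins(self):
        # anchor 4-6: two residues on E(1-5), one on E(7-9) -> majority strand
        segments = seg("EEEEECEEE")
        center = locate_center_strand(segments, MotifHit("region_QIVH", 4, 6, "QIH"))
        assert (center.start, center.end) == (1, 5)


class TestExtractLoops:
    def test_synthetic_scaffold_run_counting(self):
        # C5 E4 C3 E6(center) C2 E3 C4 E3 C7 E3 -> loop1 = C3 run, loop2 = C7 run
        labels = "C" * 5 + "E" * 4 + "C" * 3 + "E" * 6 + "C" * 2 + "E" * 3 \
            + "C" * 4 + "E" * 3 + "C" * 7 + "E" * 3
        record = SeqRecord("scaffold", "A" * len(labels))
        segments = segment_ss(SSAnnotation(labels=labels))
        center = next(s for s in segments if (s.start, s.end) == (13, 18))
        ann = extract_loops(record, segments, center)
        assert ann.loop1_span == (10, 12)
        assert ann.loop2_span == (31, 37)
        assert ann.strategy == "ss-topology"

    def test_loop_lengths_agree_three_ways(self):
        labels = "C" * 5 + "E" * 4 + "C" * 3 + "E" * 6 + "C" * 2 + "E" * 3 \
            + "C" * 4 + "E" * 3 + "C" * 7 + "E" * 3
        record = SeqRecord("scaffold", "A" * len(labels))
        segments = segment_ss(SSAnnotation(labels=labels))
        center = next(s for s in segments if s.start == 13)
        ann = extract_loops(record, segments, center)
        for span, seq in ((ann.loop1_span, ann.loop1_seq), (ann.loop2_span, ann.loop2_seq)):
            assert span[1] - span[0] + 1 == len(seq)

    def test_loop1_truncated_at_n_terminus_flagged(self):
        labels = "C" * 4 + "E" * 5 + "C" * 3 + "E" * 4 + "C" * 3 + "E" * 4 + "C" * 5 + "E" * 3
        record = SeqRecord("t", "A" * len(labels))
        segments = segment_ss(SSAnnotation(labels=labels))
        center = segments[1]  # E(5-9): loop1 runs to position 1
        ann = extract_loops(record, segments, center)
        assert ann.loop1_span == (1, 4)
        assert "loop1-truncated-at-N-terminus" in ann.flags

    def test_too_few_strands_after_center_raises(self):
        labels = "C" * 4 + "E" * 5 + "C" * 3 + "E" * 4 + "C" * 6
        record = SeqRecord("t", "A" * len(labels))
        segments = segment_ss(SSAnnotation(labels=labels))
        with pytest.raises(LoopNotFoundError):
            extract_loops(record, segments, segments[1])


class TestAnnotateLoops:
    def test_pyaly_standin_crystal_consistent_ss(self, pyaly):
        ann = annotate_loops(pyaly.record, ss=pyaly.ss)
        assert ann.loop1_span == (108, 117) and ann.loop1_seq == "TLPTPLRGMK"
        assert ann.loop2_span == (159, 170) and ann.loop2_seq == "RLNNKSGDAGRF"
        assert ann.strategy == "ss-topology"

    def test_alyv_standin_helices_counted_in_loops(self, alyv):
        """Helical insertions inside the loops count toward loop length."""
        ann = annotate_loops(alyv.record, ss=alyv.ss)
        assert ann.loop1_span == (117, 134) and ann.loop1_len == 18
        assert ann.loop2_span == (183, 210) and ann.loop2_len == 28

    def test_projection_on_identical_query(self, alyv, templates):
        ann = annotate_loops(alyv.record, ss=None, templates=templates)
        assert ann.strategy == "anchor-projection"
        assert ann.loop1_span == (117, 134)
        assert ann.loop2_span == (183, 210)

    def test_fallback_to_projection_on_bad_ss(self, alyv, templates):
        # all-coil SS: no center strand; projection must take over
        flat = SSAnnotation(labels="C" * len(alyv.record))
        ann = annotate_loops(alyv.record, ss=flat, templates=templates)
        assert ann.strategy == "anchor-projection"
        assert ann.loop1_span == (117, 134)

    def test_both_strategies_failing_raises_with_causes(self, alyv):
        flat = SSAnnotation(labels="C" * len(alyv.record))
        with pytest.raises(AnnotationFailedError) as exc:
            annotate_loops(alyv.record, ss=flat, templates=None)
        assert exc.value.causes
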