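"""Loop1/loop2 location on the beta-jelly-roll topology.

The procedure walks the predicted secondary structure of a single-domain
PL7 alginate lyase:

1. segment the three-state SS string into maximal runs (short strand runs
   are relabelled coil first);
2. find the beta-strand carrying the QI(V)H anchor — the *center strand*;
3. read the loops off the fold topology: loop1 is the non-strand run
   immediately N-terminal to the center strand, and loop2 is the third
   non-strand run C-terminal to it (two strands and two loops lie in
   between).

"Loop" here means a maximal run of non-strand residues: helices inside a
loop count toward its length, which is required for loops that contain
small helical insertions (AlyV's 18- and 28-residue loops).

When no secondary structure is available, or the SS and the motif anchor
disagree, the fallback strategy projects the loop boundaries of the
best-aligned annotated template onto the query by global alignment.  The
resulting annotation records which strategy produced it.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

from .align import global_align, project_positions
from .config import PipelineConfig, DEFAULT_CONFIG
from .errors import (
    AnchorNotFoundError,
    AnnotationFailedError,
    CenterStrandNotFoundError,
    LoopNotFoundError,
    ProjectionFailedError,
)
from .motifs import MotifHit, locate_conserved_regions
from .seqio import SeqRecord, SSAnnotation


@dataclasses.dataclass(frozen=True)
class SSSegment:
    """A maximal run of one SS label, 1-based inclusive."""

    label: str  # E, H or C
    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclasses.dataclass(frozen=True)
class LoopAnnotation:
    """The two product-determining loops of one sequence."""

    record_id: str
    center_span: Optional[tuple[int, int]]
    loop1_span: tuple[int, int]
    loop1_seq: str
    loop2_span: tuple[int, int]
    loop2_seq: str
    strategy: str  # "ss-topology" or "anchor-projection"
    flags: tuple[str, ...] = ()

    @property
    def loop1_len(self) -> int:
        return len(self.loop1_seq)

    @property
    def loop2_len(self) -> int:
        return len(self.loop2_seq)

    def __post_init__(self) -> None:
        for span, seq, name in (
            (self.loop1_span, self.loop1_seq, "loop1"),
            (self.loop2_span, self.loop2_seq, "loop2"),
        ):
            start, end = span
            if end - start + 1 != len(seq):
                raise ValueError(
                    f"{self.record_id} {name}: span {start}-{end} disagrees with "
                    f"sequence length {len(seq)}"
                )


@dataclasses.dataclass(frozen=True)
class ReferenceTemplate:
    """A fully annotated sequence usable as a projection/alignment template."""

    record: SeqRecord
    loop1_span: tuple[int, int]
    loop2_span: tuple[int, int]
    anchor_h: int  # 1-based position of the catalytic His in QI(V)H


def segment_ss(ss: SSAnnotation, min_strand_len: int = 2) -> list[SSSegment]:
    """Split an SS string into maximal runs, suppressing too-short strands.

    Strand (E) runs shorter than ``min_strand_len`` are relabelled C and
    merged with adjacent C runs; helix runs are preserved as segments (the
    loop extractor, not the segmenter, lumps non-strand labels together).
    """
    labels = ss.labels
    runs: list[list] = []
    for i, lab in enumerate(labels, start=1):
        if runs and runs[-1][0] == lab:
            runs[-1][2] = i
        else:
            runs.append([lab, i, i])
    # demote short strand runs to coil
    for run in runs:
        if run[0] == "E" and run[2] - run[1] + 1 < min_strand_len:
            run[0] = "C"
    # merge adjacent runs that now share a label
    merged: list[list] = []
    for run in runs:
        if merged and merged[-1][0] == run[0]:
            merged[-1][2] = run[2]
        else:
            merged.append(run)
    return [SSSegment(label=r[0], start=r[1], end=r[2]) for r in merged]


def locate_center_strand(segments: Sequence[SSSegment], anchor: MotifHit) -> SSSegment:
    """The strand segment carrying the QI(V)H anchor.

    Primary rule: the E segment containing the anchor's His (last) position.
    If the anchor straddles segment boundaries, the E segment covering the
    majority of anchor positions wins, ties going to the His-containing one.
    """
    overlapping = []
    for seg in segments:
        if seg.label != "E":
            continue
        overlap = min(seg.end, anchor.end) - max(seg.start, anchor.start) + 1
        if overlap > 0:
            overlapping.append((overlap, seg.contains(anchor.end), seg))
    if not overlapping:
        raise CenterStrandNotFoundError(
            f"anchor {anchor.start}-{anchor.end} lies on no strand segment"
        )
    overlapping.sort(key=lambda t: (-t[0], not t[1], t[2].start))
    return overlapping[0][2]


def extract_loops(
    record: SeqRecord, segments: Sequence[SSSegment], center: SSSegment
) -> LoopAnnotation:
    """Read loop1 and loop2 off the segment topology around the center strand.

    loop1 = all consecutive non-strand residues immediately N-terminal to the
    center strand (back to the previous strand or the sequence start, in
    which case a truncation flag is set).  loop2 = the third non-strand run
    C-terminal to the center strand.
    """
    idx = segments.index(center)
    flags: list[str] = []

    # ---- loop1: trailing non-E segments immediately before the center strand
    j = idx - 1
    loop1_start = loop1_end = None
    while j >= 0 and segments[j].label != "E":
        loop1_start = segments[j].start
        if loop1_end is None:
            loop1_end = segments[j].end
        j -= 1
    if loop1_start is None:
        raise LoopNotFoundError(
            f"record {record.id!r}: no loop precedes the center strand "
            f"{center.start}-{center.end}"
        )
    if j < 0:
        flags.append("loop1-truncated-at-N-terminus")

    # ---- loop2: third non-strand run after the center strand
    nonstrand_runs: list[tuple[int, int]] = []
    current: Optional[list[int]] = None
    for seg in segments[idx + 1 :]:
        if seg.label == "E":
            if current is not None:
                nonstrand_runs.append((current[0], current[1]))
                current = None
        else:
            if current is None:
                current = [seg.start, seg.end]
            else:
                current[1] = seg.end
    if current is not None:
        nonstrand_runs.append((current[0], current[1]))
    strands_after = sum(1 for seg in segments[idx + 1 :] if seg.label == "E")
    if len(nonstrand_runs) < 3 or strands_after < 2:
        raise LoopNotFoundError(
            f"record {record.id!r}: fewer than two strands and three loops after "
            f"the center strand; loop2 not locatable"
        )
    loop2_start, loop2_end = nonstrand_runs[2]

    return LoopAnnotation(
        record_id=record.id,
        center_span=(center.start, center.end),
        loop1_span=(loop1_start, loop1_end),
        loop1_seq=record.slice(loop1_start, loop1_end),
        loop2_span=(loop2_start, loop2_end),
        loop2_seq=record.slice(loop2_start, loop2_end),
        strategy="ss-topology",
        flags=tuple(flags),
    )


def _annotate_by_topology(
    record: SeqRecord,
    ss: SSAnnotation,
    templates: Sequence[ReferenceTemplate] | None,
    config: PipelineConfig,
) -> LoopAnnotation:
    regions = locate_conserved_regions(
        record, templates=templates, scoring=config.scoring
    )
    segments = segment_ss(ss, min_strand_len=config.min_strand_len)
    center = locate_center_strand(segments, regions.anchor)
    annotation = extract_loops(record, segments, center)
    if regions.ambiguous:
        annotation = dataclasses.replace(
            annotation, flags=annotation.flags + ("anchor-ambiguous",)
        )
    return annotation


def _annotate_by_projection(
    record: SeqRecord,
    templates: Sequence[ReferenceTemplate],
    config: PipelineConfig,
) -> LoopAnnotation:
    best = max(
        templates,
        key=lambda t: global_align(t.record, record, config.scoring).percent_identity,
    )
    spans = project_positions(
        best.record,
        [best.loop1_span, best.loop2_span],
        record,
        config.scoring,
    )
    l1, l2 = spans
    return LoopAnnotation(
        record_id=record.id,
        center_span=None,
        loop1_span=(l1.start, l1.end),
        loop1_seq=record.slice(l1.start, l1.end),
        loop2_span=(l2.start, l2.end),
        loop2_seq=record.slice(l2.start, l2.end),
        strategy="anchor-projection",
        flags=(f"projected-from:{best.record.id}",),
    )


def annotate_loops(
    record: SeqRecord,
    ss: Optional[SSAnnotation] = None,
    templates: Sequence[ReferenceTemplate] | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> LoopAnnotation:
    """Annotate loop1/loop2 on a record, dispatching between strategies.

    With ``ss`` available the SS-topology walk runs first; on failure (or
    with no SS at all) loop boundaries are projected from the best-aligned
    template.  Raises :class:`AnnotationFailedError` carrying the underlying
    causes when both strategies fail.
    """
    causes: list[Exception] = []
    if ss is not None:
        try:
            return _annotate_by_topology(record, ss, templates, config)
        except (
            AnchorNotFoundError,
            CenterStrandNotFoundError,
            LoopNotFoundError,
        ) as exc:
            causes.append(exc)
    if templates:
        try:
            return _annotate_by_projection(record, templates, config)
        except ProjectionFailedError as exc:
            causes.append(exc)
    raise AnnotationFailedError(
        f"record {record.id!r}: all loop-location strategies failed "
        f"({'; '.join(str(c) for c in causes) or 'no SS and no templates supplied'})",
        causes=causes,
    )
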