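"""End-to-end screening, loop annotation and Dp-class prediction.

The prediction rule is deliberately simple: after screening out sequences
that are likely multi-domain (length > 400 residues) or exolytic
(AlyA5-like), the length of loop1 alone classifies the product
distribution —

* loop1 length >= 12 -> SMALL_OLIGO: trisaccharides with high probability,
  disaccharides possible (Dp2-Dp3 predominant);
* loop1 length <= 11 -> LARGE_OLIGO: larger oligomers, Dp >= 4.

The class boundary and the screening rules come from the published
procedure; the AlyA5 identity cutoff is configurable because the published
screen does not state one.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from collections import Counter
from typing import Mapping, Optional, Sequence

from .align import percent_identity
from .config import PipelineConfig, DEFAULT_CONFIG
from .errors import AnchorNotFoundError, AnnotationFailedError
from .loops import LoopAnnotation, ReferenceTemplate, annotate_loops
from .motifs import find_motif
from .reference import REGION_QIVH
from .seqio import LoopTableRow, SeqRecord, SSAnnotation

logger = logging.getLogger("pl7loop")


class DpClass(enum.Enum):
    """Predicted product-distribution class of an endolytic PL7 lyase."""

    SMALL_OLIGO = "SMALL_OLIGO"  # Dp2-Dp3 predominant (tri > di likelihood)
    LARGE_OLIGO = "LARGE_OLIGO"  # Dp >= 4 predominant


#: Loop1 lengths at or above this value predict SMALL_OLIGO.
LOOP1_CLASS_BOUNDARY = 12


@dataclasses.dataclass(frozen=True)
class ScreenResult:
    """Outcome of the pre-annotation screen for one sequence."""

    passed: bool
    reasons: frozenset[str]  # subset of {"too-long", "exolytic-like", "anchor-missing"}
    sequence_length: int
    alya5_identity: Optional[float] = None
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        assert self.passed == (not self.reasons)


@dataclasses.dataclass(frozen=True)
class DpPrediction:
    """Screening verdict, loop1 length and predicted product class."""

    id: str
    screen: ScreenResult
    annotation: Optional[LoopAnnotation]
    loop1_len: Optional[int]
    dp_class: Optional[DpClass]
    rationale: str


def classify_loop1(length: int) -> DpClass:
    """Map a loop1 length to its product class (boundary at 11/12)."""
    if length < 1:
        raise ValueError(f"loop1 length must be positive, got {length}")
    return DpClass.SMALL_OLIGO if length >= LOOP1_CLASS_BOUNDARY else DpClass.LARGE_OLIGO


def screen_sequence(
    record: SeqRecord,
    alya5: Optional[SeqRecord] = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> ScreenResult:
    """Apply the pre-annotation exclusion rules; never raises.

    Rules: (1) sequences longer than the length threshold are likely
    multi-domain; (2) sequences similar to the exolytic lyase AlyA5 are
    excluded (skipped with a warning if no AlyA5 sequence is available);
    (3) sequences without any QI(V)H match cannot be processed at all.
    """
    reasons = set()
    warnings = []
    if len(record) > config.length_threshold:
        reasons.add("too-long")
    identity = None
    if alya5 is not None:
        identity = percent_identity(record, alya5, config.scoring)
        if identity >= config.exolytic_identity_threshold:
            reasons.add("exolytic-like")
    else:
        warnings.append("alya5-sequence-unavailable: exolytic screen skipped")
    if not find_motif(REGION_QIVH, record):
        reasons.add("anchor-missing")
    return ScreenResult(
        passed=not reasons,
        reasons=frozenset(reasons),
        sequence_length=len(record),
        alya5_identity=identity,
        warnings=tuple(warnings),
    )


def predict(
    record: SeqRecord,
    ss: Optional[SSAnnotation] = None,
    templates: Sequence[ReferenceTemplate] | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
    alya5: Optional[SeqRecord] = None,
) -> DpPrediction:
    """Screen, annotate and classify one sequence.

    A failed screen yields a prediction with ``dp_class`` absent and the
    screening reasons in the rationale.  :class:`AnnotationFailedError`
    propagates only when both loop-location strategies fail.
    """
    screen = screen_sequence(record, alya5=alya5, config=config)
    if not screen.passed:
        return DpPrediction(
            id=record.id,
            screen=screen,
            annotation=None,
            loop1_len=None,
            dp_class=None,
            rationale="screened out: " + ", ".join(sorted(screen.reasons)),
        )
    annotation = annotate_loops(record, ss=ss, templates=templates, config=config)
    dp_class = classify_loop1(annotation.loop1_len)
    side = ">= 12" if dp_class is DpClass.SMALL_OLIGO else "<= 11"
    return DpPrediction(
        id=record.id,
        screen=screen,
        annotation=annotation,
        loop1_len=annotation.loop1_len,
        dp_class=dp_class,
        rationale=(
            f"loop1 length {annotation.loop1_len} {side} -> {dp_class.value} "
            f"({annotation.strategy})"
        ),
    )


def build_loop_table(
    records: Sequence[SeqRecord],
    ss_by_id: Optional[Mapping[str, SSAnnotation]] = None,
    templates: Sequence[ReferenceTemplate] | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
    alya5: Optional[SeqRecord] = None,
) -> list[LoopTableRow]:
    """Batch-annotate records into loop-table rows; per-record failures never abort.

    Row order equals input order.  A summary line with per-class and
    per-failure counts is logged at INFO level.
    """
    ss_by_id = ss_by_id or {}
    rows = []
    tally: Counter = Counter()
    for record in records:
        try:
            pred = predict(
                record,
                ss=ss_by_id.get(record.id),
                templates=templates,
                config=config,
                alya5=alya5,
            )
        except (AnnotationFailedError, AnchorNotFoundError) as exc:
            rows.append(
                LoopTableRow(record.id, "", 0, "", 0, "", f"error:{type(exc).__name__}")
            )
            tally["error"] += 1
            continue
        if pred.dp_class is None:
            status = "failed:" + ",".join(sorted(pred.screen.reasons))
            rows.append(LoopTableRow(record.id, "", 0, "", 0, "", status))
            for reason in pred.screen.reasons:
                tally[f"screened:{reason}"] += 1
        else:
            ann = pred.annotation
            rows.append(
                LoopTableRow(
                    record.id,
                    ann.loop1_seq,
                    ann.loop1_len,
                    ann.loop2_seq,
                    ann.loop2_len,
                    pred.dp_class.value,
                    "passed",
                )
            )
            tally[pred.dp_class.value] += 1
    logger.info(
        "loop table: %d records (%s) [config %s]",
        len(records),
        ", ".join(f"{k}={v}" for k, v in sorted(tally.items())) or "empty",
        config.digest(),
    )
    return rows
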