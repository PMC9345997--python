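"""Global pairwise alignment utilities.

Used for (a) the percent-identity screens (exolytic AlyA5 similarity,
optional redundancy checks) and (b) projecting loop boundaries or anchor
positions from an annotated template onto a query when no secondary
structure is available.

The aligner itself is Biopython's :class:`Bio.Align.PairwiseAligner` in
global (end-to-end) mode; this module fixes the scoring conventions and
adds the column map and span projection on top.  Percent identity is
identical aligned residue pairs divided by all alignment columns (a global
pairwise alignment has no dual-gap columns), times 100 — stated explicitly
because published identity figures are method-dependent.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .config import ScoringScheme
from .errors import ProjectionFailedError
from .seqio import SeqRecord


@dataclasses.dataclass(frozen=True)
class AlignmentResult:
    """A finished global alignment of two sequences."""

    aligned_a: str
    aligned_b: str
    score: float
    percent_identity: float
    #: 1-based position in ``a`` -> 1-based position in ``b`` (None = gap).
    column_map: tuple[Optional[int], ...]

    def map_position(self, a_pos: int) -> Optional[int]:
        """Partner position in ``b`` for 1-based ``a_pos`` (None if gapped)."""
        return self.column_map[a_pos - 1]


@dataclasses.dataclass(frozen=True)
class ProjectedSpan:
    """A template span carried onto a query sequence by alignment."""

    start: int
    end: int
    provenance: str = "projected"


def _make_aligner(scoring: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if scoring.matrix is not None:
        aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    else:
        aligner.match_score = scoring.match
        aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def global_align(
    a: SeqRecord, b: SeqRecord, scoring: ScoringScheme | None = None
) -> AlignmentResult:
    """Optimal global alignment of two records under ``scoring``.

    When several alignments are co-optimal, Biopython's first traceback is
    taken; for fixed inputs and scoring the result is deterministic.
    """
    scoring = scoring or ScoringScheme()
    aligner = _make_aligner(scoring)
    alignment = aligner.align(a.residues, b.residues)[0]
    ga, gb = alignment[0], alignment[1]

    column_map: list[Optional[int]] = []
    identical = 0
    columns = 0
    bi = 0
    for ca, cb in zip(ga, gb):
        if cb != "-":
            bi += 1
        if ca != "-":
            column_map.append(bi if cb != "-" else None)
        if ca != "-" or cb != "-":
            columns += 1
            if ca == cb and ca != "-":
                identical += 1
    pid = 100.0 * identical / columns if columns else 0.0
    return AlignmentResult(
        aligned_a=ga,
        aligned_b=gb,
        score=float(alignment.score),
        percent_identity=pid,
        column_map=tuple(column_map),
    )


def percent_identity(
    a: SeqRecord, b: SeqRecord, scoring: ScoringScheme | None = None
) -> float:
    """Global percent identity between two records (see module docstring)."""
    return global_align(a, b, scoring).percent_identity


def project_positions(
    template: SeqRecord,
    spans: Sequence[tuple[int, int]],
    query: SeqRecord,
    scoring: ScoringScheme | None = None,
) -> list[ProjectedSpan]:
    """Map 1-based inclusive template spans onto the query via global alignment.

    Span endpoints that fall on gap columns snap inward to the nearest
    aligned position inside the span.  A span lying entirely within a gap
    region raises :class:`ProjectionFailedError`.
    """
    result = global_align(template, query, scoring)
    projected = []
    for start, end in spans:
        if not (1 <= start <= end <= len(template)):
            raise ProjectionFailedError(
                f"span {start}-{end} outside template 1-{len(template)}"
            )
        mapped = [
            result.map_position(p)
            for p in range(start, end + 1)
            if result.map_position(p) is not None
        ]
        if not mapped:
            raise ProjectionFailedError(
                f"span {start}-{end} of {template.id!r} falls entirely in a gap "
                f"against {query.id!r}"
            )
        projected.append(ProjectedSpan(start=min(mapped), end=max(mapped)))
    return projected
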