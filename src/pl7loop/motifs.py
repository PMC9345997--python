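"""Detection of the three PL7 conserved regions and anchor selection.

The QI(V)H region marks the center beta-strand of the beta-jelly-roll fold;
its position is the anchor from which loop1 and loop2 are read off the
strand/loop topology.  Sequences can contain more than one QI(V)H match, so
selection first enforces the N-to-C order of the three conserved regions
(RxEL(V)R before QI(V)H before YFKxGxYxQ) and then, if still ambiguous,
falls back to agreement with the anchor position of the best-aligned
reference template.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

from .config import ScoringScheme
from .errors import AnchorNotFoundError
from .reference import MotifPattern, load_patterns
from .seqio import SeqRecord


@dataclasses.dataclass(frozen=True)
class MotifHit:
    """A single pattern match, 1-based inclusive coordinates."""

    pattern: str
    start: int
    end: int
    matched: str

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclasses.dataclass(frozen=True)
class ConservedRegions:
    """Selected hits for the three conserved regions of one sequence."""

    region1: Optional[MotifHit]
    anchor: MotifHit          # the selected QI(V)H hit
    region3: Optional[MotifHit]
    ambiguous: bool           # True when several QI(V)H matches existed

    @property
    def anchor_h_position(self) -> int:
        """1-based position of the catalytic His in the QI(V)H anchor."""
        return self.anchor.end


def find_motif(pattern: MotifPattern, record: SeqRecord) -> list[MotifHit]:
    """All (possibly overlapping) matches of ``pattern``, ascending start.

    Wildcard positions match any residue letter including X; an X in the
    query never satisfies a fixed-letter or letter-set position, so unknown
    residues cannot create a false anchor.
    """
    seq = record.residues
    k = len(pattern)
    hits = []
    for start0 in range(len(seq) - k + 1):
        window = seq[start0 : start0 + k]
        ok = True
        for aa, cls in zip(window, pattern.positions):
            if cls is not None and aa not in cls:
                ok = False
                break
        if ok:
            hits.append(
                MotifHit(
                    pattern=pattern.name,
                    start=start0 + 1,
                    end=start0 + k,
                    matched=window,
                )
            )
    return hits


def _order_consistent(candidate: MotifHit, r1_hits, r3_hits) -> bool:
    """Does the candidate QI(V)H hit respect region order with regions 1 and 3?"""
    ok = True
    if r1_hits:
        ok = ok and any(h.end < candidate.start for h in r1_hits)
    if r3_hits:
        ok = ok and any(h.start > candidate.end for h in r3_hits)
    return ok


def locate_conserved_regions(
    record: SeqRecord,
    patterns: Sequence[MotifPattern] | None = None,
    templates: Sequence["object"] | None = None,
    scoring: ScoringScheme | None = None,
) -> ConservedRegions:
    """Select one hit per conserved region, disambiguating the QI(V)H anchor.

    Disambiguation order for multiple QI(V)H matches:

    1. keep candidates consistent with region order (a RxEL(V)R hit before,
       a YFKxGxYxQ hit after, whenever those regions matched at all);
    2. if several remain and reference templates with full sequences are
       supplied, choose the candidate whose His position is closest to the
       anchor position projected from the best-aligned template;
    3. otherwise the N-terminal-most surviving candidate.

    ``templates`` items need ``record`` and ``anchor_h`` attributes (see
    :class:`pl7loop.loops.ReferenceTemplate`).  Raises
    :class:`AnchorNotFoundError` when no QI(V)H match exists.
    """
    if patterns is None:
        patterns = load_patterns()
    by_order = {p.order_index: p for p in patterns}
    r1_hits = find_motif(by_order[1], record) if 1 in by_order else []
    r2_hits = find_motif(by_order[2], record) if 2 in by_order else []
    r3_hits = find_motif(by_order[3], record) if 3 in by_order else []

    if not r2_hits:
        raise AnchorNotFoundError(
            f"record {record.id!r}: no QI(V)H match; cannot place the center strand"
        )

    ambiguous = len(r2_hits) > 1
    candidates = r2_hits
    if ambiguous:
        filtered = [c for c in candidates if _order_consistent(c, r1_hits, r3_hits)]
        if filtered:
            candidates = filtered
    if len(candidates) > 1 and templates:
        candidates = [_alignment_tiebreak(record, candidates, templates, scoring)]
    anchor = candidates[0]

    region1 = max(
        (h for h in r1_hits if h.end < anchor.start),
        key=lambda h: h.start,
        default=None,
    )
    region3 = min(
        (h for h in r3_hits if h.start > anchor.end),
        key=lambda h: h.start,
        default=None,
    )
    return ConservedRegions(
        region1=region1, anchor=anchor, region3=region3, ambiguous=ambiguous
    )


def _alignment_tiebreak(record, candidates, templates, scoring):
    """Pick the candidate whose H position best agrees with the best-aligned template."""
    from .align import global_align  # local import to avoid a cycle

    scoring = scoring or ScoringScheme()
    best = None
    best_pid = -1.0
    for tpl in templates:
        res = global_align(tpl.record, record, scoring)
        if res.percent_identity > best_pid:
            best_pid = res.percent_identity
            best = (tpl, res)
    tpl, res = best
    projected = res.map_position(tpl.anchor_h)
    if projected is None:
        return candidates[0]
    return min(candidates, key=lambda c: (abs(c.end - projected), c.start))
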