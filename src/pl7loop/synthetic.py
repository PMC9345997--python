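"""Generator of PL7-like sequences with known ground truth.

Emulates the features the annotation pipeline relies on, and nothing else:
three conserved regions in N-to-C order (RxEL(V)R, QI(V)H, YFKxGxYxQ), a
strand/loop scaffold consistent with the beta-jelly-roll topology walk
(loop1 immediately N-terminal to the QI(V)H-bearing center strand, loop2
the third non-strand run after it), and configurable loop lengths.  The
default loop1 range (4-15 residues) matches the span observed across the
single-domain PL7 database.

Residues outside placed motifs are drawn from an alphabet excluding
H, I, Q, R, V and Y, so no accidental conserved-region match can arise;
decoy QI(V)H insertions are available on request to exercise anchor
disambiguation.  The same seed always reproduces the same output.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .loops import LoopAnnotation
from .motifs import ConservedRegions, MotifHit, find_motif
from .reference import REGION_QIVH
from .seqio import SeqRecord, SSAnnotation

#: Letters that can never complete any of the three conserved-region patterns.
SAFE_ALPHABET = "ACDEFGKLMNPSTW"


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one generated PL7-like sequence."""

    loop1_len: int = 10
    loop2_len: int = 12
    n_strands_before: int = 2   # strand/loop pairs upstream of the RxEL(V)R strand
    strand_len_range: tuple[int, int] = (4, 9)
    loop_len_range: tuple[int, int] = (3, 8)
    flank_len_range: tuple[int, int] = (8, 25)
    seed: int = 0
    decoy_qih: int = 0          # extra QIH copies planted in the N-terminal flank
    total_length: Optional[int] = None  # pad the C-terminal flank to this length

    def __post_init__(self) -> None:
        if self.loop1_len < 1 or self.loop2_len < 1:
            raise ValidationError("loop lengths must be >= 1")


@dataclasses.dataclass(frozen=True)
class SyntheticRecord:
    """A generated sequence with its ground-truth annotations."""

    record: SeqRecord
    ss: SSAnnotation
    loops: LoopAnnotation       # truth spans/sequences
    regions: ConservedRegions   # truth conserved-region hits
    config: SyntheticConfig


def _rand(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(SAFE_ALPHABET), size=n))


def generate(config: SyntheticConfig) -> SyntheticRecord:
    """Build one sequence plus matching SS labels and truth annotations."""
    rng = np.random.default_rng(config.seed)
    lo_s, hi_s = config.strand_len_range
    lo_l, hi_l = config.loop_len_range
    lo_f, hi_f = config.flank_len_range

    seq_parts: list[str] = []
    ss_parts: list[str] = []
    pos = 0  # residues emitted so far; next fragment starts at pos+1

    def emit(fragment: str, label: str) -> tuple[int, int]:
        nonlocal pos
        start = pos + 1
        seq_parts.append(fragment)
        ss_parts.append(label * len(fragment))
        pos += len(fragment)
        return start, pos

    # --- N-terminal flank, with optional decoy anchors
    flank_len = int(rng.integers(lo_f, hi_f + 1))
    flank = list(_rand(rng, max(flank_len, 3 * config.decoy_qih + 3)))
    for i in range(config.decoy_qih):
        at = 3 * i
        flank[at : at + 3] = "Q" + ("I" if rng.integers(2) else "V") + "H"
    emit("".join(flank), "C")

    # --- upstream scaffold strands
    for _ in range(config.n_strands_before):
        emit(_rand(rng, int(rng.integers(lo_s, hi_s + 1))), "E")
        emit(_rand(rng, int(rng.integers(lo_l, hi_l + 1))), "C")

    # --- strand carrying RxEL(V)R
    r1_motif = "R" + _rand(rng, 1) + "E" + ("L" if rng.integers(2) else "V") + "R"
    pad_l, pad_r = int(rng.integers(1, 4)), int(rng.integers(1, 4))
    r1_start, _ = emit(_rand(rng, pad_l) + r1_motif + _rand(rng, pad_r), "E")
    r1_hit_start = r1_start + pad_l

    # --- loop1 (immediately N-terminal to the center strand)
    loop1_span = emit(_rand(rng, config.loop1_len), "C")

    # --- center strand with the QI(V)H anchor
    anchor_motif = "Q" + ("I" if rng.integers(2) else "V") + "H"
    pad_l, pad_r = int(rng.integers(2, 5)), int(rng.integers(2, 5))
    center_span = emit(_rand(rng, pad_l) + anchor_motif + _rand(rng, pad_r), "E")
    anchor_start = center_span[0] + pad_l

    # --- two strands and two loops between the center strand and loop2
    emit(_rand(rng, int(rng.integers(lo_l, hi_l + 1))), "C")
    emit(_rand(rng, int(rng.integers(lo_s, hi_s + 1))), "E")
    emit(_rand(rng, int(rng.integers(lo_l, hi_l + 1))), "C")
    emit(_rand(rng, int(rng.integers(lo_s, hi_s + 1))), "E")

    # --- loop2
    loop2_span = emit(_rand(rng, config.loop2_len), "C")

    # --- strand carrying YFKxGxYxQ, then the C-terminal flank
    r3_motif = (
        "YFK" + _rand(rng, 1) + "G" + _rand(rng, 1) + "Y" + _rand(rng, 1) + "Q"
    )
    pad_l, pad_r = int(rng.integers(1, 4)), int(rng.integers(1, 4))
    r3_start, _ = emit(_rand(rng, pad_l) + r3_motif + _rand(rng, pad_r), "E")
    r3_hit_start = r3_start + pad_l
    emit(_rand(rng, int(rng.integers(lo_f, hi_f + 1))), "C")

    if config.total_length is not None:
        if pos > config.total_length:
            raise ValidationError(
                f"segments already span {pos} residues, over the "
                f"total-length target {config.total_length}"
            )
        if pos < config.total_length:
            emit(_rand(rng, config.total_length - pos), "C")

    residues = "".join(seq_parts)
    record = SeqRecord(
        id=f"synthetic-seed{config.seed}-l1_{config.loop1_len}",
        residues=residues,
        description="synthetic PL7-like scaffold",
    )
    ss = SSAnnotation(labels="".join(ss_parts), source="template-projection")

    loops = LoopAnnotation(
        record_id=record.id,
        center_span=center_span,
        loop1_span=loop1_span,
        loop1_seq=record.slice(*loop1_span),
        loop2_span=loop2_span,
        loop2_seq=record.slice(*loop2_span),
        strategy="ss-topology",
    )
    regions = ConservedRegions(
        region1=MotifHit("region_RxELVR", r1_hit_start, r1_hit_start + 4,
                         record.slice(r1_hit_start, r1_hit_start + 4)),
        anchor=MotifHit("region_QIVH", anchor_start, anchor_start + 2,
                        record.slice(anchor_start, anchor_start + 2)),
        region3=MotifHit("region_YFKxGxYxQ", r3_hit_start, r3_hit_start + 8,
                         record.slice(r3_hit_start, r3_hit_start + 8)),
        ambiguous=config.decoy_qih > 0,
    )

    if config.decoy_qih == 0:
        n_anchor_hits = len(find_motif(REGION_QIVH, record))
        assert n_anchor_hits == 1, (
            f"generator violated anchor uniqueness: {n_anchor_hits} QI(V)H hits"
        )
    return SyntheticRecord(record=record, ss=ss, loops=loops, regions=regions,
                           config=config)


def generate_panel(
    n: int,
    loop1_lengths: Optional[Sequence[int]] = None,
    seed: int = 0,
    loop1_range: tuple[int, int] = (4, 15),
    **config_overrides,
) -> list[SyntheticRecord]:
    """Generate ``n`` records with loop1 lengths from a stated distribution.

    By default lengths are drawn uniformly from ``loop1_range`` (4-15, the
    observed database range); pass ``loop1_lengths`` for explicit control,
    e.g. one record per length group.  Each record gets its own derived
    seed, so panels are reproducible record-by-record.
    """
    if n < 1:
        raise ValidationError(f"panel size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    if loop1_lengths is None:
        lengths = rng.integers(loop1_range[0], loop1_range[1] + 1, size=n).tolist()
    else:
        if len(loop1_lengths) != n:
            raise ValidationError(
                f"{len(loop1_lengths)} loop1 lengths supplied for a panel of {n}"
            )
        lengths = list(loop1_lengths)
    panel = []
    for i, l1 in enumerate(lengths):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        cfg = SyntheticConfig(loop1_len=int(l1), seed=sub_seed, **config_overrides)
        item = generate(cfg)
        item = dataclasses.replace(
            item,
            record=dataclasses.replace(item.record, id=f"panel{i:03d}-l1_{l1}"),
        )
        item = dataclasses.replace(
            item, loops=dataclasses.replace(item.loops, record_id=item.record.id)
        )
        panel.append(item)
    return panel


def truth_table_rows(panel: Sequence[SyntheticRecord]):
    """Loop-table rows from generator truth (for writing truth TSVs)."""
    from .pipeline import classify_loop1
    from .seqio import LoopTableRow

    rows = []
    for item in panel:
        rows.append(
            LoopTableRow(
                id=item.record.id,
                loop1_seq=item.loops.loop1_seq,
                loop1_len=item.loops.loop1_len,
                loop2_seq=item.loops.loop2_seq,
                loop2_len=item.loops.loop2_len,
                dp_class=classify_loop1(item.loops.loop1_len).value,
                screen_status="truth",
            )
        )
    return rows
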