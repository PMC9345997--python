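"""Synthetic full-length stand-ins for the two fully characterized references.

The complete PyAly and AlyV sequences live in GenBank (BAI66416.1 and
OM743979) and are not redistributed here.  For offline fixtures and
examples this module builds *synthetic* stand-in sequences that reproduce
every published residue-numbered fact the pipeline consumes:

* PyAly-like: loop1 Thr108-Lys117 ``TLPTPLRGMK``, loop2 Arg159-Phe170
  ``RLNNKSGDAGRF``, catalytic anchor Gln123/His125 on the center strand;
* AlyV-like: loop1 Pro117-Ala134 ``PINPRASVANTDKAKNDA`` (with a small
  helical insertion, so helix-in-loop counting is exercised), loop2
  Val183-Leu210, catalytic anchor Gln139/His141.

All other residues are synthetic filler from an alphabet that cannot
complete a conserved-region pattern, so the motifs above are unique.
These records are stand-ins, not the natural proteins: only loop spans,
loop sequences and anchor positions are faithful.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .loops import LoopAnnotation, ReferenceTemplate
from .seqio import SeqRecord, SSAnnotation
from .synthetic import SAFE_ALPHABET


@dataclasses.dataclass(frozen=True)
class Standin:
    record: SeqRecord
    ss: SSAnnotation
    loops: LoopAnnotation
    anchor_h: int

    def template(self) -> ReferenceTemplate:
        return ReferenceTemplate(
            record=self.record,
            loop1_span=self.loops.loop1_span,
            loop2_span=self.loops.loop2_span,
            anchor_h=self.anchor_h,
        )


def _assemble(
    name: str,
    length: int,
    ss_segments: Sequence[tuple[int, int, str]],
    placed: Sequence[tuple[int, str]],
    seed: int,
) -> tuple[SeqRecord, SSAnnotation]:
    """Fill a coordinate plan with deterministic safe-alphabet filler."""
    rng = np.random.default_rng(seed)
    residues = list(rng.choice(list(SAFE_ALPHABET), size=length))
    for start, fragment in placed:
        residues[start - 1 : start - 1 + len(fragment)] = list(fragment)
    labels = [""] * length
    for start, end, lab in ss_segments:
        for i in range(start - 1, end):
            labels[i] = lab
    assert all(labels), f"{name}: SS plan does not cover 1-{length}"
    record = SeqRecord(
        id=name,
        residues="".join(residues),
        description="synthetic stand-in; published loop spans and anchor only",
    )
    return record, SSAnnotation(labels="".join(labels), source="template-projection")


def pyaly_standin() -> Standin:
    """PyAly-like stand-in (241 residues, crystal-consistent SS plan)."""
    record, ss = _assemble(
        "PyAly-standin",
        241,
        ss_segments=[
            (1, 40, "C"), (41, 50, "E"), (51, 60, "C"), (61, 70, "E"),
            (71, 83, "C"), (84, 93, "E"), (94, 97, "C"), (98, 107, "E"),
            (108, 117, "C"),            # loop1
            (118, 128, "E"),            # center strand (Q123-H125)
            (129, 134, "C"), (135, 143, "E"), (144, 147, "C"), (148, 158, "E"),
            (159, 170, "C"),            # loop2
            (171, 180, "E"), (181, 190, "C"), (191, 200, "E"), (201, 241, "C"),
        ],
        placed=[
            (84, "RTELR"),              # RxEL(V)R region (Arg84...Arg88)
            (108, "TLPTPLRGMK"),        # loop1, Thr108-Lys117
            (123, "QIH"),               # anchor, Gln123/His125
            (159, "RLNNKSGDAGRF"),      # loop2, Arg159-Phe170
            (217, "YFKAGAYAQ"),         # YFKxGxYxQ region (Tyr223 at position 7)
        ],
        seed=1201,
    )
    loops = LoopAnnotation(
        record_id=record.id,
        center_span=(118, 128),
        loop1_span=(108, 117),
        loop1_seq=record.slice(108, 117),
        loop2_span=(159, 170),
        loop2_seq=record.slice(159, 170),
        strategy="ss-topology",
    )
    return Standin(record=record, ss=ss, loops=loops, anchor_h=125)


def alyv_standin() -> Standin:
    """AlyV-like stand-in (287 residues; helical insertions inside both loops)."""
    record, ss = _assemble(
        "AlyV-standin",
        287,
        ss_segments=[
            (1, 45, "C"), (46, 55, "E"), (56, 65, "C"), (66, 75, "E"),
            (76, 83, "C"), (84, 95, "E"), (96, 99, "C"), (100, 116, "E"),
            (117, 121, "C"), (122, 125, "H"), (126, 134, "C"),   # loop1 with helix
            (135, 145, "E"),            # center strand (Q139-H141)
            (146, 152, "C"), (153, 162, "E"), (163, 170, "C"), (171, 182, "E"),
            (183, 189, "C"), (190, 194, "H"), (195, 210, "C"),   # loop2 with helix
            (211, 220, "E"), (221, 230, "C"), (231, 240, "E"), (241, 287, "C"),
        ],
        placed=[
            (87, "RTELR"),                            # RxEL(V)R region
            (117, "PINPRASVANTDKAKNDA"),              # loop1, Pro117-Ala134
            (139, "QVH"),                             # anchor, Gln139/His141
            (183, "VIKNNAVNCGSKSGNKGTEECKNAYLKL"),    # loop2, Val183-Leu210
            (255, "YFKAGAYAQ"),                       # YFKxGxYxQ (Tyr261 at pos 7)
        ],
        seed=1202,
    )
    loops = LoopAnnotation(
        record_id=record.id,
        center_span=(135, 145),
        loop1_span=(117, 134),
        loop1_seq=record.slice(117, 134),
        loop2_span=(183, 210),
        loop2_seq=record.slice(183, 210),
        strategy="ss-topology",
    )
    return Standin(record=record, ss=ss, loops=loops, anchor_h=141)


def standin_templates() -> list[ReferenceTemplate]:
    """Projection templates built from the two stand-ins."""
    return [pyaly_standin().template(), alyv_standin().template()]
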