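"""Bundled reference data for the PL7 loop-annotation pipeline.

Two kinds of compiled-in knowledge live here:

* The eight structure-solved single-domain PL7 alginate lyases with their
  loop1/loop2 sequences, published boundary coordinates where available
  (AlyV and PyAly), and the product group observed for each enzyme.
* The three conserved sequence regions of the PL7 family —
  RxEL(V)R, QI(V)H and YFKxGxYxQ, in N-to-C order — expressed as
  degenerate position patterns.  The QI(V)H region sits on the center
  beta-strand of the beta-jelly-roll fold and carries the catalytic
  Gln/His, which makes it the topological anchor for loop location.

For six of the eight reference enzymes only the concatenated loop text was
available when this table was transcribed; their loop1/loop2 split is a
plausible reading and is flagged ``split_verified = False``.  AlyV and PyAly
are pinned by explicit boundary coordinates and fully verified.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Optional, Union

from .errors import FormatError

# --------------------------------------------------------------------------
# Reference enzymes


@dataclasses.dataclass(frozen=True)
class ReferenceEntry:
    """One structure-solved PL7 lyase with its loop sequences."""

    name: str
    pdb_id: str
    loop1_seq: str
    loop2_seq: str
    loop1_span: Optional[tuple[int, int]] = None
    loop2_span: Optional[tuple[int, int]] = None
    product_group: str = ""
    split_verified: bool = False

    def __post_init__(self) -> None:
        for span, seq, label in (
            (self.loop1_span, self.loop1_seq, "loop1"),
            (self.loop2_span, self.loop2_seq, "loop2"),
        ):
            if span is not None:
                start, end = span
                if end - start + 1 != len(seq):
                    raise FormatError(
                        f"{self.name} {label}: span {start}-{end} width "
                        f"{end - start + 1} != sequence length {len(seq)}"
                    )


def _parse_span(start: str, end: str) -> Optional[tuple[int, int]]:
    if start == "." or end == ".":
        return None
    return int(start), int(end)


def load_reference_set(path: Union[str, Path, None] = None) -> list[ReferenceEntry]:
    """Load the eight-entry reference table (or a user override file)."""
    if path is None:
        source = resources.files("pl7loop.data") / "reference_loops.tsv"
        text = source.read_text()
    else:
        text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    expected = [
        "name", "pdb_id", "loop1_seq", "loop1_start", "loop1_end",
        "loop2_seq", "loop2_start", "loop2_end", "product_group", "split_verified",
    ]
    if header != expected:
        raise FormatError(f"reference table header mismatch: {header}")
    entries = []
    for ln in lines[1:]:
        f = ln.split("\t")
        entries.append(
            ReferenceEntry(
                name=f[0],
                pdb_id=f[1],
                loop1_seq=f[2],
                loop1_span=_parse_span(f[3], f[4]),
                loop2_seq=f[5],
                loop2_span=_parse_span(f[6], f[7]),
                product_group=f[8],
                split_verified=(f[9] == "yes"),
            )
        )
    return entries


# --------------------------------------------------------------------------
# Conserved-region patterns


@dataclasses.dataclass(frozen=True)
class MotifPattern:
    """A degenerate sequence pattern: per position either a letter set or a wildcard.

    ``positions`` holds ``frozenset`` of allowed letters, or ``None`` for a
    wildcard.  ``order_index`` is the region's rank along the sequence,
    N-terminus first.
    """

    name: str
    positions: tuple[Optional[frozenset], ...]
    order_index: int

    def __len__(self) -> int:
        return len(self.positions)


def _p(spec: str) -> tuple[Optional[frozenset], ...]:
    """Compact pattern notation: 'R.E[LV]R' -> position classes ('.' = wildcard)."""
    out: list[Optional[frozenset]] = []
    i = 0
    while i < len(spec):
        ch = spec[i]
        if ch == ".":
            out.append(None)
            i += 1
        elif ch == "[":
            j = spec.index("]", i)
            out.append(frozenset(spec[i + 1 : j]))
            i = j + 1
        else:
            out.append(frozenset(ch))
            i += 1
    return tuple(out)


REGION_RXELVR = MotifPattern("region_RxELVR", _p("R.E[LV]R"), order_index=1)
REGION_QIVH = MotifPattern("region_QIVH", _p("Q[IV]H"), order_index=2)
REGION_YFKXGXYXQ = MotifPattern("region_YFKxGxYxQ", _p("YFK.G.Y.Q"), order_index=3)


def load_patterns() -> list[MotifPattern]:
    """The three PL7 conserved-region patterns, in N-to-C order."""
    return [REGION_RXELVR, REGION_QIVH, REGION_YFKXGXYXQ]


# --------------------------------------------------------------------------
# Optional AlyA5 sequence (exolytic screen reference)

_ALYA5_FILENAME = "alya5.fasta"


def load_alya5(path: Union[str, Path, None] = None):
    """Load the AlyA5 (PDB 4BE3) sequence for the exolytic screen, if available.

    The sequence is not bundled; users may drop a FASTA into the package data
    directory or pass a path.  Returns ``None`` when absent, which downgrades
    the exolytic screen to a warning.
    """
    from .seqio import read_fasta

    if path is None:
        candidate = resources.files("pl7loop.data") / _ALYA5_FILENAME
        try:
            if not candidate.is_file():
                return None
        except OSError:
            return None
        path = str(candidate)
    try:
        return read_fasta(path)[0]
    except (FileNotFoundError, FormatError):
        return None
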