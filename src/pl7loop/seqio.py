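"""Reading and writing the pipeline's file formats.

Three dialects are supported, all plain text:

* FASTA — protein sequences (multi-record, wrapped or unwrapped), via Biopython.
* Secondary-structure files — one three-state label string per record, either a
  bare string on a line or ``id<TAB>labels``.  JPred-style ``-`` (and other
  common coil symbols) collapse to ``C``.
* Loop tables — TSV with a fixed header, one row per protein.

All residue coordinates in this package are 1-based and inclusive, matching
the way structural biologists write spans such as Pro117-Ala134.  Conversion
to Python's 0-based slices happens only inside accessor methods.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import FormatError, ValidationError

#: The 20 standard one-letter amino-acid codes plus X (unknown residue).
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Input SS symbols that collapse to coil.  Covers JPred's '-' and the
#: DSSP-reduced states that are neither strand nor helix.
_COIL_SYMBOLS = frozenset("C-TSBG. ")

PathLike = Union[str, Path]


@dataclasses.dataclass(frozen=True)
class SeqRecord:
    """An identified amino-acid sequence with 1-based residue indexing."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        for pos, aa in enumerate(self.residues, start=1):
            if aa not in VALID_RESIDUES:
                raise ValidationError(
                    f"record {self.id!r}: invalid residue {aa!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def slice(self, start: int, end: int) -> str:
        """Residues in the 1-based inclusive span [start, end]."""
        if not (1 <= start <= end <= len(self)):
            raise ValidationError(
                f"record {self.id!r}: span {start}-{end} outside 1-{len(self)}"
            )
        return self.residues[start - 1 : end]


@dataclasses.dataclass(frozen=True)
class SSAnnotation:
    """Per-residue three-state secondary structure, aligned to a SeqRecord.

    ``labels`` uses E (strand), H (helix), C (everything else).
    """

    labels: str
    source: str = "user-file"

    def __post_init__(self) -> None:
        bad = set(self.labels) - set("EHC")
        if bad:
            raise ValidationError(f"SS labels contain symbols outside EHC: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)


@dataclasses.dataclass(frozen=True)
class LoopTableRow:
    """One protein's loop annotation in the batch output table."""

    id: str
    loop1_seq: str
    loop1_len: int
    loop2_seq: str
    loop2_len: int
    dp_class: str
    screen_status: str

    def __post_init__(self) -> None:
        if self.loop1_seq and len(self.loop1_seq) != self.loop1_len:
            raise ValidationError(
                f"{self.id}: loop1 length {self.loop1_len} != sequence length"
            )
        if self.loop2_seq and len(self.loop2_seq) != self.loop2_len:
            raise ValidationError(
                f"{self.id}: loop2 length {self.loop2_len} != sequence length"
            )


LOOP_TABLE_HEADER = (
    "id",
    "loop1_seq",
    "loop1_len",
    "loop2_seq",
    "loop2_len",
    "class",
    "screen_status",
)


def read_fasta(path: PathLike) -> list[SeqRecord]:
    """Read a (possibly multi-record) protein FASTA file.

    Residues are uppercased; line breaks and whitespace are removed by the
    parser.  Raises :class:`FormatError` for an empty file and
    :class:`ValidationError` (naming record and position) for residues outside
    the 20 standard letters plus X.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).replace(" ", "").upper()
        description = rec.description
        if description.startswith(rec.id):
            description = description[len(rec.id) :].strip()
        records.append(SeqRecord(id=rec.id, residues=residues, description=description))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SeqRecord], path: PathLike, width: int = 60) -> None:
    """Write records as FASTA with lines wrapped at ``width`` columns."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def parse_ss_labels(raw: str, record: SeqRecord, source: str = "user-file") -> SSAnnotation:
    """Map a raw label string onto {E, H, C} and length-check it.

    E and H (either case) pass through; the usual coil symbols (C, '-', T, S,
    B, G, '.') map to C; anything else is a :class:`FormatError`.  A length
    mismatch against ``record`` raises :class:`ValidationError` naming both
    lengths.
    """
    labels = []
    for sym in raw.strip():
        up = sym.upper()
        if up in "EH":
            labels.append(up)
        elif up in _COIL_SYMBOLS:
            labels.append("C")
        else:
            raise FormatError(f"unknown secondary-structure symbol {sym!r}")
    label_str = "".join(labels)
    if len(label_str) != len(record):
        raise ValidationError(
            f"record {record.id!r}: SS length {len(label_str)} != sequence length {len(record)}"
        )
    return SSAnnotation(labels=label_str, source=source)


def read_ss(path: PathLike, record: SeqRecord) -> SSAnnotation:
    """Read a secondary-structure annotation for ``record``.

    Accepts either a bare label string on one line, or ``id<TAB>labels`` lines
    (in which case the line whose id matches ``record.id`` is used).
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty secondary-structure file")
    chosen = None
    for ln in lines:
        if "\t" in ln:
            rid, _, labels = ln.partition("\t")
            if rid.strip() == record.id:
                chosen = labels
                break
        else:
            chosen = ln
            break
    if chosen is None:
        raise FormatError(f"{path}: no secondary-structure line for record {record.id!r}")
    return parse_ss_labels(chosen, record, source="user-file")


def write_ss(ann: SSAnnotation, record: SeqRecord, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"{record.id}\t{ann.labels}\n")


def write_loop_table(rows: Iterable[LoopTableRow], path: PathLike) -> None:
    """Write the batch loop table as TSV (fixed header, input row order)."""
    with open(path, "w") as fh:
        fh.write("\t".join(LOOP_TABLE_HEADER) + "\n")
        for row in rows:
            fh.write(
                "\t".join(
                    [
                        row.id,
                        row.loop1_seq,
                        str(row.loop1_len),
                        row.loop2_seq,
                        str(row.loop2_len),
                        row.dp_class,
                        row.screen_status,
                    ]
                )
                + "\n"
            )


def read_loop_table(path: PathLike) -> list[LoopTableRow]:
    """Read back a TSV written by :func:`write_loop_table`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != LOOP_TABLE_HEADER:
            raise FormatError(f"{path}: unexpected loop-table header {header}")
        rows = []
        for ln in fh:
            if not ln.strip():
                continue
            fields = ln.rstrip("\n").split("\t")
            if len(fields) != len(LOOP_TABLE_HEADER):
                raise FormatError(f"{path}: malformed row {ln!r}")
            rows.append(
                LoopTableRow(
                    id=fields[0],
                    loop1_seq=fields[1],
                    loop1_len=int(fields[2]),
                    loop2_seq=fields[3],
                    loop2_len=int(fields[4]),
                    dp_class=fields[5],
                    screen_status=fields[6],
                )
            )
    return rows
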