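"""Readers and writers for the alignment formats the pipeline touches.

Three on-disk encodings are supported -- PSICOV flat files (one aligned
sequence per line, no headers), A3M (FASTA-like, lowercase = insertion
relative to the query) and aligned FASTA -- all canonicalized to a single
in-memory :class:`Alignment`.

Canonical alphabet: the 20 standard amino acids, ``-`` for gaps and ``X``
for anything unknown. Non-standard letters (B, Z, J, O, U) and ``.`` /
``*`` style placeholders are mapped during reading; ``.`` maps to a gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
ALPHABET = AMINO_ACIDS + GAP + UNKNOWN  # 22 symbols; X folds into no aa bin

_CANON = {c: c for c in AMINO_ACIDS}
_CANON[GAP] = GAP
_CANON["."] = GAP
_CANON[UNKNOWN] = UNKNOWN


class AlignmentFormatError(ValueError):
    """Raised when an alignment file violates its format contract."""


def _canonicalize(seq: str) -> str:
    return "".join(_CANON.get(c, UNKNOWN) for c in seq.upper())


@dataclass
class Alignment:
    """An in-memory multiple sequence alignment.

    Row 0 is the query/target and defines the column numbering; columns
    are addressed 1-based at the API surface.
    """

    sequences: list[str]
    identifier: str = ""
    query_index: int = 0
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentFormatError("alignment must contain at least one sequence")
        L = len(self.sequences[0])
        if L < 1:
            raise AlignmentFormatError("alignment columns must be >= 1")
        for k, s in enumerate(self.sequences):
            if len(s) != L:
                raise AlignmentFormatError(
                    f"row {k + 1} has length {len(s)}, expected {L}"
                )
        bad = set("".join(self.sequences)) - set(ALPHABET)
        if bad:
            raise AlignmentFormatError(f"non-canonical characters: {sorted(bad)}")
        if not self.names:
            self.names = [f"seq{k}" for k in range(len(self.sequences))]

    @property
    def L(self) -> int:
        return len(self.sequences[0])

    @property
    def N(self) -> int:
        return len(self.sequences)

    @property
    def query(self) -> str:
        return self.sequences[self.query_index]

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequences)


def read_psicov(path: str | Path) -> Alignment:
    """Read a PSICOV flat alignment: one aligned sequence per line."""
    path = Path(path)
    rows: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            seq = _canonicalize(line)
            if rows and len(seq) != len(rows[0]):
                raise AlignmentFormatError(
                    f"{path}: line {lineno} has length {len(seq)}, "
                    f"expected {len(rows[0])}"
                )
            rows.append(seq)
    if not rows:
        raise AlignmentFormatError(f"{path}: empty alignment file")
    return Alignment(rows, identifier=path.stem)


def write_psicov(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq in aln.sequences:
            fh.write(seq + "\n")


def _read_fasta_records(path: Path) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records.append((name, "".join(chunks)))
                name, chunks = line[1:].split()[0] if line[1:] else "", []
            elif name is not None:
                chunks.append(line)
    if name is not None:
        records.append((name, "".join(chunks)))
    if not records:
        raise AlignmentFormatError(f"{path}: no FASTA records found")
    return records


def read_a3m(path: str | Path) -> Alignment:
    """Read an A3M alignment; lowercase insertion states are removed.

    After dropping lowercase characters every record must have exactly
    the length of the first (master) sequence.
    """
    path = Path(path)
    records = _read_fasta_records(path)
    rows: list[str] = []
    names: list[str] = []
    master_len = None
    for name, raw in records:
        seq = "".join(c for c in raw if not c.islower())
        seq = _canonicalize(seq)
        if master_len is None:
            master_len = len(seq)
        elif len(seq) != master_len:
            raise AlignmentFormatError(
                f"{path}: record '{name}' has match-state length {len(seq)}, "
                f"expected {master_len}"
            )
        rows.append(seq)
        names.append(name)
    return Alignment(rows, identifier=path.stem, names=names)


def write_a3m(aln: Alignment, path: str | Path) -> None:
    """Write as A3M. Canonical alignments have no insertion states, so
    the output is plain aligned FASTA with the query first."""
    with open(path, "w") as fh:
        for name, seq in zip(aln.names, aln.sequences):
            fh.write(f">{name}\n{seq}\n")


def read_fasta(path: str | Path) -> Alignment:
    """Read an aligned FASTA file (all records equal length)."""
    path = Path(path)
    records = _read_fasta_records(path)
    rows = [_canonicalize(raw) for _, raw in records]
    names = [name for name, _ in records]
    L = len(rows[0])
    for name, row in zip(names, rows):
        if len(row) != L:
            raise AlignmentFormatError(
                f"{path}: record '{name}' has length {len(row)}, expected {L}"
            )
    return Alignment(rows, identifier=path.stem, names=names)


def write_fasta(aln: Alignment, path: str | Path) -> None:
    write_a3m(aln, path)
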