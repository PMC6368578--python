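"""FASTA input, sequence sanitization and strand symmetrization.

Sequences are stored as *runs*: maximal contiguous stretches over {A,C,G,T}.
Ambiguous bases (and, under hard masking, soft-masked lowercase bases) split a
sequence into separate runs so that no counting window ever covers them.
Record boundaries in multi-record concatenates are likewise preserved as run
boundaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "SymmetrizedSequence",
    "read_fasta",
    "reverse_complement",
    "sanitize",
    "symmetrize",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID_RE = re.compile(r"^[ACGT]*$")
_RUN_RE = re.compile(r"[ACGT]+")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an A/C/G/T string.

    Involution: ``reverse_complement(reverse_complement(s)) == s``.

    Raises
    ------
    ValueError
        If `seq` contains a character outside {A,C,G,T}.
    """
    if not _VALID_RE.match(seq):
        bad = sorted(set(seq) - set("ACGT"))
        raise ValueError(f"non-ACGT character(s) in sequence: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


def sanitize(seq: str, hard_mask: bool = False) -> tuple[str, ...]:
    """Split a raw sequence string into unambiguous uppercase A/C/G/T runs.

    Lowercase (soft-masked) bases are upcased and kept unless ``hard_mask``
    is set, in which case they are treated as ambiguous and split runs.
    Idempotent on already-clean input.
    """
    if not hard_mask:
        seq = seq.upper()
    return tuple(_RUN_RE.findall(seq))


@dataclass(frozen=True)
class SequenceRecord:
    """A labeled sequence held as ordered unambiguous runs."""

    id: str
    runs: tuple[str, ...]

    def __post_init__(self) -> None:
        for run in self.runs:
            if not run or not _VALID_RE.match(run):
                raise ValueError(f"invalid run in record {self.id!r}: {run!r}")

    @property
    def total_length(self) -> int:
        return sum(len(r) for r in self.runs)


@dataclass(frozen=True)
class SymmetrizedSequence:
    """A sequence together with its reverse complement, as two run lists.

    Counting over ``forward_runs + reverse_runs`` is strand-symmetric: every
    word and its reverse complement have identical counts.  No window spans
    the junction between the two strands or any run boundary.
    """

    forward_runs: tuple[str, ...]
    reverse_runs: tuple[str, ...]

    @property
    def runs(self) -> tuple[str, ...]:
        return self.forward_runs + self.reverse_runs

    @property
    def total_length(self) -> int:
        return sum(len(r) for r in self.runs)


def symmetrize(rec: SequenceRecord) -> SymmetrizedSequence:
    """Pair a record's runs with their reverse complements (order-reversed)."""
    if not rec.runs:
        raise ValueError(f"record {rec.id!r} has no unambiguous runs")
    reverse = tuple(reverse_complement(r) for r in reversed(rec.runs))
    return SymmetrizedSequence(forward_runs=rec.runs, reverse_runs=reverse)


def _check_fasta_header(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}: not FASTA — expected '>' header at line {lineno}"
                )
            return
    raise ValueError(f"{path}: empty file")


def read_fasta(
    path: str | Path,
    concat_records: bool = False,
    hard_mask: bool = False,
) -> list[SequenceRecord]:
    """Read a FASTA file into sanitized :class:`SequenceRecord` objects.

    Parameters
    ----------
    path
        FASTA file; records are addressed by the first whitespace-delimited
        token of the header.
    concat_records
        Merge all records into a single record (id = first record's id) whose
        runs preserve record boundaries, so no counting window ever spans two
        records.
    hard_mask
        Treat lowercase (soft-masked) bases as ambiguous instead of upcasing.
    """
    path = Path(path)
    _check_fasta_header(path)
    records: list[SequenceRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(id=entry.id, runs=sanitize(str(entry.seq), hard_mask))
        )
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    if concat_records:
        merged: list[str] = []
        for rec in records:
            merged.extend(rec.runs)
        return [SequenceRecord(id=records[0].id, runs=tuple(merged))]
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 80) -> None:
    """Write records, joining runs with a single ``N`` so boundaries survive a round-trip."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = "N".join(rec.runs)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
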