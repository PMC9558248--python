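"""Reading hexapeptide inputs and writing prediction tables."""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from typing import Iterable, TextIO

from Bio import SeqIO

from .matrix import EffectMatrix, InvalidPeptideError, _format_milli, validate_peptide


@dataclass(frozen=True)
class PeptideInputError(ValueError):
    """One or more input records failed validation."""

    problems: tuple[str, ...]

    def __str__(self) -> str:
        return "; ".join(self.problems)


def _looks_like_fasta(text: str) -> bool:
    for line in text.splitlines():
        stripped = line.strip()
        if stripped and not stripped.startswith("#"):
            return stripped.startswith(">")
    return False


def read_peptides(source: str | os.PathLike | TextIO, *, fmt: str = "auto") -> list[str]:
    """Read hexapeptides from plain text (one per line) or FASTA.

    Plain text: one peptide per line, blank lines and '#' comments ignored.
    FASTA: every record's sequence must be exactly six residues — longer
    records are an error, never windowed (the scoring model is defined on
    hexapeptides only).

    All records are validated before anything is returned; every problem is
    reported with its line number (or record id) in a single
    :class:`PeptideInputError`.
    """
    if hasattr(source, "read"):
        text = source.read()
        name = getattr(source, "name", "<stream>")
    else:
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
        name = os.fspath(source)
    if fmt == "auto":
        fmt = "fasta" if _looks_like_fasta(text) else "plain"

    peptides: list[str] = []
    problems: list[str] = []
    if fmt == "fasta":
        for record in SeqIO.parse(io.StringIO(text), "fasta"):
            seq = str(record.seq)
            if len(seq) != 6:
                problems.append(
                    f"{name}: record {record.id!r} has length {len(seq)}; "
                    "FASTA records must be exact hexapeptides (no windowing)"
                )
                continue
            try:
                peptides.append(validate_peptide(seq))
            except InvalidPeptideError as exc:
                problems.append(f"{name}: record {record.id!r}: {exc}")
    elif fmt == "plain":
        for lineno, line in enumerate(text.splitlines(), start=1):
            stripped = line.split("#", 1)[0].strip()
            if not stripped:
                continue
            try:
                peptides.append(validate_peptide(stripped))
            except InvalidPeptideError as exc:
                problems.append(f"{name}: line {lineno}: {exc}")
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'plain', 'fasta' or 'auto'")
    if problems:
        raise PeptideInputError(tuple(problems))
    return peptides


def prediction_rows(matrix: EffectMatrix, peptides: Iterable[str]) -> Iterable[str]:
    """TSV rows (peptide, score to 3 decimals, label), header first."""
    yield "peptide\tscore\tlabel"
    for pep in peptides:
        s = matrix.score(pep)
        label = "amyloid" if s > 0 else "nonamyloid"
        yield f"{pep}\t{_format_milli(s)}\t{label}"
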