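"""Amyloid effect matrix: per-residue, per-position score contributions.

A linear SVM over hexapeptides reduces to a 20x6 table of precomputed
per-position contributions plus a scalar bias: the score of a hexapeptide is
the sum of the six table entries selected by its residues, plus the bias, and
the peptide is predicted amyloidogenic exactly when the score is positive.

All arithmetic is carried out in integer *milliunits* (1000x the published
decimal values). The default table has two decimals per entry and three on
the bias, so every quantity in this package is exact; there are no floating
point ties anywhere near the decision boundary.
"""

from __future__ import annotations

import hashlib
import io
import os
from typing import Iterable, Literal

import numpy as np

#: The 20 proteinogenic residues, in the row order of the default matrix.
RESIDUE_ORDER = "ARNDCQEGHILKMFPSTWYV"

RESIDUES = frozenset(RESIDUE_ORDER)

_ROW_INDEX = {aa: i for i, aa in enumerate(RESIDUE_ORDER)}

# Default contributions in milliunits, rows in RESIDUE_ORDER, columns are
# hexapeptide positions 1..6.
_DEFAULT_ENTRIES = np.array(
    [
        [-260, -320, -270, -140, -430, -220],  # A
        [-450, -410, -460, -330, -520, -350],  # R
        [-400, -340, -490, -270, -460, -300],  # N
        [-490, -430, -560, -410, -560, -360],  # D
        [-90, -210, 30, -50, -170, -50],       # C
        [-370, -300, -360, -340, -480, -320],  # Q
        [-510, -410, -430, -300, -610, -390],  # E
        [-230, -370, -460, -370, -300, -330],  # G
        [-320, -260, -260, -300, -350, -250],  # H
        [-60, -80, 260, 90, -60, -70],         # I
        [-100, -180, 20, 40, -220, -130],      # L
        [-390, -450, -510, -350, -590, -320],  # K
        [-170, -250, -20, -100, -190, -180],   # M
        [-130, -110, 50, -30, -130, -110],     # F
        [-560, -380, -560, -510, -420, -450],  # P
        [-370, -350, -410, -300, -480, -230],  # S
        [-340, -330, -280, -230, -400, -230],  # T
        [-170, -170, -90, -60, -120, -160],    # W
        [-230, -110, -130, -60, -180, -150],   # Y
        [-50, -140, 190, 140, -190, 10],       # V
    ],
    dtype=np.int32,
)

_DEFAULT_BIAS = 1083

AMYLOID = "amyloid"
NONAMYLOID = "nonamyloid"


class InvalidPeptideError(ValueError):
    """A peptide string is not a valid hexapeptide."""


class MatrixFormatError(ValueError):
    """A matrix file does not conform to the TSV contract."""


def validate_peptide(peptide: str) -> str:
    """Validate and canonicalize a hexapeptide string.

    Lowercase letters are accepted and uppercased; anything that is not one
    of the 20 one-letter residue codes, or a length other than 6, raises
    :class:`InvalidPeptideError` naming the offending character and position.
    """
    if not isinstance(peptide, str):
        raise InvalidPeptideError(f"peptide must be a string, got {type(peptide).__name__}")
    seq = peptide.strip().upper()
    if len(seq) != 6:
        raise InvalidPeptideError(
            f"peptide {peptide!r} has length {len(seq)}; a hexapeptide has exactly 6 residues"
        )
    for pos, ch in enumerate(seq, start=1):
        if ch not in RESIDUES:
            raise InvalidPeptideError(
                f"invalid residue {ch!r} at position {pos} in peptide {peptide!r}"
            )
    return seq


def _format_milli(value: int) -> str:
    """Render integer milliunits as an exact 3-decimal string."""
    sign = "-" if value < 0 else ""
    mag = abs(int(value))
    return f"{sign}{mag // 1000}.{mag % 1000:03d}"


def _parse_milli(text: str, *, context: str) -> int:
    """Parse a decimal string with at most 3 fractional digits to milliunits.

    More than three decimals is an error, never silently rounded: the whole
    package guarantees exact arithmetic on the stored values.
    """
    s = text.strip()
    if not s:
        raise MatrixFormatError(f"empty numeric field in {context}")
    neg = s.startswith("-")
    if s.startswith(("-", "+")):
        s = s[1:]
    # unicode minus from copy-pasted tables
    if not s and text.strip().startswith("−"):
        neg, s = True, text.strip()[1:]
    if "." in s:
        whole, frac = s.split(".", 1)
    else:
        whole, frac = s, ""
    if frac and not frac.isdigit() or (whole and not whole.isdigit()) or not (whole or frac):
        raise MatrixFormatError(f"malformed number {text!r} in {context}")
    if len(frac) > 3:
        raise MatrixFormatError(
            f"value {text!r} in {context} has more than 3 decimal places; "
            "refusing to round (exactness guarantee)"
        )
    milli = int(whole or "0") * 1000 + int(frac.ljust(3, "0") or "0")
    return -milli if neg else milli


class EffectMatrix:
    """A 20x6 table of integer-milliunit contributions plus a bias.

    Parameters
    ----------
    entries:
        Array-like of shape (20, 6), integer milliunits, rows in
        :data:`RESIDUE_ORDER`, columns = peptide positions 1..6.
    bias:
        Scalar bias in milliunits.
    """

    def __init__(self, entries, bias: int):
        arr = np.asarray(entries)
        if arr.shape != (20, 6):
            raise ValueError(f"entries must have shape (20, 6), got {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("entries must be integer milliunits; convert explicitly")
        self.entries = arr.astype(np.int32, copy=True)
        self.entries.flags.writeable = False
        self.bias = int(bias)

    # -- element access -------------------------------------------------

    def entry(self, residue: str, position: int) -> int:
        """Contribution (milliunits) of `residue` at 1-based `position`."""
        res = residue.upper()
        if res not in _ROW_INDEX:
            raise InvalidPeptideError(f"invalid residue {residue!r}")
        if not 1 <= position <= 6:
            raise ValueError(f"position must be in 1..6, got {position}")
        return int(self.entries[_ROW_INDEX[res], position - 1])

    def column(self, position: int) -> np.ndarray:
        """All 20 contributions for 1-based `position`, in RESIDUE_ORDER."""
        if not 1 <= position <= 6:
            raise ValueError(f"position must be in 1..6, got {position}")
        return self.entries[:, position - 1]

    def column_extreme(
        self,
        position: int,
        alphabet: Iterable[str],
        which: Literal["min", "max"],
    ) -> int:
        """Extreme contribution of a column restricted to an alphabet.

        `alphabet` is any non-empty iterable of residue letters (an
        :class:`~hexamyloid.alphabets.Alphabet` works directly).
        """
        rows = [_ROW_INDEX[aa] for aa in _iter_alphabet(alphabet)]
        if not rows:
            raise ValueError("alphabet must be non-empty")
        col = self.column(position)[rows]
        if which == "min":
            return int(col.min())
        if which == "max":
            return int(col.max())
        raise ValueError(f"which must be 'min' or 'max', got {which!r}")

    # -- scoring --------------------------------------------------------

    def raw_score(self, peptide: str) -> int:
        """Sum of the six selected entries, in milliunits (no bias)."""
        seq = validate_peptide(peptide)
        return int(sum(self.entries[_ROW_INDEX[aa], j] for j, aa in enumerate(seq)))

    def score(self, peptide: str) -> int:
        """Raw score plus bias, in milliunits."""
        return self.raw_score(peptide) + self.bias

    def predict(self, peptide: str) -> str:
        """Label: ``"amyloid"`` iff score > 0, else ``"nonamyloid"``.

        A score of exactly zero is nonamyloid; amyloid is the strict class.
        """
        return AMYLOID if self.score(peptide) > 0 else NONAMYLOID

    # -- serialization --------------------------------------------------

    def to_tsv(self) -> str:
        """Canonical TSV serialization (write → read → write is byte-stable)."""
        out = io.StringIO()
        out.write("residue\tpos1\tpos2\tpos3\tpos4\tpos5\tpos6\n")
        for i, aa in enumerate(RESIDUE_ORDER):
            vals = "\t".join(_format_milli(v) for v in self.entries[i])
            out.write(f"{aa}\t{vals}\n")
        out.write(f"BIAS\t{_format_milli(self.bias)}\t\t\t\t\t\n")
        return out.getvalue()

    def write_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w", encoding="ascii", newline="\n") as fh:
            fh.write(self.to_tsv())

    @classmethod
    def from_tsv(cls, source: str | os.PathLike) -> "EffectMatrix":
        """Read a matrix from a TSV file (the format :meth:`to_tsv` writes)."""
        with open(source, encoding="utf-8") as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
        if not lines or lines[0].split("\t")[0] != "residue":
            raise MatrixFormatError("missing 'residue\\tpos1..pos6' header row")
        header = lines[0].split("\t")
        if header != ["residue", "pos1", "pos2", "pos3", "pos4", "pos5", "pos6"]:
            raise MatrixFormatError(f"bad header {header!r}")
        body = lines[1:]
        if len(body) != 21:
            raise MatrixFormatError(f"expected 20 residue rows plus a BIAS row, got {len(body)}")
        entries = np.zeros((20, 6), dtype=np.int64)
        for lineno, line in enumerate(body[:20], start=2):
            fields = line.split("\t")
            if len(fields) != 7:
                raise MatrixFormatError(f"line {lineno}: expected 7 fields, got {len(fields)}")
            aa = fields[0]
            if aa != RESIDUE_ORDER[lineno - 2]:
                raise MatrixFormatError(
                    f"line {lineno}: residue {aa!r}, expected {RESIDUE_ORDER[lineno - 2]!r} "
                    "(rows must follow the canonical residue order)"
                )
            for j, field in enumerate(fields[1:]):
                entries[lineno - 2, j] = _parse_milli(field, context=f"line {lineno}, pos{j + 1}")
        bias_fields = body[20].split("\t")
        if bias_fields[0] != "BIAS":
            raise MatrixFormatError("last row must be the BIAS row")
        bias = _parse_milli(bias_fields[1], context="BIAS row")
        if any(f.strip() for f in bias_fields[2:]):
            raise MatrixFormatError("BIAS row carries a single value")
        return cls(entries, bias)

    def checksum(self) -> str:
        """SHA-256 of the canonical TSV form (used in mining output headers)."""
        return hashlib.sha256(self.to_tsv().encode("ascii")).hexdigest()

    # -- dunder ----------------------------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, EffectMatrix):
            return NotImplemented
        return self.bias == other.bias and bool(np.array_equal(self.entries, other.entries))

    def __hash__(self):
        return hash((self.bias, self.entries.tobytes()))

    def __repr__(self) -> str:
        return f"EffectMatrix(bias={self.bias}mu, checksum={self.checksum()[:8]})"


def _iter_alphabet(alphabet: Iterable[str]):
    for aa in alphabet:
        up = aa.upper()
        if up not in RESIDUES:
            raise ValueError(f"invalid residue {aa!r} in alphabet")
        yield up


_DEFAULT: EffectMatrix | None = None


def default_matrix() -> EffectMatrix:
    """The embedded default effect matrix (bias 1083 milliunits = 1.083).

    Returns a shared immutable instance; repeated calls are identical.
    """
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = EffectMatrix(_DEFAULT_ENTRIES, _DEFAULT_BIAS)
    return _DEFAULT


# Module-level functional aliases mirroring the class API.

def raw_score(matrix: EffectMatrix, peptide: str) -> int:
    return matrix.raw_score(peptide)


def score(matrix: EffectMatrix, peptide: str) -> int:
    return matrix.score(peptide)


def predict(matrix: EffectMatrix, peptide: str) -> str:
    return matrix.predict(peptide)


def column_extreme(matrix: EffectMatrix, position: int, alphabet, which) -> int:
    return matrix.column_extreme(position, alphabet, which)
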