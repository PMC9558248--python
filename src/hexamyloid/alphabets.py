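"""Residue alphabets used for wildcard substitution.

Restricting wildcard positions to a physicochemical class (small nonpolar,
hydrophobic, polar, ...) yields stronger uniform patterns than the
unrestricted 20-residue case; the built-in classes below are the standard
groupings, plus proline-free variants (proline being the classic
"structure breaker").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .matrix import RESIDUES, RESIDUE_ORDER


@dataclass(frozen=True)
class Alphabet:
    """A named, non-empty subset of the 20 proteinogenic residues."""

    name: str
    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.members:
            raise ValueError("alphabet must be non-empty")
        bad = self.members - RESIDUES
        if bad:
            raise ValueError(f"invalid residues in alphabet: {sorted(bad)}")

    @property
    def letters(self) -> str:
        """Members in standard alphabetical (one-letter) order."""
        return "".join(sorted(self.members))

    def __contains__(self, residue: str) -> bool:
        return residue.upper() in self.members

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def issubset(self, other: "Alphabet") -> bool:
        return self.members <= other.members

    def __repr__(self) -> str:
        return f"Alphabet({self.name!r}, {self.letters!r})"


def _make(name: str, letters: str) -> Alphabet:
    return Alphabet(name, frozenset(letters))


ALL = _make("all", RESIDUE_ORDER)
SMALL_NONPOLAR = _make("small_nonpolar", "GAST")
HYDROPHOBIC = _make("hydrophobic", "CVLIMPFYW")
POLAR = _make("polar", "DENQHKR")
HYDROPHOBIC_NO_P = _make("hydrophobic_noP", "CVLIMFYW")
ALL_NO_P = _make("all_noP", "".join(sorted(RESIDUES - {"P"})))

BUILTIN = {
    a.name: a
    for a in (ALL, SMALL_NONPOLAR, HYDROPHOBIC, POLAR, HYDROPHOBIC_NO_P, ALL_NO_P)
}


def get_alphabet(spec: str | Alphabet | Iterable[str]) -> Alphabet:
    """Resolve an alphabet from a name, an Alphabet, or explicit letters.

    A string is first looked up among the built-in class names; otherwise it
    is treated as an explicit set of residue letters (e.g. ``"AVIL"``) and
    returned as a custom alphabet.
    """
    if isinstance(spec, Alphabet):
        return spec
    if isinstance(spec, str):
        if spec in BUILTIN:
            return BUILTIN[spec]
        return Alphabet("custom", frozenset(spec.upper()))
    return Alphabet("custom", frozenset(aa.upper() for aa in spec))
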