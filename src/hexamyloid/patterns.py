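"""Wildcard hexapeptide patterns and uniform-class certification.

A pattern fixes some of the six positions to specific residues and leaves
the rest free ("x"); free positions range independently over a substitution
alphabet, so a pattern with f free positions stands for |alphabet|**f
hexapeptides. Because the score is additive over positions, the minimum
(maximum) score over that whole space is obtained by substituting, at each
free position independently, the residue with the smallest (largest) column
entry. A single O(1) bound therefore certifies that *every* expansion is
predicted amyloid (min score > 0) or that every one is nonamyloid
(max score <= 0), without enumerating the space.

The number of fixed positions is called the pattern's *core*. A uniform
pattern is *minimal* if freeing any single fixed position breaks uniformity;
by monotonicity of the bounds under specialization, checking single-slot
relaxations suffices for all subset relaxations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Literal

from .alphabets import ALL, Alphabet, get_alphabet
from .matrix import AMYLOID, NONAMYLOID, RESIDUES, EffectMatrix

#: Half-width (milliunits) of the rounding-ambiguity band around the decision
#: threshold. The published 2-decimal table entries are rounded from
#: full-precision SVM weights, so a deciding extreme this close to zero could
#: flip sign under the unrounded weights.
BOUNDARY_BAND = 10

UNIFORM_AMYLOID = "uniform_amyloid"
UNIFORM_NONAMYLOID = "uniform_nonamyloid"
MIXED = "mixed"

WILDCARD = "x"


class PatternError(ValueError):
    """A pattern string or pattern operation is invalid."""


@dataclass(frozen=True)
class Pattern:
    """Six slots, each a fixed residue or ``None`` (free), plus an alphabet.

    Fixed slots may hold any of the 20 residues regardless of the free-slot
    alphabet (restricted-class pattern tables routinely fix residues outside
    the substitution class).
    """

    slots: tuple[str | None, ...]
    alphabet: Alphabet = ALL

    def __post_init__(self):
        if len(self.slots) != 6:
            raise PatternError(f"pattern must have exactly 6 slots, got {len(self.slots)}")
        for pos, slot in enumerate(self.slots, start=1):
            if slot is not None and slot not in RESIDUES:
                raise PatternError(f"invalid fixed residue {slot!r} at position {pos}")

    # -- structure -------------------------------------------------------

    @property
    def core(self) -> int:
        """Number of fixed positions."""
        return sum(s is not None for s in self.slots)

    @property
    def n_free(self) -> int:
        return 6 - self.core

    @property
    def fixed_positions(self) -> tuple[int, ...]:
        """1-based positions of fixed slots."""
        return tuple(i for i, s in enumerate(self.slots, start=1) if s is not None)

    @property
    def free_positions(self) -> tuple[int, ...]:
        return tuple(i for i, s in enumerate(self.slots, start=1) if s is None)

    def expansion_count(self) -> int:
        return len(self.alphabet) ** self.n_free

    def with_alphabet(self, alphabet) -> "Pattern":
        return Pattern(self.slots, get_alphabet(alphabet))

    def relax(self, position: int) -> "Pattern":
        """Free the fixed slot at 1-based `position` (same alphabet)."""
        if self.slots[position - 1] is None:
            raise PatternError(f"position {position} is already free")
        slots = list(self.slots)
        slots[position - 1] = None
        return Pattern(tuple(slots), self.alphabet)

    def specialize(self, position: int, residue: str) -> "Pattern":
        """Fix the free slot at 1-based `position` to `residue`."""
        if self.slots[position - 1] is not None:
            raise PatternError(f"position {position} is already fixed")
        res = residue.upper()
        slots = list(self.slots)
        slots[position - 1] = res
        return Pattern(tuple(slots), self.alphabet)

    # -- expansion -------------------------------------------------------

    def expansions(self) -> Iterator[str]:
        """Yield every matching hexapeptide.

        Free slots are substituted in lexicographic order of the substituted
        residues (standard one-letter alphabetical order), so the stream is
        reproducible byte for byte.
        """
        choices = sorted(self.alphabet.members)
        free = [i for i, s in enumerate(self.slots) if s is None]
        template = list(self.slots)
        for combo in itertools.product(choices, repeat=len(free)):
            for i, aa in zip(free, combo):
                template[i] = aa
            yield "".join(template)  # type: ignore[arg-type]

    # -- text form -------------------------------------------------------

    @classmethod
    def parse(cls, text: str, alphabet=ALL) -> "Pattern":
        """Parse a 6-character pattern string like ``"xxPPxx"``.

        'x' or 'X' marks a free slot; residue letters (either case) are fixed
        slots. The free-slot alphabet defaults to all 20 residues and may be
        overridden.
        """
        if len(text) != 6:
            raise PatternError(f"pattern {text!r} has length {len(text)}, expected 6")
        slots: list[str | None] = []
        for pos, ch in enumerate(text, start=1):
            if ch in ("x", "X"):
                slots.append(None)
            elif ch.upper() in RESIDUES:
                slots.append(ch.upper())
            else:
                raise PatternError(f"invalid character {ch!r} at position {pos} in pattern {text!r}")
        return cls(tuple(slots), get_alphabet(alphabet))

    def __str__(self) -> str:
        return "".join(WILDCARD if s is None else s for s in self.slots)

    def __repr__(self) -> str:
        return f"Pattern({str(self)!r}, alphabet={self.alphabet.name!r})"


def parse_pattern(text: str, alphabet=ALL) -> Pattern:
    return Pattern.parse(text, alphabet)


def format_pattern(pattern: Pattern) -> str:
    return str(pattern)


def expansion_count(pattern: Pattern) -> int:
    return pattern.expansion_count()


def expansions(pattern: Pattern) -> Iterator[str]:
    return pattern.expansions()


def extreme_score(
    pattern: Pattern, matrix: EffectMatrix, which: Literal["min", "max"]
) -> int:
    """Exact min/max of ``score`` over all expansions, in milliunits.

    Fixed-slot contributions plus, per free slot, the column extreme over the
    substitution alphabet, plus the bias. Additivity makes the bound tight:
    the per-column argmin/argmax substitutions are witnesses.
    """
    total = matrix.bias
    for pos, slot in enumerate(pattern.slots, start=1):
        if slot is not None:
            total += matrix.entry(slot, pos)
        else:
            total += matrix.column_extreme(pos, pattern.alphabet, which)
    return total


@dataclass(frozen=True)
class PatternClassification:
    """Outcome of certifying a pattern's predicted class over its whole space."""

    label: str  # uniform_amyloid | uniform_nonamyloid | mixed
    min_score: int  # milliunits
    max_score: int  # milliunits
    boundary: bool

    @property
    def is_uniform(self) -> bool:
        return self.label != MIXED


def _boundary_flag(label: str, min_score: int, max_score: int, band: int) -> bool:
    # The deciding extreme is the min for a uniform-amyloid certificate and
    # the max for uniform-nonamyloid; a mixed verdict is flagged when either
    # extreme sits inside the band (full precision could make it uniform).
    if label == UNIFORM_AMYLOID:
        return abs(min_score) < band
    if label == UNIFORM_NONAMYLOID:
        return abs(max_score) < band
    return abs(min_score) < band or abs(max_score) < band


def classify_pattern(
    pattern: Pattern, matrix: EffectMatrix, *, band: int = BOUNDARY_BAND
) -> PatternClassification:
    """Certify a pattern as uniformly amyloid, uniformly nonamyloid, or mixed.

    ``uniform_amyloid`` iff the minimum score over all expansions is strictly
    positive; ``uniform_nonamyloid`` iff the maximum is <= 0 (a score of
    exactly zero predicts nonamyloid). The boundary flag marks verdicts whose
    deciding extreme lies within `band` milliunits of zero, where the
    rounding of the published matrix makes the verdict ambiguous.
    """
    lo = extreme_score(pattern, matrix, "min")
    hi = extreme_score(pattern, matrix, "max")
    if lo > 0:
        label = UNIFORM_AMYLOID
    elif hi <= 0:
        label = UNIFORM_NONAMYLOID
    else:
        label = MIXED
    return PatternClassification(label, lo, hi, _boundary_flag(label, lo, hi, band))


def brute_force_classify(
    pattern: Pattern,
    matrix: EffectMatrix,
    *,
    limit: int = 10**6,
    band: int = BOUNDARY_BAND,
) -> PatternClassification:
    """Classify by scoring every expansion individually.

    Independent oracle for :func:`classify_pattern`: no column bounds, just
    full enumeration. Refuses spaces larger than `limit` expansions.
    """
    n = pattern.expansion_count()
    if n > limit:
        raise PatternError(
            f"pattern {pattern} expands to {n} hexapeptides, over the limit of {limit}"
        )
    lo = hi = None
    any_amyloid = any_nonamyloid = False
    for pep in pattern.expansions():
        s = matrix.score(pep)
        lo = s if lo is None else min(lo, s)
        hi = s if hi is None else max(hi, s)
        if s > 0:
            any_amyloid = True
        else:
            any_nonamyloid = True
    assert lo is not None and hi is not None
    if not any_nonamyloid:
        label = UNIFORM_AMYLOID
    elif not any_amyloid:
        label = UNIFORM_NONAMYLOID
    else:
        label = MIXED
    return PatternClassification(label, lo, hi, _boundary_flag(label, lo, hi, band))


def is_minimal(pattern: Pattern, matrix: EffectMatrix, target_class: str) -> bool:
    """True iff no single fixed slot can be freed without losing uniformity.

    The pattern must currently be uniformly of `target_class` (contract
    error otherwise). A freed slot becomes a wildcard over the pattern's own
    alphabet. Single-slot relaxation is sufficient: validity is monotone
    under specialization, so if some subset relaxation were still valid, the
    single-slot relaxations above it would be valid too.
    """
    if target_class not in (AMYLOID, NONAMYLOID):
        raise ValueError(f"target_class must be 'amyloid' or 'nonamyloid', got {target_class!r}")
    wanted = UNIFORM_AMYLOID if target_class == AMYLOID else UNIFORM_NONAMYLOID
    if classify_pattern(pattern, matrix).label != wanted:
        raise PatternError(
            f"pattern {pattern} is not uniformly {target_class}; minimality is undefined"
        )
    for pos in pattern.fixed_positions:
        if classify_pattern(pattern.relax(pos), matrix).label == wanted:
            return False
    return True
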