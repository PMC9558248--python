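"""Exhaustive mining of uniform wildcard patterns.

For a target class, substitution alphabet and set of core sizes k, the miner
enumerates every candidate pattern — each of the C(6, k) position subsets
crossed with every residue assignment to the fixed slots — and keeps those
whose worst-case score bound certifies a uniform prediction. With fixed
slots ranging over all 20 residues and k = 1..6 that is

    sum_k C(6, k) * 20**k  =  21**6 - 1  =  85,766,120

candidates; each verification is O(1) (fixed-slot sum plus precomputed
free-column extremes), and the scan is vectorized over the residue
assignments of each position subset, so the complete sweep runs in seconds.

Minimality is checked in the same vectorized pass: freeing the fixed slot at
position p changes the deciding bound by (column extreme at p) − (entry of
the fixed residue at p), so each of the k single-slot relaxations is another
O(1) test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations, product
from math import comb
from typing import Iterable, Iterator, Sequence

import numpy as np

from .alphabets import ALL, Alphabet, get_alphabet
from .matrix import (
    AMYLOID,
    NONAMYLOID,
    RESIDUE_ORDER,
    EffectMatrix,
    _format_milli,
    _parse_milli,
    default_matrix,
)
from .patterns import (
    BOUNDARY_BAND,
    UNIFORM_AMYLOID,
    UNIFORM_NONAMYLOID,
    Pattern,
    brute_force_classify,
    classify_pattern,
)

logger = logging.getLogger(__name__)

#: Emit a progress log line roughly every this many candidates.
PROGRESS_EVERY = 10**6


def candidate_count(core_sizes: Iterable[int], n_fixed_residues: int = 20) -> int:
    """Number of (position subset, residue assignment) candidates examined.

    Fixed slots always range over the full residue pool (20 by default),
    independent of the wildcard substitution alphabet.
    """
    sizes = set(core_sizes)
    if not sizes <= set(range(7)):
        raise ValueError(f"core sizes must be within 0..6, got {sorted(sizes)}")
    return sum(comb(6, k) * n_fixed_residues**k for k in sizes)


@dataclass(frozen=True)
class MiningSpec:
    """What to mine: class, wildcard alphabet, core sizes, minimality filter."""

    target_class: str
    free_alphabet: Alphabet = ALL
    core_sizes: frozenset[int] = frozenset({4})
    minimal_only: bool = False
    matrix: EffectMatrix = field(default_factory=default_matrix)

    def __post_init__(self):
        if self.target_class not in (AMYLOID, NONAMYLOID):
            raise ValueError(f"target_class must be amyloid|nonamyloid, got {self.target_class!r}")
        sizes = frozenset(int(k) for k in self.core_sizes)
        object.__setattr__(self, "core_sizes", sizes)
        if not sizes:
            raise ValueError("core_sizes must be non-empty")
        if not sizes <= set(range(7)):
            raise ValueError(f"core sizes must be within 0..6, got {sorted(sizes)}")
        object.__setattr__(self, "free_alphabet", get_alphabet(self.free_alphabet))


@dataclass(frozen=True)
class MinedPattern:
    """One valid pattern with its certification details."""

    pattern: Pattern
    min_score: int
    max_score: int
    minimal: bool
    boundary: bool


@dataclass
class _Group:
    """Valid candidates for one (core, position subset), stored compactly.

    `indices` are base-m residue-assignment codes (m = pool size, leftmost
    fixed position most significant, digits in canonical residue row order),
    so ascending index order is the canonical secondary sort.
    """

    positions: tuple[int, ...]  # 1-based, ascending
    pool: str  # fixed-slot residue pool, canonical row order
    indices: np.ndarray  # int64
    min_scores: np.ndarray  # int32, milliunits
    max_scores: np.ndarray
    minimal: np.ndarray  # bool
    boundary: np.ndarray  # bool

    def __len__(self) -> int:
        return int(self.indices.size)

    def decode(self, idx: int) -> tuple[str, ...]:
        """Residues assigned to the fixed positions for candidate code idx."""
        k, m = len(self.positions), len(self.pool)
        return tuple(self.pool[(idx // m ** (k - 1 - i)) % m] for i in range(k))

    def residue_digits(self) -> np.ndarray:
        """(n, k) array of pool indices for all stored candidates."""
        k, m = len(self.positions), len(self.pool)
        if k == 0:
            return np.zeros((len(self), 0), dtype=np.int64)
        powers = m ** np.arange(k - 1, -1, -1, dtype=np.int64)
        return (self.indices[:, None] // powers[None, :]) % m


class MiningResult:
    """All valid patterns found by a sweep, in deterministic canonical order.

    Patterns are kept as compact per-subset index arrays and materialized on
    demand, so multi-million-pattern sweeps stay cheap; counts and summaries
    never materialize anything.
    """

    def __init__(self, spec: MiningSpec, groups: list[_Group], n_candidates: int):
        self.spec = spec
        # canonical order: primary = position subset (tuple order), then core
        self.groups = sorted(groups, key=lambda g: (g.positions, len(g.positions)))
        self.candidate_count = n_candidates

    def __len__(self) -> int:
        return sum(len(g) for g in self.groups)

    def counts_by_core(self) -> dict[int, int]:
        out: dict[int, int] = {k: 0 for k in sorted(self.spec.core_sizes)}
        for g in self.groups:
            out[len(g.positions)] += len(g)
        return out

    def boundary_counts_by_core(self) -> dict[int, int]:
        out: dict[int, int] = {k: 0 for k in sorted(self.spec.core_sizes)}
        for g in self.groups:
            out[len(g.positions)] += int(g.boundary.sum())
        return out

    def iter_patterns(self) -> Iterator[MinedPattern]:
        alphabet = self.spec.free_alphabet
        for g in self.groups:
            for j in range(len(g)):
                slots: list[str | None] = [None] * 6
                for pos, aa in zip(g.positions, g.decode(int(g.indices[j]))):
                    slots[pos - 1] = aa
                yield MinedPattern(
                    Pattern(tuple(slots), alphabet),
                    int(g.min_scores[j]),
                    int(g.max_scores[j]),
                    bool(g.minimal[j]),
                    bool(g.boundary[j]),
                )

    def patterns(self) -> list[MinedPattern]:
        return list(self.iter_patterns())

    def pattern_strings(self) -> list[str]:
        return [str(p.pattern) for p in self.iter_patterns()]

    # -- summaries -------------------------------------------------------

    def summarize(self, exclude_residues: Iterable[str] | None = None) -> dict:
        """Per-core pattern counts, boundary counts, and optionally the number
        of patterns whose fixed slots avoid a residue set entirely."""
        summary: dict = {
            "class": self.spec.target_class,
            "alphabet": self.spec.free_alphabet.name,
            "minimal_only": self.spec.minimal_only,
            "candidates": self.candidate_count,
            "total": len(self),
            "by_core": self.counts_by_core(),
            "boundary_by_core": self.boundary_counts_by_core(),
        }
        if exclude_residues is not None:
            excl = {aa.upper() for aa in exclude_residues}
            per_core = {k: 0 for k in sorted(self.spec.core_sizes)}
            for g in self.groups:
                if not len(g):
                    continue
                keep = ~np.zeros(len(g), dtype=bool)
                digits = g.residue_digits()
                for i in range(digits.shape[1]):
                    hit = np.isin(digits[:, i], [g.pool.index(a) for a in excl if a in g.pool])
                    keep &= ~hit
                per_core[len(g.positions)] += int(keep.sum())
            summary["free_of"] = {"residues": "".join(sorted(excl)), "by_core": per_core}
        return summary

    # -- serialization ---------------------------------------------------

    def write_tsv(self, path) -> None:
        spec = self.spec
        with open(path, "w", encoding="ascii", newline="\n") as fh:
            fh.write("# hexamyloid mining result\n")
            fh.write(
                "# class={} alphabet={} letters={} cores={} minimal_only={}\n".format(
                    spec.target_class,
                    spec.free_alphabet.name,
                    spec.free_alphabet.letters,
                    ",".join(str(k) for k in sorted(spec.core_sizes)),
                    str(spec.minimal_only).lower(),
                )
            )
            fh.write(f"# matrix_sha256={spec.matrix.checksum()}\n")
            fh.write(
                "pattern\talphabet\tcore\tclass\tmin_score\tmax_score\tminimal\tboundary_flag\n"
            )
            for rec in self.iter_patterns():
                fh.write(
                    "{}\t{}\t{}\t{}\t{}\t{}\t{}\t{}\n".format(
                        rec.pattern,
                        spec.free_alphabet.name,
                        rec.pattern.core,
                        spec.target_class,
                        _format_milli(rec.min_score),
                        _format_milli(rec.max_score),
                        str(rec.minimal).lower(),
                        str(rec.boundary).lower(),
                    )
                )


def read_patterns_tsv(path, alphabet: Alphabet | None = None) -> list[MinedPattern]:
    """Re-parse a mining TSV into pattern records (round-trip of write_tsv)."""
    records: list[MinedPattern] = []
    header_alphabet: Alphabet | None = alphabet
    with open(path, encoding="ascii") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("# class=") and header_alphabet is None:
                    fields = dict(f.split("=", 1) for f in line[2:].split() if "=" in f)
                    header_alphabet = Alphabet(fields["alphabet"], frozenset(fields["letters"]))
                continue
            if line.startswith("pattern\t"):
                continue
            f = line.split("\t")
            pat = Pattern.parse(f[0], header_alphabet if header_alphabet is not None else ALL)
            records.append(
                MinedPattern(
                    pat,
                    _parse_milli(f[4], context=f"min_score of {f[0]}"),
                    _parse_milli(f[5], context=f"max_score of {f[0]}"),
                    f[6] == "true",
                    f[7] == "true",
                )
            )
    return records


# -- the sweep -----------------------------------------------------------


def _alphabet_extremes(matrix: EffectMatrix, alphabet: Alphabet) -> tuple[np.ndarray, np.ndarray]:
    rows = [RESIDUE_ORDER.index(aa) for aa in alphabet]
    sub = matrix.entries[rows, :]
    return sub.min(axis=0).astype(np.int64), sub.max(axis=0).astype(np.int64)


def mine(
    spec: MiningSpec,
    *,
    fixed_residues: str | Sequence[str] | None = None,
    slack: int = 0,
    band: int = BOUNDARY_BAND,
    progress_every: int = PROGRESS_EVERY,
) -> MiningResult:
    """Run the exhaustive sweep described in the module docstring.

    Parameters
    ----------
    fixed_residues:
        Residue pool for the fixed slots; default all 20. Restricting it
        shrinks the candidate space proportionally (used for reduced sweeps
        and oracle comparisons); results are then complete w.r.t. that pool.
    slack:
        Audit knob (milliunits): shifts the decision threshold so that
        ``slack > 0`` also admits candidates whose deciding extreme misses
        the threshold by at most `slack`. The default 0 is the exact rule.
    band:
        Boundary-flag half-width in milliunits.
    """
    matrix = spec.matrix
    amyloid = spec.target_class == AMYLOID
    if fixed_residues is None:
        pool = RESIDUE_ORDER
    else:
        seen = {aa.upper() for aa in fixed_residues}
        pool = "".join(aa for aa in RESIDUE_ORDER if aa in seen)
        if len(pool) != len(seen):
            raise ValueError(f"invalid fixed-residue pool {fixed_residues!r}")
    pool_rows = np.array([RESIDUE_ORDER.index(aa) for aa in pool])
    col_min, col_max = _alphabet_extremes(matrix, spec.free_alphabet)
    entries = matrix.entries.astype(np.int64)

    groups: list[_Group] = []
    n_candidates = 0
    since_log = 0
    for k in sorted(spec.core_sizes):
        for positions0 in combinations(range(6), k):
            m = len(pool)
            n_candidates += m**k
            since_log += m**k
            free0 = [p for p in range(6) if p not in positions0]
            free_min = int(sum(col_min[p] for p in free0))
            free_max = int(sum(col_max[p] for p in free0))

            fixed = np.zeros(1, dtype=np.int64)
            for p in positions0:
                fixed = (fixed[:, None] + entries[pool_rows, p][None, :]).ravel()
            min_s = fixed + (free_min + matrix.bias)
            max_s = min_s if not free0 else fixed + (free_max + matrix.bias)
            del fixed

            valid = (min_s > -slack) if amyloid else (max_s <= slack)
            idx = np.flatnonzero(valid)
            min_v = min_s[idx].astype(np.int32)
            max_v = max_s[idx].astype(np.int32)

            # single-slot relaxations, vectorized over the valid candidates
            minimal = np.ones(idx.size, dtype=bool)
            for i, p in enumerate(positions0):
                digit = (idx // m ** (k - 1 - i)) % m
                e = entries[pool_rows[digit], p]
                if amyloid:
                    relaxed = min_v.astype(np.int64) - e + col_min[p]
                    minimal &= ~(relaxed > -slack)
                else:
                    relaxed = max_v.astype(np.int64) - e + col_max[p]
                    minimal &= ~(relaxed <= slack)

            deciding = min_v if amyloid else max_v
            boundary = np.abs(deciding) < band

            if spec.minimal_only:
                keep = minimal
                idx, min_v, max_v, boundary = idx[keep], min_v[keep], max_v[keep], boundary[keep]
                minimal = np.ones(idx.size, dtype=bool)

            groups.append(
                _Group(
                    tuple(p + 1 for p in positions0),
                    pool,
                    idx,
                    min_v,
                    max_v,
                    minimal,
                    boundary,
                )
            )
            if since_log >= progress_every:
                logger.info(
                    "mined %s candidates so far (%d patterns kept)",
                    f"{n_candidates:,}",
                    sum(len(g) for g in groups),
                )
                since_log = 0
    result = MiningResult(spec, groups, n_candidates)
    logger.info(
        "sweep done: %s candidates, %d valid patterns (class=%s, alphabet=%s)",
        f"{n_candidates:,}",
        len(result),
        spec.target_class,
        spec.free_alphabet.name,
    )
    return result


def summarize(result: MiningResult, exclude_residues: Iterable[str] | None = None) -> dict:
    """Module-level alias for :meth:`MiningResult.summarize`."""
    return result.summarize(exclude_residues)


# -- independent oracle ---------------------------------------------------


def brute_force_mine(
    spec: MiningSpec,
    *,
    fixed_residues: str | Sequence[str] | None = None,
    expansion_limit: int = 10**6,
) -> list[MinedPattern]:
    """Mine by classifying every candidate through full expansion.

    Independent oracle for :func:`mine`: validity and minimality are both
    decided by :func:`~hexamyloid.patterns.brute_force_classify`, never by
    the column bounds. Only feasible for small pools/alphabets.
    """
    matrix = spec.matrix
    wanted = UNIFORM_AMYLOID if spec.target_class == AMYLOID else UNIFORM_NONAMYLOID
    pool = RESIDUE_ORDER if fixed_residues is None else "".join(
        aa for aa in RESIDUE_ORDER if aa in {a.upper() for a in fixed_residues}
    )
    found: list[MinedPattern] = []
    for k in sorted(spec.core_sizes):
        for positions0 in combinations(range(6), k):
            for assignment in product(pool, repeat=k):
                slots: list[str | None] = [None] * 6
                for p, aa in zip(positions0, assignment):
                    slots[p] = aa
                pat = Pattern(tuple(slots), spec.free_alphabet)
                cls = brute_force_classify(pat, matrix, limit=expansion_limit)
                if cls.label != wanted:
                    continue
                minimal = all(
                    brute_force_classify(pat.relax(pos), matrix, limit=expansion_limit).label
                    != wanted
                    for pos in pat.fixed_positions
                )
                if spec.minimal_only and not minimal:
                    continue
                found.append(MinedPattern(pat, cls.min_score, cls.max_score, minimal, cls.boundary))
    return found
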