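"""Seeded synthetic fixtures: random matrices, peptide files, small alphabets.

Everything here is generated, deterministic in the seed, and sized for
oracle tests — random effect matrices bracket the default table's entry
range, and every generated matrix admits both predicted labels so that
classification tests are never vacuous.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .alphabets import Alphabet
from .matrix import RESIDUE_ORDER, EffectMatrix

#: Entry range (milliunits) for random matrices; brackets the default table.
ENTRY_RANGE = (-600, 300)
#: Bias range (milliunits) for random matrices.
BIAS_RANGE = (500, 1500)


def random_matrix(rng: np.random.Generator) -> EffectMatrix:
    """A random effect matrix guaranteed to admit both predicted labels.

    Entries are uniform integers on ``ENTRY_RANGE`` milliunits, the bias on
    ``BIAS_RANGE``; draws are rejected (rare) until the best-case peptide
    scores positive and the worst-case one scores <= 0.
    """
    while True:
        entries = rng.integers(ENTRY_RANGE[0], ENTRY_RANGE[1] + 1, size=(20, 6))
        bias = int(rng.integers(BIAS_RANGE[0], BIAS_RANGE[1] + 1))
        if entries.max(axis=0).sum() + bias > 0 and entries.min(axis=0).sum() + bias <= 0:
            return EffectMatrix(entries, bias)


def random_peptide(rng: np.random.Generator) -> str:
    return "".join(RESIDUE_ORDER[i] for i in rng.integers(0, 20, size=6))


def random_alphabet(rng: np.random.Generator, size: int) -> Alphabet:
    """A random custom alphabet of the given size (2..20)."""
    if not 1 <= size <= 20:
        raise ValueError(f"alphabet size must be 1..20, got {size}")
    picks = rng.choice(20, size=size, replace=False)
    return Alphabet("custom", frozenset(RESIDUE_ORDER[i] for i in picks))


@dataclass(frozen=True)
class FixtureSet:
    """File-backed fixtures written by :func:`make_fixtures`."""

    matrix_paths: tuple[str, ...]
    valid_peptide_path: str
    invalid_peptide_path: str
    alphabets: tuple[Alphabet, ...]


def make_fixtures(
    seed: int,
    out_dir: str | os.PathLike,
    *,
    n_matrices: int = 3,
    n_peptides: int = 50,
    alphabet_sizes: tuple[int, ...] = (2, 3, 4, 5, 6),
) -> FixtureSet:
    """Write a reproducible fixture collection under `out_dir`.

    Produces `n_matrices` random matrix TSVs, one valid peptide file, one
    peptide file with deliberate errors (bad residue, bad length), and a set
    of small random alphabets. Identical seeds yield identical bytes.
    """
    rng = np.random.default_rng(seed)
    out = os.fspath(out_dir)
    os.makedirs(out, exist_ok=True)

    matrix_paths = []
    for i in range(n_matrices):
        path = os.path.join(out, f"matrix_{i}.tsv")
        random_matrix(rng).write_tsv(path)
        matrix_paths.append(path)

    valid_path = os.path.join(out, "peptides_valid.txt")
    with open(valid_path, "w", encoding="ascii", newline="\n") as fh:
        fh.write("# synthetic hexapeptides\n")
        for _ in range(n_peptides):
            fh.write(random_peptide(rng) + "\n")

    invalid_path = os.path.join(out, "peptides_invalid.txt")
    with open(invalid_path, "w", encoding="ascii", newline="\n") as fh:
        fh.write(random_peptide(rng) + "\n")
        fh.write(random_peptide(rng)[:5] + "Z\n")  # bad residue
        fh.write(random_peptide(rng)[:4] + "\n")  # bad length
        fh.write(random_peptide(rng) + "\n")

    alphabets = tuple(random_alphabet(rng, s) for s in alphabet_sizes)
    return FixtureSet(tuple(matrix_paths), valid_path, invalid_path, alphabets)
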