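"""Pattern semantics: parsing, expansion, tight score bounds, minimality."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hexamyloid import (
    ALL,
    ALL_NO_P,
    HYDROPHOBIC_NO_P,
    Pattern,
    PatternError,
    brute_force_classify,
    classify_pattern,
    default_matrix,
    extreme_score,
    get_alphabet,
    is_minimal,
    parse_pattern,
)
from hexamyloid.fixtures import random_alphabet, random_matrix

pattern_texts = st.text(alphabet="ACDEFGHIKLMNPQRSTVWYx", min_size=6, max_size=6)


class TestParsing:
    @pytest.mark.parametrize(
        "text, core, fixed",
        [
            ("xxPPxx", 2, {3: "P", 4: "P"}),
            ("FxFLWx", 4, {1: "F", 3: "F", 4: "L", 5: "W"}),
            ("xxxxxx", 0, {}),
            ("IVIVIV", 6, dict(enumerate("IVIVIV", start=1))),
        ],
    )
    def test_core_and_fixed_slots(self, text, core, fixed):
        pat = parse_pattern(text)
        assert pat.core == core
        assert {p: pat.slots[p - 1] for p in pat.fixed_positions} == fixed

    def test_case_insensitive_with_canonical_form(self):
        assert str(parse_pattern("XXppXX")) == "xxPPxx"

    @pytest.mark.parametrize("bad", ["xxPPx", "xxPPxxx", "xxBPxx", "xx-Pxx"])
    def test_rejects_bad_text(self, bad):
        with pytest.raises(PatternError):
            parse_pattern(bad)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(text=pattern_texts)
    def test_parse_format_round_trip(self, text):
        pat = parse_pattern(text)
        assert parse_pattern(str(pat)) == pat
        assert pat.core + pat.n_free == 6


class TestExpansion:
    @pytest.mark.parametrize(
        "text, alphabet, count",
        [
            ("xxPPxx", "all", 160_000),
            ("IVIVIV", "all", 1),
            ("Cxxxxx", "hydrophobic_noP", 32_768),
            ("xxIVIx", "all_noP", 6_859),
            ("xxIVIx", "polar", 343),
        ],
    )
    def test_expansion_counts(self, text, alphabet, count):
        assert parse_pattern(text, alphabet).expansion_count() == count

    def test_expansions_enumerate_in_lexicographic_order(self):
        pat = parse_pattern("AxPxxV", get_alphabet("VAC"))
        got = list(pat.expansions())
        want = [
            f"A{a}P{b}{c}V" for a, b, c in itertools.product("ACV", repeat=3)
        ]
        assert got == want

    def test_core6_expands_to_its_single_peptide(self):
        assert list(parse_pattern("IVIVIV").expansions()) == ["IVIVIV"]

    def test_relax_and_specialize_are_inverse(self):
        pat = parse_pattern("xxPPxx")
        assert pat.relax(3) == parse_pattern("xxxPxx")
        assert parse_pattern("xxxPxx").specialize(3, "P") == pat


class TestExtremeScores:
    def test_hand_checked_bounds(self, matrix):
        assert extreme_score(parse_pattern("FxFLWx"), matrix, "min") == 23
        assert extreme_score(parse_pattern("xxPPxx"), matrix, "max") == -167

    def test_core6_min_equals_max_equals_score(self, matrix):
        pat = parse_pattern("IVIVIV")
        assert (
            extreme_score(pat, matrix, "min")
            == extreme_score(pat, matrix, "max")
            == matrix.score("IVIVIV")
        )

    def test_bounds_are_attained_by_expansions(self, matrix):
        pat = parse_pattern("xxPPxx", get_alphabet("AVILP"))
        scores = [matrix.score(p) for p in pat.expansions()]
        assert min(scores) == extreme_score(pat, matrix, "min")
        assert max(scores) == extreme_score(pat, matrix, "max")


class TestClassification:
    @pytest.mark.parametrize(
        "text, label",
        [
            ("xxPPxx", "uniform_nonamyloid"),
            ("FxFLWx", "uniform_amyloid"),
            ("xxIVIV", "uniform_amyloid"),
            ("AxxxxA", "mixed"),
        ],
    )
    def test_known_patterns(self, matrix, text, label):
        cls = classify_pattern(parse_pattern(text), matrix)
        assert cls.label == label

    def test_deciding_extreme_well_clear_of_band_is_unflagged(self, matrix):
        cls = classify_pattern(parse_pattern("FxFLWx"), matrix)
        assert cls.min_score == 23 and not cls.boundary

    def test_restricted_alphabet_upgrades_mixed_to_uniform(self, matrix):
        pat = parse_pattern("xxxFxx")
        assert classify_pattern(pat, matrix).label == "mixed"
        assert (
            classify_pattern(pat.with_alphabet(HYDROPHOBIC_NO_P), matrix).label
            == "uniform_amyloid"
        )

    def test_brute_force_refuses_oversized_spaces(self, matrix):
        with pytest.raises(PatternError, match="limit"):
            brute_force_classify(parse_pattern("xxxxxx"), matrix, limit=10**5)

    def test_agrees_with_brute_force_on_seeded_random_instances(self):
        gen = np.random.default_rng(42)
        for _ in range(30):
            m = random_matrix(gen)
            alpha = random_alphabet(gen, int(gen.integers(2, 7)))
            slots = tuple(
                None if gen.random() < 0.5 else "ACDEFGHIKLMNPQRSTVWY"[gen.integers(0, 20)]
                for _ in range(6)
            )
            pat = Pattern(slots, alpha)
            assert brute_force_classify(pat, m) == classify_pattern(pat, m)


class TestMonotonicity:
    def test_specialization_preserves_uniformity(self, matrix):
        # fix any free slot of a uniform pattern to any residue: still uniform
        for text, label in [("xxPPxx", "uniform_nonamyloid"), ("FxFLWx", "uniform_amyloid")]:
            pat = parse_pattern(text)
            for pos in pat.free_positions:
                for aa in "ACDEFGHIKLMNPQRSTVWY":
                    child = pat.specialize(pos, aa)
                    assert classify_pattern(child, matrix).label == label

    def test_alphabet_shrinkage_preserves_uniformity(self, matrix):
        pat = parse_pattern("xxPPxx")
        for sub in ("AVIL", "P", "DENQHKR", "GAST"):
            assert (
                classify_pattern(pat.with_alphabet(get_alphabet(sub)), matrix).label
                == "uniform_nonamyloid"
            )


class TestMinimality:
    def test_published_minimal_and_nonminimal_examples(self, matrix):
        assert is_minimal(parse_pattern("xxPPxx"), matrix, "nonamyloid") is True
        assert is_minimal(parse_pattern("WxPPxx"), matrix, "nonamyloid") is False
        assert is_minimal(parse_pattern("VIPPxx"), matrix, "nonamyloid") is False

    def test_single_slot_relaxations_of_minimal_pattern_are_invalid(self, matrix):
        for text in ("xxxPxx", "xxPxxx"):
            assert classify_pattern(parse_pattern(text), matrix).label == "mixed"

    def test_contract_error_when_pattern_not_uniform(self, matrix):
        with pytest.raises(PatternError, match="not uniformly"):
            is_minimal(parse_pattern("AxxxxA"), matrix, "nonamyloid")

    def test_single_slot_relaxation_equals_subset_relaxation(self):
        # monotonicity makes one-slot checks sufficient; verify against an
        # exhaustive check over every subset relaxation on random instances
        gen = np.random.default_rng(99)
        checked = 0
        while checked < 12:
            m = random_matrix(gen)
            alpha = random_alphabet(gen, int(gen.integers(2, 5)))
            slots = tuple(
                "ACDEFGHIKLMNPQRSTVWY"[gen.integers(0, 20)] if i < 4 else None
                for i in range(6)
            )
            pat = Pattern(slots, alpha)
            cls = classify_pattern(pat, m)
            if not cls.is_uniform:
                continue
            target = "amyloid" if cls.label == "uniform_amyloid" else "nonamyloid"
            fast = is_minimal(pat, m, target)
            wanted = cls.label
            slow = all(
                classify_pattern(relaxed, m).label != wanted
                for r in range(1, pat.core + 1)
                for positions in itertools.combinations(pat.fixed_positions, r)
                for relaxed in [_relax_all(pat, positions)]
            )
            assert fast == slow
            checked += 1


def _relax_all(pat: Pattern, positions) -> Pattern:
    for pos in positions:
        pat = pat.relax(pos)
    return pat
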