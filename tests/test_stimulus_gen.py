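"""Modal/minor selection, deliberate-error generation and list assignment."""

import numpy as np
import pytest

from nonwordeval.phoneme_core import Pronunciation, default_inventory, is_valid_substitution
from nonwordeval.stimulus_gen import (
    ListAssignmentError,
    NoValidSubstitutionError,
    RetryLimitError,
    StimulusError,
    assign_lists,
    build_catch_trials,
    enumerate_error_candidates,
    generate_deliberate_error,
    minor_pronunciation,
    modal_pronunciation,
    validate_lists,
)

INV = default_inventory()


class TestModalMinor:
    def test_modal_is_most_frequent(self, entry):
        e = entry(*(["p{t"] * 30 + ["pEt"] * 5 + ["pIt"] * 3))
        assert modal_pronunciation(e).disc == "p{t"

    def test_modal_of_single_response(self, entry):
        assert modal_pronunciation(entry("p{t")).disc == "p{t"

    def test_modal_tie_breaks_lexicographically(self, entry):
        assert modal_pronunciation(entry("pEt", "p{t", "p{t", "pEt")).disc == \
            min("pEt", "p{t")

    def test_minor_is_most_frequent_in_band(self, entry):
        e = entry(*(["p{t"] * 30 + ["pEt"] * 5 + ["pIt"] * 3 + ["pQt"]))
        assert minor_pronunciation(e).disc == "pEt"

    def test_minor_absent_when_no_candidate(self, entry):
        e = entry(*(["p{t"] * 30 + ["pQt"]))
        assert minor_pronunciation(e) is None

    def test_minor_tie_breaks_lexicographically(self, entry):
        e = entry(*(["p{t"] * 30 + ["pIt"] * 4 + ["pEt"] * 4))
        assert minor_pronunciation(e).disc == min("pIt", "pEt")

    def test_minor_never_returns_the_modal(self, entry):
        # Modal count falls inside the 2..6 band but modal and minor are
        # distinct stimulus conditions.
        e = entry(*(["p{t"] * 4 + ["pEt"] * 3))
        assert minor_pronunciation(e).disc == "pEt"


class TestDeliberateError:
    def test_changes_exactly_one_position_with_valid_substitute(self):
        spec = generate_deliberate_error("6tbQst", INV, seed=1)
        diffs = [i for i, (a, b) in enumerate(zip(spec.source.disc,
                                                  spec.result.disc)) if a != b]
        assert diffs == [spec.position]
        assert is_valid_substitution(INV[spec.original], INV[spec.substitute])

    def test_outbost_substitution_is_producible(self):
        # Q→5 is a legal draw for 6tbQst: a short back vowel replaced by a
        # mid diphthong.
        assert (3, "5") in enumerate_error_candidates("6tbQst", INV)

    def test_forbidden_collision_is_never_emitted(self):
        # The attested minor pronunciation 6tb5st must never come back as a
        # "deliberate error" of 6tbQst when exclusion is on.
        rng = np.random.default_rng(7)
        for _ in range(2000):
            spec = generate_deliberate_error("6tbQst", INV, seed=rng,
                                             forbidden=["6tb5st"])
            assert spec.result.disc != "6tb5st"

    def test_support_equals_exhaustive_enumeration(self):
        p = "pi"
        expected = set(enumerate_error_candidates(p, INV))
        rng = np.random.default_rng(11)
        seen = set()
        for _ in range(4000):
            spec = generate_deliberate_error(p, INV, seed=rng)
            seen.add((spec.position, spec.substitute))
        assert seen == expected

    def test_deterministic_under_fixed_seed(self):
        a = generate_deliberate_error("6tbQst", INV, seed=42)
        b = generate_deliberate_error("6tbQst", INV, seed=42)
        assert a == b

    def test_all_candidates_forbidden_exhausts_retries(self):
        p = "pi"
        everything = {p[:i] + s + p[i + 1:]
                      for i, s in enumerate_error_candidates(p, INV)}
        with pytest.raises(RetryLimitError):
            generate_deliberate_error(p, INV, seed=0, forbidden=everything,
                                      max_retries=50)

    def test_no_substitutable_position_rejected(self):
        # A single-phoneme inventory admits no substitutes at all.
        from nonwordeval.phoneme_core import Phoneme, PhonemeInventory
        tiny = PhonemeInventory([
            Phoneme("p", "p", "consonant", place="bilabial", manner="plosive"),
            Phoneme("@", "ə", "vowel", position="mid", length="short",
                    is_schwa=True),
        ])
        with pytest.raises(NoValidSubstitutionError):
            generate_deliberate_error("p@", tiny, seed=0)


class TestCatchTrials:
    ITEMS = [(f"cw{i}", d) for i, d in enumerate(
        ["p{t", "tik", "mun", "l$d", "sIp", "k5n", "f3m", "b8d", "gu_", "h2v"])]

    def test_default_split_five_five(self):
        trials = build_catch_trials(self.ITEMS, INV, seed=3)
        labels = [t.label for t in trials]
        assert labels.count("accurate") == 5
        assert labels.count("inaccurate") == 5
        by_nw = dict(self.ITEMS)
        for t in trials:
            if t.label == "accurate":
                assert t.pronunciation.disc == by_nw[t.nonword]
            else:
                assert t.pronunciation.disc != by_nw[t.nonword]
                assert len(t.pronunciation) == len(by_nw[t.nonword])

    def test_all_accurate_when_no_inaccurate_requested(self):
        trials = build_catch_trials(self.ITEMS, INV, n_accurate=5,
                                    n_inaccurate=0, seed=3)
        assert all(t.label == "accurate" for t in trials)

    def test_insufficient_items_rejected(self):
        with pytest.raises(StimulusError):
            build_catch_trials(self.ITEMS[:9], INV, seed=3)


def _independent_check(lists, stimuli, cap):
    """Re-derive the list constraints from scratch (not via validate_lists)."""
    placed = []
    for lst in lists:
        assert len(lst.entries) <= cap
        nonwords = [nw for nw, _c, _p in lst.entries]
        assert len(nonwords) == len(set(nonwords))
        placed += [(nw, c, p.disc) for nw, c, p in lst.entries]
    assert sorted(placed) == sorted(
        (nw, c, Pronunciation(d).disc) for nw, c, d in stimuli)


class TestAssignLists:
    CONDITIONS = ["Human Modal", "Human Minor", "Deliberate Error",
                  "model-a", "model-b", "model-c"]

    def _stimuli(self, n_nonwords):
        vowels = "aeIQU{"
        return [(f"nw{i:03d}", cond, f"p{vowels[j]}t".replace("a", "{").replace("e", "E"))
                for i in range(n_nonwords)
                for j, cond in enumerate(self.CONDITIONS)]

    def test_scaled_six_condition_design(self):
        # 40 nonwords x 6 conditions into 6 primary lists capped at 15:
        # every primary list holds 40 entries and splits into 3 chunks,
        # giving 18 final lists, mirroring a 528x6 -> 18x176 design.
        stimuli = self._stimuli(40)
        lists = assign_lists(stimuli, n_primary_lists=6, max_per_list=15, seed=5)
        assert len(lists) == 18
        _independent_check(lists, stimuli, cap=15)

    def test_constraints_hold_for_any_seed(self):
        stimuli = self._stimuli(12)
        for seed in range(10):
            lists = assign_lists(stimuli, n_primary_lists=6, max_per_list=8,
                                 seed=seed)
            _independent_check(lists, stimuli, cap=8)

    def test_pigeonhole_infeasibility_reported_with_witness(self):
        stimuli = [("nw000", f"c{k}", "p{t") for k in range(7)]
        with pytest.raises(ListAssignmentError) as exc:
            assign_lists(stimuli, n_primary_lists=6, max_per_list=100, seed=0)
        assert exc.value.witness == "nw000"

    def test_single_condition_fits_one_list(self):
        stimuli = [(f"nw{i}", "only", "p{t") for i in range(5)]
        lists = assign_lists(stimuli, n_primary_lists=1, max_per_list=10, seed=0)
        assert len(lists) == 1 and len(lists[0]) == 5

    def test_deterministic_under_seed(self):
        stimuli = self._stimuli(12)
        a = assign_lists(stimuli, 6, 8, seed=9)
        b = assign_lists(stimuli, 6, 8, seed=9)
        assert a == b

    def test_validator_rejects_oversized_list(self):
        stimuli = [(f"nw{i}", "only", "p{t") for i in range(5)]
        lists = assign_lists(stimuli, 1, 10, seed=0)
        with pytest.raises(ListAssignmentError):
            validate_lists(lists, max_per_list=2)
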