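"""Strict/lenient matching, frequency ranking and match-table bookkeeping."""

import pytest
from hypothesis import given, settings, strategies as st

from nonwordeval.corpus_eval import (
    CorpusError,
    MatchResult,
    MissingItemError,
    PronunciationCorpus,
    extract_substitution_patterns,
    lenient_match,
    match_against_corpus,
    match_table,
    rank_pronunciations,
    select_low_match_items,
    strict_match,
)
from nonwordeval.phoneme_core import (
    ConflationMap,
    Pronunciation,
    conflate,
    default_inventory,
)

INV = default_inventory()
DISC_STRINGS = st.text(alphabet=INV.symbols, min_size=1, max_size=8)


class TestMatchPredicates:
    def test_strict_requires_identity(self):
        assert strict_match("6ts19", "6ts19")
        assert not strict_match("6ts1$", "6ts19")
        assert not strict_match("6ts19", "6ts1")

    def test_lenient_forgives_short_vowel_schwa_both_ways(self):
        assert lenient_match("k@nglIst", "kQnglIst", INV)
        assert lenient_match("kQnglIst", "k@nglIst", INV)

    def test_lenient_does_not_forgive_long_vowels(self):
        # '#' is a long vowel: swapping it with schwa is a real error.
        assert not lenient_match("pIft@", "pIft#", INV)

    def test_lenient_never_forgives_length_changes(self):
        assert not lenient_match("k@nglIst", "k@nglIs", INV)

    @settings(derandomize=True, max_examples=100)
    @given(DISC_STRINGS, DISC_STRINGS)
    def test_leniency_is_a_superset_of_strict(self, a, b):
        if strict_match(a, b):
            assert lenient_match(a, b, INV)


class TestRanking:
    def test_sorted_by_descending_count(self, entry):
        e = entry(*(["p{t"] * 5 + ["pEt"] * 3 + ["pIt"]))
        ranked = rank_pronunciations(e)
        assert [(p.disc, c) for p, c in ranked] == \
            [("p{t", 5), ("pEt", 3), ("pIt", 1)]
        assert sum(c for _p, c in ranked) == len(e)

    def test_frequency_ties_break_by_disc_order(self, entry):
        ranked = rank_pronunciations(entry("pEt", "p{t", "p{t", "pEt"))
        assert [p.disc for p, _c in ranked] == sorted(["pEt", "p{t"])

    def test_single_response(self, entry):
        assert rank_pronunciations(entry("p{t"))[0][0].disc == "p{t"

    def test_empty_item_rejected(self):
        with pytest.raises(CorpusError):
            rank_pronunciations([])


class TestMatchAgainstCorpus:
    def test_rank_of_second_most_frequent(self, entry):
        e = entry("p{t", "p{t", "pEt")
        res = match_against_corpus("pEt", e, "strict", inv=INV)
        assert res == MatchResult("strict", True, 2)

    def test_no_match_has_absent_rank(self, entry):
        res = match_against_corpus("tik", entry("p{t", "pEt"), "strict", inv=INV)
        assert not res.matched and res.rank is None

    def test_lenient_match_takes_minimal_rank(self, entry):
        # Candidate k@t leniently matches both kIt (rank 1) and kUt (rank 3).
        e = entry("kIt", "kIt", "tik", "kUt")
        res = match_against_corpus("k@t", e, "lenient", inv=INV)
        # Brute force over every reference confirms the minimal rank.
        ranked = rank_pronunciations(e)
        brute = min(r for r, (ref, _c) in enumerate(ranked, 1)
                    if lenient_match("k@t", ref, INV))
        assert res.rank == brute == 1

    def test_conflation_applies_to_both_sides(self, entry):
        e = entry("6ts19")
        res = match_against_corpus("6ts1$", e, "strict",
                                   conflation=ConflationMap({"$": "9"}), inv=INV)
        assert res.matched and res.rank == 1

    def test_match_result_invariant(self):
        with pytest.raises(ValueError):
            MatchResult("strict", True, None)
        with pytest.raises(ValueError):
            MatchResult("strict", False, 2)


class TestMatchTable:
    def _toy(self, entry):
        corpus = PronunciationCorpus({
            "a": entry("p{t", "p{t", "pEt"),
            "b": entry("tik"),
            "c": entry("mun", "mun", "m@n"),
            "d": entry("l$d"),
        })
        outputs = {"a": "p{t", "b": "tik", "c": "m@n", "d": "sss"}
        return corpus, outputs

    def test_hand_enumerated_percentages(self, entry):
        corpus, outputs = self._toy(entry)
        t = match_table(outputs, corpus, "strict", inv=INV)
        assert t.rank_pct(1) == 50.0
        assert t.rank_pct(2) == 25.0
        assert t.match_pct == 75.0
        assert t.absent_pct == 25.0
        assert t.as_dict(rounded=True)["Match"] == 75

    def test_all_modal_outputs_match_fully(self, entry):
        corpus, _ = self._toy(entry)
        outputs = {nw: rank_pronunciations(corpus.entry(nw))[0][0]
                   for nw in corpus}
        t = match_table(outputs, corpus, "strict", inv=INV)
        assert t.rank_pct(1) == 100.0 and t.absent_pct == 0.0

    def test_match_plus_absent_conserved(self, entry):
        corpus, outputs = self._toy(entry)
        for criterion in ("strict", "lenient"):
            t = match_table(outputs, corpus, criterion, inv=INV)
            assert t.match_pct + t.absent_pct == pytest.approx(100.0)

    def test_deep_matches_fall_outside_displayed_ranks(self, entry):
        # Eight distinct pronunciations; candidate equals the rank-8 one.
        discs = [f"p{v}t" for v in "{EIQUV@i"]
        responses = []
        for i, d in enumerate(discs):
            responses += [(f"s{i}{j}", Pronunciation(d)) for j in range(8 - i)]
        corpus = PronunciationCorpus({"x": responses})
        t = match_table({"x": discs[-1]}, corpus, "strict", inv=INV, n_ranks=7)
        displayed = sum(t.rank_pct(r) for r in range(1, 8))
        assert t.match_pct == 100.0 and displayed == 0.0

    def test_missing_item_rejected(self, entry):
        corpus, _ = self._toy(entry)
        with pytest.raises(MissingItemError):
            match_table({"zzz": "p{t"}, corpus, "strict", inv=INV)

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(DISC_STRINGS, min_size=1, max_size=6), DISC_STRINGS)
    def test_conflation_invariance(self, refs, cand):
        """Conflating the corpus first equals matching with conflation on."""
        m = ConflationMap({"$": "9"})
        e = [(f"s{i}", Pronunciation(d)) for i, d in enumerate(refs)]
        e_conf = [(sp, conflate(p, m)) for sp, p in e]
        for criterion in ("strict", "lenient"):
            via_option = match_against_corpus(cand, e, criterion,
                                              conflation=m, inv=INV)
            via_corpus = match_against_corpus(conflate(cand, m), e_conf,
                                              criterion, inv=INV)
            assert via_option == via_corpus


class TestLowMatchSelection:
    def test_counts_are_per_speaker_response(self, entry):
        corpus = PronunciationCorpus({
            "multi": entry("p{t", "p{t", "p{t", "pEt", "pIt"),
            "single": entry("tik", "tuk", "t$k"),
            "none": entry("mun", "mun"),
        })
        outputs = {"multi": "p{t", "single": "tuk", "none": "m@n"}
        zero, one = select_low_match_items(outputs, corpus, "strict", inv=INV)
        assert zero == {"none"}
        assert one == {"single"}  # "multi" matched 3 speakers: in neither set

    def test_all_modal_gives_empty_sets(self, entry):
        corpus = PronunciationCorpus({"a": entry("p{t", "p{t"),
                                      "b": entry("tik", "tik")})
        outputs = {"a": "p{t", "b": "tik"}
        zero, one = select_low_match_items(outputs, corpus, "strict", inv=INV)
        assert zero == set() and one == set()


class TestSubstitutionPatterns:
    def test_hand_counted_merge_pattern(self):
        pairs = [("6ts1$", "6ts19"), ("gl$r{k", "gl9r{k")]
        res = extract_substitution_patterns(pairs, min_count=2)
        assert res.patterns == [(("$", "9"), 2)]
        assert res.n_skipped == 0

    def test_identical_pairs_yield_nothing(self):
        res = extract_substitution_patterns([("p{t", "p{t")], min_count=1)
        assert res.patterns == []

    def test_min_count_one_keeps_single_pattern(self):
        res = extract_substitution_patterns([("pIt", "pEt")], min_count=1)
        assert res.patterns == [(("I", "E"), 1)]

    def test_unequal_length_pairs_are_skipped_and_reported(self):
        res = extract_substitution_patterns(
            [("p{t", "p{ts"), ("6ts1$", "6ts19")], min_count=1)
        assert res.n_skipped == 1
        assert res.patterns == [(("$", "9"), 1)]


class TestCorpusStructure:
    def test_duplicate_speaker_response_rejected(self):
        with pytest.raises(CorpusError, match="duplicate"):
            PronunciationCorpus({"a": [("s1", "p{t"), ("s1", "pEt")]})

    def test_round_trip_through_frame(self, entry):
        corpus = PronunciationCorpus({"a": entry("p{t", "pEt")})
        again = PronunciationCorpus.from_frame(corpus.to_frame(), INV)
        assert again.items.keys() == corpus.items.keys()
        assert again.entry("a") == corpus.entry("a")
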