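"""Corpus-based evaluation of model pronunciations.

A reference corpus records, for each nonword, the pronunciation each human
speaker produced.  A model's output for a nonword is deemed correct if it
matches at least one reference pronunciation, under one of two criteria:

* **strict** — the phoneme strings must be identical;
* **lenient** — substitution errors between short vowels and schwa (in either
  direction) are forgiven; insertions and deletions never are.

Matches are reported together with the frequency rank of the matched
reference (rank 1 = the modal pronunciation).  Utilities here also select the
zero-match / one-match items (candidates for false negatives and false
positives of corpus-based scoring) and mine position-wise substitution
patterns from discrepant model/reference pairs.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .phoneme_core import (
    ConflationMap,
    PhonemeInventory,
    Pronunciation,
    as_pronunciation,
    default_inventory,
    parse_disc,
)

STRICT = "strict"
LENIENT = "lenient"
CRITERIA = (STRICT, LENIENT)

#: One reference entry: (speaker_id, pronunciation).
Response = tuple[str, Pronunciation]


class CorpusError(ValueError):
    """Structural problems with a corpus or a model-output table."""


class MissingItemError(CorpusError, KeyError):
    """A model output refers to a nonword absent from the corpus."""

    def __init__(self, nonword: str):
        self.nonword = nonword
        super().__init__(f"nonword {nonword!r} not in corpus")


def round_half_up(x: float) -> int:
    """Round a non-negative value half-up to an integer (display convention)."""
    return int(math.floor(x + 0.5))


class PronunciationCorpus:
    """Per-nonword multiset of (speaker, pronunciation) responses."""

    def __init__(self, items: Mapping[str, Sequence[tuple[str, "Pronunciation | str"]]]):
        self._items: dict[str, list[Response]] = {}
        speakers: set[str] = set()
        for nonword, responses in items.items():
            seen: set[str] = set()
            entry: list[Response] = []
            for speaker, pron in responses:
                if speaker in seen:
                    raise CorpusError(
                        f"duplicate response for item {nonword!r}, speaker {speaker!r}")
                seen.add(speaker)
                entry.append((speaker, as_pronunciation(pron)))
                speakers.add(speaker)
            if not entry:
                raise CorpusError(f"item {nonword!r} has no responses")
            self._items[nonword] = entry
        self.speakers: frozenset[str] = frozenset(speakers)

    # -- access ----------------------------------------------------------
    def __contains__(self, nonword: str) -> bool:
        return nonword in self._items

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self):
        return iter(self._items)

    @property
    def items(self) -> Mapping[str, list[Response]]:
        return self._items

    def entry(self, nonword: str) -> list[Response]:
        try:
            return self._items[nonword]
        except KeyError:
            raise MissingItemError(nonword) from None

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   inv: PhonemeInventory | None = None) -> "PronunciationCorpus":
        """Build from a table with columns nonword, speaker_id, disc."""
        inv = inv or default_inventory()
        items: dict[str, list[tuple[str, Pronunciation]]] = {}
        for row in df.itertuples(index=False):
            items.setdefault(str(row.nonword), []).append(
                (str(row.speaker_id), parse_disc(str(row.disc), inv)))
        return cls(items)

    @classmethod
    def from_tsv(cls, path: str,
                 inv: PhonemeInventory | None = None) -> "PronunciationCorpus":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str), inv)

    def to_frame(self) -> pd.DataFrame:
        rows = [(nw, sp, p.disc)
                for nw, entry in self._items.items() for sp, p in entry]
        return pd.DataFrame(rows, columns=["nonword", "speaker_id", "disc"])


def load_model_outputs(path_or_frame: "str | pd.DataFrame",
                       inv: PhonemeInventory | None = None) -> dict[str, Pronunciation]:
    """Read a model-output table (columns nonword, disc) into a mapping."""
    inv = inv or default_inventory()
    df = path_or_frame if isinstance(path_or_frame, pd.DataFrame) \
        else pd.read_csv(path_or_frame, sep="\t", dtype=str)
    out: dict[str, Pronunciation] = {}
    for row in df.itertuples(index=False):
        nw = str(row.nonword)
        if nw in out:
            raise CorpusError(f"duplicate model output for nonword {nw!r}")
        out[nw] = parse_disc(str(row.disc), inv)
    return out


# ---------------------------------------------------------------------------
# Match predicates
# ---------------------------------------------------------------------------

def strict_match(a: "Pronunciation | str", b: "Pronunciation | str") -> bool:
    """Exact phoneme-string identity."""
    return as_pronunciation(a).disc == as_pronunciation(b).disc


def lenient_match(a: "Pronunciation | str", b: "Pronunciation | str",
                  inv: PhonemeInventory | None = None) -> bool:
    """Identity up to short-vowel↔schwa substitutions, position by position.

    Only equal-length strings can match: the forgiveness covers substitution
    errors, never insertions or deletions.
    """
    inv = inv or default_inventory()
    a, b = as_pronunciation(a), as_pronunciation(b)
    if len(a) != len(b):
        return False
    schwa, short = inv.schwa, inv.short_vowels
    for x, y in zip(a.disc, b.disc):
        if x == y:
            continue
        if (x == schwa and y in short) or (y == schwa and x in short):
            continue
        return False
    return True


def _predicate(criterion: str, inv: PhonemeInventory):
    if criterion == STRICT:
        return strict_match
    if criterion == LENIENT:
        return lambda a, b: lenient_match(a, b, inv)
    raise ValueError(f"unknown criterion {criterion!r}; expected one of {CRITERIA}")


# ---------------------------------------------------------------------------
# Ranking and matching
# ---------------------------------------------------------------------------

def rank_pronunciations(entry: Sequence[Response]) -> list[tuple[Pronunciation, int]]:
    """Distinct pronunciations of an item, most frequent first.

    Ties are broken by ascending DISC string order; counts sum to the number
    of responses.  Rank 1 is the modal pronunciation.
    """
    if not entry:
        raise CorpusError("cannot rank an empty item")
    counts = Counter(as_pronunciation(p).disc for _, p in entry)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(Pronunciation(d), c) for d, c in ranked]


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one candidate against one item's references."""

    criterion: str
    matched: bool
    rank: int | None = None

    def __post_init__(self) -> None:
        if self.matched != (self.rank is not None):
            raise ValueError("matched is true iff rank is present")
        if self.rank is not None and self.rank < 1:
            raise ValueError("rank is 1-based")


def match_against_corpus(candidate: "Pronunciation | str",
                         entry: Sequence[Response],
                         criterion: str = STRICT,
                         conflation: ConflationMap | None = None,
                         inv: PhonemeInventory | None = None) -> MatchResult:
    """Match a candidate against an item's reference pronunciations.

    Both candidate and references are conflated before comparison.  The
    result carries the smallest frequency rank among matching references
    (rank 1 = modal), or no rank if nothing matches.
    """
    inv = inv or default_inventory()
    pred = _predicate(criterion, inv)
    cand = as_pronunciation(candidate)
    if conflation:
        cand = Pronunciation(conflation.apply(cand.disc))
        entry = [(sp, Pronunciation(conflation.apply(as_pronunciation(p).disc)))
                 for sp, p in entry]
    for rank, (ref, _count) in enumerate(rank_pronunciations(entry), start=1):
        if pred(cand, ref):
            return MatchResult(criterion, True, rank)
    return MatchResult(criterion, False, None)


@dataclass(frozen=True)
class MatchTable:
    """Per-model match percentages by reference frequency rank.

    ``rank_counts[r]`` is the number of scored items whose output matched the
    rank-``r`` reference pronunciation (and nothing more frequent); items
    matching no reference count as absent.  ``Match + Absent = 100`` up to
    rounding, and the displayed rank columns can sum to less than Match when
    some items matched deeper than ``n_ranks``.
    """

    criterion: str
    n: int
    rank_counts: Mapping[int, int] = field(default_factory=dict)
    n_ranks: int = 7

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise CorpusError("match table over zero items")
        object.__setattr__(self, "rank_counts", dict(self.rank_counts))

    @property
    def match_count(self) -> int:
        return sum(self.rank_counts.values())

    @property
    def absent_count(self) -> int:
        return self.n - self.match_count

    @property
    def match_pct(self) -> float:
        return 100.0 * self.match_count / self.n

    @property
    def absent_pct(self) -> float:
        return 100.0 * self.absent_count / self.n

    def rank_pct(self, rank: int) -> float:
        return 100.0 * self.rank_counts.get(rank, 0) / self.n

    def as_dict(self, rounded: bool = False) -> dict[str, float | int]:
        """Row in presentation order: rank columns, Match, Absent."""
        row: dict[str, float] = {
            f"rank{r}": self.rank_pct(r) for r in range(1, self.n_ranks + 1)}
        row["Match"] = self.match_pct
        row["Absent"] = self.absent_pct
        if rounded:
            return {k: round_half_up(v) for k, v in row.items()}
        return row


def match_table(outputs: Mapping[str, "Pronunciation | str"],
                corpus: PronunciationCorpus,
                criterion: str = STRICT,
                conflation: ConflationMap | None = None,
                inv: PhonemeInventory | None = None,
                n_ranks: int = 7) -> MatchTable:
    """Score a model's outputs against the corpus and tally ranks."""
    if not outputs:
        raise CorpusError("no model outputs to score")
    counts: Counter[int] = Counter()
    for nonword, cand in outputs.items():
        res = match_against_corpus(cand, corpus.entry(nonword), criterion,
                                   conflation=conflation, inv=inv)
        if res.matched:
            counts[res.rank] += 1
    return MatchTable(criterion, len(outputs), dict(counts), n_ranks=n_ranks)


def select_low_match_items(outputs: Mapping[str, "Pronunciation | str"],
                           corpus: PronunciationCorpus,
                           criterion: str = STRICT,
                           conflation: ConflationMap | None = None,
                           inv: PhonemeInventory | None = None
                           ) -> tuple[set[str], set[str]]:
    """Split items by how many *individual speaker responses* they match.

    Returns ``(zero_match, one_match)``: items whose output matched no
    speaker's response, and items matching exactly one speaker's response.
    Counting is per speaker response, not per distinct pronunciation, so a
    pronunciation produced by three speakers contributes three matches.
    """
    inv = inv or default_inventory()
    pred = _predicate(criterion, inv)
    zero: set[str] = set()
    one: set[str] = set()
    for nonword, cand in outputs.items():
        entry = corpus.entry(nonword)
        cand_p = as_pronunciation(cand)
        entry = [(sp, as_pronunciation(p)) for sp, p in entry]
        if conflation:
            cand_p = Pronunciation(conflation.apply(cand_p.disc))
            entry = [(sp, Pronunciation(conflation.apply(p.disc))) for sp, p in entry]
        n_hits = sum(1 for _sp, ref in entry if pred(cand_p, ref))
        if n_hits == 0:
            zero.add(nonword)
        elif n_hits == 1:
            one.add(nonword)
    return zero, one


@dataclass(frozen=True)
class SubstitutionPatterns:
    """Position-wise substitution patterns mined from discrepant pairs."""

    patterns: list[tuple[tuple[str, str], int]]
    n_skipped: int


def extract_substitution_patterns(
        pairs: Iterable[tuple["Pronunciation | str", "Pronunciation | str"]],
        min_count: int = 5) -> SubstitutionPatterns:
    """Count single-symbol substitutions a→b across equal-length pairs.

    Each pair is (model pronunciation, nearest reference).  Unequal-length
    pairs are skipped and reported via ``n_skipped``.  Returns patterns with
    count ≥ ``min_count``, most frequent first (ties by symbol pair).
    """
    counts: Counter[tuple[str, str]] = Counter()
    skipped = 0
    for a, b in pairs:
        a, b = as_pronunciation(a), as_pronunciation(b)
        if len(a) != len(b):
            skipped += 1
            continue
        for x, y in zip(a.disc, b.disc):
            if x != y:
                counts[(x, y)] += 1
    kept = sorted(((pat, c) for pat, c in counts.items() if c >= min_count),
                  key=lambda kv: (-kv[1], kv[0]))
    return SubstitutionPatterns(kept, skipped)
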