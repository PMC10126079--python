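"""DISC phoneme inventory, parsing, IPA mapping and substitution constraints.

DISC is the one-printable-character-per-phoneme transcription alphabet of the
CELEX lexical database.  Every phoneme of British English is written as a
single ASCII character (e.g. ``$`` = /ɔː/, ``9`` = /ʊə/, ``@`` = schwa,
``J`` = /tʃ/), which makes phoneme strings trivially alignable position by
position.  This module provides:

* :class:`Phoneme` / :class:`PhonemeInventory` — symbols plus the phonological
  features (place/manner for consonants, position/length for vowels and
  diphthongs) that drive error generation and lenient matching;
* :func:`parse_disc` / :func:`disc_to_ipa` / :func:`ipa_to_disc` — parsing and
  a bijective DISC↔IPA mapping over the inventory;
* :func:`is_valid_substitution` — the feature constraint used to build
  deliberate pronunciation errors: a consonant may only be replaced by a
  consonant differing in *both* place and manner, a vowel/diphthong only by a
  vocalic phoneme differing in *both* position (front/mid/back) and length
  class (short/long/diphthong);
* :class:`ConflationMap` / :func:`conflate` — treating two phonemes as
  equivalent during matching (e.g. the ``$``→``9`` merge applied by the
  reference corpus transcriber).

The shipped inventory (``data/disc_inventory.tsv``) covers the British English
DISC character set: 29 consonants (including the syllabic consonants F, H, P,
C), 12 monophthongs and 8 diphthongs.  Rare loanword nasal vowels and the
linking-r symbol are deliberately omitted.  Diphthongs carry a position
feature taken from their starting vowel quality; this is an interpretive
choice documented in the methods note.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Mapping

import pandas as pd
import yaml

CONSONANT = "consonant"
VOWEL = "vowel"
DIPHTHONG = "diphthong"

_CATEGORIES = frozenset({CONSONANT, VOWEL, DIPHTHONG})
_POSITIONS = frozenset({"front", "mid", "back"})
_LENGTHS = frozenset({"short", "long", "diphthong"})

#: Characters stripped by default when parsing DISC strings (CELEX stress
#: markers; stress is ignored throughout this package).
DEFAULT_STRESS_MARKERS = "'\""


class PhonemeError(ValueError):
    """Base class for inventory / transcription errors."""


class UnknownSymbolError(PhonemeError):
    """A DISC symbol (or IPA segment) that does not resolve in the inventory."""

    def __init__(self, symbol: str, offset: int | None = None, context: str = ""):
        self.symbol = symbol
        self.offset = offset
        msg = f"unknown symbol {symbol!r}"
        if offset is not None:
            msg += f" at offset {offset}"
        if context:
            msg += f" in {context!r}"
        super().__init__(msg)


@dataclass(frozen=True)
class Phoneme:
    """A single DISC phoneme with its phonological features.

    Consonants carry ``place`` and ``manner``; vowels and diphthongs carry
    ``position`` (front/mid/back) and ``length`` (short/long/diphthong).
    Exactly one phoneme per inventory is the schwa.
    """

    symbol: str
    ipa: str
    category: str
    place: str | None = None
    manner: str | None = None
    position: str | None = None
    length: str | None = None
    is_schwa: bool = False

    def __post_init__(self) -> None:
        if len(self.symbol) != 1:
            raise PhonemeError(f"DISC symbols are single characters, got {self.symbol!r}")
        if not self.ipa:
            raise PhonemeError(f"phoneme {self.symbol!r} lacks an IPA value")
        if self.category not in _CATEGORIES:
            raise PhonemeError(f"unknown category {self.category!r} for {self.symbol!r}")
        if self.category == CONSONANT:
            if not self.place or not self.manner:
                raise PhonemeError(f"consonant {self.symbol!r} lacks place/manner")
            if self.position or self.length:
                raise PhonemeError(f"consonant {self.symbol!r} must not carry position/length")
        else:
            if not self.position or not self.length:
                raise PhonemeError(f"vocalic phoneme {self.symbol!r} lacks position/length")
            if self.place or self.manner:
                raise PhonemeError(f"vocalic phoneme {self.symbol!r} must not carry place/manner")
            if self.position not in _POSITIONS:
                raise PhonemeError(f"bad position {self.position!r} for {self.symbol!r}")
            if self.length not in _LENGTHS:
                raise PhonemeError(f"bad length {self.length!r} for {self.symbol!r}")
            if self.category == DIPHTHONG and self.length != "diphthong":
                raise PhonemeError(f"diphthong {self.symbol!r} must have length 'diphthong'")
        if self.is_schwa and (self.symbol != "@" or self.length != "short"):
            raise PhonemeError("the schwa must be the short vowel '@'")

    @property
    def vocalic(self) -> bool:
        return self.category in (VOWEL, DIPHTHONG)


@dataclass(frozen=True)
class Pronunciation:
    """A phoneme string in DISC notation (one character per phoneme)."""

    disc: str

    def __post_init__(self) -> None:
        if not self.disc:
            raise PhonemeError("empty pronunciation")

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(self.disc)

    def __len__(self) -> int:
        return len(self.disc)

    def __iter__(self) -> Iterator[str]:
        return iter(self.disc)

    def __getitem__(self, i) -> str:
        return self.disc[i]

    def __str__(self) -> str:
        return self.disc


def as_pronunciation(p: "Pronunciation | str") -> Pronunciation:
    """Accept either a :class:`Pronunciation` or a raw DISC string."""
    return p if isinstance(p, Pronunciation) else Pronunciation(str(p))


class PhonemeInventory:
    """The set of phonemes in use, indexed by DISC symbol.

    Guarantees: symbols are unique, DISC↔IPA is a bijection, exactly one
    phoneme is the schwa.  ``short_vowels`` is the set of short monophthong
    symbols (excluding the schwa by default) forgiven against schwa under
    lenient matching; pass ``short_vowels=`` to override.
    """

    def __init__(self, phonemes: Iterable[Phoneme],
                 short_vowels: Iterable[str] | None = None):
        by_symbol: dict[str, Phoneme] = {}
        by_ipa: dict[str, str] = {}
        for ph in phonemes:
            if ph.symbol in by_symbol:
                raise PhonemeError(f"duplicate symbol {ph.symbol!r}")
            if ph.ipa in by_ipa:
                raise PhonemeError(
                    f"IPA {ph.ipa!r} shared by {by_ipa[ph.ipa]!r} and {ph.symbol!r}; "
                    "DISC↔IPA must be a bijection")
            by_symbol[ph.symbol] = ph
            by_ipa[ph.ipa] = ph.symbol
        if not by_symbol:
            raise PhonemeError("empty phoneme inventory")
        schwas = [p.symbol for p in by_symbol.values() if p.is_schwa]
        if len(schwas) != 1:
            raise PhonemeError(f"inventory must contain exactly one schwa, found {len(schwas)}")
        self._by_symbol = by_symbol
        self._by_ipa = by_ipa
        self.schwa: str = schwas[0]
        if short_vowels is None:
            short_vowels = {p.symbol for p in by_symbol.values()
                            if p.category == VOWEL and p.length == "short"
                            and not p.is_schwa}
        else:
            short_vowels = set(short_vowels)
            for s in short_vowels:
                if s not in by_symbol or not by_symbol[s].vocalic:
                    raise PhonemeError(f"short-vowel override {s!r} is not a vocalic symbol")
        self.short_vowels: frozenset[str] = frozenset(short_vowels)
        # IPA tokens longest-first for greedy decoding.
        self._ipa_tokens = sorted(self._by_ipa, key=len, reverse=True)

    # -- mapping protocol ------------------------------------------------
    def __contains__(self, symbol: str) -> bool:
        return symbol in self._by_symbol

    def __getitem__(self, symbol: str) -> Phoneme:
        try:
            return self._by_symbol[symbol]
        except KeyError:
            raise UnknownSymbolError(symbol) from None

    def __iter__(self) -> Iterator[Phoneme]:
        return iter(self._by_symbol.values())

    def __len__(self) -> int:
        return len(self._by_symbol)

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(self._by_symbol)

    # -- features --------------------------------------------------------
    @functools.lru_cache(maxsize=None)
    def valid_substitutes(self, symbol: str) -> tuple[str, ...]:
        """Symbols that may replace ``symbol`` under the feature constraint.

        Sorted for determinism; used by the deliberate-error generator.
        """
        a = self[symbol]
        return tuple(sorted(b.symbol for b in self
                            if is_valid_substitution(a, b)))

    # -- hashability: identity is fine, inventories are effectively const --
    __hash__ = object.__hash__


def is_valid_substitution(a: Phoneme, b: Phoneme) -> bool:
    """Whether ``b`` is an acceptable deliberate-error substitute for ``a``.

    True iff both are consonants differing in *both* place and manner, or
    both are vocalic (vowel or diphthong) differing in *both* position and
    length class.  Consonant↔vocalic swaps and identity are never valid.
    Symmetric and irreflexive.
    """
    if a.symbol == b.symbol:
        return False
    if a.category == CONSONANT and b.category == CONSONANT:
        return a.place != b.place and a.manner != b.manner
    if a.vocalic and b.vocalic:
        return a.position != b.position and a.length != b.length
    return False


def load_inventory(table: "pd.DataFrame | str",
                   short_vowels: Iterable[str] | None = None) -> PhonemeInventory:
    """Build an inventory from a feature table (DataFrame or TSV path).

    Expected columns: symbol, ipa, category, place, manner, position, length,
    is_schwa.  Empty cells mean "feature not applicable".
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t", dtype=str, keep_default_na=False)
    if table.empty:
        raise PhonemeError("empty phoneme feature table")

    def cell(row, col) -> str | None:
        v = str(row.get(col, "") or "").strip()
        return v or None

    phonemes = []
    for _, row in table.iterrows():
        phonemes.append(Phoneme(
            symbol=str(row["symbol"]),
            ipa=str(row["ipa"]),
            category=str(row["category"]).strip(),
            place=cell(row, "place"),
            manner=cell(row, "manner"),
            position=cell(row, "position"),
            length=cell(row, "length"),
            is_schwa=str(row.get("is_schwa", "")).strip().lower() in ("true", "1", "yes"),
        ))
    return PhonemeInventory(phonemes, short_vowels=short_vowels)


@functools.lru_cache(maxsize=1)
def default_inventory() -> PhonemeInventory:
    """The shipped British English DISC inventory."""
    path = resources.files("nonwordeval.data") / "disc_inventory.tsv"
    with resources.as_file(path) as p:
        return load_inventory(str(p))


def parse_disc(s: str, inv: PhonemeInventory | None = None,
               stress_markers: str = DEFAULT_STRESS_MARKERS) -> Pronunciation:
    """Parse a DISC string, validating every symbol against the inventory.

    Stress marker characters are stripped and discarded (stress is ignored
    throughout).  Raises :class:`UnknownSymbolError` with the offending
    character and offset, or :class:`PhonemeError` on an empty string.
    """
    inv = inv or default_inventory()
    if stress_markers:
        s = "".join(c for c in s if c not in stress_markers)
    if not s:
        raise PhonemeError("empty DISC string")
    for i, c in enumerate(s):
        if c not in inv:
            raise UnknownSymbolError(c, offset=i, context=s)
    return Pronunciation(s)


def disc_to_ipa(p: "Pronunciation | str", inv: PhonemeInventory | None = None) -> str:
    """Concatenate per-phoneme IPA, e.g. ``"J#ns"`` → ``"tʃɑːns"``."""
    inv = inv or default_inventory()
    p = as_pronunciation(p)
    return "".join(inv[c].ipa for c in p)


def ipa_to_disc(s: str, inv: PhonemeInventory | None = None) -> Pronunciation:
    """Decode a concatenated IPA string back into DISC.

    Segmentation is greedy longest-match, so an IPA sequence that could be
    read either as one phoneme or as two (e.g. ``tʃ`` = the affricate J or
    t + ʃ, ``ʊə`` = the diphthong 9 or U + @) always decodes as the single
    phoneme.  Per-symbol, the mapping is an exact bijection.
    """
    inv = inv or default_inventory()
    if not s:
        raise PhonemeError("empty IPA string")
    out = []
    i = 0
    while i < len(s):
        for tok in inv._ipa_tokens:
            if s.startswith(tok, i):
                out.append(inv._by_ipa[tok])
                i += len(tok)
                break
        else:
            raise UnknownSymbolError(s[i], offset=i, context=s)
    return Pronunciation("".join(out))


@dataclass(frozen=True)
class ConflationMap:
    """Symbol equivalences applied before matching (source → target).

    Applying the map twice equals applying it once: a target symbol may not
    itself be remapped to something else, so chains and cycles are rejected.
    """

    pairs: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for src, dst in self.pairs.items():
            if len(src) != 1 or len(dst) != 1:
                raise PhonemeError(f"conflation entries map single symbols, got {src!r}→{dst!r}")
            if dst in self.pairs and self.pairs[dst] != dst:
                raise PhonemeError(
                    f"conflation target {dst!r} is itself remapped; maps must be idempotent")
        object.__setattr__(self, "pairs", dict(self.pairs))

    @classmethod
    def from_yaml(cls, path: str) -> "ConflationMap":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls({str(k): str(v) for k, v in data.items()})

    @classmethod
    def identity(cls) -> "ConflationMap":
        return cls({})

    def apply(self, disc: str) -> str:
        return "".join(self.pairs.get(c, c) for c in disc)

    def __bool__(self) -> bool:
        return bool(self.pairs)


@functools.lru_cache(maxsize=1)
def default_conflation() -> ConflationMap:
    """The shipped default: merge $ (/ɔː/) into 9 (/ʊə/)."""
    path = resources.files("nonwordeval.data") / "conflation_default.yaml"
    with resources.as_file(path) as p:
        return ConflationMap.from_yaml(str(p))


def conflate(p: "Pronunciation | str", m: ConflationMap) -> Pronunciation:
    """Replace every mapped symbol by its target; length is preserved."""
    return Pronunciation(m.apply(as_pronunciation(p).disc))
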