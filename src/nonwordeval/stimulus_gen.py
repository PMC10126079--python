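"""Construction of rating-experiment stimuli.

Four ingredients of a ratings experiment are built here from a reference
corpus and the phoneme inventory:

* the **modal** pronunciation of each nonword (most frequent response) and a
  **minor** pronunciation (produced by a small number of speakers, 2–6 by
  default);
* **deliberate errors** — one random phoneme substituted under the feature
  constraint (consonants must change place *and* manner; vowels/diphthongs
  must change position *and* length class), yielding errors that are
  unequivocal yet close to the written form;
* **catch trials** — unanimously pronounced items presented either intact
  (Accurate) or distorted by the deliberate-error procedure (Inaccurate);
* **stimulus lists** — a partition of all stimuli such that every
  pronunciation appears at least once across lists, no list repeats an
  orthographic form, and no list exceeds a length cap.

Randomised steps are deterministic under a seed.  By default the error
generator refuses to emit a pronunciation attested in a supplied forbidden
set, to avoid a "deliberate error" colliding with a genuine pronunciation
from another condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .corpus_eval import Response, rank_pronunciations
from .phoneme_core import (
    PhonemeInventory,
    Pronunciation,
    as_pronunciation,
    default_inventory,
)


class StimulusError(ValueError):
    """Raised when stimuli cannot be constructed as requested."""


class NoValidSubstitutionError(StimulusError):
    """No position of the pronunciation admits a feature-valid substitute."""


class RetryLimitError(StimulusError):
    """All sampled candidates were forbidden within the retry budget."""


class ListAssignmentError(StimulusError):
    """List constraints are infeasible; carries a witness nonword."""

    def __init__(self, message: str, witness: str | None = None):
        self.witness = witness
        super().__init__(message)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# Modal / minor pronunciations
# ---------------------------------------------------------------------------

def modal_pronunciation(entry: Sequence[Response]) -> Pronunciation:
    """The most frequent pronunciation (frequency ties break by DISC order)."""
    return rank_pronunciations(entry)[0][0]


def minor_pronunciation(entry: Sequence[Response], lo: int = 2,
                        hi: int = 6) -> Pronunciation | None:
    """A non-modal pronunciation produced by between ``lo`` and ``hi`` speakers.

    Among candidates the most frequent wins (ties by DISC order, consistent
    with :func:`rank_pronunciations`).  The modal pronunciation itself is
    never returned — modal and minor are distinct stimulus conditions.
    Returns None when no candidate exists.
    """
    ranked = rank_pronunciations(entry)
    for pron, count in ranked[1:]:
        if lo <= count <= hi:
            return pron
    return None


# ---------------------------------------------------------------------------
# Deliberate errors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorSpec:
    """A single feature-constrained substitution applied to a pronunciation."""

    source: Pronunciation
    position: int
    original: str
    substitute: str
    result: Pronunciation

    def __post_init__(self) -> None:
        if not (0 <= self.position < len(self.source)):
            raise StimulusError("substitution position out of range")
        if self.source[self.position] != self.original:
            raise StimulusError("original symbol does not match source")
        expected = (self.source.disc[: self.position] + self.substitute
                    + self.source.disc[self.position + 1:])
        if self.result.disc != expected:
            raise StimulusError("result must differ from source at exactly the stated position")


def enumerate_error_candidates(p: "Pronunciation | str",
                               inv: PhonemeInventory | None = None
                               ) -> list[tuple[int, str]]:
    """All (position, substitute) pairs allowed by the feature constraint."""
    inv = inv or default_inventory()
    p = as_pronunciation(p)
    return [(i, sub) for i, sym in enumerate(p.disc)
            for sub in inv.valid_substitutes(sym)]


def generate_deliberate_error(p: "Pronunciation | str",
                              inv: PhonemeInventory | None = None,
                              seed: "int | np.random.Generator" = 0,
                              forbidden: Iterable["Pronunciation | str"] = (),
                              max_retries: int = 1000) -> ErrorSpec:
    """Substitute one phoneme at random under the feature constraint.

    The position is drawn uniformly among positions that admit at least one
    valid substitute, then the substitute uniformly among that position's
    valid substitutes.  If the result is in ``forbidden`` (e.g. the attested
    pronunciations of the item), the draw is repeated up to ``max_retries``
    times.  Deterministic under a fixed seed.
    """
    inv = inv or default_inventory()
    p = as_pronunciation(p)
    rng = _rng(seed)
    forbidden_discs = {as_pronunciation(f).disc for f in forbidden}
    positions = [i for i, sym in enumerate(p.disc) if inv.valid_substitutes(sym)]
    if not positions:
        raise NoValidSubstitutionError(
            f"no phoneme of {p.disc!r} admits a valid substitution")
    for _ in range(max_retries):
        pos = positions[rng.integers(len(positions))]
        subs = inv.valid_substitutes(p[pos])
        sub = subs[rng.integers(len(subs))]
        result = p.disc[:pos] + sub + p.disc[pos + 1:]
        if result in forbidden_discs:
            continue
        return ErrorSpec(source=p, position=pos, original=p[pos],
                         substitute=sub, result=Pronunciation(result))
    raise RetryLimitError(
        f"could not build a deliberate error for {p.disc!r} avoiding "
        f"{len(forbidden_discs)} forbidden pronunciations in {max_retries} tries")


# ---------------------------------------------------------------------------
# Catch trials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CatchTrial:
    nonword: str
    pronunciation: Pronunciation
    label: str  # "accurate" | "inaccurate"


def build_catch_trials(items: Sequence[tuple[str, "Pronunciation | str"]],
                       inv: PhonemeInventory | None = None,
                       n_accurate: int = 5, n_inaccurate: int = 5,
                       seed: "int | np.random.Generator" = 0) -> list[CatchTrial]:
    """Build attention-check trials from unanimously pronounced items.

    ``n_accurate`` items are kept intact; ``n_inaccurate`` are distorted by
    the deliberate-error procedure.  Items are drawn without replacement in
    seeded random order.
    """
    inv = inv or default_inventory()
    need = n_accurate + n_inaccurate
    if len(items) < need:
        raise StimulusError(
            f"need at least {need} unanimously pronounced items, got {len(items)}")
    rng = _rng(seed)
    order = rng.permutation(len(items))
    trials: list[CatchTrial] = []
    for k in range(n_accurate):
        nw, pron = items[order[k]]
        trials.append(CatchTrial(nw, as_pronunciation(pron), "accurate"))
    for k in range(n_accurate, need):
        nw, pron = items[order[k]]
        spec = generate_deliberate_error(pron, inv, seed=rng,
                                         forbidden=[pron])
        trials.append(CatchTrial(nw, spec.result, "inaccurate"))
    return trials


# ---------------------------------------------------------------------------
# Stimulus lists
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusList:
    """One presentation list: (nonword, condition, pronunciation) triples."""

    list_id: str
    entries: tuple[tuple[str, str, Pronunciation], ...]

    def __len__(self) -> int:
        return len(self.entries)


Stimulus = tuple[str, str, Pronunciation]


def assign_lists(stimuli: Sequence[tuple[str, str, "Pronunciation | str"]],
                 n_primary_lists: int, max_per_list: int,
                 seed: "int | np.random.Generator" = 0) -> list[StimulusList]:
    """Distribute stimuli into presentation lists.

    Each (nonword, condition, pronunciation) is placed in exactly one primary
    list, no primary list contains the same orthographic form twice, and
    primary lists are balanced in size.  Primary lists longer than
    ``max_per_list`` are then split into consecutive chunks, so no final list
    exceeds the cap while the no-repeat constraint is inherited.  List ids
    are "<primary>.<chunk>".  Deterministic under a fixed seed.
    """
    if n_primary_lists < 1 or max_per_list < 1:
        raise ListAssignmentError("need at least one list and a positive cap")
    norm: list[Stimulus] = [(nw, cond, as_pronunciation(p)) for nw, cond, p in stimuli]
    by_nonword: dict[str, list[Stimulus]] = {}
    for s in norm:
        by_nonword.setdefault(s[0], []).append(s)
    for nw, group in by_nonword.items():
        if len(group) > n_primary_lists:
            raise ListAssignmentError(
                f"nonword {nw!r} has {len(group)} pronunciations but only "
                f"{n_primary_lists} lists are available (pigeonhole)", witness=nw)

    rng = _rng(seed)
    nonwords = sorted(by_nonword)
    rng.shuffle(nonwords)
    primaries: list[list[Stimulus]] = [[] for _ in range(n_primary_lists)]
    # Fixed random priority breaks load ties deterministically.
    priority = rng.permutation(n_primary_lists)
    for nw in nonwords:
        group = list(by_nonword[nw])
        rng.shuffle(group)
        order = sorted(range(n_primary_lists),
                       key=lambda i: (len(primaries[i]), priority[i]))
        for stim, list_idx in zip(group, order):
            primaries[list_idx].append(stim)

    lists: list[StimulusList] = []
    for p_idx, entries in enumerate(primaries):
        if not entries:
            continue
        chunks = [entries[i:i + max_per_list]
                  for i in range(0, len(entries), max_per_list)]
        for c_idx, chunk in enumerate(chunks):
            lists.append(StimulusList(f"{p_idx + 1}.{c_idx + 1}", tuple(chunk)))
    validate_lists(lists, max_per_list, stimuli=norm)
    return lists


def validate_lists(lists: Sequence[StimulusList], max_per_list: int,
                   stimuli: Sequence[tuple[str, str, "Pronunciation | str"]] | None = None
                   ) -> None:
    """Check list constraints; raises :class:`ListAssignmentError` on violation.

    Checks the cap, the within-list orthography constraint and — when the
    input stimuli are supplied — that every stimulus appears at least once
    across lists.
    """
    for lst in lists:
        if len(lst) > max_per_list:
            raise ListAssignmentError(
                f"list {lst.list_id} has {len(lst)} entries (cap {max_per_list})")
        seen: set[str] = set()
        for nw, _cond, _p in lst.entries:
            if nw in seen:
                raise ListAssignmentError(
                    f"list {lst.list_id} repeats orthographic form {nw!r}", witness=nw)
            seen.add(nw)
    if stimuli is not None:
        placed = {(nw, cond, as_pronunciation(p).disc)
                  for lst in lists for nw, cond, p in lst.entries}
        for nw, cond, p in stimuli:
            key = (nw, cond, as_pronunciation(p).disc)
            if key not in placed:
                raise ListAssignmentError(
                    f"stimulus {key} was never placed in any list", witness=nw)
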