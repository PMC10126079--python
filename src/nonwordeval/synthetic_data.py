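"""Synthetic corpora, model outputs and listener ratings with ground truth.

No human pronunciation corpus or rating set ships with this package, so every
pipeline stage is exercised against simulated data whose generating truth is
known.  The generator emulates the statistical shape of a disyllabic-nonword
naming corpus:

* per item, a set of plausible pronunciation variants whose count is drawn
  from a truncated geometric distribution on [1, 22] tuned to a mean of 5.9
  distinct variants per item;
* frequency-skewed variant weights (Zipf-like, weight ∝ rank^−skew), so one
  modal pronunciation dominates and the tail is thin;
* occasional production/transcription errors: with a small probability a
  speaker's response is corrupted by a single feature-valid substitution,
  landing outside the plausible set;
* optionally, planted speaker personas — conformists who always produce the
  modal variant and deviants who often produce unique pronunciations — for
  validating surprise-index profiling;
* per item, a few held-out "novel plausible" variants that no speaker
  produces, reproducing the central false-negative mechanism of corpus-based
  scoring (a plausible model output absent from the corpus);
* ordinal raters with a specified per-rater sensitivity/specificity, rating
  from the correct side of the six-point scale with configurable dispersion.

Every generator is a pure function of its config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .corpus_eval import PronunciationCorpus, rank_pronunciations
from .phoneme_core import (
    CONSONANT,
    PhonemeInventory,
    Pronunciation,
    default_inventory,
)
from .stimulus_gen import RetryLimitError, generate_deliberate_error

#: Symbols never used when synthesising base strings: syllabic consonants and
#: the marginal /x/ are legitimate DISC but unnatural in generated nonwords.
_SYNTH_EXCLUDE = frozenset({"F", "H", "P", "C", "x"})


class SyntheticDataError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class CorpusConfig:
    """Study conditions for the synthetic pronunciation corpus.

    Defaults mirror a 915-item × 41-speaker naming corpus with a mean of 5.9
    distinct pronunciation variants per item (range 1–22), Zipf-skewed
    variant frequencies and a 2% chance that a response is a corrupted
    outlier production.
    """

    n_items: int = 915
    n_speakers: int = 41
    variant_mean: float = 5.9
    variant_min: int = 1
    variant_max: int = 22
    variant_weight_skew: float = 1.5
    error_rate: float = 0.02
    phoneme_length_range: tuple[int, int] = (4, 7)
    n_novel_plausible: int = 2
    deviant_speakers: Mapping[str, float] = field(default_factory=dict)
    conformist_speakers: frozenset[str] = frozenset()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_items < 1 or self.n_speakers < 1:
            raise SyntheticDataError("need at least one item and one speaker")
        if not (1 <= self.variant_min <= self.variant_max):
            raise SyntheticDataError("variant count bounds must satisfy 1 <= min <= max")
        if not (self.variant_min <= self.variant_mean <= self.variant_max):
            raise SyntheticDataError("variant mean outside [min, max]")
        if not 0.0 <= self.error_rate <= 1.0:
            raise SyntheticDataError("error_rate must be in [0, 1]")
        lo, hi = self.phoneme_length_range
        if not (2 <= lo <= hi):
            raise SyntheticDataError("phoneme lengths must be >= 2 and ordered")
        for sp, p in dict(self.deviant_speakers).items():
            if not 0.0 <= p <= 1.0:
                raise SyntheticDataError(f"deviance probability for {sp!r} outside [0, 1]")
        object.__setattr__(self, "deviant_speakers", dict(self.deviant_speakers))
        object.__setattr__(self, "conformist_speakers", frozenset(self.conformist_speakers))

    def speaker_ids(self) -> list[str]:
        return [f"s{i:02d}" for i in range(self.n_speakers)]


@dataclass(frozen=True)
class RaterConfig:
    """Operating point of the simulated listener panel.

    Each rater independently judges a plausible stimulus correct with
    probability ``sensitivity`` and an implausible one incorrect with
    probability ``specificity``; the ordinal value is then drawn from the
    chosen half of the scale, with geometric weight ``dispersion**k`` on
    steps away from the extreme (dispersion 0 → always the extreme).
    """

    n_raters_per_item: int = 6
    sensitivity: float = 0.95
    specificity: float = 0.88
    dispersion: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_raters_per_item < 1:
            raise SyntheticDataError("need at least one rater")
        for name in ("sensitivity", "specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SyntheticDataError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.dispersion <= 1.0:
            raise SyntheticDataError("dispersion must be in [0, 1]")


@dataclass
class GroundTruth:
    """Everything needed to score downstream verdicts against the generator.

    ``plausible[item]`` is the item's full plausible set (attested variants
    plus held-out novel ones); ``novel[item]`` the held-out variants no
    speaker produced; ``is_error[(item, speaker)]`` marks corrupted or
    deviant-unique responses; ``variant_counts[item]`` is the drawn number of
    attested variants; ``speaker_deviance`` the planted per-speaker deviance
    probability (0 for plain speakers).
    """

    plausible: dict[str, set[str]]
    novel: dict[str, tuple[str, ...]]
    is_error: dict[tuple[str, str], bool]
    variant_counts: dict[str, int]
    speaker_deviance: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "plausible": {k: sorted(v) for k, v in self.plausible.items()},
            "novel": {k: list(v) for k, v in self.novel.items()},
            "is_error": {f"{it}\t{sp}": bool(v)
                         for (it, sp), v in self.is_error.items()},
            "variant_counts": dict(self.variant_counts),
            "speaker_deviance": dict(self.speaker_deviance),
        }


# ---------------------------------------------------------------------------
# Variant-count distribution
# ---------------------------------------------------------------------------

def truncated_geometric_pmf(mean: float, lo: int, hi: int) -> np.ndarray:
    """PMF on {lo..hi} with P(k) ∝ q^(k−lo), with q solved to hit ``mean``.

    q < 1 gives the frequency-skewed shape (most items have few variants);
    the uniform midpoint and increasing shapes are reachable for targets up
    to hi.  Degenerate bounds (lo == hi) return a point mass.
    """
    ks = np.arange(lo, hi + 1, dtype=float)
    if lo == hi:
        return np.ones(1)

    def mean_of(logq: float) -> float:
        w = np.exp(logq * (ks - lo))
        w /= w.sum()
        return float((w * ks).sum())

    lo_m, hi_m = mean_of(-30.0), mean_of(30.0)
    if not (lo_m <= mean <= hi_m):
        raise SyntheticDataError(f"target mean {mean} unreachable on [{lo}, {hi}]")
    logq = optimize.brentq(lambda x: mean_of(x) - mean, -30.0, 30.0, xtol=1e-12)
    w = np.exp(logq * (ks - lo))
    return w / w.sum()


# ---------------------------------------------------------------------------
# Pronunciation synthesis helpers
# ---------------------------------------------------------------------------

def _synth_symbols(inv: PhonemeInventory) -> tuple[list[str], list[str]]:
    cons = sorted(p.symbol for p in inv
                  if p.category == CONSONANT and p.symbol not in _SYNTH_EXCLUDE)
    vows = sorted(p.symbol for p in inv if p.vocalic)
    return cons, vows


def _random_base(rng: np.random.Generator, inv: PhonemeInventory,
                 length: int) -> str:
    """A pronounceable-looking DISC string alternating C and V slots."""
    cons, vows = _synth_symbols(inv)
    start_consonant = bool(rng.random() < 0.7)
    out = []
    for i in range(length):
        pool = cons if (i % 2 == 0) == start_consonant else vows
        out.append(pool[rng.integers(len(pool))])
    return "".join(out)


def _perturb_plausible(rng: np.random.Generator, inv: PhonemeInventory,
                       base: str, forbidden: set[str],
                       max_tries: int = 200) -> str | None:
    """A near variant of ``base`` not in ``forbidden``.

    Alternates between lenient-forgivable edits (short vowel ↔ schwa) and
    feature-valid single substitutions, emulating the mix of minor and more
    marked — yet plausible — alternative pronunciations.
    """
    short = sorted(inv.short_vowels)
    for _ in range(max_tries):
        s = list(base)
        pos = int(rng.integers(len(s)))
        sym = s[pos]
        if rng.random() < 0.5 and (sym in inv.short_vowels or sym == inv.schwa):
            s[pos] = inv.schwa if sym != inv.schwa else short[rng.integers(len(short))]
        else:
            subs = inv.valid_substitutes(sym)
            if not subs:
                continue
            s[pos] = subs[rng.integers(len(subs))]
        cand = "".join(s)
        if cand not in forbidden:
            return cand
    return None


def _corrupt(rng: np.random.Generator, inv: PhonemeInventory, disc: str,
             forbidden: set[str]) -> str:
    """A feature-valid corruption of ``disc`` landing outside ``forbidden``."""
    spec = generate_deliberate_error(disc, inv, seed=rng, forbidden=forbidden)
    return spec.result.disc


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

def generate_corpus(cfg: CorpusConfig,
                    inv: PhonemeInventory | None = None
                    ) -> tuple[PronunciationCorpus, GroundTruth]:
    """Generate a pronunciation corpus plus its ground truth.

    Per item: draw the variant count, build that many distinct plausible
    variants (plus held-out novel ones), assign Zipf weights by variant rank,
    then let every speaker respond.  Coverage is enforced — each attested
    variant is produced by at least one plain speaker — so with
    ``error_rate=0`` the number of distinct pronunciations observed per item
    equals the drawn variant count.  Plain speakers sample variants by
    weight and are corrupted with probability ``error_rate``; conformists
    always produce the modal variant; deviants produce a unique corruption
    with their planted probability.
    """
    inv = inv or default_inventory()
    rng = np.random.default_rng(cfg.seed)
    speakers = cfg.speaker_ids()
    special = set(cfg.conformist_speakers) | set(cfg.deviant_speakers)
    plain = [sp for sp in speakers if sp not in special]
    pmf = truncated_geometric_pmf(cfg.variant_mean, cfg.variant_min,
                                  cfg.variant_max)
    supports = np.arange(cfg.variant_min, cfg.variant_max + 1)

    items: dict[str, list[tuple[str, Pronunciation]]] = {}
    truth = GroundTruth(plausible={}, novel={}, is_error={}, variant_counts={},
                        speaker_deviance={sp: float(cfg.deviant_speakers.get(sp, 0.0))
                                          for sp in speakers})
    lo_len, hi_len = cfg.phoneme_length_range
    for idx in range(cfg.n_items):
        item = f"nw{idx:04d}"
        length = int(rng.integers(lo_len, hi_len + 1))
        base = _random_base(rng, inv, length)
        k_target = int(rng.choice(supports, p=pmf))
        # Coverage requires a producer per variant.
        k_target = min(k_target, max(len(plain), 1))
        variants = [base]
        while len(variants) < k_target:
            parent = variants[int(rng.integers(len(variants)))]
            cand = _perturb_plausible(rng, inv, parent, set(variants))
            if cand is None:
                break
            variants.append(cand)
        k = len(variants)
        plausible = set(variants)
        novel: list[str] = []
        for _ in range(cfg.n_novel_plausible):
            cand = _perturb_plausible(rng, inv, base, plausible | set(novel))
            if cand is not None:
                novel.append(cand)
        plausible |= set(novel)

        weights = 1.0 / np.arange(1, k + 1) ** cfg.variant_weight_skew
        weights /= weights.sum()

        # Which plain speakers guarantee coverage of each variant.
        cover_order = rng.permutation(len(plain)) if plain else np.array([], dtype=int)
        cover = {plain[cover_order[j]]: j for j in range(min(k, len(plain)))}

        responses: list[tuple[str, Pronunciation]] = []
        taken: set[str] = set()
        for sp in speakers:
            if sp in cfg.conformist_speakers:
                continue  # assigned after everyone else, see below
            if sp in cfg.deviant_speakers and \
                    rng.random() < cfg.deviant_speakers[sp]:
                disc = _corrupt(rng, inv, variants[0], plausible | taken)
                is_err = True
            else:
                j = cover.get(sp)
                if j is None:
                    j = int(rng.choice(k, p=weights))
                disc = variants[j]
                is_err = False
                if sp in cover:
                    pass  # coverage responses are never corrupted
                elif rng.random() < cfg.error_rate:
                    disc = _corrupt(rng, inv, disc, plausible)
                    is_err = True
            responses.append((sp, Pronunciation(disc)))
            taken.add(disc)
            truth.is_error[(item, sp)] = is_err
        if cfg.conformist_speakers:
            # Conformists produce the empirical modal of everyone else's
            # responses (ties by DISC order), so by construction they are the
            # speakers who produce the item-modal pronunciation most often.
            if responses:
                modal = rank_pronunciations(responses)[0][0].disc
            else:
                modal = variants[0]
            for sp in sorted(cfg.conformist_speakers):
                responses.append((sp, Pronunciation(modal)))
                truth.is_error[(item, sp)] = False
        items[item] = responses
        truth.plausible[item] = plausible
        truth.novel[item] = tuple(novel)
        truth.variant_counts[item] = k
    return PronunciationCorpus(items), truth


# ---------------------------------------------------------------------------
# Model outputs
# ---------------------------------------------------------------------------

MODEL_CATEGORIES = ("modal", "minor", "novel_plausible", "error")


def generate_model_outputs(corpus: PronunciationCorpus, truth: GroundTruth,
                           p_modal: float = 0.55, p_minor: float = 0.15,
                           p_novel_plausible: float = 0.15,
                           p_error: float = 0.15,
                           seed: int = 0,
                           inv: PhonemeInventory | None = None) -> pd.DataFrame:
    """Emit one model output per item with a controlled mixture of categories.

    Categories: the item's modal pronunciation, a minor (non-modal attested)
    variant, a plausible pronunciation held out of the corpus (the
    false-negative regime of corpus-based scoring), or a feature-valid
    corruption.  Items lacking a requested category fall back to the modal
    pronunciation and are labelled accordingly.  Returns a frame with
    columns nonword, disc, category, plausible.
    """
    inv = inv or default_inventory()
    probs = np.array([p_modal, p_minor, p_novel_plausible, p_error], dtype=float)
    if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise SyntheticDataError("category probabilities must be >= 0 and sum to 1")
    rng = np.random.default_rng(seed)
    rows = []
    for item in corpus:
        entry = corpus.entry(item)
        ranked = rank_pronunciations(entry)
        plausible_set = truth.plausible[item]
        attested_plausible = [p.disc for p, _c in ranked if p.disc in plausible_set]
        modal = attested_plausible[0] if attested_plausible else ranked[0][0].disc
        cat = MODEL_CATEGORIES[int(rng.choice(4, p=probs))]
        if cat == "minor":
            minors = [d for d in attested_plausible if d != modal]
            if minors:
                disc = minors[int(rng.integers(len(minors)))]
            else:
                cat, disc = "modal", modal
        elif cat == "novel_plausible":
            novel = list(truth.novel[item])
            if novel:
                disc = novel[int(rng.integers(len(novel)))]
            else:
                cat, disc = "modal", modal
        elif cat == "error":
            attested = {p.disc for p, _c in ranked}
            try:
                disc = _corrupt(rng, inv, modal, plausible_set | attested)
            except RetryLimitError:
                cat, disc = "modal", modal
        else:
            disc = modal
        rows.append((item, disc, cat, cat != "error"))
    return pd.DataFrame(rows, columns=["nonword", "disc", "category", "plausible"])


# ---------------------------------------------------------------------------
# Ratings
# ---------------------------------------------------------------------------

def generate_ratings(stimuli: pd.DataFrame, cfg: RaterConfig) -> pd.DataFrame:
    """Simulate a rater panel over labelled stimuli.

    ``stimuli`` needs columns nonword, condition (or category) and plausible.
    Every rater rates every stimulus.  Returns a frame with columns
    participant_id, nonword, condition, rating (1–6), in stimulus-major
    order.  Deterministic under ``cfg.seed``.
    """
    df = stimuli.copy()
    if "condition" not in df.columns:
        if "category" not in df.columns:
            raise SyntheticDataError("stimuli need a condition or category column")
        df["condition"] = df["category"]
    if "plausible" not in df.columns:
        raise SyntheticDataError("stimuli need a plausible column")
    rng = np.random.default_rng(cfg.seed)
    n_stim = len(df)
    n_raters = cfg.n_raters_per_item
    plausible = df["plausible"].to_numpy(dtype=bool)

    u = rng.random((n_stim, n_raters))
    p_correct = np.where(plausible[:, None], cfg.sensitivity, 1.0 - cfg.specificity)
    correct = u < p_correct

    # Offset 0..2 from the extreme of the chosen half, geometric in dispersion.
    d = cfg.dispersion
    w = np.array([1.0, d, d * d])
    w /= w.sum()
    offsets = rng.choice(3, size=(n_stim, n_raters), p=w)
    ratings = np.where(correct, 6 - offsets, 1 + offsets)

    out = pd.DataFrame({
        "participant_id": np.tile([f"r{j:02d}" for j in range(n_raters)], n_stim),
        "nonword": np.repeat(df["nonword"].to_numpy(), n_raters),
        "condition": np.repeat(df["condition"].to_numpy(), n_raters),
        "rating": ratings.reshape(-1),
    })
    return out


def stimulus_labels(stimuli: pd.DataFrame) -> dict[tuple[str, str], bool]:
    """Ground-truth plausibility keyed by (nonword, condition)."""
    df = stimuli.copy()
    if "condition" not in df.columns:
        df["condition"] = df["category"]
    return {(str(r.nonword), str(r.condition)): bool(r.plausible)
            for r in df.itertuples(index=False)}
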