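"""Information-theoretic speaker profiling via the surprise index.

For each nonword the corpus provides empirical outcome probabilities: the
fraction of speakers who produced each pronunciation.  The surprise index
(SI) of a produced pronunciation is, by default, −log2 of that probability —
0 bits for a unanimous outcome, large for rare ones.  Averaging SI over a
speaker's responses profiles how far that speaker departs from the majority.
Speakers are ranked by mean SI and three roles are selected: the least
surprising (**modal**), the median (**typical**) and the most surprising
(**outlier**).  In practice the modal speaker is the one who produced the
item-modal pronunciation most often, and the outlier the one who most often
produced unique pronunciations.

The SI functional is pluggable (``si_fn`` maps a probability to bits), and
outcome probabilities may be computed plug-in (speaker's own response counts
in the denominator, the default) or leave-one-out.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, replace
from typing import Callable, Sequence

from scipy import stats

from .corpus_eval import CorpusError, PronunciationCorpus, Response
from .phoneme_core import Pronunciation, as_pronunciation


class SurpriseError(ValueError):
    """Degenerate input to a surprise computation."""


def neg_log2_surprise(probability: float) -> float:
    """Default SI functional: −log2(p) bits."""
    if probability <= 0.0:
        raise SurpriseError("surprise is undefined for zero probability")
    return -math.log2(probability)


def outcome_probability(entry: Sequence[Response],
                        p: "Pronunciation | str") -> float:
    """Fraction of an item's responses that are pronunciation ``p``."""
    if not entry:
        raise CorpusError("empty item")
    disc = as_pronunciation(p).disc
    hits = sum(1 for _sp, ref in entry if as_pronunciation(ref).disc == disc)
    return hits / len(entry)


def surprise(entry: Sequence[Response], p: "Pronunciation | str",
             si_fn: Callable[[float], float] = neg_log2_surprise) -> float:
    """Surprise (bits) of pronunciation ``p`` given the item's responses."""
    return si_fn(outcome_probability(entry, p))


@dataclass(frozen=True)
class SpeakerProfile:
    speaker_id: str
    mean_si: float
    rank: int  # 1 = least surprising
    n_responses: int
    role: str = "none"  # modal | typical | outlier | none


def speaker_profiles(corpus: PronunciationCorpus,
                     si_fn: Callable[[float], float] = neg_log2_surprise,
                     leave_one_out: bool = False) -> list[SpeakerProfile]:
    """Mean surprise per speaker, ranked ascending (rank 1 = least surprising).

    With ``leave_one_out`` the probability of a speaker's response excludes
    that response from both numerator and denominator; a response no other
    speaker produced then gets probability 0.5/(n−1) (a half-count floor) so
    its surprise stays finite.  Mean-SI ties rank by ascending speaker id.
    """
    totals: dict[str, float] = {}
    counts: dict[str, int] = {}
    for nonword, entry in corpus.items.items():
        n = len(entry)
        freq = Counter(p.disc for _sp, p in entry)
        for speaker, pron in entry:
            c = freq[pron.disc]
            if leave_one_out:
                prob = max(c - 1, 0.5) / (n - 1) if n > 1 else 1.0
            else:
                prob = c / n
            totals[speaker] = totals.get(speaker, 0.0) + si_fn(prob)
            counts[speaker] = counts.get(speaker, 0) + 1
    if not totals:
        raise CorpusError("empty corpus")
    means = {sp: totals[sp] / counts[sp] for sp in totals}
    order = sorted(means, key=lambda sp: (means[sp], sp))
    return [SpeakerProfile(sp, means[sp], rank, counts[sp])
            for rank, sp in enumerate(order, start=1)]


def select_roles(profiles: Sequence[SpeakerProfile]) -> list[SpeakerProfile]:
    """Assign modal (rank 1), outlier (rank n) and typical (rank ⌈n/2⌉)."""
    n = len(profiles)
    if n < 3:
        raise SurpriseError(f"role selection needs at least 3 speakers, got {n}")
    ranks = sorted(p.rank for p in profiles)
    if ranks != list(range(1, n + 1)):
        raise SurpriseError("profile ranks must be a permutation of 1..n")
    typical_rank = math.ceil(n / 2)
    out = []
    for p in profiles:
        if p.rank == 1:
            role = "modal"
        elif p.rank == n:
            role = "outlier"
        elif p.rank == typical_rank:
            role = "typical"
        else:
            role = "none"
        out.append(replace(p, role=role))
    return out


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    alternative: str


def compare_si_groups(g1: Sequence[float], g2: Sequence[float],
                      alternative: str = "less") -> WelchResult:
    """Welch's unequal-variance t test between two groups of SI values.

    Returns the t statistic, Welch–Satterthwaite degrees of freedom and the
    p value for the requested alternative (default one-sided: mean of ``g1``
    below mean of ``g2``).  Degenerate input (both groups constant with equal
    means) is rejected.
    """
    if len(g1) < 2 or len(g2) < 2:
        raise SurpriseError("each group needs at least 2 values")
    if alternative not in ("less", "greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = len(g1), len(g2)
    m1 = sum(g1) / n1
    m2 = sum(g2) / n2
    v1 = sum((x - m1) ** 2 for x in g1) / (n1 - 1)
    v2 = sum((x - m2) ** 2 for x in g2) / (n2 - 1)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0.0:
        raise SurpriseError("both groups have zero variance; t is undefined")
    t = (m1 - m2) / math.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    if alternative == "less":
        p = float(stats.t.cdf(t, df))
    elif alternative == "greater":
        p = float(stats.t.sf(t, df))
    else:
        p = float(2.0 * stats.t.sf(abs(t), df))
    return WelchResult(t=t, df=df, p=p, alternative=alternative)
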