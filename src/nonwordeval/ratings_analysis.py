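"""Analysis of six-point ordinal listener ratings.

Listeners rate each synthesised pronunciation on the ordinal scale
*Very bad, Bad, Probably not OK, Probably OK, Good, Very good* (1–6).
Ratings of a pronunciation are aggregated by the ordinal median (the scale
is not treated as continuous), an even-count median falling between two
steps is rounded **down**, and the median is binarised at "Probably OK":
values ≥ 4 count as a correct verdict.  From verdicts on known-good and
known-bad stimuli the pipeline estimates

* **sensitivity** — the proportion of known-good (modal) pronunciations
  rated correct, and
* **specificity** — the proportion of deliberately erroneous pronunciations
  rated incorrect.

Also here: mechanical participant gates (screening questions, catch-trial
error counts, an erratic-rater heuristic), the comparison of rating-based
and corpus-based verdicts (discrepancy partition, agreement chi-square
against a 50/50 split, combined acceptability with adjudicated ground
truth), and exclusion of items confounded by phoneme conflation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .corpus_eval import round_half_up
from .phoneme_core import Pronunciation, as_pronunciation


class RatingsError(ValueError):
    """Invalid ratings input."""


class RatingScale:
    """The six-point ordinal scale with its acceptance threshold."""

    LABELS: tuple[str, ...] = ("Very bad", "Bad", "Probably not OK",
                               "Probably OK", "Good", "Very good")
    MIN, MAX = 1, 6
    THRESHOLD = 4  # "Probably OK" and above count as correct

    _BY_LABEL = {lab.lower(): i + 1 for i, lab in enumerate(LABELS)}

    @classmethod
    def to_value(cls, rating: "int | str") -> int:
        """Normalise a label or integer to a scale value, validating range."""
        if isinstance(rating, str):
            try:
                v = int(rating)
            except ValueError:
                key = rating.strip().lower()
                if key not in cls._BY_LABEL:
                    raise RatingsError(f"unknown rating label {rating!r}") from None
                return cls._BY_LABEL[key]
        else:
            v = int(rating)
        if not cls.MIN <= v <= cls.MAX:
            raise RatingsError(f"rating {v} outside scale {cls.MIN}..{cls.MAX}")
        return v

    @classmethod
    def label(cls, value: int) -> str:
        return cls.LABELS[cls.to_value(value) - 1]


@dataclass(frozen=True)
class RatingRecord:
    """One listener judgment of one pronunciation."""

    participant_id: str
    nonword: str
    condition: str
    rating: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "rating", RatingScale.to_value(self.rating))


def median_rating(values: Sequence["int | str"]) -> int:
    """Ordinal median of scale values; half-step medians round down.

    With an even count the lower of the two middle values is returned, so a
    median tied between "Probably not OK" and "Probably OK" resolves to
    "Probably not OK".
    """
    if not len(values):
        raise RatingsError("median of no ratings")
    vals = sorted(RatingScale.to_value(v) for v in values)
    return vals[(len(vals) - 1) // 2]


def binarize(median: "int | str") -> bool:
    """Correct verdict iff the (median) rating is "Probably OK" or better."""
    return RatingScale.to_value(median) >= RatingScale.THRESHOLD


def sensitivity(modal_verdicts: Sequence[bool]) -> float:
    """Proportion of known-good pronunciations with a correct verdict."""
    if not len(modal_verdicts):
        raise RatingsError("sensitivity of an empty verdict set")
    return sum(bool(v) for v in modal_verdicts) / len(modal_verdicts)


def specificity(error_verdicts: Sequence[bool]) -> float:
    """Proportion of known-bad pronunciations with an *incorrect* verdict.

    Verdicts are correctness booleans (True = rated correct), so specificity
    counts the False entries.
    """
    if not len(error_verdicts):
        raise RatingsError("specificity of an empty verdict set")
    return sum(not bool(v) for v in error_verdicts) / len(error_verdicts)


def percent(proportion: float) -> int:
    """Half-up integer percentage for display; keep raw proportions in data."""
    return round_half_up(100.0 * proportion)


# ---------------------------------------------------------------------------
# Participant gates
# ---------------------------------------------------------------------------

def screen_participant(answers: Sequence[bool], n_questions: int = 5,
                       min_correct: int = 4) -> bool:
    """Screening gate: pass iff more than 3 of 5 questions are correct."""
    if len(answers) != n_questions:
        raise RatingsError(f"expected {n_questions} screening answers, got {len(answers)}")
    return sum(bool(a) for a in answers) >= min_correct


def catch_trial_flag(results: Sequence[bool], n_trials: int = 10,
                     max_errors: int = 2) -> bool:
    """Flag a participant who answered more than ``max_errors`` catch trials wrong.

    The flag marks the participant for review; exclusion is a separate,
    judgment-based decision (see :func:`flag_erratic_raters`).
    """
    if len(results) != n_trials:
        raise RatingsError(f"expected {n_trials} catch-trial results, got {len(results)}")
    errors = sum(not bool(r) for r in results)
    return errors > max_errors


def flag_erratic_raters(ratings: pd.DataFrame,
                        error_condition: str = "Deliberate Error") -> set[str]:
    """Participants whose mean rating of deliberate errors beats everything else.

    A rater who prefers known-bad pronunciations to every other condition is
    answering erratically.  ``ratings`` needs columns participant_id,
    condition, rating.
    """
    flagged: set[str] = set()
    for pid, sub in ratings.groupby("participant_id"):
        vals = sub["rating"].map(RatingScale.to_value)
        is_err = sub["condition"] == error_condition
        if is_err.any() and (~is_err).any():
            if vals[is_err].mean() > vals[~is_err].mean():
                flagged.add(str(pid))
    return flagged


# ---------------------------------------------------------------------------
# Method comparison
# ---------------------------------------------------------------------------

VerdictSet = Mapping[tuple[str, str], bool]  # (nonword, disc) -> accepted


def method_discrepancy(corpus_verdicts: VerdictSet,
                       rating_verdicts: VerdictSet
                       ) -> tuple[set[tuple[str, str]], set[tuple[str, str]]]:
    """Partition disagreements between the two evaluation methods.

    Returns ``(accepted_corpus_only, accepted_ratings_only)``; items the
    methods agree on appear in neither set.  Key sets must coincide.
    """
    if set(corpus_verdicts) != set(rating_verdicts):
        raise RatingsError("verdict sets are keyed by different items")
    corpus_only = {k for k, v in corpus_verdicts.items() if v and not rating_verdicts[k]}
    ratings_only = {k for k, v in rating_verdicts.items() if v and not corpus_verdicts[k]}
    return corpus_only, ratings_only


def agreement_chi_square(agree_count: int, disagree_count: int
                         ) -> tuple[float, int, float]:
    """Goodness-of-fit χ² of an observed agree/disagree split against 50/50."""
    total = agree_count + disagree_count
    if total <= 0:
        raise RatingsError("chi-square of an empty split")
    chi2, p = stats.chisquare([agree_count, disagree_count])
    return float(chi2), 1, float(p)


def combined_acceptability(agreed: VerdictSet,
                           discrepant_truth: VerdictSet) -> float:
    """Overall acceptance rate combining agreed items with adjudicated ones.

    ``agreed`` holds the common verdict of items both methods agree on;
    ``discrepant_truth`` holds the adjudicated ground truth (e.g. expert
    median judgment) for the discrepant items.  The two key sets must be
    disjoint and jointly non-empty.
    """
    overlap = set(agreed) & set(discrepant_truth)
    if overlap:
        raise RatingsError(f"items appear in both sets: {sorted(overlap)[:3]}")
    total = len(agreed) + len(discrepant_truth)
    if total == 0:
        raise RatingsError("no items to combine")
    accepted = sum(bool(v) for v in agreed.values()) \
        + sum(bool(v) for v in discrepant_truth.values())
    return accepted / total


def conflation_confounded_items(
        pronunciations_by_item: Mapping[str, Iterable["Pronunciation | str"]],
        symbols: Iterable[str] = ("9", "$")) -> set[str]:
    """Items any of whose pronunciations contains a conflation-affected phoneme.

    Used to exclude orthographic stimuli confounded by the corpus's $→9
    merge before computing comparison statistics.
    """
    symset = set(symbols)
    out: set[str] = set()
    for item, prons in pronunciations_by_item.items():
        for p in prons:
            if symset & set(as_pronunciation(p).disc):
                out.add(item)
                break
    return out


# ---------------------------------------------------------------------------
# Operating-point estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OperatingPoint:
    sensitivity: float
    specificity: float
    n_plausible: int
    n_implausible: int


def estimate_operating_point(ratings: pd.DataFrame,
                             labels: Mapping[tuple[str, str], bool],
                             aggregate: str = "rating") -> OperatingPoint:
    """Estimate listener sensitivity/specificity from labelled ratings.

    ``ratings`` needs columns nonword, condition, rating; ``labels`` maps
    (nonword, condition) to the ground-truth plausibility of that stimulus.

    ``aggregate="rating"`` treats every individual rating as a verdict and
    recovers the *per-rater* operating point (the consistent estimator of a
    rater's accept probability).  ``aggregate="median"`` first takes the
    per-stimulus ordinal median, mirroring how a ratings experiment scores
    each pronunciation; with several raters per item this majority vote is
    more accurate than a single rater, so its sensitivity/specificity exceed
    the per-rater values.
    """
    if aggregate not in ("rating", "median"):
        raise RatingsError(f"unknown aggregate mode {aggregate!r}")
    verdicts: list[tuple[bool, bool]] = []  # (plausible, accepted)
    if aggregate == "rating":
        for row in ratings.itertuples(index=False):
            key = (str(row.nonword), str(row.condition))
            if key not in labels:
                raise RatingsError(f"no plausibility label for stimulus {key}")
            verdicts.append((bool(labels[key]), binarize(row.rating)))
    else:
        for key, sub in ratings.groupby(["nonword", "condition"]):
            key = (str(key[0]), str(key[1]))
            if key not in labels:
                raise RatingsError(f"no plausibility label for stimulus {key}")
            verdicts.append((bool(labels[key]),
                             binarize(median_rating(list(sub["rating"])))))
    plaus = [acc for lab, acc in verdicts if lab]
    implaus = [acc for lab, acc in verdicts if not lab]
    if not plaus or not implaus:
        raise RatingsError("need both plausible and implausible stimuli")
    return OperatingPoint(sensitivity=sensitivity(plaus),
                          specificity=specificity(implaus),
                          n_plausible=len(plaus), n_implausible=len(implaus))
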