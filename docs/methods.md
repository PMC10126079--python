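# Methods

This note documents the models and procedures implemented in `nonwordeval`,
the choices made where the design was genuinely open, and what the synthetic
data can and cannot establish about real evaluations.

## Phoneme inventory and features

The shipped inventory (`src/nonwordeval/data/disc_inventory.tsv`) is the
British English DISC character set compiled from the CELEX transcription
documentation: 29 consonants (including the syllabic consonants F /m̩/,
H /n̩/, P /l̩/, C /ŋ̩/), 12 monophthongs and 8 diphthongs. Rare loanword
nasal vowels and the linking-r symbol are omitted: they do not occur in
nonword naming material and would distort the deliberate-error substitute
pools. Each consonant carries a single place and manner label (affricates are
labelled postalveolar affricate); each vowel carries a position
(front/mid/back) and a length class (short/long/diphthong).

Open interpretive choices, fixed and documented here:

* **Diphthong position** is the starting vowel quality: /eɪ aɪ ɪə ɛə/ front,
  /əʊ aʊ/ mid, /ɔɪ ʊə/ back. The constraint system only requires that the
  short back vowel Q can be replaced by the diphthong 5 (possible under this
  assignment); the data do not determine the assignment further.
* /ʌ/ (V) and /ɜː/ (3) are classed mid (central); /æ/ ({) front.
* The **short-vowel set** for lenient matching defaults to
  {I, E, {, Q, V, U}, with schwa as their forgivable counterpart; it is
  overridable per inventory.
* **Stress is ignored throughout**: the parser strips the CELEX stress
  markers `'` and `"` and no operation scores stress placement.

The DISC↔IPA mapping is a bijection per symbol. Full-string IPA decoding is
greedy longest-match, so an IPA sequence readable as either one phoneme or
two (tʃ = J or t+ʃ, ʊə = 9 or U+@) always decodes as the single phoneme;
round-tripping a DISC string through IPA is exact except for such adjacent
pairs, which are rare and flagged in the docstring.

## Corpus-based matching

Strict matching is string identity; lenient matching forgives
short-vowel↔schwa substitutions position by position and therefore requires
equal length (the forgiveness is defined over substitution errors only, never
insertions or deletions, so leniency is a strict superset of strict
matching). Conflation maps are applied to candidate and references *before*
frequency ranking, which makes "conflate the corpus, then match" and "match
with conflation enabled" provably identical; maps must be idempotent after
one pass (no chains or cycles).

Frequency ranks: distinct pronunciations are ordered by descending response
count with ties broken by ascending DISC string. The tie rule is arbitrary
but deterministic; it affects only which of two equally frequent variants is
called "rank 1".

Zero-match/one-match selection counts *speaker responses*, not distinct
pronunciations: an output matching a pronunciation produced by three speakers
is a three-match item even though it matched one variant.

Displayed match tables round percentages half-up to integers; raw proportions
are always available (`MatchTable.as_dict(rounded=False)`).

## Deliberate errors

A deliberate error substitutes exactly one phoneme of a source pronunciation
under the feature constraint (consonants: different place *and* manner;
vocalic phonemes: different position *and* length class; never across the
consonant/vocalic boundary). The sampling order is: position uniform among
positions with a non-empty substitute pool, then substitute uniform within
the pool. The order matters for reproducibility (it weights positions
equally regardless of pool size) and is fixed here because "at random" is
otherwise underdetermined.

Collision exclusion is available and used by default in the pipelines: the
caller passes the attested pronunciations of the item as a forbidden set and
the generator resamples (bounded at 1000 retries) until the result is
genuinely novel. Without exclusion a random "error" can coincide with a real
minor pronunciation of the same item, silently polluting the known-bad
condition — the classic failure mode of this design. Both modes exist
because published stimulus sets were evidently built without exclusion.

## Stimulus lists

List assignment places each (nonword, condition, pronunciation) into one of
`n_primary_lists` balanced lists such that no list repeats an orthographic
form (a participant never hears two pronunciations of the same nonword), then
splits lists over the length cap into consecutive chunks. Infeasibility
(more conditions of one nonword than lists) is reported with a witness. The
assignment is seeded greedy-balanced rather than an attempt to reconstruct
any particular published randomisation, which is unrecoverable; an
independent validator re-checks every constraint and is exercised
property-style in the tests.

## Surprise index

The default surprise functional is Good's surprise index applied to the
empirical outcome distribution: SI(p) = −log₂ p, where p is the fraction of
an item's responses equal to the produced pronunciation. It is 0 bits for a
unanimous outcome and strictly decreasing in probability. The functional is
pluggable (`si_fn`) because alternative surprise definitions exist in the
literature; everything downstream (profiles, ranks, roles) is agnostic to
the choice.

Probabilities are plug-in by default (the speaker's own response counts in
the denominator). A leave-one-out mode is available; a response no other
speaker produced then receives probability 0.5/(n−1) — a half-count floor
that keeps the surprise finite while preserving ordering. Speaker ranks sort
ascending mean SI with ties broken by speaker id; roles are modal (rank 1),
outlier (rank n) and typical (rank ⌈n/2⌉, i.e. rank 21 of 41).

Group comparisons of SI values use Welch's unequal-variance t with
Welch–Satterthwaite degrees of freedom, one-sided by default; the
implementation is closed-form and cross-checked against scipy in the tests.

## Ratings analysis

The six-point scale is ordinal; per-stimulus aggregation is the ordinal
median with any even-count median falling between two steps rounded *down*
(the published rule is stated only for the "Probably not OK"/"Probably OK"
boundary; it is extended uniformly because the asymmetry — a tie never
promotes a pronunciation — is the point of the rule). Binarisation accepts
values ≥ 4. Sensitivity and specificity are simple proportions over verdict
sets; percentage displays round half-up while raw proportions are kept.

Participant gates are mechanical: screening passes at ≥ 4/5 correct;
catch-trial review flags > 2 errors in 10. The additional judgment call of
excluding raters who behave erratically is implemented as a separate,
optional heuristic: flag participants whose mean rating of deliberate errors
exceeds their mean rating of everything else.

Two operating-point estimators are provided. `aggregate="rating"` treats
each individual rating as a verdict and is the consistent estimator of a
*rater's* accept probability — this is what the calibration tests check.
`aggregate="median"` first takes the per-stimulus median over the panel,
mirroring how an experiment scores each pronunciation; it is a majority
vote, so with k raters its sensitivity/specificity exceed the per-rater
values (e.g. six raters at 0.95 per-rater sensitivity yield ≈ 0.998
item-level sensitivity). The two must not be conflated when comparing an
estimate against a per-rater parameter.

## Synthetic data generator

The generator emulates the statistical shape of a disyllabic nonword naming
corpus; its defaults are the study-scale conditions:

* 915 items × 41 speakers;
* per-item distinct-variant counts from a truncated geometric on [1, 22]
  with the decay solved numerically so the mean is 5.9;
* Zipf-like variant weights (weight ∝ rank^−1.5), giving one dominant modal
  pronunciation and a thin tail;
* response corruption probability 0.02 — occasional production or
  transcription errors landing outside the plausible set, chosen as a small
  "occasional" rate consistent with the handful of implausible
  transcriptions identifiable in real corpora;
* two held-out "novel plausible" variants per item that no speaker produces,
  reproducing the false-negative mechanism of corpus scoring;
* base strings of 4–7 phonemes alternating consonant and vocalic slots
  (syllabic consonants and /x/ excluded from synthesis as unnatural in
  nonwords).

Coverage is enforced: each attested variant is produced by at least one
plain speaker, so with corruption off the observed distinct-variant count
per item equals the drawn count and the 5.9 target is measurable on the
emitted corpus.

Planted personas validate speaker profiling. A **deviant** produces a unique
corruption with a planted probability (0.6 in the pipelines — a speaker who
is idiosyncratic on more than half the items). A **conformist** is assigned,
after all other speakers have responded, the empirical modal of their
responses; adding the conformist's response makes that pronunciation
strictly modal, so the conformist's per-item surprise is minimal by
construction and modal-role recovery does not hinge on sampling luck. This
matches the ex-post characterisation of a modal speaker as the one who
produced the item-modal pronunciation most often.

When the speaker pool is scaled down, variant richness must scale with it:
11 speakers cannot exhibit 5.9-variant diversity without nearly every
response being unique, which would make every speaker an outlier. The
scaled profiling corpora therefore preserve the study's variants-per-speaker
ratio (5.9/41 ≈ 0.14 → mean ≈ 1.6 variants at 11 speakers, max 6).

Raters are independent Bernoulli judges at the configured
sensitivity/specificity; the ordinal value is then drawn from the chosen
half of the scale with geometric weight dispersionᵏ on steps away from the
extreme (dispersion 0 → always 6 or 1; default 0.25 concentrates ratings
near the extremes, as real panels do for clear stimuli).

What the synthetic data does *not* emulate: phonotactically legal English
orthography, item-level difficulty differences, correlated rater errors,
synthesiser artefacts, and the stress dimension. Passing tests therefore
establish the correctness and calibration of the pipeline machinery, not the
empirical performance of any particular reading-aloud model on human data.

## Problem sizes and numerics

The test and acceptance runs use: 1,000 random tiny corpora (≤ 10 items,
≤ 10 variants, ≤ 8 phonemes) for matcher/oracle equivalence; 10,000 draws
across 50 pronunciations for error-generator soundness, with exhaustive
support equality checked on length-2 pronunciations where full coverage is
statistically certain; 200 replicates of the 20-item × 11-speaker profiling
corpus; and 100 replicates of a 528 + 528 stimulus panel with 6 raters for
ratings calibration (estimates within ±0.03 of the generating operating
point). The truncated-geometric decay is solved with Brent's method to
1e-12; degenerate inputs (empty items, zero-probability surprise,
zero-variance Welch groups, infeasible list constraints) raise typed errors
rather than returning sentinel values.

## Known limitations

* Lenient matching is substitution-only by design; alignment-based edit
  distances are out of scope.
* The one-pass-idempotent restriction on conflation maps forbids chained
  merges; supply the transitive closure explicitly if needed.
* IPA string decoding prefers single phonemes over ambiguous two-phoneme
  readings (see above).
* The leave-one-out surprise floor (half-count) is a pragmatic smoothing
  choice, not an estimator with optimality claims.
* Catch-trial flagging marks participants for review; the package does not
  automate the final keep/exclude judgment beyond the erratic-rater
  heuristic.
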