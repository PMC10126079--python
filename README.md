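# nonwordeval

Tools for evaluating how well reading-aloud models (dual-route and
connectionist psychological models, or grapheme-to-phoneme converters such as
joint-sequence graphone models) pronounce **nonwords** — pronounceable letter
strings like *outslaw* or *conglist* that have no dictionary entry. Because
human readers themselves disagree on how to pronounce a nonword (a naming
corpus typically records around 5.9 distinct pronunciations per item, ranging
from 1 to 22), "correctness" cannot be a single gold transcription. This
package implements and compares the two evaluation strategies used in
computational psycholinguistics:

1. **Corpus-based matching.** A model output counts as correct if it matches
   at least one human reference pronunciation. Phoneme strings are written in
   DISC, the one-character-per-phoneme alphabet of the CELEX lexical database
   (`$` = /ɔː/, `9` = /ʊə/, `@` = schwa, `J` = /tʃ/). Matching is *strict*
   (exact string identity) or *lenient* (substitutions between short vowels
   {I, E, {, Q, V, U} and schwa are forgiven, in either direction; insertions
   and deletions never are). Matches are tallied by the frequency rank of the
   matched reference — rank 1 is the modal pronunciation — and a configurable
   conflation map (default `$ → 9`) reproduces transcriber merges in the
   reference corpus. Helpers select *zero-match* and *one-match* items (the
   candidates for false negatives and false positives of corpus scoring) and
   mine position-wise substitution patterns from discrepant pairs.

2. **Ratings-based evaluation.** Listeners rate synthesised pronunciations on
   a six-point ordinal scale (*Very bad … Very good*). The package builds the
   stimuli — modal and minor human pronunciations, feature-constrained
   **deliberate errors** (one random phoneme substitution where consonants
   must change both place and manner, vowels/diphthongs both position and
   length class), catch trials, and balanced presentation lists — and analyses
   the ratings: ordinal medians (ties round down), binarisation at
   "Probably OK",

   * sensitivity = P(known-good pronunciation rated correct),
   * specificity = P(deliberate error rated incorrect),

   plus participant gates, method-discrepancy partitions, χ² agreement tests
   and combined acceptability with adjudicated ground truth. Speakers are
   profiled with the **surprise index** SI = −log₂ p(pronunciation | item),
   averaged per speaker, to select modal / typical / outlier speakers.

A synthetic-data generator (`nonwordeval.synthetic_data`) emulates the corpus
structure, model-output mixtures and rater panels with known ground truth, so
the complete pipeline is testable without access to any human corpus.

## Worked example

```python
from nonwordeval import (PronunciationCorpus, default_conflation,
                         match_against_corpus, match_table)

corpus = PronunciationCorpus({
    "outslaw":  [(f"s{i}", "6ts19") for i in range(5)],
    "pifty":    [("s0", "pIfti"), ("s1", "pIfti"), ("s2", "pIfti"),
                 ("s3", "pIftI"), ("s4", "pIftI")],
    "conglist": [("s0", "kQnglIst"), ("s1", "kQnglIst"), ("s2", "k@nglIst"),
                 ("s3", "kQnglIst"), ("s4", "kQnglIst")],
})
model = {"outslaw": "6ts1$", "pifty": "pIftI", "conglist": "kQnglIst"}

print(match_table(model, corpus, "strict").as_dict(rounded=True))
print(match_against_corpus("6ts1$", corpus.entry("outslaw"), "strict",
                           conflation=default_conflation()))
```

prints

```
{'rank1': 33, 'rank2': 33, ..., 'Match': 67, 'Absent': 33}
MatchResult(criterion='strict', matched=True, rank=1)
```

i.e. one model output matched the modal pronunciation (rank 1), one matched
the second-ranked variant, and the *outslaw* output `6ts1$` matched nothing —
until the `$ → 9` conflation is applied, when it becomes a rank-1 match.
`Match + Absent` always sums to 100.

The `examples/` directory contains one short script per capability
(`corpus_matching.py`, `deliberate_errors.py`, `speaker_profiles.py`,
`ratings_pipeline.py`); each builds a small input, runs the method and prints
what the numbers mean.

## Command line

A thin CLI wraps the library:

```bash
nonwordeval simulate --seed 5 --out sim/          # synthetic corpus + ratings
nonwordeval match --corpus sim/corpus.tsv --model sim/model.tsv \
    --criterion lenient --conflate default        # match table
nonwordeval si --corpus sim/corpus.tsv            # speaker roles
nonwordeval gen-errors --corpus sim/corpus.tsv --seed 2 --out errors.tsv
nonwordeval build-lists --stimuli stimuli.tsv --lists 6 --cap 200 --out lists.tsv
nonwordeval ratings --ratings ratings.csv         # sensitivity/specificity
```

Formats are plain TSV/CSV: corpora as `nonword, speaker_id, disc`, model
outputs as `nonword, disc`, ratings as
`participant_id, nonword, condition, rating`.

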