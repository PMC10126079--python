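"""Corpus-based matching of model pronunciations, strict and lenient.

Builds a toy reference corpus of human pronunciations (DISC notation, one
character per phoneme), scores a small set of model outputs under both
criteria, and shows how phoneme conflation rescues an output that uses $
where the corpus transcriber wrote 9.
"""

from nonwordeval import (
    PronunciationCorpus,
    default_conflation,
    match_against_corpus,
    match_table,
)

corpus = PronunciationCorpus({
    # outslaw-like item: all five speakers end in the diphthong 9 (/ʊə/)
    "outslaw": [(f"s{i}", "6ts19") for i in range(5)],
    # an item with a modal and a minor pronunciation
    "pifty":   [("s0", "pIfti"), ("s1", "pIfti"), ("s2", "pIfti"),
                ("s3", "pIftI"), ("s4", "pIftI")],
    # an item answered with schwa by some speakers
    "conglist": [("s0", "kQnglIst"), ("s1", "kQnglIst"), ("s2", "k@nglIst"),
                 ("s3", "kQnglIst"), ("s4", "kQnglIst")],
})

model = {"outslaw": "6ts1$", "pifty": "pIftI", "conglist": "kQnglIst"}

for criterion in ("strict", "lenient"):
    table = match_table(model, corpus, criterion)
    print(f"{criterion:>8}: {table.as_dict(rounded=True)}")

res = match_against_corpus("6ts1$", corpus.entry("outslaw"), "strict")
print("outslaw 6ts1$ without conflation:", res)
res = match_against_corpus("6ts1$", corpus.entry("outslaw"), "strict",
                           conflation=default_conflation())
print("outslaw 6ts1$ with $->9 merge:   ", res)

# The rank columns say which frequency rank the model output matched
# (rank 1 = the modal pronunciation); Match + Absent = 100.  Without the
# $->9 merge the outslaw output is a false negative; with it, a rank-1 match.
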