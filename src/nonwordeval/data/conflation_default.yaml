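# Default phoneme conflation used when matching against the reference corpus,
# which merged the long vowel /ɔː/ ($) into the diphthong /ʊə/ (9) during
# transcription.  Supply your own mapping to extend or disable this.
"$": "9"
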