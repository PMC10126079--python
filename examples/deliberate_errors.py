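"""Building rating-experiment stimuli: modal/minor pronunciations and errors.

Picks the modal and minor pronunciation of an item, then derives a deliberate
error from the modal by one feature-constrained substitution (consonants must
change place and manner; vowels/diphthongs must change position and length
class).  The attested pronunciations are passed as forbidden so the "error"
can never collide with a genuine pronunciation from another condition.
"""

from nonwordeval import (
    default_inventory,
    generate_deliberate_error,
    minor_pronunciation,
    modal_pronunciation,
)
from nonwordeval.stimulus_gen import assign_lists, build_catch_trials

inv = default_inventory()

# outbost-like item: modal 6tbQst (28 speakers), minor 6tb5st (4 speakers)
entry = [(f"s{i:02d}", "6tbQst") for i in range(28)] + \
        [(f"s{i:02d}", "6tb5st") for i in range(28, 32)]

modal = modal_pronunciation(entry)
minor = minor_pronunciation(entry)
attested = {p for _s, p in entry}
spec = generate_deliberate_error(modal, inv, seed=11, forbidden=attested)

print("modal:", modal, " minor:", minor)
print(f"deliberate error: {spec.source} -> {spec.result} "
      f"({spec.original}->{spec.substitute} at position {spec.position})")
# The substitution always passes the feature constraint and, because 6tb5st
# is forbidden, the error can never equal the attested minor pronunciation.

catch = build_catch_trials(
    [(f"cw{i}", d) for i, d in enumerate(
        ["p{t", "tik", "mun", "l$d", "sIp", "k5n", "f3m", "b8d", "gu_", "h2v"])],
    inv, seed=2)
print("catch trials:", [(t.nonword, t.pronunciation.disc, t.label) for t in catch[:4]], "...")

stimuli = [("outbost", "Human Modal", modal),
           ("outbost", "Human Minor", minor),
           ("outbost", "Deliberate Error", spec.result)]
lists = assign_lists(stimuli, n_primary_lists=3, max_per_list=2, seed=0)
print("lists:", [(l.list_id, [nw for nw, _c, _p in l.entries]) for l in lists])
# Each pronunciation lands in exactly one list and no list repeats the
# orthographic form, so no participant hears two versions of the same nonword.
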