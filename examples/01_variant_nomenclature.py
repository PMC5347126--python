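"""Call rCRS-relative variants from a whole mitogenome.

Builds a genome carrying three known edits, calls it against the packaged
reference, and prints the calls in standard mtDNA nomenclature.
"""

from mitolineage import call_variants, load_reference, parse_variant

reference = load_reference()

# a genome carrying the M42 definer, one M42c diagnostic, and a deletion
seq = list(reference.sequence)
seq[9156 - 1] = "G"        # A9156G
seq[64 - 1] = "T"          # C64T
del seq[999]               # deletion at np 1000

profile = call_variants("".join(seq), reference, sample_id="demo")
print("called variants:", " ".join(profile.tokens()))
print("masked sites recorded:", len(profile.excluded_sites))

v = parse_variant("A9156G")
print(f"A9156G parsed -> np {v.position}, {v.ref_allele}>{v.alt_allele}")

# Each token is one mutation away from the reference: A9156G is the
# transition defining haplogroup M42; the 'd' token is the deletion placed
# at its 3'-most equivalent position.
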