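"""Classify variant profiles against the packaged haplogroup tree.

Shows the identical-by-descent reasoning encoded in the site weights: a
profile with only the M42 definer stays at M42; adding the full M42c motif
moves it to M42c; adding only the recurrent 8251 hotspot does NOT promote
it to M42a.
"""

from mitolineage import (
    VariantProfile,
    classify_sample,
    load_packaged_tree,
    parse_variant,
)

tree = load_packaged_tree()


def profile(tokens):
    return VariantProfile("demo", frozenset(parse_variant(t) for t in tokens))


M_BACKGROUND = ["A1041G", "C2092T", "G3115A"]  # macrohaplogroup M spine

cases = {
    "M42 definer only": M_BACKGROUND + ["A9156G"],
    "full M42c motif": M_BACKGROUND + ["A9156G", "C64T", "T195C"],
    "M42 + 8251 hotspot": M_BACKGROUND + ["A9156G", "G8251A"],
}

for name, tokens in cases.items():
    r = classify_sample(profile(tokens), tree)
    runner = f"(runner-up {r.runner_up[0]} at {r.runner_up[1]:.3f})"
    print(f"{name:24s} -> {r.haplogroup:5s} score {r.score:.3f} {runner}")

# The hotspot np 8251 (26 independent occurrences in PhyloTree) carries
# weight 0.2, so sharing it alone is treated as likely identical-by-state
# and does not pull the sample into M42a.
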