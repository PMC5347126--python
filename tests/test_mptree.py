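"""Maximum-parsimony sample trees: perfect phylogenies, conflicts, oracle."""

import numpy as np
import pytest

from mitolineage.classify import SiteWeights
from mitolineage.haplotree import cumulative_expected
from mitolineage.mptree import (
    ConsistencyError,
    SampleTree,
    build_mp_tree,
    characters_compatible,
    parsimony_score,
    to_newick,
)
from mitolineage.variants import (
    Variant,
    VariantKind,
    VariantProfile,
    parse_variant,
)

from .oracles import mp_min_score, random_parsimony_instance

EMPTY = VariantProfile("root", frozenset())


def sub(pos, alt="G", ref="A"):
    return Variant(pos, VariantKind.SUBSTITUTION, ref, alt)


def profile(sample_id, positions):
    return VariantProfile(sample_id, frozenset(sub(p) for p in positions))


def test_single_sample_two_privates_single_edge():
    t = build_mp_tree([profile("s1", [100, 200])], EMPTY)
    assert t.n == 1
    assert parsimony_score(t) == 2
    (tip,) = t.tips()
    assert t.path_mutations(tip.name) == 2


def test_nested_carrier_sets_give_unique_perfect_phylogeny():
    profiles = [
        profile("s1", [10]),
        profile("s2", [10, 20]),
        profile("s3", [10, 30]),
        profile("s4", []),
    ]
    t = build_mp_tree(profiles, EMPTY)
    assert parsimony_score(t) == 3
    # brute-force confirms 3 is minimal
    chars = [
        frozenset({"s1", "s2", "s3"}),
        frozenset({"s2"}),
        frozenset({"s3"}),
    ]
    assert mp_min_score(["s1", "s2", "s3", "s4"], chars) == 3
    # perfect phylogeny: every tip's path length equals its profile size
    for tip in t.tips():
        assert t.path_mutations(tip.name) == len(
            {v.position for v in profiles_by_id(profiles)[tip.sample_id].variants}
        )


def profiles_by_id(profiles):
    return {p.sample_id: p for p in profiles}


def test_incompatible_triple_matches_brute_force_minimum():
    profiles = [
        profile("s1", [10, 20]),
        profile("s2", [10, 30]),
        profile("s3", [20, 30]),
    ]
    t = build_mp_tree(profiles, EMPTY)
    chars = [
        frozenset({"s1", "s2"}),
        frozenset({"s1", "s3"}),
        frozenset({"s2", "s3"}),
    ]
    assert parsimony_score(t) == mp_min_score(["s1", "s2", "s3"], chars) == 5


def test_compatible_data_score_is_number_of_distinct_variants():
    rng = np.random.default_rng(11)
    positions = rng.choice(5000, size=12, replace=False) + 1
    # nested/disjoint carrier structure: a chain plus disjoint singletons
    profiles = [
        profile("a", positions[:4]),
        profile("b", positions[:6]),
        profile("c", positions[6:8]),
        profile("d", []),
    ]
    t = build_mp_tree(profiles, EMPTY)
    assert parsimony_score(t) == 8


def test_star_of_five_tips():
    profiles = [profile(f"s{i}", [100 + i]) for i in range(5)]
    t = build_mp_tree(profiles, EMPTY)
    assert parsimony_score(t) == 5
    for tip in t.tips():
        assert t.path_mutations(tip.name) == 1


def test_compatibility_predicate_is_symmetric_pairwise_test():
    a, b = frozenset("12"), frozenset("23")
    assert not characters_compatible(a, b)
    assert not characters_compatible(b, a)
    assert characters_compatible(frozenset("12"), frozenset("1"))
    assert characters_compatible(frozenset("12"), frozenset("34"))


def test_root_back_mutation_conflict_raises(tree):
    root = VariantProfile(
        "root",
        frozenset({parse_variant("G8251A!")}),
    )
    p = VariantProfile("s1", frozenset({parse_variant("G8251A")}))
    with pytest.raises(ConsistencyError):
        build_mp_tree([p], root)


def test_empty_input_rejected():
    with pytest.raises(ValueError):
        build_mp_tree([], EMPTY)


def test_oracle_equivalence_on_random_small_instances():
    """Greedy/bounded-exact builder hits the exhaustive-search minimum."""
    rng = np.random.default_rng(0)
    for _ in range(30):
        tips, tipstates = random_parsimony_instance(rng)
        chars_pos = sorted({p for s in tipstates.values() for p in s})
        chars = [
            frozenset(t for t in tips if p in tipstates[t]) for p in chars_pos
        ]
        profiles = [profile(t, tipstates[t]) for t in tips]
        t = build_mp_tree(profiles, EMPTY)
        assert parsimony_score(t) == mp_min_score(tips, chars)


def test_weighted_resolution_duplicates_the_cheap_site():
    """With unequal weights the recurrent (cheap) site mutates twice."""
    # conflict between site 10 (expensive) and site 20 (cheap hotspot)
    profiles = [
        profile("s1", [10, 20]),
        profile("s2", [10]),
        profile("s3", [20]),
    ]
    w = SiteWeights({20: 0.2})
    t = build_mp_tree(profiles, EMPTY, w)
    counts = {}
    for _, _, muts in t.edges():
        for v in muts:
            counts[v.position] = counts.get(v.position, 0) + 1
    assert counts[20] == 2 and counts[10] == 1


def test_p11_like_profiles_join_through_shared_mutation(tree):
    """Samples sharing C11288T (mainland + Tasmanian-like) join through it,
    rather than grouping with a P4-like profile that shares nothing."""
    root_profile = VariantProfile(
        "root_P", variants=cumulative_expected(tree, "P")
    )
    base = set(root_profile.variants)
    c11288 = parse_variant("C11288T")
    mainland = VariantProfile(
        "mainland", frozenset(base | {c11288, parse_variant("G14364A")})
    )
    tasmanian = VariantProfile(
        "tasmanian", frozenset(base | {c11288, parse_variant("T15479C")})
    )
    p4_like = VariantProfile(
        "p4like",
        frozenset(base | {parse_variant("T12346C"), parse_variant("A13422G")}),
    )
    t = build_mp_tree([mainland, tasmanian, p4_like], root_profile)
    # find the edge carrying C11288T and the tips below it
    edge = next(
        (parent, child, muts)
        for parent, child, muts in t.edges()
        if any(v.position == 11288 for v in muts)
    )
    below = tips_below_names(t, edge[1])
    assert below == {"mainland", "tasmanian"}
    assert parsimony_score(t) == 5


def tips_below_names(t: SampleTree, name: str):
    out = set()
    stack = [name]
    while stack:
        cur = stack.pop()
        node = t.nodes[cur]
        if node.is_tip:
            out.add(node.sample_id)
        stack.extend(node.children)
    return out


def test_newick_export_carries_mutation_counts():
    import dendropy

    profiles = [profile("s1", [10, 20]), profile("s2", [10])]
    t = build_mp_tree(profiles, EMPTY)
    parsed = dendropy.Tree.get(data=to_newick(t), schema="newick")
    labels = {leaf.taxon.label for leaf in parsed.leaf_node_iter()}
    assert labels == {"s1", "s2"}
    total = sum(
        e.length for e in parsed.preorder_edge_iter() if e.length is not None
    )
    assert total == parsimony_score(t) == 2
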