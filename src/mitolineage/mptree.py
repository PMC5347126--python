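"""Maximum-parsimony haplotype trees within a single haplogroup clade.

Samples are reduced to *characters*: derived mutations relative to the clade
root haplotype (gains, plus losses of root-motif variants expressed as back
mutations).  When every pair of characters is compatible — their carrier
sets nested or disjoint, the rooted analogue of the four-gamete test — the
unique perfect phylogeny is returned, with each mutation arising exactly
once.  Incompatible pairs are resolved by letting one character arise more
than once (its carrier set is split), preferring to duplicate the character
at the most mutable site: recurrent hotspots are cheap to duplicate,
near-stable positions expensive.  Small instances are solved exactly by a
bounded branch-and-bound over duplication choices; larger ones fall back to
a deterministic greedy rule.

The resulting :class:`SampleTree` — tips, internal haplotypes, and edge
mutation lists — is the substrate for the rho statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Optional, Sequence

from .classify import SiteWeights
from .variants import Variant, VariantProfile, format_variant


class ConsistencyError(ValueError):
    """A profile carries a state the clade root explicitly reverted."""


@dataclass
class SampleNode:
    name: str
    parent: Optional[str]
    mutations: tuple[Variant, ...] = ()
    children: list[str] = field(default_factory=list)
    sample_id: Optional[str] = None

    @property
    def is_tip(self) -> bool:
        return self.sample_id is not None


@dataclass
class SampleTree:
    """Mutation-labelled genealogy of samples within one clade."""

    nodes: dict[str, SampleNode]
    root: str

    @classmethod
    def from_parent_map(
        cls,
        parents: Mapping[str, Optional[str]],
        mutations: Mapping[str, Sequence[Variant]],
        tips: Mapping[str, str] | Iterable[str],
    ) -> "SampleTree":
        """Build a tree from child->parent links.

        ``tips`` maps node name -> sample id (or iterates names used as both).
        """
        tip_map = dict(tips) if isinstance(tips, Mapping) else {t: t for t in tips}
        nodes: dict[str, SampleNode] = {}
        root: Optional[str] = None
        for name, parent in parents.items():
            nodes[name] = SampleNode(
                name=name,
                parent=parent,
                mutations=tuple(mutations.get(name, ())),
                sample_id=tip_map.get(name),
            )
            if parent is None:
                root = name
        if root is None:
            raise ValueError("no root (parent None) in parent map")
        for name, node in nodes.items():
            if node.parent is not None:
                nodes[node.parent].children.append(name)
        return cls(nodes=nodes, root=root)

    def tips(self) -> list[SampleNode]:
        return [n for n in self.nodes.values() if n.is_tip]

    @property
    def n(self) -> int:
        return len(self.tips())

    def path_mutations(self, name: str) -> int:
        """Number of mutations on the root-to-node path."""
        count = 0
        node = self.nodes[name]
        while node.parent is not None:
            count += len(node.mutations)
            node = self.nodes[node.parent]
        return count

    def tips_below(self, name: str) -> int:
        node = self.nodes[name]
        own = 1 if node.is_tip else 0
        return own + sum(self.tips_below(c) for c in node.children)

    def edges(self) -> list[tuple[str, str, tuple[Variant, ...]]]:
        return [
            (n.parent, n.name, n.mutations)
            for n in self.nodes.values()
            if n.parent is not None
        ]


def parsimony_score(tree: SampleTree) -> int:
    """Total number of mutation events on the tree."""
    return sum(len(muts) for _, _, muts in tree.edges())


def characters_compatible(a: frozenset, b: frozenset) -> bool:
    """Rooted pairwise compatibility: carrier sets nested or disjoint."""
    return a.isdisjoint(b) or a <= b or b <= a


# ---------------------------------------------------------------------------
# character extraction

def _derived_characters(
    profiles: Sequence[VariantProfile], root_profile: VariantProfile
) -> tuple[dict[tuple, Variant], dict[tuple, set[str]]]:
    root_reverted = {
        v.state_key for v in root_profile.variants if v.back_mutation
    }
    root_states = {
        v.state_key: v for v in root_profile.variants if not v.back_mutation
    }
    char_variant: dict[tuple, Variant] = {}
    carriers: dict[tuple, set[str]] = {}
    for p in profiles:
        states = {v.state_key: v for v in p.variants if not v.back_mutation}
        for key, v in states.items():
            if key in root_reverted:
                raise ConsistencyError(
                    f"sample {p.sample_id} carries {format_variant(v)}, which "
                    "the clade root reverts"
                )
            if key in root_states:
                continue
            ck = ("+", key)
            char_variant.setdefault(ck, v.forward())
            carriers.setdefault(ck, set()).add(p.sample_id)
        for key, v in root_states.items():
            if key not in states and v.position not in p.excluded_sites:
                ck = ("-", key)
                char_variant.setdefault(ck, replace(v, back_mutation=True))
                carriers.setdefault(ck, set()).add(p.sample_id)
    return char_variant, carriers


# ---------------------------------------------------------------------------
# laminar resolution of incompatible characters
#
# A block is one mutation event: (character key, carrier set, inverted).
# ``inverted`` marks a reversal event — the character state flips back for
# the block's carriers — which lets the resolver express a mutation gained
# on a superset and reverted in a sub-lineage, sometimes one event cheaper
# than duplicating the gain.

Block = tuple[tuple, frozenset, bool]


def _conflicts(blocks: Sequence[Block]) -> list[tuple[int, int]]:
    out = []
    for i in range(len(blocks)):
        for j in range(i + 1, len(blocks)):
            if not characters_compatible(blocks[i][1], blocks[j][1]):
                out.append((i, j))
    return out


def _block_sort_key(b: Block):
    return (b[0], tuple(sorted(b[1])), b[2])


def _split(blocks: tuple[Block, ...], i: int, j: int) -> tuple[Block, ...]:
    """Replace block i by its intersection with and difference from block j."""
    ck, s, inv = blocks[i]
    other = blocks[j][1]
    parts = [p for p in (s & other, s - other) if p]
    new = (
        list(blocks[:i])
        + [(ck, frozenset(p), inv) for p in parts]
        + list(blocks[i + 1:])
    )
    return tuple(sorted(new, key=_block_sort_key))


def _merge_up(blocks: tuple[Block, ...], i: int, j: int) -> tuple[Block, ...]:
    """Lift block i onto the union with block j, reverting in the overhang.

    The character is gained once for ``S_i | S_j`` and reverted for
    ``S_j - S_i``, leaving its carriers unchanged at the tips.
    """
    ck, s, inv = blocks[i]
    other = blocks[j][1]
    overhang = other - s
    if not overhang:
        return tuple(sorted(blocks, key=_block_sort_key))
    new = (
        list(blocks[:i])
        + [(ck, s | other, inv), (ck, frozenset(overhang), not inv)]
        + list(blocks[i + 1:])
    )
    return tuple(sorted(new, key=_block_sort_key))

def _greedy_priority(blocks, conflicts, weight_of):
    degree: dict[int, int] = {}
    for i, j in conflicts:
        degree[i] = degree.get(i, 0) + 1
        degree[j] = degree.get(j, 0) + 1

    def prio(idx: int):
        ck = blocks[idx][0]
        return (weight_of(ck), -degree.get(idx, 0), ck[1][0], ck)

    return prio


def _resolve_greedy(
    blocks: tuple[Block, ...], weight_of: Callable[[tuple], float]
) -> tuple[Block, ...]:
    while True:
        conflicts = _conflicts(blocks)
        if not conflicts:
            return blocks
        prio = _greedy_priority(blocks, conflicts, weight_of)
        involved = sorted({i for pair in conflicts for i in pair}, key=prio)
        victim = involved[0]
        partners = sorted(
            (j for pair in conflicts for j in
             ([pair[1]] if pair[0] == victim else [pair[0]] if pair[1] == victim else [])),
            key=lambda j: _block_sort_key(blocks[j]),
        )
        blocks = _split(blocks, victim, partners[0])


def _resolve_exact(
    blocks: tuple[Block, ...],
    weight_of: Callable[[tuple], float],
    node_budget: int = 30000,
) -> Optional[tuple[Block, ...]]:
    """Bounded branch-and-bound over pairwise split choices.

    Returns the cheapest conflict-free refinement found, or ``None`` if the
    node budget is exhausted before the search completes.
    """
    best: list[Optional[tuple[Block, ...]]] = [None]
    best_cost = [float("inf")]
    seen: set[tuple[Block, ...]] = set()
    budget = [node_budget]

    def cost(bls: tuple[Block, ...]) -> float:
        return sum(weight_of(ck) for ck, _, _ in bls)

    def rec(bls: tuple[Block, ...]) -> None:
        if budget[0] <= 0:
            return
        budget[0] -= 1
        c = cost(bls)
        if c >= best_cost[0] or bls in seen:
            return
        seen.add(bls)
        conflicts = _conflicts(bls)
        if not conflicts:
            best[0], best_cost[0] = bls, c
            return
        i, j = conflicts[0]
        # either member of the pair may be duplicated (split) or lifted onto
        # the union and reverted in the overhang; try cheaper victims first
        order = sorted(
            [(i, j), (j, i)], key=lambda p: weight_of(bls[p[0]][0])
        )
        for victim, partner in order:
            rec(_split(bls, victim, partner))
        for victim, partner in order:
            rec(_merge_up(bls, victim, partner))

    rec(tuple(sorted(blocks, key=_block_sort_key)))
    return best[0]


def _resolve(blocks, weight_of, exact_char_limit: int = 16):
    conflicts = _conflicts(blocks)
    if not conflicts:
        return tuple(sorted(blocks, key=_block_sort_key))
    if len(blocks) <= exact_char_limit:
        exact = _resolve_exact(tuple(sorted(blocks, key=_block_sort_key)), weight_of)
        if exact is not None:
            return exact
    return _resolve_greedy(tuple(sorted(blocks, key=_block_sort_key)), weight_of)


# ---------------------------------------------------------------------------
# tree assembly

def build_mp_tree(
    profiles: Sequence[VariantProfile],
    root_profile: VariantProfile,
    w: Optional[SiteWeights] = None,
) -> SampleTree:
    """Build the maximum-parsimony sample genealogy of one clade.

    ``root_profile`` is the cumulative motif of the clade root; every sample
    profile must belong to the clade.  On pairwise-compatible characters the
    result is the unique perfect phylogeny.
    """
    if not profiles:
        raise ValueError("build_mp_tree requires at least one profile")
    w = w if w is not None else SiteWeights()
    char_variant, carriers = _derived_characters(profiles, root_profile)

    def weight_of(ck: tuple) -> float:
        # floor keeps zero-weight (masked) characters from being duplicated freely
        return max(w[char_variant[ck].position], 1e-3)

    blocks = tuple(
        sorted(
            ((ck, frozenset(cs), False) for ck, cs in carriers.items()),
            key=_block_sort_key,
        )
    )
    resolved = _resolve(blocks, weight_of)

    sample_ids = [p.sample_id for p in profiles]
    # group mutation events by carrier set
    by_set: dict[frozenset, list[tuple[tuple, bool]]] = {}
    for ck, cs, inv in resolved:
        by_set.setdefault(cs, []).append((ck, inv))

    sets = sorted(by_set, key=lambda s: (-len(s), tuple(sorted(s))))
    parents: dict[str, Optional[str]] = {"root": None}
    mutations: dict[str, Sequence[Variant]] = {}
    tips: dict[str, str] = {}
    set_name: dict[frozenset, str] = {}

    def containing(s: frozenset) -> str:
        """Deepest existing node whose carrier set properly contains s."""
        best_name, best_size = "root", None
        for t, name in set_name.items():
            if s < t and (best_size is None or len(t) < best_size):
                best_name, best_size = name, len(t)
        return best_name

    for idx, s in enumerate(sets):
        muts = sorted(
            (
                replace(
                    char_variant[ck],
                    back_mutation=char_variant[ck].back_mutation ^ inv,
                )
                for ck, inv in by_set[s]
            ),
            key=lambda v: (v.position, v.back_mutation, v.alt_allele),
        )
        if len(s) == 1:
            (sid,) = s
            name = f"tip_{sid}"
            tips[name] = sid
        else:
            name = f"h{idx}"
        parents[name] = containing(s)
        mutations[name] = tuple(muts)
        set_name[s] = name

    for sid in sample_ids:
        tipname = f"tip_{sid}"
        if tipname in parents:
            continue
        candidates = [s for s in set_name if sid in s]
        host = set_name[min(candidates, key=len)] if candidates else "root"
        parents[tipname] = host
        mutations[tipname] = ()
        tips[tipname] = sid

    return SampleTree.from_parent_map(parents, mutations, tips)


# ---------------------------------------------------------------------------
# export

def to_newick(tree: SampleTree) -> str:
    """Newick with edge lengths equal to mutation counts."""

    def render(name: str) -> str:
        node = tree.nodes[name]
        label = node.sample_id or node.name
        inner = ",".join(render(c) for c in sorted(node.children))
        body = f"({inner}){label}" if inner else label
        if node.parent is None:
            return body
        return f"{body}:{len(node.mutations)}"

    return render(tree.root) + ";"


def write_edge_tsv(tree: SampleTree, path) -> None:
    with open(path, "w") as fh:
        fh.write("parent\tchild\tmutations\n")
        for parent, child, muts in sorted(tree.edges()):
            toks = " ".join(format_variant(v) for v in muts)
            fh.write(f"{parent}\t{child}\t{toks}\n")
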