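"""Independent brute-force oracles used by the test suite.

These are deliberately naive implementations — exhaustive enumeration and
direct definitions — kept separate from the package so they can stand as
independent checks of its algorithms.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# exhaustive maximum parsimony: all rooted binary topologies + Fitch counting,
# with the ancestral (root) state fixed to 'absent' for every character

def rooted_topologies(taxa):
    """All rooted binary leaf-labelled topologies on ``taxa`` (nested tuples)."""
    if len(taxa) == 1:
        yield taxa[0]
        return
    for t in rooted_topologies(taxa[1:]):
        yield from _insertions(t, taxa[0])


def _insertions(tree, x):
    yield (tree, x)
    if isinstance(tree, tuple):
        left, right = tree
        for nl in _insertions(left, x):
            yield (nl, right)
        for nr in _insertions(right, x):
            yield (left, nr)


def _fitch(tree, carriers):
    if not isinstance(tree, tuple):
        return ({1 if tree in carriers else 0}, 0)
    ls, lc = _fitch(tree[0], carriers)
    rs, rc = _fitch(tree[1], carriers)
    inter = ls & rs
    if inter:
        return (inter, lc + rc)
    return (ls | rs, lc + rc + 1)


def mp_min_score(taxa, characters, weights=None):
    """Minimum (weighted) parsimony score over all topologies.

    ``characters`` is a list of carrier sets (tips carrying the derived
    state); the root state is absent.  ``weights`` gives one weight per
    character (default 1).
    """
    weights = weights if weights is not None else [1.0] * len(characters)
    best = None
    for topo in rooted_topologies(list(taxa)):
        total = 0.0
        for carriers, w in zip(characters, weights):
            states, changes = _fitch(topo, carriers)
            if 0 not in states:
                changes += 1
            total += w * changes
        if best is None or total < best:
            best = total
    return best


# ---------------------------------------------------------------------------
# random small parsimony instances: mutations down a random genealogy over a
# small site pool, with repeat hits toggling state (homoplasy)

SITE_POOL = tuple(101 + 7 * i for i in range(12))


def random_parsimony_instance(rng: np.random.Generator, mean_per_branch=1.0,
                              max_tips=6):
    """Tip character states from a random genealogy with recurrent mutation."""
    n = int(rng.integers(2, max_tips + 1))
    nodes = [f"t{i}" for i in range(n)]
    parent: dict[str, str] = {}
    k = 0
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        name = f"i{k}"
        k += 1
        parent[a] = name
        parent[b] = name
        nodes = [x for x in nodes if x not in (a, b)] + [name]
    root = nodes[0]
    children: dict[str, list[str]] = {}
    for c, p in parent.items():
        children.setdefault(p, []).append(c)
    order, stack = [], [root]
    while stack:
        cur = stack.pop()
        order.append(cur)
        stack.extend(children.get(cur, []))
    state = {root: frozenset()}
    for node in order:
        if node == root:
            continue
        s = set(state[parent[node]])
        for _ in range(rng.poisson(mean_per_branch)):
            s ^= {SITE_POOL[int(rng.integers(len(SITE_POOL)))]}
        state[node] = frozenset(s)
    tips = [x for x in order if x.startswith("t")]
    return tips, {t: state[t] for t in tips}


# ---------------------------------------------------------------------------
# naive cumulative-motif walker (path walking with explicit cancellation)

def naive_cumulative(tree, label):
    """Walk root->label, applying tokens one by one with '!'-cancellation."""
    path = []
    cur = label
    while cur is not None:
        path.append(cur)
        cur = tree.nodes[cur].parent
    acc = {}
    for node_label in reversed(path):
        for v in tree.nodes[node_label].branch_variants:
            if v.back_mutation:
                acc.pop(v.state_key, None)
            else:
                acc[v.state_key] = v
    return frozenset(acc.values())
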