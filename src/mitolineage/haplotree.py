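"""Haplogroup phylogeny: PhyloTree-style definition files and motif algebra.

A haplogroup tree is a rooted tree whose edges carry diagnostic mutations.
The *cumulative expected motif* of a haplogroup is the union of the branch
variants on its root-to-node path, with back-mutation tokens (``X!``)
cancelling the matching forward mutation acquired higher up — so a clade
"defined by the absence of" a mutation genuinely lacks it in motif space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

from .variants import Variant, VariantParseError, format_variant, parse_variant


class HaploTreeError(ValueError):
    """Raised for structurally invalid haplogroup definitions."""


@dataclass
class HaploNode:
    name: str
    parent: Optional[str]
    branch_variants: tuple[Variant, ...] = ()
    children: list[str] = field(default_factory=list)


@dataclass
class HaploTree:
    """Rooted haplogroup tree keyed by label."""

    nodes: dict[str, HaploNode]
    root_label: str
    reference: str = "chrM"

    def __contains__(self, label: str) -> bool:
        return label in self.nodes

    def node(self, label: str) -> HaploNode:
        try:
            return self.nodes[label]
        except KeyError:
            raise KeyError(f"unknown haplogroup label {label!r}") from None

    def path_to_root(self, label: str) -> list[str]:
        """Labels from ``label`` up to and including the root."""
        path = [label]
        node = self.node(label)
        while node.parent is not None:
            path.append(node.parent)
            node = self.nodes[node.parent]
        return path

    def depth(self, label: str) -> int:
        return len(self.path_to_root(label)) - 1

    def descendants(self, label: str) -> list[str]:
        """All labels strictly below ``label`` (preorder)."""
        out: list[str] = []
        stack = list(self.node(label).children)
        while stack:
            cur = stack.pop()
            out.append(cur)
            stack.extend(self.nodes[cur].children)
        return out

    def all_positions(self) -> frozenset[int]:
        """Every nucleotide position referenced anywhere in the tree."""
        return frozenset(
            v.position for n in self.nodes.values() for v in n.branch_variants
        )


def load_haplotree(source, reference: str = "chrM") -> HaploTree:
    """Load a haplogroup tree from a tab-delimited definition.

    ``source`` is a path or iterable of lines.  Each non-comment line holds
    ``label<TAB>parent<TAB>token token ...`` with ``-`` as the root's parent
    and an empty token list allowed only for the root.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with open(source) as fh:
            lines = fh.readlines()
    else:
        lines = list(source)

    nodes: dict[str, HaploNode] = {}
    root_label: Optional[str] = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise HaploTreeError(f"line {lineno}: expected label<TAB>parent")
        label = fields[0].strip()
        parent = fields[1].strip()
        token_field = fields[2].strip() if len(fields) > 2 else ""
        if not label:
            raise HaploTreeError(f"line {lineno}: empty label")
        if label in nodes:
            raise HaploTreeError(f"line {lineno}: duplicate label {label!r}")
        try:
            variants = tuple(parse_variant(t) for t in token_field.split())
        except (VariantParseError, ValueError) as exc:
            raise HaploTreeError(f"line {lineno}: {exc}") from exc
        if parent == "-":
            if root_label is not None:
                raise HaploTreeError(f"line {lineno}: second root {label!r}")
            if variants:
                raise HaploTreeError(f"line {lineno}: root must have no motif")
            root_label = label
            nodes[label] = HaploNode(label, None, ())
        else:
            nodes[label] = HaploNode(label, parent, variants)

    if root_label is None:
        raise HaploTreeError("no root line (parent '-') found")
    for node in nodes.values():
        if node.parent is not None:
            if node.parent not in nodes:
                raise HaploTreeError(
                    f"node {node.name!r} names unknown parent {node.parent!r}"
                )
            nodes[node.parent].children.append(node.name)

    tree = HaploTree(nodes=nodes, root_label=root_label, reference=reference)
    _check_acyclic_connected(tree)
    _check_back_mutations(tree)
    return tree


def load_packaged_tree(name: str = "australia_2017") -> HaploTree:
    """Load a tree shipped with the package (currently ``australia_2017``)."""
    text = resources.files("mitolineage.data").joinpath(f"{name}.tsv").read_text()
    return load_haplotree(text.splitlines(keepends=True))


def _check_acyclic_connected(tree: HaploTree) -> None:
    for label in tree.nodes:
        seen = set()
        cur: Optional[str] = label
        while cur is not None:
            if cur in seen:
                raise HaploTreeError(f"cycle through {cur!r}")
            seen.add(cur)
            cur = tree.nodes[cur].parent
        # the walk terminated at the root, so label is connected


def _check_back_mutations(tree: HaploTree) -> None:
    for label in tree.nodes:
        acquired: set = set()
        for anc in reversed(tree.path_to_root(label)):
            for v in tree.nodes[anc].branch_variants:
                if v.back_mutation:
                    if v.state_key not in acquired:
                        raise HaploTreeError(
                            f"back mutation {format_variant(v)} on branch to "
                            f"{anc!r} has no matching forward mutation above"
                        )
                    acquired.discard(v.state_key)
                else:
                    acquired.add(v.state_key)


def cumulative_expected(tree: HaploTree, label: str) -> frozenset[Variant]:
    """Net expected motif of ``label``: root-to-node union with cancellation.

    Back-mutation tokens remove the matching forward variant, so the result
    contains only forward variants the haplogroup is expected to carry.
    """
    acquired: dict[tuple, Variant] = {}
    for anc in reversed(tree.path_to_root(label)):
        for v in tree.nodes[anc].branch_variants:
            if v.back_mutation:
                acquired.pop(v.state_key, None)
            else:
                acquired[v.state_key] = v
    return frozenset(acquired.values())


def to_newick(tree: HaploTree) -> str:
    """Newick string with branch lengths equal to branch mutation counts."""

    def render(label: str) -> str:
        node = tree.nodes[label]
        inner = ",".join(render(c) for c in sorted(node.children))
        body = f"({inner}){label}" if inner else label
        if node.parent is None:
            return body
        return f"{body}:{len(node.branch_variants)}"

    return render(tree.root_label) + ";"


def motif_table(tree: HaploTree) -> dict[str, list[str]]:
    """Cumulative motifs of every node as sorted token lists (for export)."""
    return {
        label: sorted(
            (format_variant(v) for v in cumulative_expected(tree, label)),
            key=lambda s: (len(s), s),
        )
        for label in tree.nodes
    }
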