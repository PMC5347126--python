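"""Haplogroup assignment by weighted motif matching.

Each candidate haplogroup ``h`` is scored against a sample's variant profile
with a Kulczynski-style measure (the scheme used by modern mtDNA haplogroup
callers):

    K(h) = 1/2 * ( W(matched) / W(expected)  +  W(matched) / W(observed*) )

where ``expected`` is the cumulative motif of ``h``, ``matched`` the motif
variants the sample carries, and ``observed*`` the *phylogenetically
informative* part of the profile — variants at positions that occur anywhere
in the tree.  Private mutations at positions unknown to the tree describe
novel sub-lineages, not errors, and never penalise a candidate.

``W`` sums per-position site weights.  Down-weighting recurrent positions
encodes identical-by-state versus identical-by-descent caution as a soft
preference: a motif supported only by a hotspot such as np 8251 (26
independent occurrences in PhyloTree Build 17) counts far less than one
supported by a near-stable position such as np 9156.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .haplotree import HaploTree, cumulative_expected
from .reference import DEFAULT_MASK
from .variants import Variant, VariantProfile, format_variant


@dataclass(frozen=True)
class SiteWeights:
    """Per-position positive weights; unlisted positions weigh 1.0.

    A weight of 0 silences a position entirely (used for masked sites).
    """

    weights: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pos, w in self.weights.items():
            if w < 0:
                raise ValueError(f"negative weight at np {pos}")

    def __getitem__(self, position: int) -> float:
        return self.weights.get(position, 1.0)

    def total(self, variants: Iterable[Variant]) -> float:
        return sum(self[v.position] for v in variants)


def default_classification_weights(mask: Iterable[int] = DEFAULT_MASK) -> SiteWeights:
    """Reliability weights: hotspots down-weighted, masked sites silenced."""
    w = {p: 0.0 for p in mask}
    w[8251] = 0.2   # major recurrent hotspot
    w[9156] = 0.8   # mildly recurrent
    return SiteWeights(w)


@dataclass
class ClassificationResult:
    sample_id: str
    haplogroup: str
    score: float
    matched: frozenset[Variant]
    missing: frozenset[Variant]
    private: frozenset[Variant]
    runner_up: Optional[tuple[str, float]] = None
    tied: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0 + 1e-12:
            raise ValueError(f"score {self.score} outside [0, 1]")


class EmptyTreeError(ValueError):
    pass


def _score(
    expected: frozenset[Variant],
    profile_states: dict[tuple, Variant],
    informative_weight: float,
    w: SiteWeights,
) -> tuple[float, frozenset[Variant], frozenset[Variant]]:
    matched = frozenset(
        v for v in expected if v.state_key in profile_states
    )
    missing = expected - matched
    w_exp = w.total(expected)
    w_match = w.total(matched)
    term1 = w_match / w_exp if w_exp > 0 else 1.0
    term2 = w_match / informative_weight if informative_weight > 0 else 1.0
    return 0.5 * (term1 + term2), matched, missing


def rank_haplogroups(
    profile: VariantProfile,
    tree: HaploTree,
    w: Optional[SiteWeights] = None,
    k: int = 1,
) -> list[tuple[str, float]]:
    """Top-``k`` haplogroups by score, deterministic tie-breaking.

    Ties are broken towards greater path depth (the more derived clade),
    then lexicographically by label.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not tree.nodes:
        raise EmptyTreeError("cannot classify against an empty tree")
    w = w if w is not None else default_classification_weights()

    profile_states = {v.state_key: v for v in profile.variants}
    tree_positions = tree.all_positions()
    informative = [v for v in profile.variants if v.position in tree_positions]
    w_inf = w.total(informative)

    scored: list[tuple[float, int, str]] = []
    for label in tree.nodes:
        expected = cumulative_expected(tree, label)
        s, _, _ = _score(expected, profile_states, w_inf, w)
        scored.append((s, tree.depth(label), label))
    # descending score, descending depth, ascending label
    scored.sort(key=lambda t: (-round(t[0], 12), -t[1], t[2]))
    return [(label, s) for s, _, label in scored[:k]]


def classify_sample(
    profile: VariantProfile,
    tree: HaploTree,
    w: Optional[SiteWeights] = None,
) -> ClassificationResult:
    """Assign the best-fitting haplogroup and report the evidence.

    The result records the motif variants matched and missing, the sample's
    private mutations, the runner-up, and any exact score ties (reported,
    never silently resolved beyond the documented deterministic rule).
    """
    w = w if w is not None else default_classification_weights()
    ranking = rank_haplogroups(profile, tree, w, k=len(tree.nodes))
    best_label, best_score = ranking[0]

    profile_states = {v.state_key: v for v in profile.variants}
    tree_positions = tree.all_positions()
    informative = [v for v in profile.variants if v.position in tree_positions]
    expected = cumulative_expected(tree, best_label)
    _, matched, missing = _score(expected, profile_states, w.total(informative), w)
    matched_states = {v.state_key for v in matched}
    private = frozenset(
        v for v in profile.variants if v.state_key not in matched_states
    )

    tied = tuple(
        label for label, s in ranking[1:] if abs(s - best_score) < 1e-12
    )
    runner_up = ranking[1] if len(ranking) > 1 else None
    return ClassificationResult(
        sample_id=profile.sample_id,
        haplogroup=best_label,
        score=best_score,
        matched=matched,
        missing=missing,
        private=private,
        runner_up=runner_up,
        tied=tied,
    )


def _tok(variants: Iterable[Variant]) -> str:
    return " ".join(sorted(format_variant(v) for v in variants))


def write_classification_tsv(results: Sequence[ClassificationResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\thaplogroup\tscore\tmatched\tmissing\tprivate\n")
        for r in results:
            fh.write(
                f"{r.sample_id}\t{r.haplogroup}\t{r.score:.4f}\t"
                f"{_tok(r.matched)}\t{_tok(r.missing)}\t{_tok(r.private)}\n"
            )


def write_hsd(results: Sequence[ClassificationResult],
              profiles: Mapping[str, VariantProfile], path) -> None:
    """HSD-style export: sample_id, range, haplogroup, observed tokens."""
    with open(path, "w") as fh:
        for r in results:
            toks = "\t".join(profiles[r.sample_id].tokens())
            fh.write(f"{r.sample_id}\t1-16569\t{r.haplogroup}\t{toks}\n")
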