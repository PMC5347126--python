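"""Synthetic mitogenome cohorts with known genealogy and TMRCA.

Sequences descend from a founder haplotype (a haplogroup's cumulative motif
applied to the packaged reference) down a star or pure-birth (Yule)
genealogy of known depth.  Each branch of duration ``t`` years accumulates
``Poisson(mu * t)`` substitutions, where ``mu`` is the whole-genome rate
implied by the configured clock; sites are drawn proportionally to a
mutability weight table (hotspots hit more often, masked sites never), and
transitions are favoured over transversions by ``ts_tv_ratio``.  A repeat
hit at a site that already left its inherited background toggles it back,
producing realistic back mutations and identical-by-state sharing.

Everything is deterministic given the seed, and the full ground truth —
genealogy, per-branch mutation events, per-tip haplogroup and rCRS-relative
profile — is recorded so every downstream stage can be scored against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .classify import SiteWeights
from .haplotree import HaploTree, cumulative_expected, load_packaged_tree
from .reference import DEFAULT_MASK, MT_LENGTH, ReferenceGenome
from .synthetic_reference import load_reference
from .tmrca import Clock, load_clocks
from .mptree import SampleTree
from .variants import Variant, VariantKind, VariantProfile, format_variant

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G")
}

#: Per-state sample counts of the default cohort (total 127).
DEFAULT_COHORT_LABELS: dict[str, int] = {
    "Queensland": 103,
    "New South Wales": 14,
    "Victoria": 6,
    "Tasmania": 2,
    "Western Australia": 2,
}

#: Clades the default cohort draws its founders from.
DEFAULT_FOUNDERS: tuple[str, ...] = (
    "M42a", "M42a1", "M42c", "M42c1", "M42c2", "M15", "M16", "Q1",
    "S", "S1", "S2", "N13", "O",
    "P3", "P5", "P6", "P8", "P11", "P11a", "P11b", "P12", "P12a", "P12b",
)


def default_mutability_weights(mask=DEFAULT_MASK) -> SiteWeights:
    """Site mutability for simulation: hotspots hit more, masked sites never.

    The inverse of the classification reliability weights for the listed
    recurrent positions (np 8251 is a major hotspot, np 9156 near-stable).
    """
    w = {p: 0.0 for p in mask}
    w[8251] = 5.0
    w[9156] = 1.25
    return SiteWeights(w)


@dataclass
class SimConfig:
    """Study conditions for one simulated clade.

    ``true_tmrca_years`` is the genealogy depth; the default clock is the
    whole-genome evolutionary calibration (one substitution / 3,624 years).
    """

    n_tips: int = 10
    true_tmrca_years: float = 50_000.0
    topology: str = "star"  # or "yule"
    clock: Optional[Clock] = None
    site_weights: Optional[SiteWeights] = None
    ts_tv_ratio: float = 20.0
    seed: int = 0
    avoid_homoplasy: bool = False
    emit_sequences: bool = True   # False: genealogy/profiles only (faster)
    sample_ids: Optional[Sequence[str]] = None
    cohort_labels: Optional[dict[str, int]] = None

    def __post_init__(self) -> None:
        if self.n_tips < 1:
            raise ValueError("n_tips must be >= 1")
        if self.topology not in ("star", "yule"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.clock is None:
            self.clock = load_clocks()["soares_whole_mtdna"]
        if self.site_weights is None:
            self.site_weights = default_mutability_weights()
        if self.sample_ids is not None and len(self.sample_ids) != self.n_tips:
            raise ValueError("sample_ids length must equal n_tips")


@dataclass
class SimTruth:
    """Ground truth of one simulated clade."""

    genealogy: SampleTree
    founder: str
    tip_haplogroups: dict[str, str]
    tip_profiles: dict[str, VariantProfile]
    branch_events: dict[str, tuple[Variant, ...]]
    true_tmrca_years: float


def _star_genealogy(n: int, depth: float, rng) -> tuple[dict, dict, list[str]]:
    parents = {"root": None}
    durations = {}
    tips = []
    for i in range(n):
        name = f"tip{i}"
        parents[name] = "root"
        durations[name] = depth
        tips.append(name)
    return parents, durations, tips


def _yule_genealogy(n: int, depth: float, rng) -> tuple[dict, dict, list[str]]:
    """Pure-birth genealogy rescaled so every tip sits at ``depth`` years."""
    if n == 1:
        return _star_genealogy(1, depth, rng)
    # waiting times while k lineages are alive, k = 2..n; the last one is the
    # stretch from the final split to the present
    waits = [rng.exponential(1.0 / k) for k in range(2, n + 1)]
    scale = depth / sum(waits)
    times = np.cumsum([w * scale for w in waits])

    parents: dict[str, Optional[str]] = {"root": None}
    birth = {"root": 0.0}
    active = []
    counter = [0]

    def new_node(parent: str, t: float) -> str:
        counter[0] += 1
        name = f"n{counter[0]}"
        parents[name] = parent
        birth[name] = t
        return name

    active = [new_node("root", 0.0), new_node("root", 0.0)]
    for split_time in times[:-1]:
        idx = rng.integers(len(active))
        victim = active.pop(int(idx))
        active.append(new_node(victim, split_time))
        active.append(new_node(victim, split_time))
    durations = {}
    tips = []
    for name in list(parents):
        if name == "root":
            continue
        kids = [c for c, p in parents.items() if p == name]
        end = birth[kids[0]] if kids else depth
        durations[name] = end - birth[name]
        if not kids:
            tips.append(name)
    return parents, durations, tips


def simulate_cohort(
    cfg: SimConfig,
    tree: Optional[HaploTree] = None,
    founder: str = "M42c",
    reference: Optional[ReferenceGenome] = None,
) -> tuple[list[SeqRecord], SimTruth]:
    """Simulate one clade cohort; returns FASTA records and the ground truth."""
    tree = tree if tree is not None else load_packaged_tree()
    reference = reference if reference is not None else load_reference()
    if founder not in tree:
        raise KeyError(f"unknown founder haplogroup {founder!r}")
    rng = np.random.default_rng(cfg.seed)

    motif = cumulative_expected(tree, founder)
    for v in motif:
        if v.kind is not VariantKind.SUBSTITUTION:
            raise ValueError("simulator supports substitution motifs only")
    founder_state = {v.position: v.alt_allele for v in motif}

    weights = np.array(
        [cfg.site_weights[p] for p in range(1, MT_LENGTH + 1)], dtype=float
    )
    if cfg.avoid_homoplasy:
        for p in tree.all_positions():
            weights[p - 1] = 0.0
    prob = weights / weights.sum()

    if cfg.topology == "star":
        parents, durations, tip_names = _star_genealogy(
            cfg.n_tips, cfg.true_tmrca_years, rng
        )
    else:
        parents, durations, tip_names = _yule_genealogy(
            cfg.n_tips, cfg.true_tmrca_years, rng
        )

    mu = 1.0 / cfg.clock.years_per_substitution()
    p_ts = cfg.ts_tv_ratio / (cfg.ts_tv_ratio + 1.0)

    # states are deviations from the founder haplotype, keyed by np
    node_state: dict[str, dict[int, str]] = {"root": {}}
    branch_events: dict[str, list[Variant]] = {}
    used_sites: set[int] = set(founder_state)

    def background(pos: int) -> str:
        return founder_state.get(pos, reference.base_at(pos))

    order = _preorder(parents)
    for name in order:
        if name == "root":
            continue
        state = dict(node_state[parents[name]])
        events: list[Variant] = []
        m = rng.poisson(mu * durations[name])
        drawn = rng.choice(MT_LENGTH, size=m, p=prob) if m else []
        for pos0 in drawn:
            pos = int(pos0) + 1
            if cfg.avoid_homoplasy:
                while pos in used_sites:
                    pos = int(rng.choice(MT_LENGTH, p=prob)) + 1
                used_sites.add(pos)
            if pos in state:  # repeat hit: toggle back to inherited background
                del state[pos]
                new = background(pos)
            else:
                cur = background(pos)
                if rng.random() < p_ts:
                    new = _TRANSITION[cur]
                else:
                    new = _TRANSVERSIONS[cur][int(rng.integers(2))]
                state[pos] = new
            events.append(_event_variant(pos, new, reference))
        node_state[name] = state
        branch_events[name] = events

    tip_ids = list(cfg.sample_ids) if cfg.sample_ids else [
        f"SIM{i:04d}" for i in range(cfg.n_tips)
    ]
    tip_map = dict(zip(tip_names, tip_ids))

    genealogy = SampleTree.from_parent_map(
        parents,
        {name: tuple(evs) for name, evs in branch_events.items()},
        tip_map,
    )

    records: list[SeqRecord] = []
    tip_profiles: dict[str, VariantProfile] = {}
    base = list(reference.sequence)
    for name in tip_names:
        sid = tip_map[name]
        final = {
            pos: alt for pos, alt in {**founder_state, **node_state[name]}.items()
            if alt != reference.base_at(pos)
        }
        variants = frozenset(
            Variant(pos, VariantKind.SUBSTITUTION, reference.base_at(pos), alt)
            for pos, alt in final.items()
        )
        tip_profiles[sid] = VariantProfile(sample_id=sid, variants=variants)
        if cfg.emit_sequences:
            seq = list(base)
            for pos, alt in final.items():
                seq[pos - 1] = alt
            records.append(
                SeqRecord(Seq("".join(seq)), id=sid,
                          description=f"haplogroup={founder}")
            )

    truth = SimTruth(
        genealogy=genealogy,
        founder=founder,
        tip_haplogroups={sid: founder for sid in tip_ids},
        tip_profiles=tip_profiles,
        branch_events={k: tuple(v) for k, v in branch_events.items()},
        true_tmrca_years=cfg.true_tmrca_years,
    )
    return records, truth


def _event_variant(pos: int, new_base: str, reference: ReferenceGenome) -> Variant:
    ref_base = reference.base_at(pos)
    if new_base == ref_base:
        # reversion to the reference state: a back mutation in rCRS space
        return Variant(pos, VariantKind.SUBSTITUTION, ref_base,
                       _TRANSITION[ref_base], back_mutation=True)
    return Variant(pos, VariantKind.SUBSTITUTION, ref_base, new_base)


def _preorder(parents: dict[str, Optional[str]]) -> list[str]:
    children: dict[str, list[str]] = {}
    root = None
    for name, parent in parents.items():
        if parent is None:
            root = name
        else:
            children.setdefault(parent, []).append(name)
    out, stack = [], [root]
    while stack:
        cur = stack.pop()
        out.append(cur)
        stack.extend(sorted(children.get(cur, ()), reverse=True))
    return out


@dataclass
class CohortSheetRow:
    sample_id: str
    state: str
    haplogroup: str


def default_study_cohort(
    seed: int = 0,
    tree: Optional[HaploTree] = None,
    clade_tmrca_years: float = 40_000.0,
    avoid_homoplasy: bool = False,
) -> tuple[list[SeqRecord], dict[str, SimTruth], list[CohortSheetRow]]:
    """Simulate the default 127-genome cohort (103/14/6/2/2 by state).

    Founders are drawn uniformly from the packaged Australian clades; each
    founder's samples form a star clade of depth ``clade_tmrca_years``.
    Returns FASTA records, per-founder ground truths, and the sample sheet.
    """
    tree = tree if tree is not None else load_packaged_tree()
    rng = np.random.default_rng(seed)

    pairs: list[tuple[str, str]] = []  # (sample_id, state)
    i = 0
    for state, count in DEFAULT_COHORT_LABELS.items():
        code = "".join(word[0] for word in state.split()).upper()
        for _ in range(count):
            pairs.append((f"{code}{i:04d}", state))
            i += 1

    founders = [
        DEFAULT_FOUNDERS[int(k)]
        for k in rng.integers(len(DEFAULT_FOUNDERS), size=len(pairs))
    ]
    by_founder: dict[str, list[tuple[str, str]]] = {}
    for (sid, state), f in zip(pairs, founders):
        by_founder.setdefault(f, []).append((sid, state))

    records: list[SeqRecord] = []
    truths: dict[str, SimTruth] = {}
    sheet: list[CohortSheetRow] = []
    for founder in sorted(by_founder):
        group = by_founder[founder]
        cfg = SimConfig(
            n_tips=len(group),
            true_tmrca_years=clade_tmrca_years,
            topology="star",
            seed=int(rng.integers(2**31 - 1)),
            sample_ids=[sid for sid, _ in group],
            avoid_homoplasy=avoid_homoplasy,
        )
        recs, truth = simulate_cohort(cfg, tree, founder)
        records.extend(recs)
        truths[founder] = truth
        for sid, state in group:
            sheet.append(CohortSheetRow(sid, state, founder))

    order = {sid: k for k, (sid, _) in enumerate(pairs)}
    records.sort(key=lambda r: order[r.id])
    sheet.sort(key=lambda r: order[r.sample_id])
    return records, truths, sheet


def write_sample_sheet(sheet: Sequence[CohortSheetRow], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tstate\thaplogroup\n")
        for row in sheet:
            fh.write(f"{row.sample_id}\t{row.state}\t{row.haplogroup}\n")


def write_truth_json(truths: dict[str, SimTruth], path) -> None:
    payload = {
        founder: {
            "true_tmrca_years": t.true_tmrca_years,
            "tip_haplogroups": t.tip_haplogroups,
            "tip_variants": {
                sid: prof.tokens() for sid, prof in t.tip_profiles.items()
            },
            "branch_events": {
                b: [format_variant(v) for v in evs]
                for b, evs in t.branch_events.items()
            },
        }
        for founder, t in truths.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
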