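"""Rho statistic, its standard error, and clock conversion."""

import math

import numpy as np
import pytest

from mitolineage.mptree import SampleTree
from mitolineage.tmrca import (
    Clock,
    ClockConfigError,
    compute_rho,
    compute_sigma,
    estimate_clade_tmrca,
    load_clocks,
    rho_edge_form,
    rho_to_time,
)
from mitolineage.variants import Variant, VariantKind, VariantProfile
from mitolineage.haplotree import cumulative_expected


def dummy_muts(k, start=1000):
    return tuple(
        Variant(start + i, VariantKind.SUBSTITUTION, "A", "G") for i in range(k)
    )


def star_tree(distances):
    parents = {"root": None}
    muts = {}
    tips = {}
    for i, d in enumerate(distances):
        name = f"t{i}"
        parents[name] = "root"
        muts[name] = dummy_muts(d, start=1000 + 100 * i)
        tips[name] = f"s{i}"
    return SampleTree.from_parent_map(parents, muts, tips)


def caterpillar_tree():
    # root -1- A(internal) -1- tips x,y ; root -3- tip z
    parents = {"root": None, "A": "root", "x": "A", "y": "A", "z": "root"}
    muts = {
        "A": dummy_muts(1, 1000),
        "x": dummy_muts(1, 1100),
        "y": dummy_muts(1, 1200),
        "z": dummy_muts(3, 1300),
    }
    return SampleTree.from_parent_map(parents, muts, {"x": "x", "y": "y", "z": "z"})


def random_tree(rng, max_nodes=12, max_edge=4):
    n_internal = int(rng.integers(1, max_nodes))
    parents = {"root": None}
    names = ["root"]
    muts = {}
    for i in range(n_internal):
        name = f"n{i}"
        parents[name] = names[int(rng.integers(len(names)))]
        muts[name] = dummy_muts(int(rng.integers(max_edge + 1)), 1000 + 50 * i)
        names.append(name)
    tips = {}
    # every leaf-less node gets a sampled tip; some internals sampled too
    for name in names:
        is_leaf = name not in {p for p in parents.values() if p}
        if is_leaf or rng.random() < 0.3:
            tipname = f"tip_{name}"
            parents[tipname] = name
            muts[tipname] = dummy_muts(int(rng.integers(max_edge + 1)), 5000)
            tips[tipname] = tipname
    return SampleTree.from_parent_map(parents, muts, tips)


def test_rho_symmetric_star():
    assert compute_rho(star_tree([2, 2, 2])) == 2.0


def test_rho_is_arithmetic_mean_of_tip_distances():
    assert compute_rho(star_tree([1, 2, 3])) == 2.0


def test_rho_caterpillar_hand_enumeration():
    t = caterpillar_tree()
    assert compute_rho(t) == pytest.approx(7 / 3)
    assert rho_edge_form(t) == pytest.approx(7 / 3)


def test_sigma_star_closed_form():
    for n in (2, 5, 10):
        t = star_tree([1] * n)
        assert compute_sigma(t) == pytest.approx(math.sqrt(1 / n))


def test_sigma_single_tip_four_mutations():
    assert compute_sigma(star_tree([4])) == 2.0


def test_sigma_caterpillar_hand_evaluation():
    assert compute_sigma(caterpillar_tree()) == pytest.approx(1.0)


def test_path_sum_equals_edge_sum_on_random_trees():
    rng = np.random.default_rng(123)
    for _ in range(200):
        t = random_tree(rng)
        assert compute_rho(t) == pytest.approx(rho_edge_form(t))


def test_sigma_bounded_by_sqrt_total_length():
    rng = np.random.default_rng(321)
    for _ in range(50):
        t = random_tree(rng)
        total = sum(len(m) for _, _, m in t.edges())
        assert compute_sigma(t) <= math.sqrt(total) + 1e-12


def test_packaged_clock_values():
    clocks = load_clocks()
    soares = clocks["soares_whole_mtdna"]
    assert soares.years_per_substitution() == 3624.0
    fu = clocks["fu_ancient_dna"]
    # computed independently from the printed rate and genome length
    assert fu.years_per_substitution() == pytest.approx(1.0 / (2.67e-8 * 16569))


def test_rho_one_sigma_zero_under_soares_clock_is_calibration_constant():
    soares = load_clocks()["soares_whole_mtdna"]
    est = rho_to_time(1.0, 0.0, soares)
    assert est.tmrca_years == 3624.0
    assert est.ci_low_years == est.ci_high_years == 3624.0


def test_rho_zero_gives_zero_years():
    soares = load_clocks()["soares_whole_mtdna"]
    assert rho_to_time(0.0, 0.0, soares).tmrca_years == 0.0


def test_fu_clock_point_estimate():
    fu = load_clocks()["fu_ancient_dna"]
    est = rho_to_time(1.0, 0.0, fu)
    assert est.tmrca_years == pytest.approx(1.0 / (2.67e-8 * 16569))
    # rate bounds widen the interval beyond the sigma-only one
    assert est.ci_low_years == pytest.approx(1.0 / (3.16e-8 * 16569))
    assert est.ci_high_years == pytest.approx(1.0 / (2.16e-8 * 16569))


def test_tmrca_scales_linearly_in_rho_and_rate():
    c1 = Clock(name="a", mode="years_per_substitution", value=1000.0)
    c2 = Clock(name="b", mode="years_per_substitution", value=2000.0)
    e1 = rho_to_time(3.0, 1.0, c1)
    e2 = rho_to_time(6.0, 2.0, c1)
    e3 = rho_to_time(3.0, 1.0, c2)
    assert e2.tmrca_years == pytest.approx(2 * e1.tmrca_years)
    assert e3.tmrca_years == pytest.approx(2 * e1.tmrca_years)
    assert e2.ci_high_years == pytest.approx(2 * e1.ci_high_years)


def test_interval_floored_at_zero():
    c = Clock(name="a", mode="years_per_substitution", value=3624.0)
    est = rho_to_time(0.5, 2.0, c)
    assert est.ci_low_years == 0.0


def test_selection_correction_hook_defaults_to_identity():
    c = Clock(name="a", mode="years_per_substitution", value=3624.0)
    plain = rho_to_time(2.0, 0.5, c)
    corrected = rho_to_time(2.0, 0.5, c, selection_correction=lambda y: 0.9 * y)
    assert corrected.tmrca_years == pytest.approx(0.9 * plain.tmrca_years)


def test_invalid_clock_rejected():
    with pytest.raises(ClockConfigError):
        Clock(name="bad", mode="years_per_substitution", value=-1.0)
    with pytest.raises(ClockConfigError):
        Clock(name="bad", mode="nonsense", value=1.0)


def test_clade_estimate_single_sample_two_privates(tree):
    soares = load_clocks()["soares_whole_mtdna"]
    motif = cumulative_expected(tree, "M42c")
    extra = {
        Variant(5555, VariantKind.SUBSTITUTION, "", "G"),
        Variant(6666, VariantKind.SUBSTITUTION, "", "T"),
    }
    p = VariantProfile("s1", frozenset(motif | extra))
    (est,) = estimate_clade_tmrca([p], tree, "M42c", [soares],
                                  preclassified={"s1": "M42c"})
    assert est.rho == 2.0
    assert est.tmrca_years == pytest.approx(2 * 3624.0)
    assert est.n == 1


def test_clade_with_no_samples_yields_empty_result(tree):
    soares = load_clocks()["soares_whole_mtdna"]
    assert estimate_clade_tmrca([], tree, "M42c", [soares]) == []
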