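"""Variant calling against the packaged reference."""

import numpy as np
import pytest

from mitolineage.calling import (
    AlignmentBandError,
    SampleLengthError,
    call_variants,
    rotate_to_reference,
)
from mitolineage.reference import DEFAULT_MASK
from mitolineage.variants import (
    Variant,
    VariantKind,
    VariantProfile,
    apply_profile,
    format_variant,
)


def test_reference_calls_empty_profile(reference):
    profile = call_variants(reference.sequence, reference)
    assert len(profile) == 0
    assert profile.excluded_sites == frozenset(DEFAULT_MASK)


def test_single_known_substitution(reference):
    seq = list(reference.sequence)
    seq[9156 - 1] = "G"
    profile = call_variants("".join(seq), reference)
    assert profile.tokens() == ["A9156G"]


def test_injected_substitutions_recovered_exactly(reference):
    """Injection oracle: the generator records edits before calling."""
    rng = np.random.default_rng(42)
    seq = list(reference.sequence)
    injected = set()
    positions = rng.choice(reference.length, size=10, replace=False) + 1
    for pos in positions:
        pos = int(pos)
        if pos in DEFAULT_MASK:
            continue
        ref_base = reference.base_at(pos)
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref_base]
        seq[pos - 1] = alt
        injected.add(f"{ref_base}{pos}{alt}")
    profile = call_variants("".join(seq), reference)
    assert set(profile.tokens()) == injected


def test_n_bases_produce_no_calls(reference):
    seq = list(reference.sequence)
    seq[499] = "N"
    seq[599] = "N"
    profile = call_variants("".join(seq), reference)
    assert len(profile) == 0


def test_masked_positions_suppressed_but_recorded(reference):
    seq = list(reference.sequence)
    seq[16519 - 1] = "C" if reference.base_at(16519) != "C" else "A"
    profile = call_variants("".join(seq), reference)
    assert len(profile) == 0
    assert 16519 in profile.excluded_sites


def test_length_tolerance_enforced(reference):
    with pytest.raises(SampleLengthError):
        call_variants(reference.sequence[:16000], reference)


def test_band_exceeded_suggests_larger_band(reference):
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))
    scrambled = "".join(rng.choice(bases, size=reference.length))
    with pytest.raises(AlignmentBandError, match="larger band"):
        call_variants(scrambled, reference, band=50)


def test_deletion_called_and_placed_3prime(reference):
    seq = list(reference.sequence)
    del seq[999]  # delete np 1000
    profile = call_variants("".join(seq), reference, mask=None)
    assert len(profile) == 1
    (v,) = profile.variants
    assert v.kind is VariantKind.DELETION
    # 3'-most placement: the reported position cannot be followed by an
    # identical reference base
    assert reference.base_at(v.position) != reference.sequence[v.position]


def test_insertion_called_with_index(reference):
    seq = reference.sequence[:2000] + "A" + reference.sequence[2000:]
    profile = call_variants(seq, reference, mask=None)
    kinds = {v.kind for v in profile.variants}
    assert kinds == {VariantKind.INSERTION}
    assert all(v.insertion_index == 1 for v in profile.variants)


def test_indel_canonicalisation_same_profile_for_equivalent_alignments(reference):
    """Deleting either copy of a duplicated base yields the same call."""
    # find a position with ref[i] == ref[i+1]
    pos = next(
        i for i in range(1000, 2000)
        if reference.sequence[i] == reference.sequence[i + 1]
    )
    a = list(reference.sequence)
    del a[pos]
    b = list(reference.sequence)
    del b[pos + 1]
    pa = call_variants("".join(a), reference, mask=None)
    pb = call_variants("".join(b), reference, mask=None)
    assert pa.tokens() == pb.tokens()


def test_call_apply_round_trip_random_profiles(reference):
    """call(apply(P)) == P for random substitution profiles off-mask."""
    rng = np.random.default_rng(2024)
    for _ in range(5):
        positions = rng.choice(reference.length, size=25, replace=False) + 1
        variants = set()
        for pos in positions:
            pos = int(pos)
            if pos in DEFAULT_MASK:
                continue
            ref_base = reference.base_at(pos)
            alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref_base]
            variants.add(Variant(pos, VariantKind.SUBSTITUTION, ref_base, alt))
        profile = VariantProfile("rt", frozenset(variants))
        called = call_variants(apply_profile(profile, reference), reference,
                               sample_id="rt")
        assert called.variants == profile.variants


def test_rotation_pre_step_recovers_in_phase_sequence(reference):
    rotated = reference.sequence[5000:] + reference.sequence[:5000]
    fixed = rotate_to_reference(rotated, reference)
    assert fixed == reference.sequence
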