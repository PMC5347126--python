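"""Variant calling: whole mitogenomes against the rCRS coordinate frame.

Sequences are aligned globally to the reference with an exact unit-cost
aligner (edlib) capped at a configurable edit-distance band; mitogenomes are
near-identical to the reference, so the optimal alignment is unambiguous in
practice.  Differences are reported as :class:`~mitolineage.variants.Variant`
records with indels normalised to their 3'-most equivalent placement, the
convention used by mtDNA phylogenetic nomenclature.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import edlib

from .reference import DEFAULT_MASK, ReferenceGenome, VALID_BASES
from .variants import Variant, VariantKind, VariantProfile, format_variant

logger = logging.getLogger(__name__)

DEFAULT_BAND = 200


class SampleLengthError(ValueError):
    """Sample length too different from the reference to be a mitogenome."""


class AlignmentBandError(RuntimeError):
    """Optimal alignment exceeds the configured band."""


def call_variants(
    sample: str,
    reference: ReferenceGenome,
    *,
    sample_id: str = "sample",
    mask: Optional[Iterable[int]] = DEFAULT_MASK,
    length_tolerance: int = 100,
    band: int = DEFAULT_BAND,
) -> VariantProfile:
    """Call rCRS-relative variants for one whole-mitogenome sequence.

    Parameters
    ----------
    sample
        Nucleotide sequence over ``A,C,G,T,N`` (case-insensitive).
    mask
        Positions excluded from calling; they are recorded in the profile's
        ``excluded_sites`` instead.  Pass ``None``/empty for no masking.
    length_tolerance
        Maximum absolute length difference from the reference (bases).
    band
        Maximum allowed edit distance; exceeding it raises
        :class:`AlignmentBandError` suggesting a larger band.
    """
    seq = sample.strip().upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"sample {sample_id}: invalid characters {sorted(bad)}")
    if abs(len(seq) - reference.length) > length_tolerance:
        raise SampleLengthError(
            f"sample {sample_id}: length {len(seq)} outside "
            f"{reference.length}±{length_tolerance}"
        )

    masked = frozenset(p for p in (mask or ()) if 1 <= p <= reference.length)
    if masked:
        logger.debug("sample %s: masking %d sites", sample_id, len(masked))

    result = edlib.align(seq, reference.sequence, mode="NW", task="path", k=band)
    if result["editDistance"] < 0:
        raise AlignmentBandError(
            f"sample {sample_id}: alignment exceeds band {band}; "
            "retry with a larger band"
        )

    variants = _cigar_to_variants(result["cigar"], seq, reference, masked)
    return VariantProfile(sample_id=sample_id, variants=frozenset(variants),
                          excluded_sites=masked)


def _cigar_to_variants(
    cigar: str, query: str, reference: ReferenceGenome, masked: frozenset[int]
) -> list[Variant]:
    ref = reference.sequence
    qpos = 0          # 0-based index into query
    rpos = 0          # 0-based index into reference
    variants: list[Variant] = []
    # (ref_start_0based, deleted_bases) / (ref_pos_after_which, inserted_bases)
    for length, op in _iter_cigar(cigar):
        if op == "=":
            qpos += length
            rpos += length
        elif op == "X":
            for i in range(length):
                p = rpos + i + 1
                alt = query[qpos + i]
                if alt == "N" or p in masked:
                    continue
                variants.append(
                    Variant(p, VariantKind.SUBSTITUTION, ref[p - 1], alt)
                )
            qpos += length
            rpos += length
        elif op == "D":  # present in reference, absent in sample: deletion
            start = _shift_deletion_3prime(ref, rpos, length)
            for i in range(length):
                p = start + i + 1
                if p in masked:
                    continue
                variants.append(Variant(p, VariantKind.DELETION, ref[p - 1], ""))
            rpos += length
        elif op == "I":  # present in sample only: insertion after ref position
            bases = query[qpos:qpos + length]
            anchor, bases = _shift_insertion_3prime(ref, rpos, bases)
            if anchor == 0:
                # leading insertion on a circular molecule: anchor after the
                # final position instead
                anchor = reference.length if reference.circular else 1
            if anchor not in masked:
                for i, b in enumerate(bases, start=1):
                    if b == "N":
                        continue
                    variants.append(
                        Variant(anchor, VariantKind.INSERTION, "", b,
                                insertion_index=i)
                    )
            qpos += length
        else:  # pragma: no cover
            raise ValueError(f"unexpected CIGAR op {op!r}")
    return variants


def _iter_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def _shift_deletion_3prime(ref: str, start0: int, length: int) -> int:
    """Slide a deletion window right while the alignment stays equivalent."""
    s = start0
    while s + length < len(ref) and ref[s] == ref[s + length]:
        s += 1
    return s


def _shift_insertion_3prime(ref: str, anchor0: int, bases: str) -> tuple[int, str]:
    """Slide an insertion right while its first base matches the next ref base.

    Returns the 1-based reference position after which the insertion sits,
    together with the (rotated) inserted bases.
    """
    anchor = anchor0  # insertion sits after ref[anchor-1], i.e. before ref[anchor0]
    b = bases
    while anchor < len(ref) and b and ref[anchor] == b[0]:
        b = b[1:] + b[0]
        anchor += 1
    return anchor, b


def rotate_to_reference(sample: str, reference: ReferenceGenome,
                        seed_length: int = 30) -> str:
    """Optional pre-step for circular inputs: rotate so the sample starts
    where the reference starts.

    Finds the best match of the reference's leading ``seed_length``-mer in the
    doubled sample and rotates the sample to begin there.  A no-op when the
    sample already starts in phase.
    """
    seq = sample.strip().upper()
    seed = reference.sequence[:seed_length]
    doubled = seq + seq
    hit = edlib.align(seed, doubled, mode="HW", task="locations")
    if hit["editDistance"] < 0 or not hit["locations"]:
        return seq
    start = hit["locations"][0][0] % len(seq)
    return seq[start:] + seq[:start]


def write_profiles_tsv(profiles: Sequence[VariantProfile], path) -> None:
    """Write per-sample variant lists (sample_id, space-joined tokens)."""
    with open(path, "w") as fh:
        fh.write("sample_id\tvariants\n")
        for p in profiles:
            fh.write(f"{p.sample_id}\t{' '.join(p.tokens())}\n")


def write_profiles_vcf(profiles: Sequence[VariantProfile],
                       reference: ReferenceGenome, path) -> None:
    """Write substitution/deletion/insertion calls as a minimal multi-sample VCF."""
    samples = [p.sample_id for p in profiles]
    carriers: dict[tuple, set[str]] = {}
    records: dict[tuple, Variant] = {}
    for p in profiles:
        for v in p.variants:
            carriers.setdefault(v.state_key, set()).add(p.sample_id)
            records.setdefault(v.state_key, v)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID=chrM,length={reference.length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for key in sorted(records, key=lambda k: (k[0], k[1], k[2] or 0)):
            v = records[key]
            pos, ref_f, alt_f = _vcf_alleles(v, reference)
            gts = "\t".join(
                "1" if s in carriers[key] else "0" for s in samples
            )
            fh.write(f"chrM\t{pos}\t{format_variant(v)}\t{ref_f}\t{alt_f}\t.\t.\t.\tGT\t{gts}\n")


def _vcf_alleles(v: Variant, reference: ReferenceGenome) -> tuple[int, str, str]:
    if v.kind is VariantKind.SUBSTITUTION:
        return v.position, reference.base_at(v.position), v.alt_allele
    if v.kind is VariantKind.DELETION:
        p = max(v.position - 1, 1)
        return p, reference.base_at(p) + reference.base_at(v.position), reference.base_at(p)
    anchor = reference.base_at(v.position)
    return v.position, anchor, anchor + v.alt_allele
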