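"""mtDNA variant nomenclature: parsing, formatting, and profile application.

Variants are expressed relative to the rCRS coordinate frame in the compact
notation used throughout mitochondrial phylogenetics:

=============  ==========================================================
``A9156G``     substitution: reference A at np 9156 replaced by G
``9156G``      same, reference allele implied by the reference genome
``315.1C``     insertion of C after np 315 (first inserted base)
``249d``       deletion of the base at np 249
``G8251A!``    back mutation: the derived 8251A state reverts to reference
=============  ==========================================================

The trailing ``!`` is meaningful only inside haplogroup definitions, where
it cancels a forward mutation acquired higher up the tree.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional

from .reference import MT_LENGTH, ReferenceGenome


class VariantKind(str, Enum):
    SUBSTITUTION = "substitution"
    INSERTION = "insertion"
    DELETION = "deletion"


class VariantParseError(ValueError):
    """Raised for a malformed variant token; carries the offending token."""

    def __init__(self, token: str, reason: str = "malformed token"):
        self.token = token
        super().__init__(f"{reason}: {token!r}")


class PositionRangeError(ValueError):
    """Raised when a variant position falls outside the reference frame."""


@dataclass(frozen=True)
class Variant:
    """One rCRS-relative mutation event.

    ``insertion_index`` is the ``.1``/``.2`` suffix of insertion tokens
    (first, second... base inserted after ``position``).  ``back_mutation``
    flags reversion tokens (``...!``) inside haplogroup definitions.
    """

    position: int
    kind: VariantKind
    ref_allele: str = ""
    alt_allele: str = ""
    insertion_index: Optional[int] = None
    back_mutation: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.position <= MT_LENGTH:
            raise PositionRangeError(
                f"np {self.position} outside [1, {MT_LENGTH}]"
            )
        if self.kind is VariantKind.SUBSTITUTION:
            if len(self.alt_allele) != 1 or len(self.ref_allele) > 1:
                raise ValueError(f"bad substitution alleles: {self!r}")
            if self.ref_allele and self.ref_allele == self.alt_allele:
                raise ValueError(f"substitution with identical alleles: {self!r}")
        elif self.kind is VariantKind.INSERTION:
            if not self.alt_allele or (self.insertion_index or 0) < 1:
                raise ValueError(f"insertion needs alt allele and index >= 1: {self!r}")
        elif self.kind is VariantKind.DELETION:
            if self.alt_allele:
                raise ValueError(f"deletion must have empty alt allele: {self!r}")

    @property
    def site_key(self) -> tuple[int, str, Optional[int]]:
        """Identity of the mutated site: (position, kind, insertion index)."""
        return (self.position, self.kind.value, self.insertion_index)

    @property
    def state_key(self) -> tuple[int, str, Optional[int], str]:
        """Identity of the derived state (ignores the back-mutation flag)."""
        return (self.position, self.kind.value, self.insertion_index, self.alt_allele)

    def forward(self) -> "Variant":
        """The same variant without the back-mutation flag."""
        return replace(self, back_mutation=False) if self.back_mutation else self

    def __str__(self) -> str:  # pragma: no cover - delegates
        return format_variant(self)


_SUB_RE = re.compile(r"^(?:([ACGTN]))?(\d+)([ACGTN])(!?)$")
_INS_RE = re.compile(r"^(\d+)\.(\d+)([ACGTN]+)(!?)$")
_DEL_RE = re.compile(r"^(\d+)(?:-(\d+))?d(!?)$", re.IGNORECASE)


def parse_variant(token: str, reference: Optional[ReferenceGenome] = None) -> Variant:
    """Parse one nomenclature token into a :class:`Variant`.

    Accepts the ``RefPosAlt`` (``A9156G``), ``PosAlt`` (``9156G``),
    insertion (``315.1C``) and deletion (``249d``) dialects, each with an
    optional trailing ``!``.  For ``PosAlt`` tokens the reference allele is
    filled in from ``reference`` when one is supplied.
    """
    if not token:
        raise VariantParseError(token, "empty token")
    t = token.strip().upper()

    m = _SUB_RE.match(t)
    if m:
        ref, pos, alt, bang = m.group(1) or "", int(m.group(2)), m.group(3), m.group(4)
        _check_range(pos, token)
        if not ref and reference is not None:
            ref = reference.base_at(pos)
        if ref and reference is not None and reference.base_at(pos) != ref:
            raise VariantParseError(
                token, f"reference allele mismatch at np {pos} "
                f"(reference has {reference.base_at(pos)})"
            )
        if ref == alt:
            raise VariantParseError(token, "substitution with identical alleles")
        return Variant(pos, VariantKind.SUBSTITUTION, ref, alt,
                       back_mutation=bool(bang))

    m = _INS_RE.match(t)
    if m:
        pos, idx, bases, bang = int(m.group(1)), int(m.group(2)), m.group(3), m.group(4)
        _check_range(pos, token)
        if idx < 1:
            raise VariantParseError(token, "insertion index must be >= 1")
        return Variant(pos, VariantKind.INSERTION, "", bases, insertion_index=idx,
                       back_mutation=bool(bang))

    m = _DEL_RE.match(t)
    if m:
        if m.group(2) is not None:
            raise VariantParseError(
                token, "range deletions must be given per-position"
            )
        pos, bang = int(m.group(1)), m.group(3)
        _check_range(pos, token)
        ref = reference.base_at(pos) if reference is not None else ""
        return Variant(pos, VariantKind.DELETION, ref, "", back_mutation=bool(bang))

    raise VariantParseError(token)


def _check_range(pos: int, token: str) -> None:
    if not 1 <= pos <= MT_LENGTH:
        raise PositionRangeError(f"np {pos} outside [1, {MT_LENGTH}] in {token!r}")


def format_variant(v: Variant) -> str:
    """Canonical token for a variant; inverse of :func:`parse_variant`."""
    bang = "!" if v.back_mutation else ""
    if v.kind is VariantKind.SUBSTITUTION:
        return f"{v.ref_allele}{v.position}{v.alt_allele}{bang}"
    if v.kind is VariantKind.INSERTION:
        return f"{v.position}.{v.insertion_index}{v.alt_allele}{bang}"
    return f"{v.position}d{bang}"


@dataclass
class VariantProfile:
    """A sample's full set of rCRS-relative variants.

    ``excluded_sites`` records positions that were masked during calling and
    therefore carry no information either way.
    """

    sample_id: str
    variants: frozenset[Variant] = frozenset()
    excluded_sites: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        self.variants = frozenset(self.variants)
        self.excluded_sites = frozenset(self.excluded_sites)
        seen: set[tuple] = set()
        for v in self.variants:
            if v.site_key in seen:
                raise ValueError(
                    f"profile {self.sample_id}: duplicate variant at site {v.site_key}"
                )
            seen.add(v.site_key)

    def tokens(self) -> list[str]:
        """Sorted canonical tokens (by position, then kind/index)."""
        return [format_variant(v) for v in sorted(
            self.variants,
            key=lambda v: (v.position, v.kind.value, v.insertion_index or 0),
        )]

    def __len__(self) -> int:
        return len(self.variants)


def apply_profile(profile: VariantProfile | Iterable[Variant],
                  reference: ReferenceGenome) -> str:
    """Materialise the sequence carrying a profile's variants.

    Substitutions must agree with the reference allele when one is recorded;
    deletions remove the base at their position; insertions are inserted
    after their position in ``insertion_index`` order.
    """
    variants = profile.variants if isinstance(profile, VariantProfile) else profile
    subs: dict[int, str] = {}
    dels: set[int] = set()
    ins: dict[int, list[tuple[int, str]]] = {}
    for v in variants:
        if v.back_mutation:
            continue
        if v.kind is VariantKind.SUBSTITUTION:
            if v.ref_allele and reference.base_at(v.position) != v.ref_allele:
                raise ValueError(
                    f"cannot apply {format_variant(v)}: reference has "
                    f"{reference.base_at(v.position)} at np {v.position}"
                )
            subs[v.position] = v.alt_allele
        elif v.kind is VariantKind.DELETION:
            dels.add(v.position)
        else:
            ins.setdefault(v.position, []).append((v.insertion_index or 1, v.alt_allele))

    out: list[str] = []
    for pos in range(1, reference.length + 1):
        if pos in dels:
            pass
        elif pos in subs:
            out.append(subs[pos])
        else:
            out.append(reference.sequence[pos - 1])
        if pos in ins:
            for _, bases in sorted(ins[pos]):
                out.append(bases)
    # insertions "after np 0" are not representable; circular convention puts
    # them after the last position, which the loop above already covers
    return "".join(out)
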