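"""Reference genome model for human mtDNA.

All coordinates in this package are 1-based nucleotide positions ("np") on a
16,569-bp circular mitochondrial reference, the coordinate frame in which
mtDNA variants are conventionally reported (e.g. ``A9156G`` means the
reference carries A at np 9156 and the sample carries G).
"""

from __future__ import annotations

from dataclasses import dataclass, field

MT_LENGTH = 16569
"""Length in bases of the standard human mitochondrial reference frame."""

VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class ReferenceGenome:
    """A named reference sequence providing the variant coordinate frame.

    Parameters
    ----------
    name
        Identifier of the reference (e.g. ``"chrM"``).
    sequence
        Upper-case nucleotide string over ``A,C,G,T,N``.
    circular
        Whether the molecule is circular (true for mtDNA).
    """

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"reference contains invalid characters: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base_at(self, position: int) -> str:
        """Return the reference base at a 1-based position."""
        if not 1 <= position <= self.length:
            raise IndexError(f"position {position} outside [1, {self.length}]")
        return self.sequence[position - 1]


# Positions conventionally masked in whole-mitogenome phylogenetics: the two
# control-region C-tracts (length heteroplasmy) and the hypermutable 16519.
DEFAULT_MASK: frozenset[int] = frozenset(
    set(range(303, 316)) | set(range(16183, 16195)) | {16519}
)
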