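"""SYNTHETIC stand-in for the revised Cambridge Reference Sequence (rCRS).

The real rCRS (GenBank NC_012920.1) is not redistributed with this package.
Instead :func:`load_reference` builds a deterministic synthetic mitogenome
that shares the rCRS's structural properties:

* exactly 16,569 bp, circular, alphabet ``A/C/G/T``;
* the reference allele at every nucleotide position used by the packaged
  haplogroup tree is pinned to the token's reference base (so ``A9156G``
  really finds an A at np 9156);
* the conventionally masked control-region C-tracts (303-315, 16183-16194)
  are poly-C runs, and np 16519 is pinned, so default masking behaves as it
  does on real data.

Everything downstream (variant nomenclature, classification, parsimony
trees, rho/TMRCA) operates purely on the 1-based coordinate frame and is
unchanged by the substitution of this synthetic sequence for the real rCRS;
only the literal background bases differ.
"""

from __future__ import annotations

import re
from functools import lru_cache
from importlib import resources

import numpy as np

from .reference import MT_LENGTH, ReferenceGenome

_TOKEN_RE = re.compile(r"^([ACGT])(\d+)([ACGT])!?$")

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _pinned_alleles() -> dict[int, str]:
    """Reference alleles implied by the packaged haplogroup definition file."""
    pins: dict[int, str] = {}
    text = (
        resources.files("mitolineage.data").joinpath("australia_2017.tsv").read_text()
    )
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            continue
        for token in fields[2].split():
            m = _TOKEN_RE.match(token)
            if m is None:
                continue
            ref, pos = m.group(1), int(m.group(2))
            prev = pins.setdefault(pos, ref)
            if prev != ref:
                raise ValueError(
                    f"conflicting reference alleles pinned at np {pos}: {prev}/{ref}"
                )
    return pins


@lru_cache(maxsize=1)
def load_reference() -> ReferenceGenome:
    """Return the packaged synthetic rCRS stand-in (cached, deterministic)."""
    rng = np.random.default_rng(16569)
    seq = rng.choice(_BASES, size=MT_LENGTH)
    # control-region C-tracts and the hypermutable 16519, as on the real rCRS
    seq[302:315] = b"C"
    seq[16182:16194] = b"C"
    seq[16518] = b"T"
    for pos, base in _pinned_alleles().items():
        seq[pos - 1] = base.encode()
    return ReferenceGenome(name="chrM", sequence=seq.tobytes().decode(), circular=True)
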