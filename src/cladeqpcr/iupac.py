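"""IUPAC nucleotide alphabet utilities.

Primer–template comparisons throughout the package use set semantics: two
IUPAC codes are *compatible* when the sets of standard bases they denote
intersect. A position with an empty intersection counts as one mismatch.
"""

from __future__ import annotations

import numpy as np

# Code -> set of standard bases it denotes.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B", "N": "N",
}

# 4-bit encoding (A=1, C=2, G=4, T=8); compatibility is a nonzero bitwise AND.
_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
IUPAC_BITS: dict[str, int] = {
    code: sum(_BIT[b] for b in bases) for code, bases in IUPAC_SETS.items()
}

_ENCODE = np.zeros(256, dtype=np.uint8)
for _code, _bits in IUPAC_BITS.items():
    _ENCODE[ord(_code)] = _bits


def normalize(seq: str) -> str:
    """Upper-case and map U→T; raise on characters outside the IUPAC alphabet."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - set(IUPAC_SETS)
    if bad:
        raise ValueError(f"non-IUPAC nucleotide characters: {sorted(bad)!r}")
    return s


def encode(seq: str) -> np.ndarray:
    """Encode a normalized sequence as a 4-bit uint8 array."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE[arr]
    if (codes == 0).any():
        bad = sorted({seq[i] for i in np.nonzero(codes == 0)[0]})
        raise ValueError(f"non-IUPAC nucleotide characters: {bad!r}")
    return codes


def reverse_complement(seq: str) -> str:
    try:
        return "".join(IUPAC_COMPLEMENT[c] for c in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"non-IUPAC nucleotide character: {exc.args[0]!r}") from None


def base_compatible(primer_char: str, template_char: str) -> bool:
    """True iff the IUPAC sets of the two codes intersect."""
    p = primer_char.upper()
    t = template_char.upper()
    if p not in IUPAC_SETS or t not in IUPAC_SETS:
        bad = p if p not in IUPAC_SETS else t
        raise ValueError(f"non-IUPAC nucleotide character: {bad!r}")
    return bool(IUPAC_SETS[p] & IUPAC_SETS[t])
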