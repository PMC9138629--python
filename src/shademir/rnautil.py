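"""Small RNA-alphabet helpers shared across the package.

All internal sequence handling is uppercase RNA ({A, C, G, U}); DNA input
is transliterated at ingest (T -> U).
"""

from __future__ import annotations

RNA_BASES = "ACGU"
GAP = "-"

# Watson-Crick pairs plus the G:U wobble tolerated in plant miRNA duplexes.
_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}

# Simplified per-pair stacking-free energies (kcal/mol) used consistently by
# the hairpin filter and the duplex energy descriptors.
PAIR_ENERGY = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


class AlphabetError(ValueError):
    """Sequence contains characters outside the RNA alphabet."""


def to_rna(seq: str) -> str:
    """Uppercase and transliterate T -> U; validate the alphabet."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - set(RNA_BASES)
    if bad:
        raise AlphabetError(f"non-RNA characters {sorted(bad)!r} in sequence")
    return s


def is_wc(a: str, b: str) -> bool:
    return (a, b) in _WC


def is_wobble(a: str, b: str) -> bool:
    return (a, b) in _WOBBLE


def is_paired(a: str, b: str) -> bool:
    return (a, b) in _WC or (a, b) in _WOBBLE


def pair_energy(a: str, b: str) -> float:
    """Energy of a base pair; 0.0 for a non-pairing combination."""
    return PAIR_ENERGY.get((a, b), 0.0)


def complement(base: str) -> str:
    return _COMPLEMENT[base]


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))
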