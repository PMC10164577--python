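"""Small sequence and geometry helpers."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# Average helical rise of B-form duplex DNA, angstroms per base pair.
BDNA_RISE_A_PER_BP = 3.3


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def duplex_length_bp(length_angstrom: float, rise: float = BDNA_RISE_A_PER_BP) -> float:
    """Convert a physical length along a B-DNA duplex axis to base pairs.

    A ~145 A helix spans ~44 bp at the canonical 3.3 A/bp rise; used to relate
    protein-domain dimensions to the DNA footprint they can cover.
    """
    if length_angstrom < 0:
        raise ValueError("length must be nonnegative")
    if rise <= 0:
        raise ValueError("rise must be positive")
    return length_angstrom / rise


def duplex_length_angstrom(n_bp: float, rise: float = BDNA_RISE_A_PER_BP) -> float:
    """Inverse of :func:`duplex_length_bp`."""
    if n_bp < 0:
        raise ValueError("base-pair count must be nonnegative")
    return n_bp * rise


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x != y for x, y in zip(a, b))
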