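"""Small DNA string helpers shared across modules."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

DNA_ALPHABET = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_dna(seq: str) -> bool:
    """True iff ``seq`` is non-empty and contains only uppercase A/C/G/T."""
    return bool(seq) and set(seq) <= DNA_ALPHABET


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def stop_positions(seq: str, frame_offset: int = 0) -> list[int]:
    """0-based start positions of stop codons read in the frame whose codons
    begin at positions congruent to ``frame_offset`` (mod 3)."""
    start = frame_offset % 3
    return [
        i for i in range(start, len(seq) - 2, 3) if seq[i : i + 3] in STOP_CODONS
    ]
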