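"""Small DNA string helpers shared across modules.

Internal coordinates are 0-based, half-open everywhere in this package;
conversion to 1-based inclusive happens only at the GFF3/report boundary.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGTN")
BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_palindrome(seq: str) -> bool:
    """True if ``seq`` equals its own reverse complement.

    Only even-length sequences over {A,C,G,T} can satisfy this; an N
    anywhere makes the test fail because N is never a complement match.
    """
    if len(seq) % 2 or "N" in seq:
        return False
    return seq == revcomp(seq)


def validate_dna(seq: str, *, allow_n: bool = True) -> None:
    """Raise ValueError naming the first illegal character position."""
    allowed = DNA_ALPHABET if allow_n else frozenset("ACGT")
    for i, ch in enumerate(seq):
        if ch not in allowed:
            raise ValueError(f"illegal character {ch!r} at position {i}")
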