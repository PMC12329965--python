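"""Small DNA helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANTGCAN")

# A=0, C=1, G=2, T=3; anything else maps to 255
CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    CODE[ord(_b)] = _i
    CODE[ord(_b.lower())] = _i

DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved as upper)."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """2-bit codes (uint8) for an ACGT string; raises on other characters."""
    codes = CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.size and codes.max() > 3:
        bad = int(np.argmax(codes > 3))
        raise ValueError(f"non-ACGT character {seq[bad]!r} at position {bad}")
    return codes


def decode(codes: np.ndarray) -> str:
    return DECODE[codes].tobytes().decode("ascii")
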