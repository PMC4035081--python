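"""Byte-level DNA helpers shared by the simulator and the toy mapper.

Sequences travel through the numerical code as uint8 arrays of ASCII codes;
2-bit base codes (A=0 C=1 G=2 T=3, anything else=4) are used for k-mer
hashing and mismatch counting.
"""
from __future__ import annotations

import numpy as np

#: ASCII codes of the four bases, indexable by 2-bit code.
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase

_COMP = np.arange(256, dtype=np.uint8)
for _x, _y in zip(b"ACGTNacgtn", b"TGCANtgcan"):
    _COMP[_x] = _y

#: complement in 2-bit code space; the invalid code 4 maps to itself.
CODE_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 ASCII array."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def decode(arr: np.ndarray) -> str:
    """uint8 ASCII array -> DNA string."""
    return arr.tobytes().decode("ascii")


def to_codes(ascii_arr: np.ndarray) -> np.ndarray:
    """ASCII bytes -> 2-bit codes (4 marks non-ACGT)."""
    return _CODE[ascii_arr]


def from_codes(codes: np.ndarray) -> np.ndarray:
    """2-bit codes -> ASCII bytes; invalid codes become 'N'."""
    out = np.where(codes > 3, np.uint8(ord("N")), BASES[np.minimum(codes, 3)])
    return out.astype(np.uint8)


def revcomp(ascii_arr: np.ndarray) -> np.ndarray:
    """Reverse complement of an ASCII byte array (last axis)."""
    return _COMP[ascii_arr][..., ::-1]


def revcomp_str(seq: str) -> str:
    return decode(revcomp(encode(seq)))


def random_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    """n uniform 2-bit base codes."""
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def mutate_codes(rng: np.random.Generator, codes: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each base with probability ``rate``; substitutions always
    change the base. Invalid codes (4) are left untouched."""
    if rate <= 0:
        return codes
    out = codes.copy()
    mask = (rng.random(codes.shape) < rate) & (codes < 4)
    n_mut = int(mask.sum())
    if n_mut:
        shift = rng.integers(1, 4, size=n_mut, dtype=np.uint8)
        out[mask] = (out[mask] + shift) % 4
    return out
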