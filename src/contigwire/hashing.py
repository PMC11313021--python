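"""Fixed 64-bit hashing and k-mer encoding primitives.

All sketching in :mod:`contigwire.sketch_mapper` goes through the splitmix64
finalizer below with constants committed here, so sketches are reproducible
across platforms and Python versions (no dependence on builtin ``hash``).
"""

from __future__ import annotations

import numpy as np

_MASK64 = np.uint64(0xFFFFFFFFFFFFFFFF)

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = "ACGT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


def splitmix64(x):
    """splitmix64 finalizer; accepts scalars or uint64 numpy arrays."""
    with np.errstate(over="ignore"):
        z = (np.uint64(x) + np.uint64(0x9E3779B97F4A7C15)) & _MASK64
        z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & _MASK64
        z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & _MASK64
        return z ^ (z >> np.uint64(31))


def encode_kmer(kmer: str) -> int:
    """2-bit encode an ACGT k-mer (k <= 31) into an int."""
    v = 0
    for b in kmer:
        v = (v << 2) | _BASE_CODE[b]
    return v


def decode_kmer(value: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_CODE_BASE[value & 3])
        value >>= 2
    return "".join(reversed(out))


def hash_kmer(kmer_value, salt: int):
    """H(m, salt): salted 64-bit hash of an encoded k-mer (scalar or array)."""
    seed = splitmix64(np.uint64(salt & 0xFFFFFFFFFFFFFFFF))
    return splitmix64(np.uint64(kmer_value) ^ seed)


def encode_sequence(seq: str) -> np.ndarray:
    """Per-base 2-bit codes as uint64; non-ACGT bases become 4 (invalid)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 4, dtype=np.uint64)
    for base, code in _BASE_CODE.items():
        codes[arr == ord(base)] = code
    return codes
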