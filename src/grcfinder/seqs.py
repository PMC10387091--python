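"""Low-level nucleotide helpers shared across the pipeline.

Sequences are plain uppercase strings over {A,C,G,T,N}; the numeric side
encodes A,C,G,T as 0..3 (N as 4) in uint8 arrays for vectorised work.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes (A=0, C=1, G=2, T=3, N=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _DECODE[codes].tobytes().decode("ascii")


def random_sequence(rng: np.random.Generator, length: int) -> str:
    """Uniform random nucleotide string of the given length."""
    return decode(rng.integers(0, 4, size=length, dtype=np.uint8))


def mutate_substitutions(
    rng: np.random.Generator, seq: str, rate: float
) -> tuple[str, np.ndarray]:
    """Apply i.i.d. per-site substitutions at the given rate.

    Substituted sites always change to a *different* base (never silent).
    Returns the mutated sequence and the 0-based positions substituted.
    """
    codes = encode(seq)
    hit = np.flatnonzero(rng.random(len(codes)) < rate)
    if hit.size:
        # shift by 1..3 mod 4 guarantees a real change
        shift = rng.integers(1, 4, size=hit.size, dtype=np.uint8)
        codes = codes.copy()
        codes[hit] = (codes[hit] + shift) % 4
    return decode(codes), hit


def kmer_set(seq: str, k: int) -> set[str]:
    """All k-length substrings of ``seq`` (forward orientation only)."""
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


# standard genetic code; stops as '*', any-N codons as 'X'
_CODON_TABLE: dict[str, str] = {}
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, (_a, _b, _c) in enumerate(
    (a, b, c) for a in "TCAG" for b in "TCAG" for c in "TCAG"
):
    _CODON_TABLE[_a + _b + _c] = _AA[_i]


def translate(seq: str, frame: int = 0) -> str:
    """Translate a nucleotide string in the given frame (0, 1 or 2).

    Stop codons become '*'; codons containing other letters become 'X';
    a trailing partial codon is dropped.
    """
    seq = seq.upper()
    out = []
    for i in range(frame, len(seq) - 2, 3):
        out.append(_CODON_TABLE.get(seq[i : i + 3], "X"))
    return "".join(out)
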