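"""Hamming-distance kernels for equal-length nucleotide strings.

Junction sequences are stratified by length upstream, so every kernel here
assumes (and checks) equal lengths.  Strings are encoded once into a compact
integer matrix so that batched sequence-versus-anchor distances reduce to
vectorised inequality counts.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import ContractError

# Fixed bijection {A,C,G,T} -> {0,1,2,3}; anything else is invalid here
# because ambiguous sequences are dropped at read time.
_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i

def encode_sequences(seqs: Sequence[str]) -> np.ndarray:
    """Encode equal-length DNA strings into a uint8 matrix (one row each).

    Raises
    ------
    ContractError
        If the sequences do not all share one length or contain characters
        outside {A, C, G, T}.
    """
    seqs = list(seqs)
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ContractError("sequences must all share one length")
    raw = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    enc = _LUT[raw].reshape(len(seqs), L)
    if (enc == 255).any():
        raise ContractError("sequences contain characters outside A/C/G/T")
    return enc


def decode_sequences(enc: np.ndarray) -> list[str]:
    """Inverse of :func:`encode_sequences`."""
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return [bytes(bases[row]).decode("ascii") for row in enc]


def hamming(a: str, b: str) -> int:
    """Number of mismatched positions between two equal-length strings."""
    if len(a) != len(b):
        raise ContractError(
            f"hamming distance requires equal lengths, got {len(a)} and {len(b)}"
        )
    return sum(x != y for x, y in zip(a, b))


def normalized_hamming(a: str, b: str) -> float:
    """Hamming distance divided by the shared length; a fraction in [0, 1]."""
    if len(a) == 0:
        raise ContractError("normalized hamming distance undefined for empty strings")
    return hamming(a, b) / len(a)


_WORD_BASES = 32  # 2-bit base codes per uint64 word
_FIELD_MASK = np.uint64(0x5555555555555555)  # low bit of every 2-bit field


def pack_bits(enc: np.ndarray) -> np.ndarray:
    """Pack an encoded matrix into 2-bit fields inside uint64 words.

    Hamming distances then reduce to XOR + popcount, which is ~10x fewer
    memory operations than bytewise comparison.  Padding fields are zero in
    every row, so they never contribute to a distance.
    """
    n, L = enc.shape
    w = max(1, (L + _WORD_BASES - 1) // _WORD_BASES)
    padded = np.zeros((n, w * _WORD_BASES), dtype=np.uint64)
    padded[:, :L] = enc
    shifts = (2 * np.arange(_WORD_BASES, dtype=np.uint64))[None, None, :]
    return (padded.reshape(n, w, _WORD_BASES) << shifts).sum(
        axis=2, dtype=np.uint64
    )


def packed_distances_to_point(packed: np.ndarray, point: np.ndarray) -> np.ndarray:
    """Integer Hamming distances of every packed row to one packed row."""
    z = packed ^ point[None, :]
    differing = (z | (z >> np.uint64(1))) & _FIELD_MASK
    return np.bitwise_count(differing).sum(axis=1, dtype=np.int64)


def batch_distance(seqs: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """Normalized Hamming distance of every sequence to every anchor.

    Parameters
    ----------
    seqs, anchors
        Encoded matrices sharing the junction length L (columns).

    Returns
    -------
    float matrix of shape (n_seqs, n_anchors) with entries in [0, 1];
    entry (i, j) equals ``normalized_hamming(seq_i, anchor_j)``.
    """
    if anchors.ndim != 2 or anchors.shape[0] == 0:
        raise ContractError("batch_distance requires at least one anchor")
    if seqs.shape[1] != anchors.shape[1]:
        raise ContractError("sequences and anchors must share the junction length")
    n, L = seqs.shape
    seq_bits = pack_bits(seqs)
    anchor_bits = pack_bits(anchors)
    out = np.empty((n, anchors.shape[0]), dtype=np.float64)
    for j in range(anchors.shape[0]):
        out[:, j] = packed_distances_to_point(seq_bits, anchor_bits[j])
    out /= L
    return out


def distances_to_point(seqs: np.ndarray, point: np.ndarray) -> np.ndarray:
    """Raw (integer) Hamming distances of every encoded row to one row."""
    return np.count_nonzero(seqs != point[None, :], axis=1)
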