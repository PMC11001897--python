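"""The 522-dimensional positional k-mer feature encoding.

Each 41-nt window is described by six blocks, concatenated in a fixed
layout:

========================  ====  =================================
block                     size  content
========================  ====  =================================
PRIM moments                90  raw+central+Hahn (30) of the 4x4,
                                16x16 and 64x64 incidence matrices
RPRIM moments               90  same, on the reversed sequence
frequency vector            84  overlapping 1/2/3-mer counts
AAPIV                       84  per-k-mer sums of 1-based positions
RAAPIV                      84  AAPIV of the reversed sequence
2D-matrix moments           90  raw+central+Hahn of the integer-
                                encoded k-mer streams reshaped 7x7
========================  ====  =================================

Total: 522 features per window.

The position-relative incidence matrix (PRIM) entry convention: for
source k-mer i with first occurrence at 1-based position f_i and target
k-mer j occurring at positions q, entry(i -> j) = sum_q (q - f_i),
signed, and 0 whenever i or j is absent. K-mers are ordered
lexicographically over (A, C, G, U).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .moments import (
    MOMENT_ORDER,
    HahnParams,
    central_moments,
    hahn_moments,
    raw_moments,
)
from .windows import ALPHABET, RnaWindow, WindowDataset

logger = logging.getLogger(__name__)

FEATURE_COUNT = 522
#: sizes of the six layout blocks, in order
BLOCK_SIZES = {
    "prim_moments": 90,
    "rprim_moments": 90,
    "frequency": 84,
    "aapiv": 84,
    "raapiv": 84,
    "matrix2d_moments": 90,
}

KS = (1, 2, 3)


def kmers(k: int) -> list[str]:
    """All 4^k k-mers in lexicographic (A, C, G, U) order."""
    return ["".join(p) for p in itertools.product(ALPHABET, repeat=k)]


_KMER_INDEX = {k: {km: i for i, km in enumerate(kmers(k))} for k in KS}


def kmer_index(kmer: str) -> int:
    return _KMER_INDEX[len(kmer)][kmer]


@dataclass(frozen=True)
class PrimMatrix:
    """k-mer-level position-relative incidence matrix."""

    k: int
    values: np.ndarray
    direction: str = "forward"  # forward | reverse

    def __post_init__(self) -> None:
        side = 4 ** self.k
        if self.values.shape != (side, side):
            raise ValueError(
                f"PRIM for k={self.k} must be {side}x{side}, "
                f"got {self.values.shape}"
            )


def _occurrences(seq: str, k: int) -> dict[int, list[int]]:
    """1-based start positions of every overlapping k-mer, by k-mer index."""
    table = _KMER_INDEX[k]
    occ: dict[int, list[int]] = {}
    for pos in range(len(seq) - k + 1):
        idx = table[seq[pos : pos + k]]
        occ.setdefault(idx, []).append(pos + 1)
    return occ


def kmer_counts(seq: str, k: int) -> np.ndarray:
    """Overlapping k-mer counts in lexicographic order (length 4^k)."""
    out = np.zeros(4 ** k, dtype=int)
    for idx, positions in _occurrences(seq, k).items():
        out[idx] = len(positions)
    return out


def aapiv_seq(seq: str, k: int) -> np.ndarray:
    """Accumulative absolute position incidence vector of a sequence.

    delta_i = sum of 1-based start positions of occurrences of k-mer i.
    """
    out = np.zeros(4 ** k, dtype=int)
    for idx, positions in _occurrences(seq, k).items():
        out[idx] = sum(positions)
    return out


def prim_seq(seq: str, k: int) -> np.ndarray:
    """PRIM of a plain sequence (see module docstring for the convention)."""
    side = 4 ** k
    occ = _occurrences(seq, k)
    out = np.zeros((side, side))
    if not occ:
        return out
    present = sorted(occ)
    first = np.full(side, np.nan)
    pos_sum = np.zeros(side)
    count = np.zeros(side)
    for idx in present:
        positions = occ[idx]
        first[idx] = positions[0]
        pos_sum[idx] = sum(positions)
        count[idx] = len(positions)
    for i in present:
        # entry(i -> j) = sum_q (q - f_i) = pos_sum_j - count_j * f_i
        out[i, :] = pos_sum - count * first[i]
    return out


def frequency_vector(w: RnaWindow) -> np.ndarray:
    """84 overlapping k-mer counts: 4 mono + 16 di + 64 tri."""
    return np.concatenate([kmer_counts(w.sequence, k) for k in KS])


def aapiv(w: RnaWindow, k: int) -> np.ndarray:
    return aapiv_seq(w.sequence, k)


def raapiv(w: RnaWindow, k: int) -> np.ndarray:
    """AAPIV computed on the reversed (3'->5') sequence."""
    return aapiv_seq(w.sequence[::-1], k)


def prim(w: RnaWindow, k: int) -> PrimMatrix:
    return PrimMatrix(k, prim_seq(w.sequence, k), "forward")


def rprim(w: RnaWindow, k: int) -> PrimMatrix:
    """PRIM of the reversed sequence."""
    return PrimMatrix(k, prim_seq(w.sequence[::-1], k), "reverse")


def sequence_matrix_2d(w: RnaWindow, k: int) -> np.ndarray:
    """Integer-encoded k-mer stream reshaped row-major into a square.

    Codes run 1..4^k (lexicographic index + 1); the tail of the smallest
    enclosing square (7x7 for a 41-nt window at every k) is zero-padded.
    """
    seq = w.sequence
    codes = [
        _KMER_INDEX[k][seq[pos : pos + k]] + 1
        for pos in range(len(seq) - k + 1)
    ]
    side = math.isqrt(len(codes) - 1) + 1 if codes else 1
    out = np.zeros(side * side)
    out[: len(codes)] = codes
    return out.reshape(side, side)


def _matrix_moments(
    matrix: np.ndarray, origin: str, params: HahnParams
) -> np.ndarray:
    """30 moment values of one matrix; zero-mass central block -> zeros."""
    raw = raw_moments(matrix)
    if matrix.sum() == 0.0:
        if np.any(matrix):
            logger.warning(
                "%s: zero total mass, central moments substituted with zeros",
                origin,
            )
        central = np.zeros(len(MOMENT_ORDER))
    else:
        central = central_moments(matrix)
    return np.concatenate([raw, central, hahn_moments(matrix, params)])


def _moment_block_names(block: str) -> list[str]:
    names = []
    for k in KS:
        for family in ("raw", "central", "hahn"):
            for j, l in MOMENT_ORDER:
                names.append(f"{block}_k{k}_{family}_{j}{l}")
    return names


def feature_names() -> list[str]:
    """The 522 stable column names, in layout order."""
    names: list[str] = []
    names += _moment_block_names("prim")
    names += _moment_block_names("rprim")
    names += [f"freq_{km}" for k in KS for km in kmers(k)]
    names += [f"aapiv_{km}" for k in KS for km in kmers(k)]
    names += [f"raapiv_{km}" for k in KS for km in kmers(k)]
    names += _moment_block_names("mat2d")
    assert len(names) == FEATURE_COUNT
    return names


def assemble_features(
    w: RnaWindow, params: HahnParams = HahnParams()
) -> np.ndarray:
    """The full 522-value descriptor of one window, in layout order."""
    parts: list[np.ndarray] = []
    for direction, seq in (("prim", w.sequence), ("rprim", w.sequence[::-1])):
        for k in KS:
            parts.append(
                _matrix_moments(prim_seq(seq, k), f"{direction}_k{k}", params)
            )
    parts.append(frequency_vector(w).astype(float))
    parts.append(np.concatenate([aapiv(w, k) for k in KS]).astype(float))
    parts.append(np.concatenate([raapiv(w, k) for k in KS]).astype(float))
    for k in KS:
        parts.append(
            _matrix_moments(sequence_matrix_2d(w, k), f"mat2d_k{k}", params)
        )
    vec = np.concatenate(parts)
    assert vec.shape == (FEATURE_COUNT,)
    return vec


def encode_dataset(
    ds: WindowDataset, params: HahnParams = HahnParams()
) -> pd.DataFrame:
    """One row per window: id, label, then the 522 named features."""
    if len(ds) == 0:
        raise ValueError("cannot encode an empty dataset")
    rows = np.stack([assemble_features(w, params) for w in ds])
    df = pd.DataFrame(rows, columns=feature_names())
    df.insert(0, "label", ds.labels)
    df.insert(0, "id", [w.id for w in ds])
    return df
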