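"""Nucleotide Positional Specificity (NPS) encoding.

Two descriptors are concatenated:

1. a positional orthogonal binary code — each of the ``width`` positions
   contributes 4 entries using the code table
   A=(0,0,0,1), T=(0,0,1,0), C=(0,1,0,0), G=(1,0,0,0), N=(0,0,0,0);
2. position-independent overlapping k-mer frequencies over the whole window
   for k in {2, 3, 4} (16 + 64 + 256 entries, lexicographic k-mer order).

With the default 41-nt window the encoding is 4*41 + 336 = 500-dimensional.
The binary code table is deliberately the nonstandard one used by the original
predictor (A maps to the last slot, not the first); an RBF-SVM downstream is
invariant to this column permutation, but feature names stay faithful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np

from .io import SequenceRecord, SequenceValidationError

# Orthogonal binary code; column order is G, C, T, A.
BINARY_CODE: dict[str, tuple[int, int, int, int]] = {
    "A": (0, 0, 0, 1),
    "T": (0, 0, 1, 0),
    "C": (0, 1, 0, 0),
    "G": (1, 0, 0, 0),
    "N": (0, 0, 0, 0),
}
_CODE_CHANNELS = ("G", "C", "T", "A")  # channel c is 1 iff base == _CODE_CHANNELS[c]

__all__ = ["BINARY_CODE", "NPSConfig", "encode_binary", "kmer_frequencies", "encode_nps", "nps_feature_names", "encode_nps_matrix"]


@dataclass(frozen=True)
class NPSConfig:
    """Configuration of the NPS encoder.

    ``kmer_sizes`` are the k values of the frequency blocks; counting is
    overlapping, and k-mers containing N are skipped with the denominator
    adjusted to the number of N-free windows.
    """

    width: int = 41
    kmer_sizes: tuple[int, ...] = (2, 3, 4)

    @property
    def n_features(self) -> int:
        return 4 * self.width + sum(4**k for k in self.kmer_sizes)


def _check_window(seq: str, width: int) -> str:
    seq = str(seq)
    if len(seq) != width:
        raise SequenceValidationError(f"window length {len(seq)} != configured width {width}")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise SequenceValidationError(f"illegal characters {sorted(bad)} in window {seq!r}")
    return seq


def encode_binary(seq: str) -> np.ndarray:
    """Per-position orthogonal binary code; length ``4 * len(seq)``."""
    bad = set(seq) - set("ACGTN")
    if bad:
        raise SequenceValidationError(f"illegal characters {sorted(bad)} in window")
    out = np.empty(4 * len(seq), dtype=float)
    for p, base in enumerate(seq):
        out[4 * p : 4 * p + 4] = BINARY_CODE[base]
    return out


def _kmer_index(kmer: str) -> int:
    idx = 0
    for ch in kmer:
        idx = idx * 4 + "ACGT".index(ch)
    return idx


def kmer_frequencies(seq: str, k: int) -> np.ndarray:
    """Overlapping k-mer frequencies over {A,C,G,T}^k in lexicographic order.

    Windows containing N are excluded from both numerator and denominator;
    if no N-free window exists the vector is all zeros.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(seq) < k:
        raise SequenceValidationError(f"sequence of length {len(seq)} shorter than k={k}")
    counts = np.zeros(4**k, dtype=float)
    valid = 0
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        counts[_kmer_index(kmer)] += 1
        valid += 1
    if valid:
        counts /= valid
    return counts


def encode_nps(seq: str, cfg: NPSConfig = NPSConfig()) -> np.ndarray:
    """Full NPS vector: [binary block | k-mer blocks in ascending k]."""
    seq = _check_window(seq, cfg.width)
    blocks = [encode_binary(seq)]
    blocks.extend(kmer_frequencies(seq, k) for k in cfg.kmer_sizes)
    return np.concatenate(blocks)


def nps_feature_names(cfg: NPSConfig = NPSConfig()) -> list[str]:
    """Stable feature names: pos{p}_{G|C|T|A} (1-based p), then k-mer strings."""
    names = [f"pos{p + 1}_{ch}" for p in range(cfg.width) for ch in _CODE_CHANNELS]
    for k in cfg.kmer_sizes:
        names.extend("".join(t) for t in product("ACGT", repeat=k))
    return names


def encode_nps_matrix(records: Sequence[SequenceRecord], cfg: NPSConfig = NPSConfig()):
    """Encode many records into a :class:`~sixma.features.FeatureMatrix`."""
    from .features import FeatureMatrix

    values = np.vstack([encode_nps(r.seq, cfg) for r in records])
    labels = None
    if all(r.label is not None for r in records):
        labels = np.array([r.label for r in records], dtype=int)
    return FeatureMatrix(values=values, feature_names=nps_feature_names(cfg), labels=labels, ids=[r.id for r in records])
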