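"""Pseudo Dinucleotide Composition (PseDNC) encoding.

A sequence of length L is summarized by a (16 + lambda)-dimensional vector

    R = [d_1 ... d_16, d_17 ... d_{16+lambda}]

where the first 16 components derive from dinucleotide frequencies f_u and the
remaining lambda components from tiered sequence-order correlation factors

    theta_j = (1 / (L - j - 1)) * sum_{i=1}^{L-j-1} C_{i,i+j}
    C_{i,i+j} = (1 / mu) * sum_g [P_g(D_i) - P_g(D_{i+j})]^2

with P_g the g-th physicochemical property of a dinucleotide, standardized to
zero mean and unit (population) standard deviation over the 16 dinucleotides.
The two blocks are combined as

    d_u = f_u / (sum_i f_i + w * sum_j theta_j)          for u <= 16
    d_u = w * theta_{u-16} / (sum_i f_i + w * sum_j theta_j)  for u > 16

so that sum_u d_u = 1.  ``w`` balances composition against sequence order.

Three properties are used by default — melting enthalpy (dH), entropy (dS)
and free energy at 37 C (dG) of each dinucleotide stack, from the unified
nearest-neighbor thermodynamic parameter set (SantaLucia, PNAS 1998).  The
standardization step makes the encoding invariant to any affine rescaling of
a property, so the choice of units is immaterial; an alternative table can be
supplied as a TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import SequenceRecord, SequenceValidationError

DINUCLEOTIDES: tuple[str, ...] = tuple("".join(t) for t in product("ACGT", repeat=2))

# Unified nearest-neighbor parameters (SantaLucia 1998): dinucleotide ->
# (enthalpy dH kcal/mol, entropy dS cal/(mol*K), free energy dG37 kcal/mol).
# Complementary stacks share values (e.g. TT == AA read on the other strand).
DEFAULT_PROPERTIES: dict[str, tuple[float, float, float]] = {
    "AA": (-7.9, -22.2, -1.00),
    "AC": (-8.4, -22.4, -1.44),
    "AG": (-7.8, -21.0, -1.28),
    "AT": (-7.2, -20.4, -0.88),
    "CA": (-8.5, -22.7, -1.45),
    "CC": (-8.0, -19.9, -1.84),
    "CG": (-10.6, -27.2, -2.17),
    "CT": (-7.8, -21.0, -1.28),
    "GA": (-8.2, -22.2, -1.30),
    "GC": (-9.8, -24.4, -2.24),
    "GG": (-8.0, -19.9, -1.84),
    "GT": (-8.4, -22.4, -1.44),
    "TA": (-7.2, -21.3, -0.58),
    "TC": (-8.2, -22.2, -1.30),
    "TG": (-8.5, -22.7, -1.45),
    "TT": (-7.9, -22.2, -1.00),
}
PROPERTY_NAMES = ("enthalpy", "entropy", "free_energy")

__all__ = [
    "DINUCLEOTIDES",
    "DEFAULT_PROPERTIES",
    "DinucPropertyTable",
    "PseDNCConfig",
    "PseDNCVector",
    "standardize_properties",
    "dinuc_frequencies",
    "correlation",
    "theta",
    "encode_psednc",
    "psednc_feature_names",
    "encode_psednc_matrix",
]


@dataclass(frozen=True)
class DinucPropertyTable:
    """Original and standardized physicochemical values for the 16 dinucleotides.

    ``raw`` and ``standardized`` are 16 x mu arrays in :data:`DINUCLEOTIDES`
    row order; ``property_names`` labels the mu columns.
    """

    raw: np.ndarray
    standardized: np.ndarray
    property_names: tuple[str, ...]

    @property
    def n_properties(self) -> int:
        return self.raw.shape[1]

    def standardized_row(self, dinuc: str) -> np.ndarray:
        return self.standardized[DINUCLEOTIDES.index(dinuc)]

    @classmethod
    def from_dict(cls, values: dict[str, Sequence[float]], property_names: Sequence[str] = PROPERTY_NAMES) -> "DinucPropertyTable":
        missing = [d for d in DINUCLEOTIDES if d not in values]
        if missing:
            raise ValueError(f"property table is missing dinucleotides: {missing}")
        raw = np.array([values[d] for d in DINUCLEOTIDES], dtype=float)
        if raw.ndim != 2 or raw.shape[0] != 16:
            raise ValueError("expected one value per property for each of the 16 dinucleotides")
        return standardize_properties(raw, property_names)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DinucPropertyTable":
        """Load a table from a TSV with columns: dinucleotide, then one per property."""
        df = pd.read_csv(path, sep="\t")
        first = df.columns[0]
        df[first] = df[first].str.upper()
        values = {row[first]: row.iloc[1:].to_numpy(dtype=float) for _, row in df.iterrows()}
        return cls.from_dict(values, tuple(df.columns[1:]))

    @classmethod
    def default(cls) -> "DinucPropertyTable":
        return cls.from_dict(DEFAULT_PROPERTIES)


def standardize_properties(raw: np.ndarray, property_names: Sequence[str] = PROPERTY_NAMES) -> DinucPropertyTable:
    """Standardize each property to mean 0, population SD 1 over the 16 dinucleotides."""
    raw = np.asarray(raw, dtype=float)
    if raw.shape[0] != 16:
        raise ValueError(f"expected 16 dinucleotide rows, got {raw.shape[0]}")
    means = raw.mean(axis=0)
    sds = raw.std(axis=0)  # population SD (ddof=0)
    for name, sd in zip(property_names, sds):
        if sd == 0:
            raise ValueError(f"property {name!r} is constant over the 16 dinucleotides (zero SD)")
    return DinucPropertyTable(raw=raw, standardized=(raw - means) / sds, property_names=tuple(property_names))


@dataclass(frozen=True)
class PseDNCConfig:
    """PseDNC parameters: correlation depth ``lam`` (lambda), weight ``w``,
    dinucleotide counting mode, and the property table."""

    lam: int = 6
    w: float = 0.1
    overlapping: bool = True
    table: DinucPropertyTable = field(default_factory=DinucPropertyTable.default)

    def __post_init__(self) -> None:
        if self.lam < 1:
            raise ValueError("lambda must be a positive integer")
        if not 0 < self.w <= 1:
            raise ValueError("w must be in (0, 1]")

    @property
    def n_features(self) -> int:
        return 16 + self.lam


@dataclass(frozen=True)
class PseDNCVector:
    """The assembled vector ``d`` plus its ingredients ``f`` and ``theta``."""

    d: np.ndarray
    f: np.ndarray
    theta: np.ndarray


def _valid_dinucs(seq: str, step: int) -> list[tuple[int, str]]:
    """(start, dinucleotide) pairs with N-containing dinucleotides dropped."""
    return [
        (i, seq[i : i + 2])
        for i in range(0, len(seq) - 1, step)
        if "N" not in seq[i : i + 2]
    ]


def dinuc_frequencies(seq: str, overlapping: bool = True) -> np.ndarray:
    """Normalized dinucleotide frequencies f over the 16 dinucleotides.

    N-containing dinucleotides are excluded from count and denominator.
    """
    seq = str(seq)
    if len(seq) < 2:
        raise SequenceValidationError("sequence must have length >= 2")
    pairs = _valid_dinucs(seq, 1 if overlapping else 2)
    if not pairs:
        raise SequenceValidationError("no valid (N-free) dinucleotide in sequence")
    f = np.zeros(16, dtype=float)
    for _, d in pairs:
        f[DINUCLEOTIDES.index(d)] += 1
    return f / len(pairs)


def correlation(d_i: str, d_j: str, table: DinucPropertyTable) -> float:
    """Correlation function C between two dinucleotides: mean squared
    difference of their standardized properties."""
    diff = table.standardized_row(d_i) - table.standardized_row(d_j)
    return float(np.mean(diff**2))


def theta(seq: str, lam: int, table: DinucPropertyTable) -> np.ndarray:
    """The lambda correlation factors theta_1..theta_lam.

    theta_j averages C over all dinucleotide pairs j apart; pairs with an
    N-containing member are dropped and the denominator adjusted.
    """
    seq = str(seq)
    L = len(seq)
    if lam >= L - 1:
        raise ValueError(f"lambda={lam} must be < L-1 = {L - 1}")
    dinucs = [seq[i : i + 2] for i in range(L - 1)]
    valid = ["N" not in d for d in dinucs]
    out = np.zeros(lam, dtype=float)
    for j in range(1, lam + 1):
        terms = [
            correlation(dinucs[i], dinucs[i + j], table)
            for i in range(L - 1 - j)
            if valid[i] and valid[i + j]
        ]
        out[j - 1] = float(np.mean(terms)) if terms else 0.0
    return out


def encode_psednc(seq: str, cfg: PseDNCConfig = PseDNCConfig()) -> PseDNCVector:
    """Assemble the (16 + lambda)-dimensional PseDNC vector for one sequence."""
    f = dinuc_frequencies(seq, overlapping=cfg.overlapping)
    th = theta(seq, cfg.lam, cfg.table)
    denom = f.sum() + cfg.w * th.sum()
    d = np.concatenate([f / denom, cfg.w * th / denom])
    return PseDNCVector(d=d, f=f, theta=th)


def psednc_feature_names(cfg: PseDNCConfig = PseDNCConfig()) -> list[str]:
    return [f"f_{d}" for d in DINUCLEOTIDES] + [f"theta{j}" for j in range(1, cfg.lam + 1)]


def encode_psednc_matrix(records: Sequence[SequenceRecord], cfg: PseDNCConfig = PseDNCConfig()):
    """Encode many records into a :class:`~sixma.features.FeatureMatrix`."""
    from .features import FeatureMatrix

    values = np.vstack([encode_psednc(r.seq, cfg).d for r in records])
    labels = None
    if all(r.label is not None for r in records):
        labels = np.array([r.label for r in records], dtype=int)
    return FeatureMatrix(values=values, feature_names=psednc_feature_names(cfg), labels=labels, ids=[r.id for r in records])
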