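"""Synthetic benchmark generator for 6mA site prediction.

Emulates the structure of the rice 6mA benchmark: two balanced classes of
41-nt windows with an adenine at the center.  Positives carry a tunable
position-specific composition bias at a handful of informative flanking
positions (the kind of signal a positional one-hot encoder captures);
negatives are uniform background with a GAGG context motif placed so its
adenine is the candidate site (the kind of contrast k-mer and dinucleotide
features capture).  Together the two signals give both encoders detectable,
separable structure.

The generator does not imitate rice genome composition, sequencing error
models or redundancy filtering — it provides controlled, reproducible signal
for testing the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .io import SequenceRecord, write_fasta

__all__ = ["SimConfig", "generate", "write_benchmark"]

NUCS = np.array(list("ACGT"))

# 1-based positions flanking the central adenine (position 21 of 41)
DEFAULT_INFORMATIVE_POSITIONS: tuple[int, ...] = (17, 18, 19, 23, 24, 25)
# nucleotide favored at each informative position, cycled if positions differ
DEFAULT_BIASED_NUCLEOTIDES: tuple[str, ...] = ("G", "C", "T", "G", "C", "T")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of one synthetic benchmark.

    ``effect_size`` in [0, 1] sets the positional bias in positives: at each
    informative position the designated nucleotide has probability
    0.25 + 0.75 * effect_size (uniform at 0, deterministic at 1).
    ``informative_positions`` are 1-based window coordinates.
    """

    n_pos: int = 400
    n_neg: int = 400
    width: int = 41
    effect_size: float = 0.5
    motif: str = "GAGG"
    informative_positions: tuple[int, ...] = DEFAULT_INFORMATIVE_POSITIONS
    biased_nucleotides: tuple[str, ...] = DEFAULT_BIASED_NUCLEOTIDES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.width % 2 == 0:
            raise ValueError("width must be odd and positive")
        if not 0.0 <= self.effect_size <= 1.0:
            raise ValueError("effect_size must lie in [0, 1]")
        if "A" not in self.motif:
            raise ValueError(f"motif {self.motif!r} contains no adenine to center on")
        if len(self.motif) > self.width:
            raise ValueError("motif longer than window width")
        center = (self.width - 1) // 2 + 1  # 1-based
        for p in self.informative_positions:
            if not 1 <= p <= self.width:
                raise ValueError(f"informative position {p} outside 1..{self.width}")
            if p == center:
                raise ValueError("the central position is fixed to 'A' and cannot carry bias")

    @property
    def center(self) -> int:
        """0-based center index."""
        return (self.width - 1) // 2

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_pos": self.n_pos, "n_neg": self.n_neg, "width": self.width,
                "effect_size": self.effect_size, "motif": self.motif,
                "informative_positions": list(self.informative_positions),
                "biased_nucleotides": list(self.biased_nucleotides),
                "seed": self.seed,
            },
            indent=1,
        )


def _uniform_windows(rng: np.random.Generator, n: int, width: int) -> np.ndarray:
    return NUCS[rng.integers(0, 4, size=(n, width))]


def generate(cfg: SimConfig = SimConfig()) -> list[SequenceRecord]:
    """Draw the labeled benchmark: positives first, then negatives.

    Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    center = cfg.center

    # positives: uniform background + positional bias, center forced to A
    pos = _uniform_windows(rng, cfg.n_pos, cfg.width)
    pos[:, center] = "A"
    p_hit = 0.25 + 0.75 * cfg.effect_size
    for k, p1 in enumerate(cfg.informative_positions):
        nuc = cfg.biased_nucleotides[k % len(cfg.biased_nucleotides)]
        others = [c for c in "ACGT" if c != nuc]
        col = rng.random(cfg.n_pos)
        draw = np.where(
            col < p_hit, nuc, np.array(others)[rng.integers(0, 3, size=cfg.n_pos)]
        )
        pos[:, p1 - 1] = draw

    # negatives: uniform background + motif with its adenine at the center
    neg = _uniform_windows(rng, cfg.n_neg, cfg.width)
    a_offset = cfg.motif.index("A")
    start = center - a_offset
    if start < 0 or start + len(cfg.motif) > cfg.width:
        raise ValueError("motif does not fit in the window when centered on its adenine")
    for j, ch in enumerate(cfg.motif):
        neg[:, start + j] = ch

    records = [
        SequenceRecord(id=f"pos_{i}", seq="".join(row), label=1) for i, row in enumerate(pos)
    ] + [
        SequenceRecord(id=f"neg_{i}", seq="".join(row), label=0) for i, row in enumerate(neg)
    ]
    return records


def write_benchmark(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write paired FASTA files plus a manifest recording the full config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = generate(cfg)
    paths = {
        "positives": outdir / "positives.fasta",
        "negatives": outdir / "negatives.fasta",
        "manifest": outdir / "manifest.json",
    }
    write_fasta([r for r in records if r.label == 1], paths["positives"])
    write_fasta([r for r in records if r.label == 0], paths["negatives"])
    paths["manifest"].write_text(cfg.to_json())
    return paths
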