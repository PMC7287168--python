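"""FASTA input/output and site-centered window extraction.

A candidate 6mA site is represented as a fixed-width window (default 41 nt)
centered on the adenine under consideration.  Windows that would run off the
end of the source sequence are padded with the gap character ``N`` so that the
site stays exactly central.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

ALPHABET = frozenset("ACGTN")

__all__ = [
    "ALPHABET",
    "SequenceRecord",
    "WindowConfig",
    "FastaParseError",
    "SequenceValidationError",
    "read_fasta",
    "read_labeled_fasta",
    "write_fasta",
    "extract_window",
    "validate_records",
]


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed."""


class SequenceValidationError(ValueError):
    """Raised when a sequence violates the alphabet or length contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """One candidate site window.

    Attributes
    ----------
    id : str
        Record identifier (FASTA header up to first whitespace).
    seq : str
        Uppercase sequence over {A, C, G, T, N}.
    label : int or None
        1 for a methylated (6mA) site, 0 for a non-site, None for an
        unlabeled query record.
    """

    id: str
    seq: str
    label: Optional[int] = None


@dataclass(frozen=True)
class WindowConfig:
    """Geometry of the site-centered window.

    ``width`` must be odd so that the candidate base is exactly central.
    ``center_check`` controls what happens when the central base of a window
    is not an adenine: ``"warn"`` (default) emits a warning, ``"error"``
    raises, ``"ignore"`` does nothing.
    """

    width: int = 41
    pad_char: str = "N"
    center_check: Literal["error", "warn", "ignore"] = "warn"

    def __post_init__(self) -> None:
        if self.width < 1 or self.width % 2 == 0:
            raise ValueError(f"window width must be odd and positive, got {self.width}")
        if self.pad_char != "N":
            raise ValueError("pad_char is fixed to 'N'")
        if self.center_check not in ("error", "warn", "ignore"):
            raise ValueError(f"unknown center_check mode {self.center_check!r}")

    @property
    def flank(self) -> int:
        return (self.width - 1) // 2


def _clean_sequence(raw: str, record_id: str) -> str:
    """Uppercase, map U->T, and validate the alphabet."""
    seq = str(raw).upper().replace("U", "T")
    for pos, ch in enumerate(seq):
        if ch not in ALPHABET:
            raise SequenceValidationError(
                f"record {record_id!r}: illegal character {ch!r} at position "
                f"{pos + 1} (1-based); allowed alphabet is A/C/G/T/N"
            )
    return seq


def read_fasta(path: str | Path, label: Optional[int] = None) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Sequences are uppercased and RNA ``U`` is mapped to ``T``.  Any character
    outside {A, C, G, T, N} raises :class:`SequenceValidationError` naming the
    record and position.  ``label`` (0 or 1), when given, is attached to every
    record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    try:
        for entry in SeqIO.parse(str(path), "fasta"):
            records.append(
                SequenceRecord(id=entry.id, seq=_clean_sequence(str(entry.seq), entry.id), label=label)
            )
    except SequenceValidationError:
        raise
    except Exception as exc:  # malformed FASTA
        raise FastaParseError(f"cannot parse {path} as FASTA: {exc}") from exc
    return records


def read_labeled_fasta(positive: str | Path, negative: str | Path) -> list[SequenceRecord]:
    """Read a positive and a negative FASTA file into one labeled list."""
    return read_fasta(positive, label=1) + read_fasta(negative, label=0)


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, wrap: Optional[int] = None) -> None:
    """Write records to FASTA. ``wrap=None`` writes one line per sequence."""
    path = Path(path)
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        if wrap is None:
            for rec in bio:
                fh.write(f">{rec.id}\n{str(rec.seq)}\n")
        else:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
            writer.write_file(bio)


def extract_window(seq: str, center_index: int, cfg: WindowConfig = WindowConfig()) -> str:
    """Extract the ``cfg.width``-long window centered on ``center_index``.

    ``center_index`` is 0-based.  Flanks that fall outside the sequence are
    filled with ``N`` so the candidate base always sits at position
    ``(width - 1) // 2`` of the returned string.
    """
    seq = str(seq).upper().replace("U", "T")
    L = len(seq)
    if not 0 <= center_index < L:
        raise IndexError(f"center_index {center_index} out of range for sequence of length {L}")
    if seq[center_index] != "A":
        msg = (
            f"central base at index {center_index} is {seq[center_index]!r}, not 'A' "
            f"(position {center_index + 1}, 1-based)"
        )
        if cfg.center_check == "error":
            raise SequenceValidationError(msg)
        if cfg.center_check == "warn":
            warnings.warn(msg, stacklevel=2)
    flank = cfg.flank
    left = center_index - flank
    right = center_index + flank + 1
    core = seq[max(left, 0) : min(right, L)]
    return cfg.pad_char * max(0, -left) + core + cfg.pad_char * max(0, right - L)


def validate_records(records: Sequence[SequenceRecord], width: int = 41) -> None:
    """Check that every record has the configured width and a clean alphabet."""
    for rec in records:
        if len(rec.seq) != width:
            raise SequenceValidationError(
                f"record {rec.id!r}: length {len(rec.seq)} != required window width {width}"
            )
        for pos, ch in enumerate(rec.seq):
            if ch not in ALPHABET:
                raise SequenceValidationError(
                    f"record {rec.id!r}: illegal character {ch!r} at position {pos + 1}"
                )
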