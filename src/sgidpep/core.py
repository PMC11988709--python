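"""Core domain types: peptides, pools, validation, filtering and deduplication.

A :class:`Peptide` is a validated sequence over the 20 canonical one-letter
residue codes with a source label (which pool it was observed in) and an
optional ALC (average local confidence) score from de novo sequencing.
A :class:`PeptidePool` is a named, ordered collection of peptides.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Iterator, List, Optional

from .residues import CANONICAL_RESIDUES

_CANONICAL_SET = frozenset(CANONICAL_RESIDUES)


class Source(str, enum.Enum):
    """Origin of a peptide: undigested concentrate, gastric or intestinal
    digest, ultrafiltration size fractions thereof, or synthetic."""

    SPC = "SPC"
    GD = "GD"
    ID = "ID"
    GD1 = "GD1"
    GD2 = "GD2"
    GD3 = "GD3"
    ID1 = "ID1"
    ID2 = "ID2"
    ID3 = "ID3"
    SYNTHETIC = "SYNTHETIC"


class InvalidResidueError(ValueError):
    """Raised when a sequence contains a non-canonical residue letter."""

    def __init__(self, sequence: str, position: int):
        self.sequence = sequence
        self.position = position
        self.residue = sequence[position]
        super().__init__(
            f"invalid residue {self.residue!r} at position {position + 1} "
            f"in sequence {sequence!r}"
        )


@dataclass(frozen=True)
class Peptide:
    """A validated amino-acid sequence.

    ``alc`` is the de novo sequencing confidence as a percentage in [0, 100],
    or ``None`` for peptides without a score (e.g. simulator ground truth).
    """

    sequence: str
    source: Source = Source.SYNTHETIC
    alc: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        for i, ch in enumerate(self.sequence):
            if ch not in _CANONICAL_SET:
                raise InvalidResidueError(self.sequence, i)
        if self.alc is not None and not (0.0 <= self.alc <= 100.0):
            raise ValueError(f"ALC must be in [0, 100], got {self.alc}")

    def __len__(self) -> int:
        return len(self.sequence)


def validate_sequence(raw: str, source: Source = Source.SYNTHETIC,
                      alc: Optional[float] = None) -> Peptide:
    """Upper-case and validate a raw sequence, returning a :class:`Peptide`.

    Raises :class:`InvalidResidueError` naming the offending character and its
    1-based position if any letter is outside the canonical 20-letter alphabet.
    """
    if not raw:
        raise ValueError("peptide sequence must be non-empty")
    return Peptide(raw.upper(), source=source, alc=alc)


@dataclass(frozen=True)
class PeptidePool:
    """A named, ordered collection of peptides."""

    name: str
    peptides: tuple

    def __init__(self, name: str, peptides: Iterable[Peptide] = ()):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "peptides", tuple(peptides))

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self) -> Iterator[Peptide]:
        return iter(self.peptides)

    def __getitem__(self, i):
        return self.peptides[i]

    def sequences(self) -> List[str]:
        return [p.sequence for p in self.peptides]

    def with_peptides(self, peptides: Iterable[Peptide]) -> "PeptidePool":
        return PeptidePool(self.name, peptides)


def filter_by_alc(pool: PeptidePool, min_alc: float = 85.0,
                  keep_unscored: bool = False) -> PeptidePool:
    """Retain peptides whose ALC score is >= ``min_alc`` (inclusive).

    Peptides without a score are dropped unless ``keep_unscored`` is set;
    de novo output always carries a score, so an unscored peptide is treated
    as unfiltered input rather than a confident identification. Order is
    preserved.
    """
    kept = []
    for p in pool:
        if p.alc is None:
            if keep_unscored:
                kept.append(p)
        elif p.alc >= min_alc:
            kept.append(p)
    return pool.with_peptides(kept)


def dedup_key(sequence: str, merge_il: bool = False) -> str:
    """Equality key for deduplication; I is folded into L when ``merge_il``."""
    return sequence.replace("I", "L") if merge_il else sequence


def deduplicate(pool: PeptidePool, merge_il: bool = False) -> PeptidePool:
    """Drop repeated sequences, keeping the first occurrence of each.

    With ``merge_il`` set, isoleucine and leucine are treated as equivalent
    for the purpose of equality only (de novo MS cannot distinguish them);
    stored sequences are never rewritten.
    """
    seen = set()
    kept = []
    for p in pool:
        key = dedup_key(p.sequence, merge_il)
        if key not in seen:
            seen.add(key)
            kept.append(p)
    return pool.with_peptides(kept)
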