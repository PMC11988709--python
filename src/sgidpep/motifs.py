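"""Terminal-position criteria engine for α-amylase inhibitor candidates.

Inhibitory peptides of α-amylase are enriched in particular residues at their
terminal positions: the ultimate (N1, C1), penultimate (N2, C2) and
antepenultimate (N3, C3) residues from each end. A :class:`CriteriaSet` maps
each of the six positions to a set of allowed residues; a peptide's score is
the number of positions whose residue is allowed. Medium peptides (6–10
residues) meeting ≥3 criteria and long peptides (>10) meeting ≥4 are selected
as candidates; short peptides are never selected.

The default criteria set shipped here (basic residues at the termini, H/P at
C2, bulky hydrophobics at C3, aromatics at N2, hydrophobics at N3) is a
demonstration approximation of published α-amylase-inhibitor position
preferences, and is meant to be replaced by a user-supplied set.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping

import yaml

from .core import Peptide, PeptidePool
from .physchem import LengthClass, length_class

POSITIONS = ("N1", "N2", "N3", "C1", "C2", "C3")

#: Offsets into the sequence for each terminal position.
_OFFSETS = {"N1": 0, "N2": 1, "N3": 2, "C1": -1, "C2": -2, "C3": -3}


class CriteriaBin(str, enum.Enum):
    ZERO = "zero"
    ONE = "one"
    TWO = "two"
    THREE = "three"
    FOUR_PLUS = "four_plus"


_BIN_ORDER = [CriteriaBin.ZERO, CriteriaBin.ONE, CriteriaBin.TWO,
              CriteriaBin.THREE, CriteriaBin.FOUR_PLUS]


def bin_of(criteria_met: int) -> CriteriaBin:
    """Clamp a criteria count into the {0, 1, 2, 3, ≥4} bins."""
    if criteria_met < 0:
        raise ValueError("criteria count cannot be negative")
    return _BIN_ORDER[min(criteria_met, 4)]


@dataclass(frozen=True)
class CriteriaSet:
    """Map from terminal position (N1–N3, C1–C3) to allowed residue letters."""

    rules: Mapping[str, FrozenSet[str]]
    name: str = "criteria"

    def __post_init__(self) -> None:
        bad = set(self.rules) - set(POSITIONS)
        if bad:
            raise ValueError(f"unknown positions {sorted(bad)}; allowed: {POSITIONS}")
        empty = [pos for pos, allowed in self.rules.items() if not allowed]
        if empty:
            raise ValueError(f"empty residue set for positions {empty}")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str], name: str = "criteria") -> "CriteriaSet":
        """Build from {position: residue string}, e.g. ``{"N1": "RK"}``."""
        return cls({pos: frozenset(res) for pos, res in mapping.items()}, name=name)

    @classmethod
    def from_file(cls, path) -> "CriteriaSet":
        """Load a YAML file of the form ``{name: ..., rules: {N1: RK, ...}}``
        (or a bare position→residues mapping)."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "rules" in data:
            return cls.from_mapping(data["rules"], name=data.get("name", "criteria"))
        return cls.from_mapping(data)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"name": self.name,
                 "rules": {pos: "".join(sorted(res)) for pos, res in self.rules.items()}},
                fh,
            )


#: Demonstration default: R/K at both ultimate positions, H/P at C2,
#: W/L/F at C3, aromatic at N2, hydrophobic at N3.
DEFAULT_AMYLASE_CRITERIA = CriteriaSet.from_mapping(
    {
        "N1": "RK",
        "N2": "FWY",
        "N3": "ACFGHLMPVWY",
        "C1": "RK",
        "C2": "HP",
        "C3": "WLF",
    },
    name="amylase-demo",
)


def criteria_met(p: Peptide, c: CriteriaSet) -> int:
    """Number of terminal positions whose residue is in the allowed set.

    N1 is the first residue, C1 the last, N2/C2 adjacent inward, N3/C3 next
    inward. For peptides shorter than 6 residues, positions from the two ends
    can coincide; each rule is still evaluated independently at its own index,
    and positions that do not exist (length < 3) are skipped.
    """
    n = len(p.sequence)
    count = 0
    for pos, allowed in c.rules.items():
        off = _OFFSETS[pos]
        idx = off if off >= 0 else n + off
        if 0 <= idx < n and p.sequence[idx] in allowed:
            count += 1
    return count


@dataclass(frozen=True)
class ScreenResult:
    peptide: Peptide
    criteria_met: int
    bin: CriteriaBin
    candidate: bool


def screen(pool: PeptidePool, c: CriteriaSet) -> List[ScreenResult]:
    """Score every peptide and flag candidates (medium ≥3 / long ≥4)."""
    out = []
    for p in pool:
        k = criteria_met(p, c)
        lc = length_class(p)
        cand = (lc is LengthClass.MEDIUM and k >= 3) or (lc is LengthClass.LONG and k >= 4)
        out.append(ScreenResult(p, k, bin_of(k), cand))
    return out


def bin_distribution(pool: PeptidePool, c: CriteriaSet) -> Dict[CriteriaBin, float]:
    """Percentage of peptides falling in each criteria bin (sums to 100)."""
    if len(pool) == 0:
        raise ValueError("bin distribution of an empty pool is undefined")
    counts = {b: 0 for b in _BIN_ORDER}
    for p in pool:
        counts[bin_of(criteria_met(p, c))] += 1
    n = len(pool)
    return {b: 100.0 * counts[b] / n for b in _BIN_ORDER}


def select_candidates(pool: PeptidePool, c: CriteriaSet) -> PeptidePool:
    """Medium peptides meeting ≥3 criteria plus long peptides meeting ≥4,
    in pool order; short peptides are never selected."""
    selected = [r.peptide for r in screen(pool, c) if r.candidate]
    return PeptidePool(f"{pool.name}_candidates", selected)


def write_screen_tsv(pool: PeptidePool, c: CriteriaSet, path) -> None:
    """TSV screen report: sequence, per-position hit flags, score, bin,
    candidate verdict."""
    results = screen(pool, c)
    with open(path, "w") as fh:
        cols = [pos for pos in POSITIONS if pos in c.rules]
        fh.write("sequence\t" + "\t".join(cols) + "\tcriteria_met\tbin\tcandidate\n")
        for r in results:
            n = len(r.peptide.sequence)
            hits = []
            for pos in cols:
                off = _OFFSETS[pos]
                idx = off if off >= 0 else n + off
                hit = 0 <= idx < n and r.peptide.sequence[idx] in c.rules[pos]
                hits.append("1" if hit else "0")
            fh.write(
                f"{r.peptide.sequence}\t" + "\t".join(hits)
                + f"\t{r.criteria_met}\t{r.bin.value}\t{r.candidate}\n"
            )
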