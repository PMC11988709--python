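"""Residue-level constant tables: average masses, pKa values, composition classes.

The tables are plain data so that alternative mass or pKa sets can be swapped
in through :class:`ResidueTables` without touching any algorithm. The defaults
are the field-standard choices: average residue (i.e. water-subtracted) masses,
a Lehninger-style pKa set, and the four-way composition classification used for
hydrolysate characterisation (hydrophobic / acidic / basic / neutral).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Average residue masses (g/mol), i.e. amino acid mass minus one water.
AVERAGE_RESIDUE_MASS: Dict[str, float] = {
    "A": 71.0788,
    "C": 103.1388,
    "D": 115.0886,
    "E": 129.1155,
    "F": 147.1766,
    "G": 57.0519,
    "H": 137.1411,
    "I": 113.1594,
    "K": 128.1741,
    "L": 113.1594,
    "M": 131.1926,
    "N": 114.1038,
    "P": 97.1167,
    "Q": 128.1307,
    "R": 156.1875,
    "S": 87.0782,
    "T": 101.1051,
    "V": 99.1326,
    "W": 186.2132,
    "Y": 163.1760,
}

WATER_MASS = 18.0153

#: Lehninger-style pKa values for the ionizable groups of a peptide.
#: "nterm"/"cterm" are the free termini; single letters are side chains.
DEFAULT_PKA: Dict[str, float] = {
    "nterm": 9.60,
    "cterm": 2.34,
    "D": 3.65,
    "E": 4.25,
    "C": 8.33,
    "Y": 10.07,
    "H": 6.00,
    "K": 10.53,
    "R": 12.48,
}

#: Groups that are positively charged when protonated.
BASIC_GROUPS = frozenset({"nterm", "H", "K", "R"})
#: Groups that are negatively charged when deprotonated.
ACIDIC_GROUPS = frozenset({"cterm", "D", "E", "C", "Y"})

#: Four-way composition classification (hydrolysate-characterisation style):
#: note that G and H count as hydrophobic and C is hydrophobic, while
#: N/Q/S/T form the "neutral" (polar uncharged) class. Isoleucine is grouped
#: with the hydrophobics (de novo peptide lists often omit it, reporting the
#: isobaric leucine instead, so published class lists sometimes skip it).
DEFAULT_CLASS_OF: Dict[str, str] = {
    **{r: "hydrophobic" for r in "ACFGHILMPVWY"},
    **{r: "acidic" for r in "DE"},
    **{r: "basic" for r in "KR"},
    **{r: "neutral" for r in "NQST"},
}

COMPOSITION_CLASSES = ("hydrophobic", "acidic", "basic", "neutral")


@dataclass(frozen=True)
class ResidueTables:
    """Bundle of residue-level constants used by the physicochemical layer.

    Parameters
    ----------
    avg_mass : mapping of residue letter to average residue mass (g/mol)
    water_mass : mass of one water molecule (g/mol), added once per peptide
    pka : mapping of ionizable group ("nterm", "cterm", or a side-chain
        letter) to its pKa
    class_of : mapping of every canonical residue to one of
        ``{"hydrophobic", "acidic", "basic", "neutral"}``
    """

    avg_mass: Mapping[str, float] = field(default_factory=lambda: dict(AVERAGE_RESIDUE_MASS))
    water_mass: float = WATER_MASS
    pka: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PKA))
    class_of: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_CLASS_OF))

    def __post_init__(self) -> None:
        missing = set(CANONICAL_RESIDUES) - set(self.class_of)
        if missing:
            raise ValueError(f"class_of must cover all 20 residues; missing {sorted(missing)}")
        bad = {r: c for r, c in self.class_of.items() if c not in COMPOSITION_CLASSES}
        if bad:
            raise ValueError(f"unknown composition classes: {bad}")


DEFAULT_TABLES = ResidueTables()
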