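"""Physicochemical descriptors of peptides.

Implements the descriptor set used to characterise digestion-resistant
peptides: average molecular weight, Henderson–Hasselbalch net charge and
isoelectric point, four-way composition percentages
(hydrophobic / acidic / basic / neutral), length classification
(short 2–5, medium 6–10, long >10 residues) and a rule-based solubility
verdict.

The net charge of a peptide at pH ``x`` is the Henderson–Hasselbalch sum

    Z(x) =  Σ_basic 10^(pKa−x) / (1 + 10^(pKa−x))
          − Σ_acidic 10^(x−pKa) / (1 + 10^(x−pKa))

over every ionizable group (both termini plus D, E, C, Y, H, K, R side
chains). Z is strictly decreasing in pH, so the isoelectric point — the pH
at which Z = 0 — is its unique root, found by bisection on [0, 14].
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Dict

import pandas as pd

from .core import Peptide, PeptidePool
from .residues import (
    BASIC_GROUPS,
    COMPOSITION_CLASSES,
    DEFAULT_TABLES,
    ResidueTables,
)


class LengthClass(str, enum.Enum):
    SHORT = "short"    # 2-5 residues
    MEDIUM = "medium"  # 6-10 residues
    LONG = "long"      # >10 residues


def molecular_weight(p: Peptide, tables: ResidueTables = DEFAULT_TABLES) -> float:
    """Average molecular weight in g/mol: sum of average residue masses plus
    one water, reported to 2 decimals."""
    mass = sum(tables.avg_mass[r] for r in p.sequence) + tables.water_mass
    return round(mass, 2)


def _ionizable_groups(p: Peptide, tables: ResidueTables):
    """Yield (group name, pKa, sign) for every ionizable group of a peptide."""
    yield "nterm", tables.pka["nterm"], +1
    yield "cterm", tables.pka["cterm"], -1
    for r in p.sequence:
        if r in tables.pka:
            yield r, tables.pka[r], +1 if r in BASIC_GROUPS else -1


def net_charge(p: Peptide, ph: float, tables: ResidueTables = DEFAULT_TABLES) -> float:
    """Net charge (elementary charges) at the given pH."""
    if not (0.0 <= ph <= 14.0):
        raise ValueError(f"pH must be in [0, 14], got {ph}")
    z = 0.0
    for _name, pka, sign in _ionizable_groups(p, tables):
        if sign > 0:
            ratio = 10.0 ** (pka - ph)
        else:
            ratio = 10.0 ** (ph - pka)
        z += sign * ratio / (1.0 + ratio)
    return z


def isoelectric_point(p: Peptide, tables: ResidueTables = DEFAULT_TABLES,
                      tol: float = 1e-4) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14].

    The charge curve is strictly decreasing and every peptide carries both
    termini, so a unique zero crossing always exists. Iterates until
    |charge| < ``tol`` (and the bracket is tighter than ``tol`` in pH).
    """
    lo, hi = 0.0, 14.0
    # charge(0) > 0 > charge(14) always holds: at pH 0 every basic group is
    # protonated, at pH 14 every acidic group is deprotonated.
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        z = net_charge(p, mid, tables)
        if abs(z) < tol and (hi - lo) < tol:
            return mid
        if z > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def composition_percentages(p: Peptide,
                            tables: ResidueTables = DEFAULT_TABLES) -> Dict[str, float]:
    """Percentage of residues in each composition class, rounded to 2 decimals.

    Returns a dict with keys ``hydrophobic``, ``acidic``, ``basic``,
    ``neutral``; the unrounded values sum to exactly 100.
    """
    n = len(p.sequence)
    counts = {c: 0 for c in COMPOSITION_CLASSES}
    for r in p.sequence:
        counts[tables.class_of[r]] += 1
    return {c: round(100.0 * counts[c] / n, 2) for c in COMPOSITION_CLASSES}


def length_class(p: Peptide) -> LengthClass:
    """Classify by residue count: short 2–5, medium 6–10, long >10."""
    n = len(p.sequence)
    if n < 2:
        raise ValueError("length classification requires at least 2 residues")
    if n <= 5:
        return LengthClass.SHORT
    if n <= 10:
        return LengthClass.MEDIUM
    return LengthClass.LONG


def solubility_estimate(p: Peptide, tables: ResidueTables = DEFAULT_TABLES) -> bool:
    """Rule-based water-solubility verdict.

    A peptide is called soluble when it is very short (<5 residues) or when
    its charged-residue content (D, E, K, R, plus one charge for the termini)
    reaches one per five residues — a charged-fraction heuristic in the style
    of web peptide calculators. Deterministic and composition-only.
    """
    n = len(p.sequence)
    if n < 5:
        return True
    charged = sum(1 for r in p.sequence if r in "DEKR")
    return (charged + 1) >= n / 5.0


@dataclass(frozen=True)
class PhyschemProfile:
    """Per-peptide descriptor bundle."""

    sequence: str
    length: int
    mw: float
    pi: float
    net_charge_ph7: float
    pct_hydrophobic: float
    pct_acidic: float
    pct_basic: float
    pct_neutral: float
    length_class: LengthClass
    soluble: bool


def profile(p: Peptide, tables: ResidueTables = DEFAULT_TABLES) -> PhyschemProfile:
    """Compute the full physicochemical profile of one peptide."""
    pct = composition_percentages(p, tables)
    return PhyschemProfile(
        sequence=p.sequence,
        length=len(p.sequence),
        mw=molecular_weight(p, tables),
        pi=round(isoelectric_point(p, tables), 2),
        net_charge_ph7=round(net_charge(p, 7.0, tables), 2),
        pct_hydrophobic=pct["hydrophobic"],
        pct_acidic=pct["acidic"],
        pct_basic=pct["basic"],
        pct_neutral=pct["neutral"],
        length_class=length_class(p),
        soluble=solubility_estimate(p, tables),
    )


def profile_table(pool: PeptidePool,
                  tables: ResidueTables = DEFAULT_TABLES) -> pd.DataFrame:
    """Profile every peptide in a pool into a DataFrame (one row per peptide,
    2-decimal numeric columns, table-report style)."""
    rows = [profile(p, tables) for p in pool]
    df = pd.DataFrame(
        {
            "sequence": [r.sequence for r in rows],
            "length": [r.length for r in rows],
            "length_class": [r.length_class.value for r in rows],
            "mw": [r.mw for r in rows],
            "pi": [r.pi for r in rows],
            "net_charge_ph7": [r.net_charge_ph7 for r in rows],
            "pct_hydrophobic": [r.pct_hydrophobic for r in rows],
            "pct_acidic": [r.pct_acidic for r in rows],
            "pct_basic": [r.pct_basic for r in rows],
            "pct_neutral": [r.pct_neutral for r in rows],
            "soluble": [r.soluble for r in rows],
        }
    )
    return df


def write_profile_tsv(pool: PeptidePool, path,
                      tables: ResidueTables = DEFAULT_TABLES) -> pd.DataFrame:
    df = profile_table(pool, tables)
    df.to_csv(path, sep="\t", index=False, float_format="%.2f")
    return df
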