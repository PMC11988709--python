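"""Synthetic peptide-pool generator with ground-truth digestion-resistant labels.

Emulates the inputs of a gastrointestinal-digestion peptidomics study without
any mass-spectrometry data: parent proteins are digested in silico through a
gastric phase (pepsin) and an intestinal phase (trypsin + chymotrypsin), and
three de novo-style peptide pools are observed:

* ``SPC`` — the undigested concentrate: nonspecifically fragmented
  parent-protein peptides (in-source/collisional fragmentation during MS has
  no enzymatic specificity, so cut points are uniform random positions);
* ``GD``  — the gastric digest (pepsin products);
* ``ID``  — the intestinal digest (gastric products further cleaved), into
  which a planted subset of SPC peptides is passed through uncleaved: these
  are the digestion-resistant peptides.

Sequencing noise models de novo error: each true peptide is observed as
several reads; individual reads may be corrupted by residue substitutions,
terminal truncation and I/L swaps, and corrupted reads receive lower ALC
confidence scores. The deduplicated, ALC-filtered observation of an abundant
peptide therefore usually retains the correct sequence alongside occasional
noisy variants — the regime in which confidence filtering is useful.

All randomness flows from the seeds in :class:`DigestionSpec` (digestion and
planting) and :class:`NoiseSpec` (observation noise); identical seeds give
bit-identical pools.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np

from .core import Peptide, PeptidePool, Source
from .physchem import molecular_weight
from .residues import CANONICAL_RESIDUES, DEFAULT_TABLES, ResidueTables

#: Cleavage specificities: cut C-terminal to these residues, unless the next
#: residue is proline (the classical proline guard). Pepsin is simplified to
#: its preference for bulky hydrophobics.
CLEAVAGE_RULES: Dict[str, frozenset] = {
    "pepsin": frozenset("FLWY"),
    "trypsin": frozenset("KR"),
    "chymotrypsin": frozenset("FWY"),
}

_RESIDUES = np.array(list(CANONICAL_RESIDUES))


def _resolve_rules(rules: Union[str, Iterable[str]]) -> frozenset:
    if isinstance(rules, str):
        if rules in CLEAVAGE_RULES:
            return CLEAVAGE_RULES[rules]
        return frozenset(rules)
    return frozenset(rules)


@dataclass(frozen=True)
class Fragment:
    """A digestion product with 0-based half-open coordinates on its parent."""

    sequence: str
    protein_index: int
    start: int
    end: int


@dataclass(frozen=True)
class DigestionSpec:
    """Two-phase digestion parameters.

    ``enzymes`` is the ordered list of phases, each a tuple of enzyme names
    applied sequentially within the phase; the default is the classical
    gastric (pepsin) then intestinal (trypsin + chymotrypsin) sequence.
    ``min_len``/``max_len`` bound the observable peptide lengths, mimicking
    the mass range a de novo pipeline reports.
    """

    enzymes: Tuple[Tuple[str, ...], ...] = (("pepsin",), ("trypsin", "chymotrypsin"))
    missed_cleavage_prob: float = 0.1
    min_len: int = 5
    max_len: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_len < 2:
            raise ValueError("min_len must be at least 2")
        if self.max_len < self.min_len:
            raise ValueError("max_len must be >= min_len")
        if not (0.0 <= self.missed_cleavage_prob <= 1.0):
            raise ValueError("missed_cleavage_prob must be in [0, 1]")


@dataclass(frozen=True)
class NoiseSpec:
    """De novo sequencing-noise parameters.

    ``substitution_rate`` is per residue per read; ``truncation_prob`` is the
    per-read chance of losing a terminal residue; ``il_swap_rate`` is the
    per-I/L-residue chance of an isobaric swap (not penalised in ALC, since
    de novo engines cannot tell the two apart). ALC scores are drawn from a
    normal (``alc_mean``, ``alc_sd``) clipped to [0, 100], minus a penalty
    per corrupting error. ``mean_reads`` is the average number of reads per
    true peptide (1 + Poisson(mean_reads − 1)).
    """

    substitution_rate: float = 0.02
    il_swap_rate: float = 0.005
    truncation_prob: float = 0.01
    alc_mean: float = 93.0
    alc_sd: float = 3.0
    mean_reads: float = 4.0
    alc_error_penalty: float = 9.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "il_swap_rate", "truncation_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mean_reads < 1:
            raise ValueError("mean_reads must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    """True resistant sequences and provenance of every true peptide.

    ``resistant_set`` is the intersection of the true (pre-noise) SPC and ID
    sequence sets — the sequences that genuinely survived digestion intact.
    ``provenance`` maps each true sequence to its (protein index, start, end)
    coordinates, 0-based half-open, first occurrence.
    """

    resistant_set: frozenset
    provenance: Mapping[str, Tuple[int, int, int]]


def generate_parent_proteins(
    n: int,
    length_range: Tuple[int, int] = (200, 400),
    seed: int = 0,
    residue_weights: Optional[Mapping[str, float]] = None,
    gly_ser_rich: bool = False,
) -> List[str]:
    """Seeded random parent proteins over the 20-letter alphabet.

    Residue frequencies default to uniform; ``gly_ser_rich`` up-weights G and
    S five-fold (seed-storage proteins of oilseeds are glycine-rich, and
    glycine-rich peptides dominate real resistant-peptide lists).
    Explicit ``residue_weights`` override both.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid length_range {length_range}")
    rng = np.random.default_rng(seed)
    weights = np.ones(20)
    if gly_ser_rich:
        weights[list(CANONICAL_RESIDUES).index("G")] = 5.0
        weights[list(CANONICAL_RESIDUES).index("S")] = 5.0
    if residue_weights is not None:
        weights = np.array([residue_weights.get(r, 1.0) for r in CANONICAL_RESIDUES], float)
    probs = weights / weights.sum()
    proteins = []
    for _ in range(n):
        length = int(rng.integers(lo, hi + 1))
        proteins.append("".join(rng.choice(_RESIDUES, size=length, p=probs)))
    return proteins


def cleave(
    protein: str,
    rules: Union[str, Iterable[str]],
    missed_cleavage_prob: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    protein_index: int = 0,
    offset: int = 0,
) -> List[Fragment]:
    """Cleave C-terminal to rule residues (proline guard), returning fragments
    that tile the parent exactly.

    Each eligible site is independently skipped with ``missed_cleavage_prob``.
    ``rules`` may be an enzyme name ("pepsin", "trypsin", "chymotrypsin") or
    an explicit residue set. Coordinates are 0-based half-open, shifted by
    ``offset`` (used when re-digesting a fragment of a larger parent).
    """
    residues = _resolve_rules(rules)
    if rng is None:
        rng = np.random.default_rng(seed)
    cuts = []
    for i in range(len(protein) - 1):
        if protein[i] in residues and protein[i + 1] != "P":
            if missed_cleavage_prob == 0.0 or rng.random() >= missed_cleavage_prob:
                cuts.append(i + 1)
    bounds = [0] + cuts + [len(protein)]
    return [
        Fragment(protein[a:b], protein_index, offset + a, offset + b)
        for a, b in zip(bounds[:-1], bounds[1:])
    ]


def fragment_nonspecific(
    protein: str,
    cut_rate: float,
    rng: np.random.Generator,
    protein_index: int = 0,
) -> List[Fragment]:
    """Nonspecific fragmentation: every inter-residue bond is independently
    broken with ``cut_rate``. Models the enzyme-free fragmentation seen when
    de novo sequencing an intact protein concentrate; fragments tile the
    parent exactly."""
    if not (0.0 <= cut_rate <= 1.0):
        raise ValueError("cut_rate must be in [0, 1]")
    cuts = [i + 1 for i in range(len(protein) - 1) if rng.random() < cut_rate]
    bounds = [0] + cuts + [len(protein)]
    return [
        Fragment(protein[a:b], protein_index, a, b)
        for a, b in zip(bounds[:-1], bounds[1:])
    ]


def cleave_phase(
    fragments: Sequence[Fragment],
    enzymes: Tuple[str, ...],
    missed_cleavage_prob: float,
    rng: np.random.Generator,
) -> List[Fragment]:
    """Apply a phase's enzymes sequentially to every fragment."""
    current = list(fragments)
    for enzyme in enzymes:
        nxt: List[Fragment] = []
        for frag in current:
            nxt.extend(
                cleave(frag.sequence, enzyme, missed_cleavage_prob, rng=rng,
                       protein_index=frag.protein_index, offset=frag.start)
            )
        current = nxt
    return current


def _observable(fragments: Iterable[Fragment], dspec: DigestionSpec) -> List[Fragment]:
    return [f for f in fragments if dspec.min_len <= len(f.sequence) <= dspec.max_len]


def _observe_read(seq: str, nspec: NoiseSpec, rng: np.random.Generator) -> Tuple[str, int]:
    """One noisy de novo read of a true sequence; returns (read, error count).
    I/L swaps are applied but not counted as errors (isobaric ambiguity)."""
    chars = list(seq)
    errors = 0
    if len(chars) > 2 and rng.random() < nspec.truncation_prob:
        if rng.random() < 0.5:
            chars.pop(0)
        else:
            chars.pop()
        errors += 1
    for i, ch in enumerate(chars):
        if rng.random() < nspec.substitution_rate:
            alternatives = [r for r in CANONICAL_RESIDUES if r != ch]
            chars[i] = alternatives[int(rng.integers(len(alternatives)))]
            errors += 1
        elif ch in "IL" and rng.random() < nspec.il_swap_rate:
            chars[i] = "L" if ch == "I" else "I"
    return "".join(chars), errors


def observe_pool(
    true_sequences: Sequence[str],
    nspec: NoiseSpec,
    source: Source,
    name: str,
    rng: Optional[np.random.Generator] = None,
    origin: Optional[Dict[str, str]] = None,
) -> PeptidePool:
    """Observe true peptides as noisy, ALC-scored de novo reads.

    Each true sequence yields 1 + Poisson(mean_reads − 1) reads; reads are
    corrupted independently and scored
    ALC = clip(N(alc_mean, alc_sd) − penalty · errors, 0, 100). The returned
    pool is the raw read list (not deduplicated, not confidence-filtered) in
    stable order. When ``origin`` is given, each observed read sequence is
    recorded against the true sequence it came from (first origin wins).
    """
    if rng is None:
        rng = np.random.default_rng(nspec.seed)
    peptides: List[Peptide] = []
    for seq in true_sequences:
        n_reads = 1 + int(rng.poisson(nspec.mean_reads - 1.0))
        for _ in range(n_reads):
            read, errors = _observe_read(seq, nspec, rng)
            alc = float(np.clip(
                rng.normal(nspec.alc_mean, nspec.alc_sd) - nspec.alc_error_penalty * errors,
                0.0, 100.0,
            ))
            if len(read) >= 2:
                peptides.append(Peptide(read, source=source, alc=round(alc, 1)))
                if origin is not None:
                    origin.setdefault(read, seq)
    return PeptidePool(name, peptides)


@dataclass(frozen=True)
class SimulationResult:
    """Pools, ground truth, the true (pre-noise) sequence content of each
    pool, and ``read_origin``: observed read sequence → originating true
    sequence (identity for clean reads)."""

    pools: Mapping[str, PeptidePool]
    truth: GroundTruth
    true_sequences: Mapping[str, Tuple[str, ...]]
    read_origin: Mapping[str, str]


def simulate_sgid(
    proteins: Sequence[str],
    dspec: DigestionSpec = DigestionSpec(),
    nspec: NoiseSpec = NoiseSpec(),
    n_resistant: Optional[int] = None,
    resistant_fraction: float = 0.2,
    spc_fragmentation_rate: float = 0.06,
    resistant_length_range: Tuple[int, int] = (6, 17),
    detect_prob: float = 0.5,
) -> SimulationResult:
    """Simulate the SPC / GD / ID peptide pools with known resistant labels.

    The SPC pool is a nonspecific fragmentation of the parents (cut points
    uniform at ``spc_fragmentation_rate`` per bond, giving a mean fragment of
    ~17 residues). GD is the first-phase digest of the parents; ID is GD
    further cleaved by the second phase, plus a planted subset of medium-
    length SPC peptides passed through uncleaved — the ground-truth resistant
    peptides. ``n_resistant`` fixes the planted count; otherwise it is
    ``resistant_fraction`` of the observable ID background.

    ``detect_prob`` models data-dependent-acquisition undersampling: each
    background fragment in the observable length window is detected with this
    probability. Planted peptides are always detected in both pools — a
    resistant peptide is only ever *called* resistant because it was seen on
    both sides, so the ground truth is defined over detected peptides.
    Noise per :class:`NoiseSpec` is then applied to every pool independently.
    """
    if not proteins:
        raise ValueError("need at least one parent protein")
    if not (0.0 < detect_prob <= 1.0):
        raise ValueError("detect_prob must be in (0, 1]")
    rng_d = np.random.default_rng(dspec.seed)

    # True peptide content of each pool, before observation noise.
    spc_frags: List[Fragment] = []
    gd_frags: List[Fragment] = []
    for idx, prot in enumerate(proteins):
        spc_frags.extend(fragment_nonspecific(prot, spc_fragmentation_rate,
                                              rng_d, protein_index=idx))
    gastric, intestinal = dspec.enzymes[0], dspec.enzymes[1]
    for idx, prot in enumerate(proteins):
        gd_frags.extend(
            cleave_phase([Fragment(prot, idx, 0, len(prot))], gastric,
                         dspec.missed_cleavage_prob, rng_d)
        )
    id_frags = cleave_phase(gd_frags, intestinal, dspec.missed_cleavage_prob, rng_d)

    def _detected(frags: List[Fragment]) -> List[Fragment]:
        if detect_prob >= 1.0:
            return frags
        return [f for f in frags if rng_d.random() < detect_prob]

    spc_obs = _detected(_observable(spc_frags, dspec))
    gd_obs = _detected(_observable(gd_frags, dspec))
    id_obs = _detected(_observable(id_frags, dspec))

    # Plant resistant peptides: medium-length SPC peptides that pass through
    # intestinal digestion uncleaved.
    lo, hi = resistant_length_range
    candidates: List[Fragment] = []
    seen: Set[str] = set()
    for f in spc_obs:
        if lo <= len(f.sequence) <= hi and f.sequence not in seen:
            seen.add(f.sequence)
            candidates.append(f)
    if n_resistant is None:
        n_resistant = min(int(round(resistant_fraction * len(id_obs))), len(candidates))
    if n_resistant > len(candidates):
        raise ValueError(
            f"cannot plant {n_resistant} resistant peptides: only "
            f"{len(candidates)} distinct medium-length SPC peptides available"
        )
    planted_idx = rng_d.choice(len(candidates), size=n_resistant, replace=False)
    planted = [candidates[int(i)] for i in sorted(planted_idx)]
    id_final = id_obs + planted

    spc_seqs = tuple(f.sequence for f in spc_obs)
    gd_seqs = tuple(f.sequence for f in gd_obs)
    id_seqs = tuple(f.sequence for f in id_final)

    provenance: Dict[str, Tuple[int, int, int]] = {}
    for f in spc_obs + gd_obs + id_final:
        provenance.setdefault(f.sequence, (f.protein_index, f.start, f.end))
    resistant = frozenset(spc_seqs) & frozenset(id_seqs)
    truth = GroundTruth(resistant_set=resistant, provenance=provenance)

    rng_n = np.random.default_rng(nspec.seed)
    origin: Dict[str, str] = {}
    pools = {
        "SPC": observe_pool(spc_seqs, nspec, Source.SPC, "SPC", rng=rng_n, origin=origin),
        "GD": observe_pool(gd_seqs, nspec, Source.GD, "GD", rng=rng_n, origin=origin),
        "ID": observe_pool(id_seqs, nspec, Source.ID, "ID", rng=rng_n, origin=origin),
    }
    return SimulationResult(
        pools=pools,
        truth=truth,
        true_sequences={"SPC": spc_seqs, "GD": gd_seqs, "ID": id_seqs},
        read_origin=origin,
    )


def fractionate_by_size(
    pool: PeptidePool,
    cutoffs: Sequence[float] = (3000.0, 10000.0),
    tables: ResidueTables = DEFAULT_TABLES,
) -> Dict[str, PeptidePool]:
    """Partition a pool into molecular-weight fractions.

    Sharp half-open bins [0, c1), [c1, c2), ..., [ck, ∞) — an idealised
    ultrafiltration. With the default 3 kDa / 10 kDa cutoffs the labels are
    "<3000", "3000-10000", ">=10000". The fractions are disjoint and their
    union is the input pool.
    """
    cuts = list(cutoffs)
    if cuts != sorted(cuts) or len(set(cuts)) != len(cuts):
        raise ValueError("cutoffs must be strictly ascending")
    labels = []
    for i in range(len(cuts) + 1):
        if i == 0:
            labels.append(f"<{cuts[0]:g}")
        elif i == len(cuts):
            labels.append(f">={cuts[-1]:g}")
        else:
            labels.append(f"{cuts[i - 1]:g}-{cuts[i]:g}")
    buckets: Dict[str, List[Peptide]] = {lab: [] for lab in labels}
    for p in pool:
        mw = molecular_weight(p, tables)
        i = sum(1 for c in cuts if mw >= c)
        buckets[labels[i]].append(p)
    return {lab: PeptidePool(f"{pool.name}_{lab}", peps) for lab, peps in buckets.items()}


def evaluate_recovery(
    resistant_pool: PeptidePool,
    truth: GroundTruth,
    read_origin: Optional[Mapping[str, str]] = None,
) -> Tuple[float, float]:
    """Precision and recall of a recovered resistant pool against ground truth.

    Ground truth is "present up to noise": when ``read_origin`` is given,
    each recovered sequence is mapped back to the true sequence its read came
    from before comparison, so an accepted noisy read of a genuinely
    resistant peptide counts as a true positive. Without ``read_origin``,
    sequences are compared exactly. Recall is the fraction of ground-truth
    resistant sequences recovered (directly or through a noisy read).
    """
    predicted = set(resistant_pool.sequences())
    if not predicted:
        return 0.0, 0.0
    if read_origin is None:
        origins = {seq: seq for seq in predicted}
    else:
        origins = {seq: read_origin.get(seq, seq) for seq in predicted}
    tp_truths = {origins[s] for s in predicted if origins[s] in truth.resistant_set}
    n_tp_pred = sum(1 for s in predicted if origins[s] in truth.resistant_set)
    precision = n_tp_pred / len(predicted)
    recall = len(tp_truths) / len(truth.resistant_set) if truth.resistant_set else 0.0
    return precision, recall
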