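"""Digestion-resistant peptide identification by composition cosine similarity.

An intestinal-digest (ID) peptide is called digestion-resistant when its
residue-count composition vector has cosine similarity strictly greater than a
threshold (default 0.95) with some peptide of the undigested concentrate (SPC)
pool, and the pair's length difference does not exceed a guard (default 8
residues). Each query is assigned its single best reference: highest
similarity, ties broken by smaller length difference, then by SPC pool order.

Composition vectors are 20-dimensional residue counts by default; an optional
I/L merge folds the two isobaric residues into one bin, and dipeptide (k=2)
vectors are available as an alternative vectorisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import List, Tuple

import numpy as np

from .core import Peptide, PeptidePool, deduplicate
from .residues import CANONICAL_RESIDUES

_INDEX = {r: i for i, r in enumerate(CANONICAL_RESIDUES)}
_DIPEPTIDES = ["".join(t) for t in product(CANONICAL_RESIDUES, repeat=2)]
_DI_INDEX = {d: i for i, d in enumerate(_DIPEPTIDES)}


def composition_vector(p: Peptide, merge_il: bool = False) -> np.ndarray:
    """Residue-count vector (20 ints, indexed alphabetically).

    With ``merge_il``, I counts are folded into the L bin (the I bin stays
    zero), giving an effectively 19-dimensional vector. The counts always sum
    to the peptide length.
    """
    v = np.zeros(20, dtype=np.int64)
    for r in p.sequence:
        v[_INDEX[r]] += 1
    if merge_il:
        v[_INDEX["L"]] += v[_INDEX["I"]]
        v[_INDEX["I"]] = 0
    return v


def kmer_vector(p: Peptide, k: int = 2) -> np.ndarray:
    """Overlapping k-mer count vector (k=2: 400 dipeptide bins)."""
    if k != 2:
        raise ValueError("only k=2 is supported")
    v = np.zeros(len(_DIPEPTIDES), dtype=np.int64)
    for i in range(len(p.sequence) - 1):
        v[_DI_INDEX[p.sequence[i:i + 2]]] += 1
    return v


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """dot(a,b) / (|a||b|); in [0, 1] for non-negative count vectors."""
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    # clamp float round-off so parallel vectors report exactly 1.0
    return float(min(1.0, max(0.0, np.dot(a, b) / (na * nb))))


@dataclass(frozen=True)
class MatchRecord:
    """Best-reference pairing of one query peptide with its verdict."""

    query: Peptide
    reference: Peptide
    similarity: float
    length_diff: int
    accepted: bool


def _vector_matrix(pool: PeptidePool, merge_il: bool, kmer: bool) -> np.ndarray:
    fn = (lambda p: kmer_vector(p)) if kmer else (lambda p: composition_vector(p, merge_il))
    return np.array([fn(p) for p in pool], dtype=float)


def find_resistant(
    id_pool: PeptidePool,
    spc_pool: PeptidePool,
    threshold: float = 0.95,
    max_len_diff: int = 8,
    merge_il: bool = False,
    kmer: bool = False,
) -> Tuple[List[MatchRecord], PeptidePool]:
    """Identify digestion-resistant peptides in ``id_pool`` against ``spc_pool``.

    Returns one :class:`MatchRecord` per query (its best reference) and the
    resistant pool: accepted queries, deduplicated, in query order. Acceptance
    requires similarity strictly greater than ``threshold`` and a length
    difference of at most ``max_len_diff`` residues. Among references passing
    both filters the best is the highest-similarity one, ties broken by
    smaller length difference, then earliest SPC position; a query with no
    passing reference is reported against its highest-similarity reference
    with ``accepted=False``.
    """
    if len(id_pool) == 0 or len(spc_pool) == 0:
        raise ValueError("both pools must be non-empty")

    q = _vector_matrix(id_pool, merge_il, kmer)
    r = _vector_matrix(spc_pool, merge_il, kmer)
    qn = q / np.linalg.norm(q, axis=1, keepdims=True)
    rn = r / np.linalg.norm(r, axis=1, keepdims=True)
    sim = np.clip(qn @ rn.T, 0.0, 1.0)  # (n_id, n_spc)

    qlen = np.array([len(p) for p in id_pool])
    rlen = np.array([len(p) for p in spc_pool])
    ldiff = np.abs(qlen[:, None] - rlen[None, :])

    passing = (sim > threshold) & (ldiff <= max_len_diff)

    records: List[MatchRecord] = []
    accepted_peps: List[Peptide] = []
    n_ref = len(spc_pool)
    ref_order = np.arange(n_ref)
    for i, query in enumerate(id_pool):
        if passing[i].any():
            # lexicographic best: max similarity, min length_diff, min index
            cand = np.where(passing[i])[0]
            order = np.lexsort((ref_order[cand], ldiff[i, cand], -sim[i, cand]))
            j = int(cand[order[0]])
            ok = True
        else:
            j = int(np.argmax(sim[i]))
            ok = False
        rec = MatchRecord(
            query=query,
            reference=spc_pool[j],
            similarity=float(sim[i, j]),
            length_diff=int(ldiff[i, j]),
            accepted=ok,
        )
        records.append(rec)
        if ok:
            accepted_peps.append(query)

    resistant = deduplicate(
        PeptidePool(f"{id_pool.name}_resistant", accepted_peps), merge_il=merge_il
    )
    return records, resistant


def audit_pairs(
    id_pool: PeptidePool,
    spc_pool: PeptidePool,
    threshold: float = 0.95,
    max_len_diff: int = 8,
    merge_il: bool = False,
) -> List[MatchRecord]:
    """All-pairs audit: every (query, reference) pair passing both filters."""
    out = []
    for query in id_pool:
        qv = composition_vector(query, merge_il)
        for ref in spc_pool:
            s = cosine_similarity(qv, composition_vector(ref, merge_il))
            d = abs(len(query) - len(ref))
            if s > threshold and d <= max_len_diff:
                out.append(MatchRecord(query, ref, s, d, True))
    return out


def write_match_tsv(records: List[MatchRecord], path) -> None:
    """TSV match table: query, reference, similarity (4 decimals),
    length_diff, accepted."""
    with open(path, "w") as fh:
        fh.write("query\treference\tsimilarity\tlength_diff\taccepted\n")
        for rec in records:
            fh.write(
                f"{rec.query.sequence}\t{rec.reference.sequence}\t"
                f"{rec.similarity:.4f}\t{rec.length_diff}\t{rec.accepted}\n"
            )


def export_resistant_fasta(pool: PeptidePool, path) -> None:
    """Write the resistant pool as FASTA (deduplicated; see io.write_fasta)."""
    from .io import write_fasta

    if len(pool) == 0:
        raise ValueError("refusing to export an empty pool")
    write_fasta(deduplicate(pool), path)
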