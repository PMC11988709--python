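"""Composition vectors, cosine similarity and resistant-peptide matching.

The vectorized production matcher is checked pair-for-pair against a
brute-force all-pairs python-loop oracle, and cosine similarity against
scipy's implementation.
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.distance import cosine as scipy_cosine_distance

from sgidpep import (
    Peptide,
    PeptidePool,
    composition_vector,
    cosine_similarity,
    deduplicate,
    export_resistant_fasta,
    find_resistant,
    read_fasta,
)
from sgidpep.matcher import audit_pairs, kmer_vector
from sgidpep.residues import CANONICAL_RESIDUES

sequences = st.text(alphabet=CANONICAL_RESIDUES, min_size=2, max_size=25)


def brute_force_find(id_pool, spc_pool, threshold=0.95, max_len_diff=8, merge_il=False):
    """Oracle: per query, scan all references in order, track the best
    (similarity, -length_diff, -index) passing pair."""
    results = []
    for q in id_pool:
        qv = composition_vector(q, merge_il)
        best = None
        for j, ref in enumerate(spc_pool):
            s = cosine_similarity(qv, composition_vector(ref, merge_il))
            d = abs(len(q) - len(ref))
            if s > threshold and d <= max_len_diff:
                key = (-s, d, j)
                if best is None or key < best[0]:
                    best = (key, j, s, d)
        results.append(None if best is None else (best[1], best[2], best[3]))
    return results


class TestCompositionVector:
    def test_simple_counts(self):
        v = composition_vector(Peptide("AAK"))
        assert v[CANONICAL_RESIDUES.index("A")] == 2
        assert v[CANONICAL_RESIDUES.index("K")] == 1
        assert v.sum() == 3

    def test_reference_peptide_counts(self):
        v = composition_vector(Peptide("RHWLPR"))
        expected = {"R": 2, "H": 1, "W": 1, "L": 1, "P": 1}
        for r, c in expected.items():
            assert v[CANONICAL_RESIDUES.index(r)] == c
        assert v.sum() == 6

    @given(sequences, st.booleans())
    def test_counts_sum_to_length(self, seq, merge_il):
        assert composition_vector(Peptide(seq), merge_il).sum() == len(seq)

    def test_il_merge_folds_isoleucine(self):
        v = composition_vector(Peptide("AIL"), merge_il=True)
        assert v[CANONICAL_RESIDUES.index("I")] == 0
        assert v[CANONICAL_RESIDUES.index("L")] == 2

    def test_dipeptide_vector_counts_overlapping_kmers(self):
        v = kmer_vector(Peptide("AAA"))
        assert v.sum() == 2


class TestCosineSimilarity:
    def test_identical_sequences_give_one(self):
        v = composition_vector(Peptide("PSPSLVWR"))
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_scale_invariance_parallel_compositions(self):
        a = composition_vector(Peptide("AAAA"))
        b = composition_vector(Peptide("AA"))
        assert cosine_similarity(a, b) == pytest.approx(1.0)

    def test_disjoint_residue_sets_orthogonal(self):
        a = composition_vector(Peptide("AR"))
        b = composition_vector(Peptide("ND"))
        assert cosine_similarity(a, b) == 0.0

    @given(sequences, sequences)
    def test_symmetric_bounded_and_matches_scipy(self, s1, s2):
        a = composition_vector(Peptide(s1))
        b = composition_vector(Peptide(s2))
        ours = cosine_similarity(a, b)
        assert 0.0 <= ours <= 1.0
        assert ours == pytest.approx(cosine_similarity(b, a))
        assert ours == pytest.approx(1.0 - scipy_cosine_distance(a, b), abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(20), np.ones(20))


def _pool(name, seqs, **kw):
    return PeptidePool(name, [Peptide(s, **kw) for s in seqs])


class TestFindResistant:
    def test_exact_copies_all_resistant(self):
        spc = _pool("SPC", ["AAKDE", "GGFWR", "PLMNQS"])
        idp = _pool("ID", ["GGFWR", "AAKDE"])
        records, resistant = find_resistant(idp, spc)
        assert all(r.accepted and r.similarity == pytest.approx(1.0) for r in records)
        assert resistant.sequences() == ["GGFWR", "AAKDE"]

    def test_length_difference_guard_rejects(self):
        # parallel compositions but 9-residue length gap: must be rejected
        spc = _pool("SPC", ["A" * 11])
        idp = _pool("ID", ["A" * 20])
        records, resistant = find_resistant(idp, spc)
        assert records[0].similarity == pytest.approx(1.0)
        assert not records[0].accepted
        assert len(resistant) == 0

    def test_threshold_is_strict(self):
        spc = _pool("SPC", ["AAAA"])
        idp = _pool("ID", ["AAAA"])
        records, resistant = find_resistant(idp, spc, threshold=1.0)
        assert not records[0].accepted  # similarity 1.0 is not > 1.0

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            find_resistant(PeptidePool("ID"), _pool("SPC", ["AAK"]))

    @given(st.lists(sequences, min_size=1, max_size=25),
           st.lists(sequences, min_size=1, max_size=25))
    def test_agrees_with_brute_force_oracle(self, id_seqs, spc_seqs):
        idp, spc = _pool("ID", id_seqs), _pool("SPC", spc_seqs)
        records, _ = find_resistant(idp, spc)
        oracle = brute_force_find(idp, spc)
        for rec, orc in zip(records, oracle):
            if orc is None:
                assert not rec.accepted
            else:
                j, s, d = orc
                assert rec.accepted
                assert rec.reference is spc[j]
                assert rec.similarity == pytest.approx(s)
                assert rec.length_diff == d

    @given(st.lists(sequences, min_size=2, max_size=20, unique=True),
           st.lists(sequences, min_size=2, max_size=20, unique=True),
           st.randoms(use_true_random=False))
    def test_resistant_set_invariant_under_pool_permutation(self, id_seqs, spc_seqs, rnd):
        idp, spc = _pool("ID", id_seqs), _pool("SPC", spc_seqs)
        _, res1 = find_resistant(idp, spc)
        id_shuf, spc_shuf = list(id_seqs), list(spc_seqs)
        rnd.shuffle(id_shuf)
        rnd.shuffle(spc_shuf)
        _, res2 = find_resistant(_pool("ID", id_shuf), _pool("SPC", spc_shuf))
        assert set(res1.sequences()) == set(res2.sequences())

    @given(st.lists(sequences, min_size=1, max_size=20),
           st.lists(sequences, min_size=1, max_size=20))
    def test_monotone_in_threshold_and_length_guard(self, id_seqs, spc_seqs):
        idp, spc = _pool("ID", id_seqs), _pool("SPC", spc_seqs)
        _, loose = find_resistant(idp, spc, threshold=0.90, max_len_diff=10)
        _, tight_thr = find_resistant(idp, spc, threshold=0.97, max_len_diff=10)
        _, tight_len = find_resistant(idp, spc, threshold=0.90, max_len_diff=4)
        assert set(tight_thr.sequences()) <= set(loose.sequences())
        assert set(tight_len.sequences()) <= set(loose.sequences())

    def test_audit_mode_lists_every_passing_pair(self):
        spc = _pool("SPC", ["AAKW", "AAWK", "DDDD"])
        idp = _pool("ID", ["AKAW"])
        pairs = audit_pairs(idp, spc)
        assert len(pairs) == 2
        assert all(p.similarity == pytest.approx(1.0) for p in pairs)


class TestExport:
    def test_fasta_round_trip_and_dedup(self, tmp_path):
        pool = _pool("res", ["AAKDE", "GGFWR", "AAKDE"], alc=91.5)
        path = tmp_path / "resistant.fasta"
        export_resistant_fasta(pool, path)
        back = read_fasta(path)
        assert back.sequences() == ["AAKDE", "GGFWR"]
        assert [p.alc for p in back] == [91.5, 91.5]
        # byte-identical on rewrite
        export_resistant_fasta(deduplicate(pool), tmp_path / "again.fasta")
        assert (tmp_path / "again.fasta").read_bytes() == path.read_bytes()

    def test_empty_pool_refused(self, tmp_path):
        with pytest.raises(ValueError):
            export_resistant_fasta(PeptidePool("empty"), tmp_path / "x.fasta")
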