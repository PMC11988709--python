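"""Digestion simulator: cleavage rules, tiling, determinism, ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sgidpep import (
    DigestionSpec,
    NoiseSpec,
    Peptide,
    PeptidePool,
    cleave,
    fractionate_by_size,
    generate_parent_proteins,
    molecular_weight,
    simulate_sgid,
)
from sgidpep.residues import CANONICAL_RESIDUES
from sgidpep.simulate import fragment_nonspecific

ZERO_NOISE = NoiseSpec(substitution_rate=0.0, il_swap_rate=0.0, truncation_prob=0.0,
                       alc_mean=95.0, alc_sd=0.5, mean_reads=1.0, seed=9)


class TestGenerateParentProteins:
    def test_seed_reproducibility(self):
        assert generate_parent_proteins(5, seed=3) == generate_parent_proteins(5, seed=3)

    def test_count_and_length_bounds(self):
        prots = generate_parent_proteins(5, (200, 400), seed=1)
        assert len(prots) == 5
        assert all(200 <= len(p) <= 400 for p in prots)
        assert all(set(p) <= set(CANONICAL_RESIDUES) for p in prots)

    def test_glycine_enrichment_shifts_composition(self):
        # 5x G/S weight: expected G fraction 5/28 vs uniform 1/20; a 10k-residue
        # sample separates these by far more than binomial noise
        prots = generate_parent_proteins(30, (300, 400), seed=2, gly_ser_rich=True)
        joined = "".join(prots)
        frac_g = joined.count("G") / len(joined)
        n = len(joined)
        assert n > 8000
        assert frac_g > 1 / 20 + 3 * np.sqrt((1 / 20) * (19 / 20) / n)


class TestCleave:
    def test_pepsin_single_site(self):
        frags = cleave("AAFAAA", "pepsin")
        assert [f.sequence for f in frags] == ["AAF", "AAA"]
        assert [(f.start, f.end) for f in frags] == [(0, 3), (3, 6)]

    def test_trypsin_proline_guard(self):
        assert [f.sequence for f in cleave("AKPA", "trypsin")] == ["AKPA"]
        assert [f.sequence for f in cleave("AKAA", "trypsin")] == ["AK", "AA"]

    def test_full_missed_cleavage_leaves_parent_intact(self):
        frags = cleave("AFAFAFA", "pepsin", missed_cleavage_prob=1.0, seed=0)
        assert [f.sequence for f in frags] == ["AFAFAFA"]

    @given(st.text(alphabet=CANONICAL_RESIDUES, min_size=1, max_size=200),
           st.sampled_from(["pepsin", "trypsin", "chymotrypsin"]),
           st.floats(0.0, 1.0), st.integers(0, 2**31 - 1))
    def test_fragments_tile_parent(self, protein, enzyme, missed, seed):
        frags = cleave(protein, enzyme, missed, seed=seed)
        assert "".join(f.sequence for f in frags) == protein
        pos = 0
        for f in frags:
            assert f.start == pos and f.end == pos + len(f.sequence)
            pos = f.end
        assert pos == len(protein)

    def test_reconstruction_over_many_seeded_proteins(self):
        for i, prot in enumerate(generate_parent_proteins(100, (50, 150), seed=7)):
            frags = cleave(prot, "pepsin", 0.2, seed=i)
            assert "".join(f.sequence for f in frags) == prot

    def test_nonspecific_fragments_tile_parent(self):
        rng = np.random.default_rng(5)
        prot = generate_parent_proteins(1, (300, 300), seed=5)[0]
        frags = fragment_nonspecific(prot, 0.06, rng)
        assert "".join(f.sequence for f in frags) == prot


class TestSimulateSgid:
    def test_zero_noise_intersection_equals_ground_truth(self):
        prots = generate_parent_proteins(15, seed=4)
        sim = simulate_sgid(prots, DigestionSpec(seed=4), ZERO_NOISE, n_resistant=40)
        inter = set(sim.pools["SPC"].sequences()) & set(sim.pools["ID"].sequences())
        assert inter == set(sim.truth.resistant_set)
        assert len(sim.truth.resistant_set) >= 40

    def test_zero_noise_planted_fully_recovered(self):
        from sgidpep import deduplicate, evaluate_recovery, find_resistant

        prots = generate_parent_proteins(15, seed=4)
        sim = simulate_sgid(prots, DigestionSpec(seed=4), ZERO_NOISE, n_resistant=40)
        idp = deduplicate(sim.pools["ID"])
        spc = deduplicate(sim.pools["SPC"])
        _, resistant = find_resistant(idp, spc)
        _, recall = evaluate_recovery(resistant, sim.truth, sim.read_origin)
        assert recall == 1.0

    def test_same_seeds_give_identical_pools(self):
        prots = generate_parent_proteins(10, seed=6)
        a = simulate_sgid(prots, DigestionSpec(seed=6), NoiseSpec(seed=7), n_resistant=20)
        b = simulate_sgid(prots, DigestionSpec(seed=6), NoiseSpec(seed=7), n_resistant=20)
        for name in ("SPC", "GD", "ID"):
            assert a.pools[name].peptides == b.pools[name].peptides
        assert a.truth.resistant_set == b.truth.resistant_set

    def test_different_noise_seed_changes_reads_not_truth(self):
        prots = generate_parent_proteins(10, seed=6)
        a = simulate_sgid(prots, DigestionSpec(seed=6), NoiseSpec(seed=7), n_resistant=20)
        b = simulate_sgid(prots, DigestionSpec(seed=6), NoiseSpec(seed=8), n_resistant=20)
        assert a.truth.resistant_set == b.truth.resistant_set
        assert a.pools["ID"].peptides != b.pools["ID"].peptides

    def test_provenance_coordinates_locate_fragment_in_parent(self):
        prots = generate_parent_proteins(10, seed=6)
        sim = simulate_sgid(prots, DigestionSpec(seed=6), ZERO_NOISE, n_resistant=20)
        for seq, (pi, start, end) in list(sim.truth.provenance.items())[:200]:
            assert prots[pi][start:end] == seq

    def test_overplanting_rejected(self):
        prots = generate_parent_proteins(2, (60, 80), seed=1)
        with pytest.raises(ValueError):
            simulate_sgid(prots, DigestionSpec(seed=1), ZERO_NOISE, n_resistant=10**4)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            DigestionSpec(min_len=1)
        with pytest.raises(ValueError):
            DigestionSpec(min_len=10, max_len=5)
        with pytest.raises(ValueError):
            NoiseSpec(substitution_rate=1.5)


class TestFractionation:
    def test_small_peptide_in_sub3k_fraction(self):
        pool = PeptidePool("p", [Peptide("PSPSLVWR")])  # MW 941 < 3000
        fractions = fractionate_by_size(pool)
        assert fractions["<3000"].sequences() == ["PSPSLVWR"]

    def test_empty_pool_gives_empty_fractions(self):
        fractions = fractionate_by_size(PeptidePool("e"))
        assert set(fractions) == {"<3000", "3000-10000", ">=10000"}
        assert all(len(f) == 0 for f in fractions.values())

    @settings(max_examples=25)
    @given(st.lists(st.text(alphabet=CANONICAL_RESIDUES, min_size=2, max_size=60),
                    max_size=30))
    def test_fractions_partition_pool(self, seqs):
        pool = PeptidePool("p", [Peptide(s) for s in seqs])
        fractions = fractionate_by_size(pool, cutoffs=(1000.0, 4000.0))
        all_peps = [p for f in fractions.values() for p in f]
        assert sorted(p.sequence for p in all_peps) == sorted(pool.sequences())
        for label, f in fractions.items():
            for p in f:
                mw = molecular_weight(p)
                if label == "<1000":
                    assert mw < 1000
                elif label == "1000-4000":
                    assert 1000 <= mw < 4000
                else:
                    assert mw >= 4000

    def test_unsorted_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            fractionate_by_size(PeptidePool("e"), cutoffs=(5000.0, 1000.0))
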