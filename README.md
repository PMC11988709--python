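# sgidpep

Identification and characterisation of peptides that survive simulated
gastrointestinal digestion (SGID), for food-protein peptidomics: given de novo
peptide lists from an undigested protein concentrate (e.g. sacha inchi, SPC)
and from its intestinal digest (ID), `sgidpep` finds the digest peptides that
match concentrate peptides — the digestion-resistant peptides — and
characterises them as α-amylase-inhibitor candidates. A synthetic
digestion-and-noise simulator with ground-truth labels makes every stage
testable without mass-spectrometry data.

## What it computes

**Resistant-peptide matching.** Each peptide is represented by its
20-dimensional residue-count composition vector `c`. An ID peptide *q* is
called resistant when some SPC peptide *r* satisfies

```
cos(q, r) = c_q · c_r / (‖c_q‖ ‖c_r‖) > 0.95   and   | |q| − |r| | ≤ 8
```

after ALC ≥ 85 % confidence filtering and deduplication of both pools. Each
query is paired with its best reference (highest similarity, then smallest
length difference, then pool order).

**Physicochemical profiles.** Average molecular weight (Σ residue masses +
H₂O), Henderson–Hasselbalch net charge
`Z(pH) = Σ_basic 10^(pKa−pH)/(1+10^(pKa−pH)) − Σ_acidic 10^(pH−pKa)/(1+10^(pH−pKa))`,
isoelectric point (the unique root of Z, by bisection), four-class
composition percentages (hydrophobic/acidic/basic/neutral), length classes
(short 2–5, medium 6–10, long >10 residues) and a charged-fraction
solubility heuristic.

**Motif screen.** Counts how many terminal-position criteria (allowed
residues at N1–N3/C1–C3) each peptide meets; medium peptides meeting ≥3 and
long peptides meeting ≥4 criteria become α-amylase-inhibitor candidates.

**Assay calculators.** Linear standard curves (OLS), the α-amylase
inhibition formula `100 − 100·(maltose_sample − maltose_blank)/maltose_control`,
and Griess nitrite quantification with extrapolation flagging.

**Simulator.** Parent proteins → pepsin (gastric) → trypsin + chymotrypsin
(intestinal) digestion with missed cleavages and a proline guard; planted
resistant peptides passed through intact; per-read substitution/truncation/
I-L-swap noise with ALC scores; molecular-weight ultrafiltration fractions.

## Worked example

```python
from sgidpep import (DigestionSpec, NoiseSpec, deduplicate, evaluate_recovery,
                     filter_by_alc, find_resistant, generate_parent_proteins,
                     simulate_sgid)

proteins = generate_parent_proteins(n=40, seed=7)
sim = simulate_sgid(proteins, DigestionSpec(seed=7),
                    NoiseSpec(substitution_rate=0.02, seed=8), n_resistant=100)
id_pool  = deduplicate(filter_by_alc(sim.pools["ID"]))
spc_pool = deduplicate(filter_by_alc(sim.pools["SPC"]))
records, resistant = find_resistant(id_pool, spc_pool)
precision, recall = evaluate_recovery(resistant, sim.truth, sim.read_origin)
print(len(id_pool), len(spc_pool), len(resistant), precision, recall)
```

prints (seeds as above):

```
677 328 106 0.9811320754716981 0.97
```

677 intestinal-digest and 328 concentrate peptides survive confidence
filtering; 106 digest peptides are called resistant, of which 98.1 % are
genuine survivors, recovering 97 % of the planted ground truth despite the
2 % per-residue sequencing noise. Profiling the classic resistant peptides:

```python
from sgidpep import Peptide, PeptidePool, profile_table
print(profile_table(PeptidePool("r", [Peptide("RHWLPR"), Peptide("QCCDFMK")])))
```

```
  sequence  length length_class      mw     pi  net_charge_ph7  ...
    RHWLPR       6       medium  864.02  12.48            2.09  ...
   QCCDFMK       7       medium  874.06   5.84           -0.09  ...
```

RHWLPR is strongly basic (two arginines; pI 12.48, +2 at pH 7) — the kind of
positively charged peptide expected to interact with the acidic catalytic
residues of α-amylase — while QCCDFMK is near-neutral at pH 7.

More narrative scripts live in `examples/` (one per capability); the same
functionality is scriptable from the shell via the `sgidpep` CLI
(`simulate`, `match`, `profile`, `screen`, `assay`, `run`).

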