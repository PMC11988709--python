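# Methods

## The screening problem

Food-protein hydrolysates are screened for bioactive peptides by asking which
peptides of an intestinal digest were already present, intact, in the
undigested protein concentrate: a peptide observed on both sides of simulated
gastrointestinal digestion has, by construction, survived gastric and
intestinal proteolysis and is a candidate for oral bioactivity. Because both
pools come from de novo sequencing (no database), identification is
sequence-list matching, not spectrum matching, and must tolerate de novo
error — hence a similarity match rather than exact string equality.

## Resistant-peptide matching

Peptides are vectorised as 20-dimensional residue-count composition vectors;
the match statistic is the cosine of two count vectors. Acceptance requires
cosine strictly greater than 0.95 and an absolute length difference of at
most 8 residues; both pools are first filtered to ALC ≥ 85 % and
deduplicated. These four constants are the workflow's standard operating
point and are the package defaults.

Design choices the workflow definition leaves open, resolved here:

* **Vectorisation.** Residue counts are the simplest object for which cosine
  similarity of sequences is well defined; overlapping-dipeptide (k = 2)
  vectors are available as an alternative (`kmer=True`), and an I/L merge
  flag folds the two isobaric residues into one bin. Defaults: plain counts,
  no merge — de novo lists keep I and L distinct, so equality-level merging
  is opt-in.
* **Strict threshold.** Acceptance uses `> 0.95` (not `≥`), matching the
  realized-selection description of the workflow.
* **Best-reference tie-break.** Highest similarity, then smallest length
  difference, then earliest reference-pool position. Any rule would do
  scientifically; a fixed one makes runs reproducible and testable.
* **One record per query.** The production matcher reports each query's best
  reference only; `audit_pairs` enumerates every passing pair when the full
  bipartite structure is wanted.

The production matcher is a vectorised matrix computation; a brute-force
all-pairs loop (in `matcher.audit_pairs` and the test suite) serves as its
independent oracle and agrees pair-for-pair on every tested pool.

## Physicochemical descriptors

* **Molecular weight** is the sum of standard average residue masses plus one
  water (18.0153 g/mol), reported to 2 decimals. The mass table is data, not
  code, so alternative tables can be swapped in; agreement with Biopython's
  independent average-mass computation is asserted in tests.
* **Net charge** is the Henderson–Hasselbalch sum over both termini and the
  D, E, C, Y, H, K, R side chains. The default pKa set is the Lehninger-style
  set (N-term 9.60, C-term 2.34, D 3.65, E 4.25, C 8.33, Y 10.07, H 6.00,
  K 10.53, R 12.48). Web calculators use undisclosed sets, so pI values are
  validated property-wise (monotone charge curve, oracle agreement), not
  against published numbers.
* **Isoelectric point** is the unique zero of the strictly decreasing charge
  curve, found by bisection on [0, 14] to |Z| < 1e-4. An independent
  fine-grid (ΔpH = 1e-4) sign-change scan is the test oracle; agreement is
  required within 1e-3.
* **Composition classes** follow the four-way split used in hydrolysate
  characterisation tables: hydrophobic = {A,C,F,G,H,I,L,M,P,V,W,Y}, acidic =
  {D,E}, basic = {K,R}, neutral = {N,Q,S,T}. Published versions of this split
  omit isoleucine (de novo output reports it as leucine); it is grouped with
  the hydrophobics here, the only chemically sensible completion. The four
  percentages are each rounded to 2 decimals, so their reported sum can
  drift from 100 by up to 0.02.
* **Length classes**: short 2–5, medium 6–10, long > 10 residues.
  Single-residue input is rejected.
* **Solubility** is a deterministic charged-fraction heuristic in the style
  of web peptide calculators: soluble iff length < 5 or
  (count of D/E/K/R + 1 for the termini) ≥ length/5. It is a coarse verdict,
  swappable via the residue tables, and makes no claim to match any
  particular proprietary predictor.

## Terminal-motif screen

A criteria set maps the six terminal positions (N1–N3, C1–C3) to allowed
residue sets; a peptide's score is the number of satisfied positions, binned
as {0, 1, 2, 3, ≥4}. Candidates are medium peptides with ≥3 and long peptides
with ≥4 criteria; short peptides are never selected. For peptides of length
3–5 the two ends overlap; each rule is still evaluated independently at its
own index, which keeps counting well defined without inventing exclusions.
The shipped default set (R/K at N1 and C1, aromatics at N2, hydrophobics at
N3, H/P at C2, W/L/F at C3) is a demonstration approximation of published
α-amylase-inhibitor position preferences — real screens should supply their
own YAML criteria file, which is why the criteria set is a first-class input.

## Assay calculators

Standard curves are ordinary least-squares lines (replicate signals averaged
per concentration before fitting); inversion is exact inside the fitted
range and flagged as extrapolation outside it. The α-amylase inhibition
formula is implemented as `100 − 100·(sample − blank)/negative_control` —
the only reading of the conventional formula under which sample = blank
gives 100 % inhibition and release equal to the uninhibited control gives
0 %. Values outside [0, 100] are reported as-is (activation or
super-inhibition), to 1 decimal. Whether per-replicate values or means enter
the formula is configurable; means are the default.

## Synthetic data generator

The simulator emulates the study design end to end so that every pipeline
stage can be exercised against known ground truth.

* **Parent proteins**: seeded random sequences (default 200–400 residues,
  uniform residue frequencies; a Gly/Ser-rich option mimics the glycine-rich
  seed-storage proteins that dominate real resistant-peptide lists).
* **Digestion**: cleavage C-terminal to rule residues with a proline guard —
  pepsin {F,L,W,Y}, trypsin {K,R}, chymotrypsin {F,W,Y} — a standard
  simplification of enzyme specificity. Each eligible site is independently
  skipped with the missed-cleavage probability (default 0.1). Fragments tile
  the parent exactly, with 0-based half-open provenance coordinates.
* **The SPC observation** is a *nonspecific* fragmentation of the parents
  (each bond broken with probability 0.06, mean fragment ≈ 17 residues):
  peptides sequenced from an intact concentrate arise from in-source and
  collisional fragmentation, which has no enzymatic specificity. Modelling
  it with pepsin rules would artificially share cut sites with the digests
  and create spurious near-substring pairs.
* **Detection**: each background fragment inside the observable length
  window (default 5–40 residues) is detected with probability 0.5,
  mimicking data-dependent-acquisition undersampling. Planted resistant
  peptides are always detected on both sides — ground truth is only defined
  over peptides that were actually observed.
* **Planting**: the resistant set is a sample of medium-length (6–17
  residue) SPC peptides passed into the intestinal pool uncleaved; its size
  is explicit (`n_resistant`) or 20 % of the ID background. The ground-truth
  resistant set is the intersection of the true (pre-noise) SPC and ID
  sequence sets, so coincidental survivors (fragments identical on both
  sides by chance) count as genuinely resistant, and with zero noise the
  observed intersection equals the ground truth exactly.
* **Sequencing noise**: each true peptide is observed as 1 + Poisson(3)
  reads; each read is independently corrupted by per-residue substitution
  (default 0.02), terminal truncation (0.01/read) and I↔L swaps
  (0.005/residue, not ALC-penalised since the two are isobaric). ALC is
  drawn from N(93, 3) clipped to [0, 100], minus 9 points per corrupting
  error — so an abundant peptide's deduplicated observation usually retains
  the correct, high-confidence sequence, while noisy variants tend to fall
  below the 85 % filter. This reproduces the regime in which confidence
  filtering is actually useful.
* **Recovery evaluation** maps each accepted read back to the true sequence
  it was observed from (`read_origin`) before comparing with ground truth:
  an accepted noisy read of a genuinely resistant peptide is a true
  positive, consistent with ground truth meaning "present, up to noise, in
  both pools". Exact-sequence evaluation remains available by omitting the
  origin map.

All stochastic steps are pure functions of (inputs, seed): digestion and
planting draw from the digestion seed, observation noise from the noise
seed, and identical seeds give bit-identical pools.

**What the simulator does not model**: digestion kinetics and enzyme
concentration effects, bile chemistry, fuzzy ultrafiltration (membrane
cutoffs are sharp molecular-weight bins, keeping the partition property
exact), spectrum-level effects, retention time, and realistic protein
homology (parents are independent random sequences, so cross-protein
near-duplicate peptides are rarer than in a real proteome). Passing recovery
tests therefore demonstrate the pipeline's correctness and noise tolerance
under these idealisations, not a performance claim on real digests.

## Problem sizes and numerical choices

The recovery benchmark uses 80 parent proteins, 200 planted resistant
peptides and a 2 % substitution rate (pools of roughly 2 500 and 900
peptides after filtering), which profiles the matcher's intended scale while
keeping the whole suite fast; matcher/oracle equivalence is asserted on
pools up to 500 × 500. Cosine values are clamped to [0, 1] against float
round-off so parallel vectors compare exactly equal to 1. Degenerate inputs
are rejected with informative errors: empty pools, zero composition vectors
(impossible for valid peptides), single-residue length classification,
non-positive assay controls, equal-concentration calibration designs.

## Known limitations

* The default motif criteria are a demonstration set, not a validated
  inhibitor model.
* pI and solubility depend on the chosen pKa set and heuristic; absolute
  values are not comparable across calculators, only orderings and
  properties are.
* The composition cosine is length-insensitive by design (parallel
  compositions of different lengths score 1), which is why the length-
  difference guard exists; anagrams of the same composition are
  indistinguishable to the matcher.
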