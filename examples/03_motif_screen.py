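"""Terminal-motif screen for alpha-amylase inhibitor candidates.

Scores peptides by how many terminal-position criteria they meet (allowed
residues at the ultimate, penultimate and antepenultimate positions from
both ends) and selects candidates: medium peptides (6-10 residues) meeting
>= 3 criteria, long peptides (> 10) meeting >= 4.
"""

from sgidpep import (
    DEFAULT_AMYLASE_CRITERIA,
    Peptide,
    PeptidePool,
    bin_distribution,
    screen,
    select_candidates,
)

pool = PeptidePool("resistant", [
    Peptide("RHWLPR"), Peptide("PSPSLVWR"), Peptide("SDTLFFAR"),
    Peptide("YNLPMLR"), Peptide("SGGFGGNFGNR"), Peptide("HGGGGGGFGGGGFSR"),
])

print(f"criteria set: {DEFAULT_AMYLASE_CRITERIA.name}")
for pos, allowed in sorted(DEFAULT_AMYLASE_CRITERIA.rules.items()):
    print(f"  {pos}: {''.join(sorted(allowed))}")
print()
for result in screen(pool, DEFAULT_AMYLASE_CRITERIA):
    print(f"{result.peptide.sequence:18} criteria met: {result.criteria_met}  "
          f"candidate: {result.candidate}")
print()
dist = bin_distribution(pool, DEFAULT_AMYLASE_CRITERIA)
print("criteria-count distribution (% of pool):",
      {b.value: round(v, 1) for b, v in dist.items()})
candidates = select_candidates(pool, DEFAULT_AMYLASE_CRITERIA)
print("selected candidates:", candidates.sequences())
print()
print("The shipped criteria set is a demonstration approximation of published")
print("position preferences; supply your own YAML set for real screens.")
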