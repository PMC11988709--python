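"""Physicochemical profile of a few digestion-resistant peptides.

Computes molecular weight (g/mol), isoelectric point, net charge at pH 7,
composition-class percentages and a solubility verdict for peptides reported
as survivors of simulated gastrointestinal digestion of a sacha inchi
protein concentrate.
"""

from sgidpep import Peptide, PeptidePool, profile_table

peptides = ["QCCDFMK", "RHWLPR", "PSPSLVWR", "SDTLFFAR", "LLFPMSR",
            "HGGGGGGFGGGGFSR"]
pool = PeptidePool("resistant", [Peptide(s) for s in peptides])

df = profile_table(pool)
print(df.to_string(index=False))
print()
print("MW is the average molecular weight; pI the pH of zero net charge; a")
print("negative net charge at pH 7 means acidic character under physiological")
print("conditions. Percentages follow the hydrophobic/acidic/basic/neutral")
print("four-class split used for hydrolysate characterisation.")
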