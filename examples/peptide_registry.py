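"""Look up the TNFR transmembrane peptide variants and their numbering.

The registry holds the simulated variants (wild types and point mutants of
p75NTR, Fas and DR5) plus the NMR construct rows, with author residue
numbering preserved.
"""

from helixpack import peptide_registry

for name in ["p75 dimer (SS)", "p75 (C257A)", "Fas wt", "Fas C178R",
             "DR5 wt", "DR5 G217Y"]:
    rec = peptide_registry(name)
    print(f"{rec.name:16s} {rec.start_number}-{rec.sequence}-{rec.end_number}"
          f"  ({len(rec.sequence)} residues)  {rec.notes}")

# Residue 257 carries the disulphide-forming cysteine of p75; the C257A
# mutant replaces it and loses the covalent dimer.
wt, mut = peptide_registry("p75 dimer (SS)"), peptide_registry("p75 (C257A)")
print(f"\nposition 257: wild type = {wt.one_letter(257)}, "
      f"C257A mutant = {mut.one_letter(257)}")
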