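"""Molecular formulas and monoisotopic masses of the five synthesized
collagen-type peptides, straight from their triplet notation.

These are the desk-check numbers a mass-spectrometry lab compares
against its MALDI-TOF [M+H]+ readings (add ~1.007 for the proton).
"""

from collagen_roa import monoisotopic_mass, parse_triplet_notation, sequence_to_formula

PEPTIDES = ["(PHG)9PHA", "(PPG)9PPA", "D-(PPG)10", "(HPG)9HPA", "(GHP)10A"]

print(f"{'peptide':<12} {'residues':>8} {'formula':<16} {'monoisotopic mass / Da':>22}")
for notation in PEPTIDES:
    seq = parse_triplet_notation(notation)
    formula = sequence_to_formula(seq)
    mass = monoisotopic_mass(formula)
    print(f"{notation:<12} {len(seq):>8} {str(formula):<16} {mass:>22.4f}")

print()
print("Swapping Pro and Hyp ((PHG)9PHA vs (HPG)9HPA) is mass-neutral;")
print("the all-D analogue D-(PPG)10 differs from (PPG)9PPA by one CH2 (Ala vs Gly).")
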