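"""Simulate a backscattered Raman/ROA spectrum pair for a small helix
and demonstrate the mirror-image (enantiomer) antisymmetry.

Property tensors come from the synthetic generator (a stand-in for
quantum-chemistry output) calibrated so per-mode |ROA|/|Raman| sits
near 10^-3, the circular-intensity-difference scale of peptide ROA.
"""

import numpy as np

from collagen_roa import build_helix, make_chiral_tensors, mirror_image, spectrum_from_tensors

helix = build_helix("(PHG)2P", n_chains=1)
tensors = make_chiral_tensors(helix, roa_scale=1.0e-3, seed=7)
pair = spectrum_from_tensors(helix, tensors, fwhm=10.0, temperature=300.0)

ratio = np.abs(pair.roa).max() / pair.raman.max()
print(f"simulated pair on {pair.grid[0]:.0f}-{pair.grid[-1]:.0f} cm^-1 grid")
print(f"max |ROA|/max Raman = {ratio:.2e}  (weak chirality regime, as in experiment)")

mir_geom, mir_tensors = mirror_image(helix, tensors)
mir_pair = spectrum_from_tensors(mir_geom, mir_tensors)
roa_dev = np.abs(mir_pair.roa + pair.roa).max() / np.abs(pair.roa).max()
raman_dev = np.abs(mir_pair.raman - pair.raman).max() / pair.raman.max()
print(f"enantiomer: ROA sign-flip deviation {roa_dev:.1e}, "
      f"Raman change {raman_dev:.1e}")
print("-> the two enantiomers give exact mirror-image ROA and identical Raman,")
print("   the computational counterpart of the observed near-mirror spectra of")
print("   all-L and all-D polyproline-type peptides.")
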