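"""Conformational analysis of a PPII-concentrated trajectory:
backbone dihedrals, the (φ, ψ) free-energy surface, and triplet
segment lengths.
"""

import numpy as np

from collagen_roa import (
    backbone_dihedrals,
    make_ppii_trajectory,
    ramachandran_surface,
    segment_lengths,
)

traj, truth = make_ppii_trajectory("(PHG)3", n_snapshots=200, kappa=20.0, seed=3)
series = backbone_dihedrals(traj)
print(f"{truth['n_snapshots']} snapshots of (PHG)3 sampled around "
      f"(phi, psi) = {truth['means']} with kappa = {truth['kappa']}")
print(f"measured means: phi {np.nanmean(series.phi):7.1f} deg, "
      f"psi {np.nanmean(series.psi):6.1f} deg")

surf = ramachandran_surface(series, residue_selector="Pro", bins=36, temperature=300.0)
print(f"free-energy minimum bin (Pro residues): {surf.minimum_bin} "
      "(10 deg bins; 0 kJ/mol at the most populated bin)")

lengths, counts, edges = segment_lengths(traj, "Pro-Hyp-Gly")
print(f"Pro-Hyp-Gly segment length (Calpha_i -> Calpha_i+3): "
      f"{lengths.mean():.2f} +/- {lengths.std():.2f} A over {len(lengths)} samples")
print("-> the basin sits at the polyproline-II values, as in collagen strands.")
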