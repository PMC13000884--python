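# collagen-roa

Simulation and analysis of Raman and Raman optical activity (ROA)
spectra of collagen-type triple-helical peptides.

Collagen strands are polyproline-II (PPII) helices (φ ≈ −75°,
ψ ≈ +150°) wound in threes into a right-handed superhelix, with Gly
every third residue and Pro/4-hydroxyproline (Hyp) filling the
repeats. ROA — the difference in Raman scattering of right- vs
left-circularly polarized light — is exquisitely sensitive to this
chirality: the normalized circular intensity difference
CID = (I_R − I_L)/(I_R + I_L) sits near 10⁻³, an amide-I couplet with
a (−/+) low/high sign pattern reports the intact triple helix, and a
positive ROA band at 473 cm⁻¹ (a Hyp ring deformation) distinguishes
collagen I from collagen II. This package implements the desk-scale
protocol around such measurements for structural-bioinformatics work:

- **peptide models** — triplet-notation sequences (`(PHG)9PHA`,
  `D-(PPG)10`, …), exact molecular formulas and monoisotopic masses,
  and an idealized PPII single/triple-helix builder with PDB/XYZ I/O;
- **fragmentation** — cutting a labelled helix into partially
  overlapping fragments of 4 (or 7) amide units, offset by one amide,
  with hydrogen caps and parent atom maps;
- **tensor transfer** — Cartesian property-tensor transfer (dipole,
  α, G′, A derivatives and the Hessian) from fragments onto parent or
  snapshot geometries via best-fit Kabsch local rotations;
- **vibrational spectra** — Eckart-projected harmonic analysis,
  far-from-resonance invariants (a², β(α)², β(G′)², β(A)²),
  backscattered SCP stick intensities with the 300 K Boltzmann
  factor, Lorentzian convolution (FWHM 10 cm⁻¹), snapshot averaging,
  and normal-mode-subspace partial optimization;
- **spectral analysis** — iterative polynomial baseline removal,
  normalization to the 1650 cm⁻¹ water band, CID/ΔCID couplet
  statistics, band detection, and marker-band typing
  (collagen I / II / denatured I);
- **conformation** — backbone dihedrals, periodic Ramachandran
  free-energy surfaces, triplet segment-length histograms;
- **synthetic data** — seeded generators standing in for the
  quantum-chemistry and MD engines: spring-network force fields with
  closed-form oracles, chiral tensor sets calibrated to the 10⁻³ CID
  regime, experiment-like noisy spectra with marker-band fixtures,
  and PPII-concentrated dihedral trajectories.

The backscattered stick intensities use the standard invariant
combinations S_p ∝ 90a_p² + 14β(α)_p² (Raman) and
D_p ∝ (4/c)(12β(G′)_p² + 4β(A)_p²) (ROA), with a common
(ν̃₀−ν̃_p)⁴/ν̃_p Boltzmann-weighted prefactor; only normalized shapes
and CID ratios are meaningful, never absolute cross sections. See
`docs/methods.md` for every model choice and its rationale.

## Worked example

Mass arithmetic from the sequence alone (`examples/peptide_masses.py`):

```
peptide      residues formula          monoisotopic mass / Da
(PHG)9PHA          30 C121H174N30O41                2703.2453
(PPG)9PPA          30 C121H174N30O31                2543.2961
D-(PPG)10          30 C120H172N30O31                2529.2805
(HPG)9HPA          30 C121H174N30O41                2703.2453
(GHP)10A           31 C123H177N31O42                2760.2667
```

Swapping Pro and Hyp is mass-neutral (2703.25 twice); the all-D
peptide differs from its all-L analogue by one CH₂ (Ala vs Gly).

Simulating a spectrum pair and its enantiomer
(`examples/simulate_roa_spectrum.py`):

```
simulated pair on 0-1800 cm^-1 grid
max |ROA|/max Raman = 5.96e-04  (weak chirality regime, as in experiment)
enantiomer: ROA sign-flip deviation 6.5e-14, Raman change 7.0e-14
```

The synthetic tensors are calibrated so per-mode |ROA|/|Raman| sits
near 10⁻³, and the mirror-image system flips every ROA band exactly
while leaving Raman unchanged — the computational counterpart of the
near-mirror spectra of all-L and all-D polyproline-type peptides.

Typing experiment-like spectra (`examples/classify_collagen_type.py`):

```
type_I       -> call: type_I        evidence: ['roa_473_positive', 'amide_i_couplet_neg_pos']
type_II      -> call: type_II       evidence: ['raman_306_339_doublet', 'amide_i_couplet_neg_pos']
denatured_I  -> call: denatured_I   evidence: ['raman_221', 'amide_i_couplet_neg_pos']
ambiguous    -> call: indeterminate evidence: ['roa_473_positive', 'raman_306_339_doublet', ...]

amide-I couplet delta_CID: native 1.83e-03 vs denatured 3.28e-04
```

The 473 cm⁻¹ positive ROA marker calls type I, the 306+339 cm⁻¹ Raman
doublet calls type II, conflicting evidence stays indeterminate, and
denaturation shrinks the amide-I ΔCID by a factor of ~6.

The other examples cover helix building + fragmentation, Ramachandran
analysis of a PPII trajectory, and the end-to-end pipeline. A thin CLI
mirrors the stages:

```sh
collagen-roa build --sequence "(PHG)9PHA" --chains 3 --phi -75 --psi 150 --out helix.pdb
collagen-roa fragment --in helix.pdb --window 4 --out frags/
collagen-roa analyze --in spectrum.tsv --report report.json
collagen-roa run --out-dir demo/           # full synthetic pipeline
```

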