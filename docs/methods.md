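# Methods

`collagen_roa` implements the desk-scale computational protocol around
Raman optical activity (ROA) spectroscopy of collagen-type peptides:
idealized structure building, overlapping-fragment property-tensor
transfer, harmonic spectral synthesis, experiment-style spectral
analysis with circular-intensity-difference (CID) statistics, and
Ramachandran conformational analysis. The quantum-chemistry and
molecular-dynamics engines that would normally feed such a protocol
are replaced by seeded synthetic generators whose outputs obey the
same contracts (symmetries, magnitudes, file formats).

## Peptide models

Sequences are restricted to the collagen-model alphabet Pro (P),
4-hydroxyproline Hyp (H or X), Gly (G) and Ala (A), written in triplet
notation — `(PHG)9PHA`, `(GHP)10A`, `D-(PPG)10` — with free H-/−OH
termini. A leading `D-` makes every chiral residue D; Gly is achiral.

Molecular formulas are residue-composition sums (Pro C5H7NO,
Hyp C5H7NO2, Gly C2H3NO, Ala C3H5NO) plus one water for the termini.
Masses are **monoisotopic** (¹H 1.0078250319, ¹²C 12 exactly,
¹⁴N 14.0030740052, ¹⁶O 15.9949146221 Da): recomputation shows the
customary printed values for these peptides are monoisotopic sums, not
average masses, so that is the comparison standard.

The helix builder places backbone and side-chain heavy atoms by
internal coordinates (N–Cα 1.46 Å, Cα–C 1.52 Å, C–N 1.33 Å, C=O
1.23 Å; tetrahedral/trigonal angles) with the requested (φ, ψ) on
every residue and ω = 180°. Defaults are the canonical polyproline-II
(PPII) values φ = −75°, ψ = +150°. The proline ring is a rigid
idealized pucker whose two placement torsions were solved once so the
ring approximately closes (Cδ–N = 1.47 Å); Hyp adds a 4R-like hydroxyl
at C–O 1.41 Å. D residues negate every side-chain placement torsion,
which makes the builder exactly parity-consistent: an all-D build at
(−φ, −ψ) is the exact mirror image of the all-L build at (φ, ψ).
Hydrogens are omitted (nothing downstream needs them; fragment caps
are the only H atoms). For a triple helix the strand is aligned to its
principal axis, offset 4 Å radially, and copied at 0°/120°/240° with a
one-residue mutual stagger by default. This is an idealized stand-in
for a crystallographic starting structure, not a replica of one: only
relative geometry matters for the tests downstream.

## Fragmentation

A chain with M amide units (one per peptide bond) is cut into
M − w + 1 windows of w consecutive amides, offset by one amide
(defaults w = 4; w = 7 available). A fragment owns every residue
contributing an atom to an amide in its window; side chains travel
with their residue. Windows never span a chain break. Severed backbone
bonds are capped with hydrogen placed along the old bond direction at
1.09 Å (a methyl variant exists). Every non-cap fragment atom carries
its parent atom index; caps map to nothing.

## Tensor transfer

Per-atom Cartesian derivative tensors — dipole (N,3,3), polarizability
α (N,3,3,3), electric-dipole–magnetic-dipole G′ (N,3,3,3),
electric-dipole–electric-quadrupole A (N,3,3,3,3), plus the (3N,3N)
Hessian — are transferred from fragments to a target geometry by
best-fit local rotations:

- the support of an atom is itself plus its 12 nearest mapped
  neighbours in the fragment (ties broken by lower index);
- the Kabsch SVD rotation (determinant forced to +1; mirror fits are
  rejected, enantiomers must be requested explicitly through
  `mirror_image`) aligns fragment support onto target support;
- a rank-n tensor is rotated with one copy of the rotation per axis,
  the displacement axis included;
- per-atom tensors average over all fragments containing the atom,
  with weight 1 + (distance in residues from the nearer fragment
  edge), so fragment interiors dominate; weights are normalized to
  sum to 1 per atom;
- Hessian 3×3 blocks (a,b) average over fragments containing both
  atoms (pair weight = product of the per-atom weights) and rotate as
  R_a·H_ab·R_bᵀ; pairs never co-resident in a fragment get zero
  blocks — the long-range force constants are deliberately dropped;
- the result is symmetrized exactly, and the diagonal blocks are then
  rebuilt from the acoustic sum rule H_aa = −Σ_{b≠a} H_ab
  (`enforce_sum_rule=True`). Without this repair, block-wise
  averaging plus capped fragment edges breaks translational
  invariance enough to produce spurious imaginary modes at tens of
  cm⁻¹; with it the rigid-body residuals drop to ~10⁻⁶ cm⁻¹. The
  repair is a no-op for any translation-invariant input, so
  self-transfer of a whole-molecule fragment reproduces its input
  exactly.

## Harmonic spectra

Internal units: masses Da, lengths Å, Hessian mdyn/Å (100 N/m). The
single conversion constant is ν̃ = √λ · 1302.79 cm⁻¹ for λ in
mdyn/(Å·Da), computed from CODATA constants at import time.

`normal_modes` builds the mass-weighted Hessian, projects out the
rigid-body space (3 translations + 3 rotations about the centre of
mass; 5 vectors for linear molecules), and diagonalizes in the
complement; imaginary modes are reported as negative wavenumbers.
Returned mode vectors are mass-weighted and orthonormal.

Mode invariants contract the atomic derivative tensors with the
Cartesian mode displacements and form the standard far-from-resonance
quantities a², β(α)², β(G′)², β(A)² (the last with the excitation
angular frequency; tensors are treated as atomic-unit quantities, so
c = 137.036 and ω = ν̃₀/219474.63).

Backscattered SCP stick weights use the fixed convention
S_p = k_p(90a² + 14β(α)²) and D_p = k_p(4/c)(12β(G′)² + 4β(A)²), with
k_p = ((ν̃₀−ν̃_p)/ν̃₀)⁴/ν̃_p · 1/(1−exp(−hcν̃_p/k_BT)). The global
scale is arbitrary — only normalized shapes and CID ratios are ever
compared — so the ν̃₀⁴ normalization merely keeps numbers of order
1/ν̃. Defaults: 532 nm excitation (ν̃₀ = 18797.0 cm⁻¹), 300 K, and a
Lorentzian FWHM of 10 cm⁻¹ on a 1 cm⁻¹ grid spanning 50–1800 cm⁻¹.
Modes with ν̃ ≤ 0 are skipped with a warning; modes below a 50 cm⁻¹
floor (the lower edge of the modelled spectral window, where the
1/ν̃_p prefactor diverges) are dropped silently. Convolution uses
unit-area Lorentzians, so band area equals stick weight; the grid must
cover every stick ± 5 FWHM (clamped at 0 cm⁻¹). Snapshot averaging is
an unweighted pointwise mean — whether an MD ensemble should be
energy-weighted is an open question upstream, and equal weights are
the least-assumption choice.

`subspace_optimize` minimizes a caller-supplied energy/gradient model
along the normal modes inside a wavenumber window while freezing the
others: Newton iterations in mode-coefficient space use the supplied
Hessian projected onto the subspace (eigenvalue magnitudes floored at
10⁻¹⁰ relative), so a quadratic surface converges in one step, and
frozen-mode coordinates are unchanged exactly by construction.
Convergence: max projected gradient < 10⁻⁸ within 200 iterations.

## Spectral analysis

- **Baseline**: iterative polynomial fitting (degree 5, ≤50
  iterations, clip factor 1σ by default) on an abscissa scaled to
  [−1, 1]; points above fit + clipσ are pulled down to that level and
  the fit repeated until the working spectrum stabilizes, which
  excludes peaks while keeping the smooth fluorescence background.
  Non-convergence returns the last iterate with a flag.
- **Water normalization**: divide both channels by the maximum Raman
  intensity in 1630–1670 cm⁻¹ (a window rather than the exact
  1650 cm⁻¹ point, robust to ~7 cm⁻¹ instrument resolution). CID is a
  ratio and therefore unchanged. Preprocessing order is pinned:
  baseline first (fluorescence lives in the Raman channel), then
  normalization.
- **CID** = ROA/Raman at the nearest grid point; undefined where
  Raman ≤ 0. **Couplets**: within a region the extremal positive and
  negative ROA lobes give CID₁ (higher wavenumber) and CID₂ (lower);
  ΔCID = CID₁ − CID₂; evaluation at lobe extrema is a documented
  choice (band-integrated ratios would also be defensible).
- **Band detection**: a 7-point moving average (≈ instrument
  resolution; disableable) precedes SciPy peak picking with a
  prominence threshold; ROA bands are detected on both signs. Two
  equal bands 9 cm⁻¹ apart at FWHM 10 split into two inward-pulled
  peaks — pinned by a fixture.
- **Typing rules**: positive ROA band at 473 ± 8 cm⁻¹ → collagen I
  (the Hyp-ring fingerprint); Raman bands at both 306 ± 6 and
  339 ± 6 cm⁻¹ → collagen II; Raman band at 221 ± 6 cm⁻¹ → denatured
  I; amide-I ROA couplet (−/+) → triple-helix-consistent flag. The
  call is the unique type whose evidence fires alone; conflicts give
  `indeterminate`. Tolerances are set near the instrument resolution.

## Conformational analysis

Torsions use the standard atan2 construction with the IUPAC sign
convention (invariant under proper rigid motions, odd under
reflection). Ramachandran surfaces are periodic 10°×10° histograms
(36 bins per axis by default) converted to G = −k_BT·ln(n/n_max);
empty bins are +∞, never extrapolated. Segment length is defined as
the Cα(i)→Cα(i+3) distance over each occurrence of a named residue
triplet — one full triplet repeat of the collagen chain.

## Synthetic generators

Every generator is a pure function of its configuration (seeded
NumPy Generator streams; same config → identical bytes).

- **Spring systems**: nearest-neighbour chains (closed-form
  dispersion ω_j = 2√(k/m)·sin(jπ/2n), the frequency oracle) or 3-D
  networks with first/second/third-neighbour springs — exactly 3n−6
  constraints, so the generic network is rigid with the full set of
  six zero modes. Hessians are analytic (±k·eeᵀ blocks) and PSD.
- **Chiral tensors**: per-atom random draws keyed by atom id, so
  overlapping fragments cut from one parent receive identical tensors
  for shared atoms; force constants are a fixed smooth function of
  bond length (k = 0.8·exp(−(d−1.4)/0.8) mdyn/Å over a distance
  cutoff grown until the graph is rigid) for the same reason. α and A
  derivatives are symmetrized in the required index pairs; G′ and A
  are then scaled so the median per-mode |D_p|/S_p equals `roa_scale`
  (default 10⁻³, the CID magnitude regime of peptide ROA).
  `roa_scale=0` gives an exactly achiral set.
- **Experiment-like spectra**: Lorentzian band tables plus a water
  band at 1650 cm⁻¹, a polynomial fluorescence baseline (Raman channel
  only) and i.i.d. Gaussian noise, with the ground truth returned for
  recovery tests. Four canonical fixtures encode the marker-band
  rules (`type_I`, `type_II`, `denatured_I`, `ambiguous`); the
  denatured fixture scales the amide-I ROA couplet by 0.18, giving it
  the smallest ΔCID, mirroring the experimental ordering.
- **PPII trajectories**: per-residue, per-frame (φ, ψ) drawn from
  independent von Mises distributions centred on the PPII basin
  (κ = 20 by default) and rebuilt through the helix builder.
  κ ≥ 10⁶ is treated as the exact rigid limit (the means are used
  directly — sampling at κ = 10⁶ would still accumulate ~10⁻² Å of
  coordinate noise along a chain, which is not what the rigid limit
  means).
- **Pipeline snapshots** are Gaussian coordinate jitter of the parent
  (σ = 0.03 Å), a minimal stand-in for MD geometry dispersion; they
  carry no dihedral-level physics.

What the generators do **not** emulate: true quantum-chemical tensor
magnitudes and their mode specificity (so simulated band positions
carry no chemical meaning — amide-I physics is only present in the
experiment-like fixtures, not in the spring-network spectra),
solvent bands beyond the single 1650 cm⁻¹ water Lorentzian,
anharmonicity, and resonance effects. Passing tests therefore
demonstrate the correctness of the machinery (symmetries, oracles,
calibrations, round trips), not agreement with any measured collagen
spectrum.

## Pipeline and problem sizes

`run_pipeline` chains build → fragment → tensors → transfer (parent +
snapshots) → spectra → average → analyze, records every parameter, and
writes a manifest with SHA-256 checksums; fixed-format text output
makes runs byte-reproducible under a fixed seed. The demo
configuration is the (PHG)9PHA triple helix (573 heavy atoms, 87 amide
units, 78 four-amide fragments) with 10 snapshots, which completes in
about a minute on one CPU. Tests use a 7-residue strand for unit-level
checks and the 30-residue strand (191 atoms, 26 fragments) for the
transfer-equivariance checks; the Ramachandran recovery check uses
10⁴ von Mises samples per seed across 20 seeds.

## Known limitations

- The idealized proline ring does not exactly close and ring strain is
  ignored; the builder is a geometric stand-in, not a force-field
  structure.
- Dropping non-co-resident Hessian blocks discards long-range force
  constants; stitched low-frequency modes (< ~50 cm⁻¹) are therefore
  artifacts of the fragmentation, which is one reason for the
  spectral-window floor.
- The transfer weighting rule (edge-distance) is a documented
  surrogate for in-house conventions that published descriptions of
  Cartesian tensor transfer leave unspecified; a `uniform` alternative
  is exposed.
- The classifier is a fixed rule set for clean, preprocessed spectra;
  it is not trained and makes no claim of robustness to real
  instrument artifacts.
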