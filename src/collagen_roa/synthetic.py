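"""Seeded synthetic inputs for the whole pipeline.

The quantum-chemistry and molecular-dynamics engines that would supply
force fields, chiral property tensors and trajectories are emulated
here by construction-transparent generators:

- spring-network force fields with analytic Hessians (and closed-form
  frequencies for linear chains, usable as oracles),
- random smooth chiral property-tensor sets calibrated so the
  per-mode circular intensity difference sits in the ~10⁻³ regime
  typical of peptide ROA,
- experiment-like noisy spectra with a water band at 1650 cm⁻¹ and a
  polynomial fluorescence background, including canonical marker-band
  fixtures for the collagen-type classifier,
- dihedral-angle trajectories concentrated around the PPII basin.

Every generator is a pure function of its configuration: the same
seed gives byte-identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Geometry
from .peptides import build_helix, parse_triplet_notation
from .spectra import FREQ_CONV, SpectrumPair, default_grid
from .transfer import PropertyTensorSet

__all__ = [
    "make_spring_system",
    "spring_hessian",
    "linear_chain_frequencies",
    "make_chiral_tensors",
    "make_experiment_spectrum",
    "canonical_fixture",
    "make_ppii_trajectory",
    "jittered_snapshots",
]


# ----------------------------------------------------------------------
# spring-network force fields

def spring_hessian(
    coords: np.ndarray, bonds: list[tuple[int, int]], k: np.ndarray
) -> np.ndarray:
    """Analytic Hessian of E = Σ_b k_b/2 (|r_i−r_j| − r0_b)² at its own
    equilibrium (r0 = current distances): per bond, ±k e eᵀ blocks with
    e the unit bond vector.  Symmetric and positive semidefinite with
    the full set of rigid-body zero modes."""
    n = len(coords)
    H = np.zeros((3 * n, 3 * n))
    for (i, j), kb in zip(bonds, k):
        e = coords[j] - coords[i]
        e = e / np.linalg.norm(e)
        block = kb * np.outer(e, e)
        H[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] += block
        H[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] += block
        H[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] -= block
        H[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] -= block
    return H


def linear_chain_frequencies(n_atoms: int, k: float, mass: float) -> np.ndarray:
    """Closed-form longitudinal frequencies (cm⁻¹) of a free linear
    chain of equal masses and springs: ω_j = 2√(k/m)·sin(jπ/2n),
    j = 1 … n−1."""
    j = np.arange(1, n_atoms)
    return 2.0 * np.sqrt(k / mass) * np.sin(j * np.pi / (2 * n_atoms)) * FREQ_CONV


def make_spring_system(
    n_atoms: int,
    k: float | np.ndarray = 1.0,
    masses: np.ndarray | None = None,
    seed: int = 0,
    kind: str = "network",
) -> tuple[Geometry, np.ndarray]:
    """A connected spring system with analytic Hessian.

    ``kind="chain"`` places the atoms on a straight line with
    nearest-neighbour springs (the closed-form dispersion oracle);
    ``kind="network"`` scatters them in 3-D and adds first- and
    second-neighbour springs, giving a generic nonlinear system with
    exactly six rigid-body zero modes.
    """
    if n_atoms < 2:
        raise ValueError("need at least 2 atoms")
    rng = np.random.default_rng(seed)
    if masses is None:
        masses = np.full(n_atoms, 12.0)
    masses = np.asarray(masses, dtype=float)
    if kind == "chain":
        coords = np.column_stack(
            [1.5 * np.arange(n_atoms), np.zeros(n_atoms), np.zeros(n_atoms)]
        )
        bonds = [(i, i + 1) for i in range(n_atoms - 1)]
    elif kind == "network":
        coords = np.column_stack(
            [1.5 * np.arange(n_atoms), np.zeros(n_atoms), np.zeros(n_atoms)]
        ) + 0.4 * rng.standard_normal((n_atoms, 3))
        # first-, second- and third-neighbour springs: (n−1)+(n−2)+(n−3)
        # = 3n−6 constraints, so the generic network is exactly rigid
        bonds = [(i, i + 1) for i in range(n_atoms - 1)]
        bonds += [(i, i + 2) for i in range(n_atoms - 2)]
        bonds += [(i, i + 3) for i in range(n_atoms - 3)]
    else:
        raise ValueError(f"unknown spring-system kind {kind!r}")
    kvec = np.broadcast_to(np.asarray(k, dtype=float), (len(bonds),))
    geom = Geometry(
        elements=np.array(["C"] * n_atoms, dtype=object),
        coords=coords,
        masses=masses,
    )
    return geom, spring_hessian(coords, bonds, kvec)


# ----------------------------------------------------------------------
# chiral property tensors

def _distance_bonds(coords: np.ndarray, cutoff: float = 3.0) -> list[tuple[int, int]]:
    """Bond list by distance cutoff; the cutoff grows until the graph
    is connected and carries at least 3N constraints, which makes a
    generic embedding rigid (no floppy zero modes)."""
    from scipy.sparse.csgraph import connected_components
    from scipy.sparse import coo_matrix
    from scipy.spatial.distance import squareform, pdist

    n = len(coords)
    d = squareform(pdist(coords))
    target = max(3 * n - 6, 1)
    cut = cutoff
    while True:
        ii, jj = np.nonzero((d < cut) & np.triu(np.ones_like(d, dtype=bool), 1))
        adj = coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(n, n))
        ncomp, _ = connected_components(adj, directed=False)
        if (ncomp == 1 and len(ii) >= target + 6) or cut > 100.0:
            return list(zip(ii.tolist(), jj.tolist()))
        cut *= 1.25


def make_chiral_tensors(
    geometry: Geometry,
    roa_scale: float = 1.0e-3,
    seed: int = 0,
    hessian: np.ndarray | None = None,
    k_spring: float = 0.8,
    atom_ids: np.ndarray | None = None,
) -> PropertyTensorSet:
    """A random smooth chiral property-tensor set for ``geometry``.

    If no Hessian is supplied, a distance-cutoff spring network
    provides one, with per-bond force constants a fixed smooth
    function of the bond length — so overlapping fragments cut from
    one parent agree on their shared force constants.  α derivatives
    are symmetric random fields; the G′ and A derivatives are scaled
    post hoc so the median per-mode |ROA|/|Raman| stick ratio equals
    ``roa_scale`` (default 10⁻³, the circular-intensity-difference
    regime of peptide ROA).  ``roa_scale = 0`` yields an achiral set
    (all ROA weights zero).

    ``atom_ids`` (default 0 … N−1) key the per-atom random draws:
    passing parent atom indices for a fragment makes its tensors
    identical to any other fragment's tensors for the shared atoms.
    """
    if roa_scale < 0:
        raise ValueError("roa_scale must be non-negative")
    from .spectra import backscatter_sticks, mode_invariants, normal_modes

    n = geometry.n_atoms
    if atom_ids is None:
        atom_ids = np.arange(n)
    atom_ids = np.asarray(atom_ids, dtype=int)
    if len(atom_ids) != n:
        raise ValueError("atom_ids length mismatch")
    if hessian is None:
        bonds = _distance_bonds(geometry.coords)
        d = np.array([np.linalg.norm(geometry.coords[j] - geometry.coords[i])
                      for i, j in bonds])
        k = k_spring * np.exp(-(d - 1.4) / 0.8)
        hessian = spring_hessian(geometry.coords, bonds, k)

    dip = np.empty((n, 3, 3))
    alpha = np.empty((n, 3, 3, 3))
    gprime = np.empty((n, 3, 3, 3))
    a_t = np.empty((n, 3, 3, 3, 3))
    for i, aid in enumerate(atom_ids):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(seed), spawn_key=(int(aid),))
        )
        dip[i] = rng.standard_normal((3, 3))
        alpha[i] = rng.standard_normal((3, 3, 3))
        gprime[i] = rng.standard_normal((3, 3, 3))
        a_t[i] = rng.standard_normal((3, 3, 3, 3))
    alpha = 0.5 * (alpha + alpha.transpose(0, 2, 1, 3))
    a_t = 0.5 * (a_t + a_t.transpose(0, 1, 3, 2, 4))

    ts = PropertyTensorSet(
        hessian=hessian,
        dipole_deriv=dip,
        alpha_deriv=alpha,
        gprime_deriv=gprime,
        a_deriv=a_t,
    )
    if roa_scale == 0.0:
        ts.gprime_deriv = np.zeros_like(gprime)
        ts.a_deriv = np.zeros_like(a_t)
        return ts
    import warnings

    modes = normal_modes(geometry, hessian)
    inv = mode_invariants(modes, ts)
    with warnings.catch_warnings():
        # near-zero eigenvalue noise is irrelevant to the calibration
        warnings.simplefilter("ignore", UserWarning)
        sticks = backscatter_sticks(modes, inv)
    ok = sticks.raman > 0
    ratio = np.median(np.abs(sticks.roa[ok]) / sticks.raman[ok])
    scale = roa_scale / ratio
    ts.gprime_deriv = gprime * scale
    ts.a_deriv = a_t * scale
    return ts


# ----------------------------------------------------------------------
# experiment-like spectra

def make_experiment_spectrum(
    bands: list[tuple[float, float, float]],
    baseline_coeffs: tuple[float, ...] = (),
    noise_sd: float = 0.0,
    seed: int = 0,
    fwhm: float = 10.0,
    water_height: float = 1.0,
    grid: np.ndarray | None = None,
) -> tuple[SpectrumPair, dict]:
    """An experiment-like spectrum pair with known ground truth.

    ``bands`` holds ``(center, raman_height, roa_height)`` triples
    (Lorentzian peaks of the given FWHM, heights not areas).  A water
    band at 1650 cm⁻¹ of ``water_height``, a polynomial fluorescence
    baseline (coefficients over the scaled abscissa, Raman channel
    only) and i.i.d. Gaussian noise are added on top.  Returns
    ``(pair, truth)`` with the truth record for recovery tests.
    """
    if grid is None:
        grid = default_grid(100.0, 1800.0)
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    gamma = 0.5 * fwhm

    def lorentz(center, height):
        return height * gamma**2 / ((grid - center) ** 2 + gamma**2)

    raman = lorentz(1650.0, water_height)
    roa = np.zeros_like(grid)
    for center, r_h, o_h in bands:
        raman = raman + lorentz(center, r_h)
        roa = roa + lorentz(center, o_h)
    x = 2.0 * (grid - grid[0]) / (grid[-1] - grid[0]) - 1.0
    baseline = (
        np.polynomial.polynomial.polyval(x, list(baseline_coeffs))
        if baseline_coeffs
        else np.zeros_like(grid)
    )
    raman_obs = raman + baseline + noise_sd * rng.standard_normal(len(grid))
    roa_obs = roa + 1.0e-3 * noise_sd * rng.standard_normal(len(grid))
    truth = {
        "bands": list(bands),
        "baseline_coeffs": tuple(baseline_coeffs),
        "noise_sd": noise_sd,
        "fwhm": fwhm,
        "water_height": water_height,
        "clean_raman": raman,
        "clean_roa": roa,
        "seed": seed,
    }
    pair = SpectrumPair(
        grid=grid, raman=raman_obs, roa=roa_obs, meta={"synthetic": True, "seed": seed}
    )
    return pair, truth


# marker-band tables for the canonical classifier fixtures; heights are
# relative to the water band (=1); ROA heights sit in the CID ~ 1e-3
# regime of the shared backbone bands
_COMMON_BANDS: list[tuple[float, float, float]] = [
    # amide I couplet: negative low / positive high lobe
    (1668.0, 0.85, 8.0e-4),
    (1630.0, 0.55, -6.0e-4),
    (1455.0, 0.45, 3.0e-4),
    (1345.0, 0.40, -2.5e-4),
    (1320.0, 0.38, 2.5e-4),
    (1268.0, 0.42, 2.8e-4),
    (1247.0, 0.40, -2.6e-4),
    (1033.0, 0.25, 1.5e-4),
    (874.0, 0.30, 1.6e-4),
    (856.0, 0.28, 0.0),
    (765.0, 0.20, -1.2e-4),
    (570.0, 0.22, 1.4e-4),
    (535.0, 0.24, 1.5e-4),
]

_FIXTURE_EXTRAS: dict[str, list[tuple[float, float, float]]] = {
    "type_I": [(473.0, 0.30, 6.0e-4), (300.0, 0.08, -1.0e-4)],
    "type_II": [(468.0, 0.10, 0.0), (306.0, 0.12, 0.0), (339.0, 0.12, -1.2e-4)],
    "denatured_I": [(221.0, 0.15, 0.0), (300.0, 0.04, 0.0)],
    "ambiguous": [(473.0, 0.30, 6.0e-4), (306.0, 0.12, 0.0), (339.0, 0.12, 0.0)],
}


def canonical_fixture(
    name: str,
    seed: int = 0,
    noise_sd: float = 0.002,
    baseline_coeffs: tuple[float, ...] = (0.3, -0.2, 0.15, 0.05),
) -> tuple[SpectrumPair, dict]:
    """The canonical classifier fixtures: ``type_I`` (positive 473 cm⁻¹
    ROA marker), ``type_II`` (306 + 339 cm⁻¹ Raman doublet),
    ``denatured_I`` (221 cm⁻¹ Raman band, weakened amide-I couplet)
    and ``ambiguous`` (conflicting evidence)."""
    if name not in _FIXTURE_EXTRAS:
        raise ValueError(
            f"unknown fixture {name!r}; choose from {sorted(_FIXTURE_EXTRAS)}"
        )
    bands = [list(b) for b in _COMMON_BANDS]
    if name == "denatured_I":
        # heat denaturation: amide-I ROA couplet much weaker
        for b in bands:
            if b[0] in (1668.0, 1630.0):
                b[2] *= 0.18
    bands = [tuple(b) for b in bands] + _FIXTURE_EXTRAS[name]
    return make_experiment_spectrum(
        bands,
        baseline_coeffs=baseline_coeffs,
        noise_sd=noise_sd,
        seed=seed,
    )


# ----------------------------------------------------------------------
# PPII-concentrated trajectories

def make_ppii_trajectory(
    sequence: str = "(PHG)3",
    n_snapshots: int = 100,
    kappa: float = 20.0,
    means: tuple[float, float] = (-75.0, 150.0),
    seed: int = 0,
    n_chains: int = 1,
) -> tuple[list[Geometry], dict]:
    """Snapshots of an idealized helix with (φ, ψ) sampled per residue
    and per frame from independent von Mises distributions centred on
    the PPII basin.  ``kappa`` is capped at 10⁶ (the rigid limit).
    Returns ``(trajectory, truth)``.
    """
    if n_snapshots < 1:
        raise ValueError("need at least one snapshot")
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    rigid = kappa >= 1.0e6  # treated as the exact zero-variance limit
    seq = parse_triplet_notation(sequence)
    rng = np.random.default_rng(seed)
    phi0, psi0 = means
    traj: list[Geometry] = []
    for _ in range(n_snapshots):
        if rigid:
            phi = np.full(len(seq), phi0)
            psi = np.full(len(seq), psi0)
        else:
            phi = np.degrees(rng.vonmises(np.radians(phi0), kappa, len(seq)))
            psi = np.degrees(rng.vonmises(np.radians(psi0), kappa, len(seq)))
        traj.append(
            build_helix(seq, phi=phi, psi=psi, n_chains=n_chains, check_clashes=False)
        )
    truth = {
        "sequence": sequence,
        "kappa": kappa,
        "means": means,
        "seed": seed,
        "n_snapshots": n_snapshots,
    }
    return traj, truth


def jittered_snapshots(
    geometry: Geometry, n_snapshots: int, sigma: float = 0.03, seed: int = 0
) -> list[Geometry]:
    """Gaussian coordinate jitter of one geometry — a stand-in for the
    geometry dispersion of a molecular-dynamics ensemble."""
    rng = np.random.default_rng(seed)
    return [
        geometry.with_coords(
            geometry.coords + sigma * rng.standard_normal(geometry.coords.shape)
        )
        for _ in range(n_snapshots)
    ]
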