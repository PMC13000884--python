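"""Harmonic normal-mode analysis and backscattered Raman/ROA synthesis.

Units: masses in Da, lengths in Å, Hessian elements in mdyn/Å
(= 100 N/m).  With these choices a harmonic eigenvalue λ in
mdyn/(Å·Da) converts to a wavenumber as ν̃ = √λ · ``FREQ_CONV`` with
``FREQ_CONV`` ≈ 1302.8 cm⁻¹, the single conversion constant of the
module.  The property tensors (α, G′, A derivatives) are treated as
atomic-unit quantities, so the ROA prefactor uses c = 137.036 a.u.
and the excitation angular frequency ν̃₀/219474.63 a.u.; only
normalized shapes and circular intensity difference (CID) ratios are
meaningful downstream, never absolute cross sections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import constants

from .geometry import Geometry, GeometryError
from .transfer import PropertyTensorSet

__all__ = [
    "FREQ_CONV",
    "EXCITATION_CM",
    "NormalModes",
    "StickSpectrum",
    "SpectrumPair",
    "normal_modes",
    "subspace_optimize",
    "mode_invariants",
    "backscatter_sticks",
    "default_grid",
    "convolve",
    "average_snapshots",
    "write_spectrum",
    "read_spectrum",
    "spectrum_from_tensors",
]

#: √(mdyn/(Å·Da)) → cm⁻¹
FREQ_CONV = float(
    np.sqrt(100.0 / constants.atomic_mass) / (2.0 * np.pi * constants.c * 100.0)
)

#: 532 nm laser excitation in vacuum wavenumbers
EXCITATION_CM = 1.0e7 / 532.0

#: hc/k_B in cm·K, for the Boltzmann factor
_HC_OVER_KB = constants.h * constants.c * 100.0 / constants.k

_C_AU = 137.035999  # speed of light in atomic units
_CM_PER_HARTREE = 219474.6313632


@dataclass
class NormalModes:
    """Vibrational modes after Eckart projection.

    ``frequencies`` are ascending wavenumbers in cm⁻¹ (imaginary modes
    reported as negative numbers); ``displacements`` holds the
    mass-weighted orthonormal mode vectors, shape ``(n_modes, N, 3)``;
    ``n_projected`` rigid-body modes were removed (6, or 5 for linear
    molecules).
    """

    frequencies: np.ndarray
    displacements: np.ndarray
    masses: np.ndarray
    n_projected: int

    @property
    def n_modes(self) -> int:
        return len(self.frequencies)

    def cartesian_displacements(self) -> np.ndarray:
        """Non-mass-weighted Cartesian displacement per mode, (n_modes, N, 3)."""
        return self.displacements / np.sqrt(self.masses)[None, :, None]


def _rigid_body_basis(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Orthonormal mass-weighted translation + rotation vectors,
    shape (3N, k) with k = 6 (5 for linear molecules)."""
    n = len(masses)
    sq = np.sqrt(masses)
    com = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    x = coords - com
    vecs = []
    for i in range(3):
        t = np.zeros((n, 3))
        t[:, i] = sq
        vecs.append(t.ravel())
    for i in range(3):
        e = np.zeros(3)
        e[i] = 1.0
        r = np.cross(x, e) * sq[:, None]
        vecs.append(r.ravel())
    B = np.array(vecs).T  # (3N, 6)
    q, r = np.linalg.qr(B)
    keep = np.abs(np.diag(r)) > 1e-8 * max(np.abs(np.diag(r)).max(), 1e-300)
    return q[:, keep]


def normal_modes(geometry: Geometry, hessian: np.ndarray) -> NormalModes:
    """Eckart-projected harmonic analysis of a Cartesian Hessian.

    The mass-weighted Hessian M^{-1/2} H M^{-1/2} is diagonalized in
    the orthogonal complement of the rigid-body space; frequencies are
    sign(λ)·√|λ|·``FREQ_CONV``.
    """
    n = geometry.n_atoms
    H = np.asarray(hessian, dtype=float)
    if H.shape != (3 * n, 3 * n):
        raise GeometryError(f"hessian shape {H.shape}, expected {(3 * n, 3 * n)}")
    scale = max(np.abs(H).max(), 1e-300)
    if np.abs(H - H.T).max() > 1e-8 * scale:
        raise GeometryError("hessian is not symmetric")
    masses = geometry.masses
    inv_sq = 1.0 / np.sqrt(np.repeat(masses, 3))
    Hmw = H * inv_sq[:, None] * inv_sq[None, :]
    B = _rigid_body_basis(geometry.coords, masses)
    # orthonormal complement of the rigid-body space
    proj = np.eye(3 * n) - B @ B.T
    u, s, _ = np.linalg.svd(proj)
    V = u[:, s > 0.5]
    lam, y = np.linalg.eigh(V.T @ Hmw @ V)
    freqs = np.sign(lam) * np.sqrt(np.abs(lam)) * FREQ_CONV
    order = np.argsort(freqs)
    modes = (V @ y).T[order].reshape(-1, n, 3)
    return NormalModes(
        frequencies=freqs[order],
        displacements=modes,
        masses=masses.copy(),
        n_projected=B.shape[1],
    )


def subspace_optimize(
    geometry: Geometry,
    energy_and_gradient,
    hessian: np.ndarray,
    freq_window: tuple[float, float],
    tol: float = 1e-8,
    max_iter: int = 200,
) -> Geometry:
    """Minimize the energy along normal modes inside ``freq_window``
    (cm⁻¹, on |ν̃|) while freezing all other collective coordinates.

    ``energy_and_gradient(coords) -> (E, grad)`` supplies the model
    force field (gradient shape (N, 3)).  Newton iterations use the
    supplied Hessian projected onto the selected-mode subspace, so a
    quadratic surface converges in a single step.  Coordinates along
    the frozen modes are unchanged exactly by construction.
    """
    modes = normal_modes(geometry, hessian)
    lo, hi = freq_window
    sel = (np.abs(modes.frequencies) >= lo) & (np.abs(modes.frequencies) <= hi)
    if not sel.any():
        raise ValueError("freq_window selects no modes")
    n = geometry.n_atoms
    D = (
        modes.displacements[sel].reshape(sel.sum(), -1)
        / np.sqrt(np.repeat(modes.masses, 3))[None, :]
    ).T  # (3N, m) Cartesian directions of the selected modes
    Hc = D.T @ np.asarray(hessian, dtype=float) @ D
    # guard against indefinite subspace Hessians
    w, Q = np.linalg.eigh(Hc)
    w = np.maximum(np.abs(w), 1e-10 * max(np.abs(w).max(), 1e-300))
    Hc_inv = Q @ np.diag(1.0 / w) @ Q.T

    x0 = geometry.coords.ravel()
    c = np.zeros(D.shape[1])
    for _ in range(max_iter):
        _, grad = energy_and_gradient((x0 + D @ c).reshape(n, 3))
        g = D.T @ np.asarray(grad, dtype=float).ravel()
        if np.abs(g).max() < tol:
            return geometry.with_coords((x0 + D @ c).reshape(n, 3))
        c = c - Hc_inv @ g
    _, grad = energy_and_gradient((x0 + D @ c).reshape(n, 3))
    g = D.T @ np.asarray(grad, dtype=float).ravel()
    if np.abs(g).max() < tol:
        return geometry.with_coords((x0 + D @ c).reshape(n, 3))
    raise RuntimeError(
        f"subspace optimization did not converge in {max_iter} iterations; "
        f"residual projected gradient {np.abs(g).max():.3e}"
    )


def mode_invariants(
    modes: NormalModes,
    tensors: PropertyTensorSet,
    excitation_cm: float = EXCITATION_CM,
) -> dict[str, np.ndarray]:
    """Far-from-resonance Raman/ROA tensor invariants per mode.

    The atomic derivative tensors are contracted with the Cartesian
    mode displacements to give α_p, G′_p and A_p, from which:

    - ``a2``: isotropic invariant a_p² with a_p = Tr(α_p)/3
    - ``beta_alpha2``: anisotropy β(α)_p² = (3 α:α − (Tr α)²)/2
    - ``beta_g2``: β(G′)_p² = (3 α_ij G′_ij − α_ii G′_jj)/2
    - ``beta_a2``: β(A)_p² = (ω/2) α_ij ε_ikl A_klj, with ω the
      excitation angular frequency (atomic units)
    """
    if tensors.n_atoms != modes.displacements.shape[1]:
        raise GeometryError("tensor set and modes have different atom counts")
    disp = modes.cartesian_displacements()  # (m, N, 3)
    alpha_p = np.einsum("aijb,mab->mij", tensors.alpha_deriv, disp, optimize=True)
    g_p = np.einsum("aijb,mab->mij", tensors.gprime_deriv, disp, optimize=True)
    a_p = np.einsum("aijkb,mab->mijk", tensors.a_deriv, disp, optimize=True)

    tr = np.trace(alpha_p, axis1=1, axis2=2)
    a2 = (tr / 3.0) ** 2
    aa = np.einsum("mij,mij->m", alpha_p, alpha_p)
    beta_alpha2 = 0.5 * (3.0 * aa - tr**2)
    ag = np.einsum("mij,mij->m", alpha_p, g_p)
    trg = np.trace(g_p, axis1=1, axis2=2)
    beta_g2 = 0.5 * (3.0 * ag - tr * trg)
    eps = np.zeros((3, 3, 3))
    for i, j, k in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
        eps[i, j, k] = 1.0
        eps[k, j, i] = -1.0
    omega = excitation_cm / _CM_PER_HARTREE
    beta_a2 = 0.5 * omega * np.einsum(
        "mij,ikl,mklj->m", alpha_p, eps, a_p, optimize=True
    )
    return {
        "a2": a2,
        "beta_alpha2": beta_alpha2,
        "beta_g2": beta_g2,
        "beta_a2": beta_a2,
    }


@dataclass
class StickSpectrum:
    """Per-mode Raman/ROA weights before lineshape convolution."""

    frequencies: np.ndarray
    raman: np.ndarray
    roa: np.ndarray

    def __add__(self, other: "StickSpectrum") -> "StickSpectrum":
        return StickSpectrum(
            frequencies=np.concatenate([self.frequencies, other.frequencies]),
            raman=np.concatenate([self.raman, other.raman]),
            roa=np.concatenate([self.roa, other.roa]),
        )


def boltzmann_factor(freqs_cm: np.ndarray, temperature: float) -> np.ndarray:
    """1/(1 − exp(−hcν̃/k_B T)); → 1 as T → 0 for positive ν̃."""
    freqs_cm = np.asarray(freqs_cm, dtype=float)
    if temperature <= 0.0:
        return np.ones_like(freqs_cm)
    return 1.0 / (1.0 - np.exp(-_HC_OVER_KB * freqs_cm / temperature))


def backscatter_sticks(
    modes: NormalModes,
    invariants: dict[str, np.ndarray],
    excitation_cm: float = EXCITATION_CM,
    temperature: float = 300.0,
    min_wavenumber: float = 50.0,
) -> StickSpectrum:
    """Backscattered SCP Raman and ROA stick weights.

    With the module's fixed convention the Raman weight is
    ``S_p = k_p (90 a_p² + 14 β(α)_p²)`` and the ROA weight
    ``D_p = k_p (4/c)(12 β(G′)_p² + 4 β(A)_p²)``, sharing the
    prefactor ``k_p = (ν̃₀−ν̃_p)⁴/ν̃_p · B(ν̃_p, T)`` with the
    Boltzmann factor B (the (ν̃₀−ν̃_p)⁴ factor is normalized by ν̃₀⁴
    to keep intensities of order 1/ν̃).  The global scale is
    arbitrary; modes with non-positive wavenumbers are skipped with a
    warning, and modes below ``min_wavenumber`` — the lower edge of
    the modelled spectral window, where the 1/ν̃_p prefactor diverges
    — are dropped silently.
    """
    freqs = modes.frequencies
    if excitation_cm <= np.max(freqs):
        raise ValueError("excitation wavenumber must exceed all mode wavenumbers")
    if np.any(freqs <= 0):
        warnings.warn(
            f"skipping {int((freqs <= 0).sum())} non-positive-wavenumber modes",
            stacklevel=2,
        )
    ok = freqs >= min_wavenumber
    f = freqs[ok]
    if len(f) == 0:
        return StickSpectrum(
            frequencies=f, raman=np.zeros(0), roa=np.zeros(0)
        )
    k = ((excitation_cm - f) / excitation_cm) ** 4 / f * boltzmann_factor(f, temperature)
    raman = k * (90.0 * invariants["a2"][ok] + 14.0 * invariants["beta_alpha2"][ok])
    roa = k * (4.0 / _C_AU) * (
        12.0 * invariants["beta_g2"][ok] + 4.0 * invariants["beta_a2"][ok]
    )
    return StickSpectrum(frequencies=f, raman=raman, roa=roa)


@dataclass
class SpectrumPair:
    """Raman (I_R + I_L) and ROA (I_R − I_L) intensities on one grid."""

    grid: np.ndarray
    raman: np.ndarray
    roa: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.raman = np.asarray(self.raman, dtype=float)
        self.roa = np.asarray(self.roa, dtype=float)
        if not (len(self.grid) == len(self.raman) == len(self.roa)):
            raise ValueError("grid/raman/roa length mismatch")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")

    def copy(self) -> "SpectrumPair":
        return SpectrumPair(
            grid=self.grid.copy(),
            raman=self.raman.copy(),
            roa=self.roa.copy(),
            meta=dict(self.meta),
        )


def default_grid(start: float = 50.0, stop: float = 1800.0, step: float = 1.0):
    """The module's default wavenumber grid (cm⁻¹)."""
    return np.arange(start, stop + 0.5 * step, step)


def convolve(
    sticks: StickSpectrum,
    fwhm: float = 10.0,
    grid: np.ndarray | None = None,
) -> SpectrumPair:
    """Broaden sticks with unit-area Lorentzians of the given FWHM.

    Each stick of weight w contributes w·(Γ/π)/((ν̃−ν̃_p)² + Γ²) with
    Γ = fwhm/2, so the integrated band area equals the stick weight.
    The grid must cover every stick ± 5·fwhm.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if len(sticks.frequencies):
        lo = max(sticks.frequencies.min() - 5.0 * fwhm, 0.0)
        hi = sticks.frequencies.max() + 5.0 * fwhm
        if grid[0] > lo or grid[-1] < hi:
            raise ValueError(
                f"grid [{grid[0]:.0f}, {grid[-1]:.0f}] too narrow for sticks "
                f"spanning [{lo:.0f}, {hi:.0f}] cm^-1 (± 5 FWHM)"
            )
    gamma = 0.5 * fwhm
    shapes = (gamma / np.pi) / (
        (grid[None, :] - sticks.frequencies[:, None]) ** 2 + gamma**2
    )
    return SpectrumPair(
        grid=grid,
        raman=sticks.raman @ shapes,
        roa=sticks.roa @ shapes,
        meta={"fwhm": fwhm},
    )


def average_snapshots(spectra: list[SpectrumPair]) -> SpectrumPair:
    """Unweighted pointwise mean of snapshot spectra (identical grids)."""
    if not spectra:
        raise ValueError("no spectra to average")
    grid = spectra[0].grid
    for sp in spectra[1:]:
        if len(sp.grid) != len(grid) or not np.allclose(sp.grid, grid, atol=1e-9):
            raise ValueError("snapshot spectra are on different grids")
    return SpectrumPair(
        grid=grid.copy(),
        raman=np.mean([sp.raman for sp in spectra], axis=0),
        roa=np.mean([sp.roa for sp in spectra], axis=0),
        meta=dict(spectra[0].meta, n_averaged=len(spectra)),
    )


def spectrum_from_tensors(
    geometry: Geometry,
    tensors: PropertyTensorSet,
    fwhm: float = 10.0,
    temperature: float = 300.0,
    excitation_cm: float = EXCITATION_CM,
    grid: np.ndarray | None = None,
) -> SpectrumPair:
    """Convenience chain: modes → invariants → sticks → convolution."""
    modes = normal_modes(geometry, tensors.hessian)
    inv = mode_invariants(modes, tensors, excitation_cm)
    sticks = backscatter_sticks(modes, inv, excitation_cm, temperature)
    if grid is None:
        hi = max(1800.0, sticks.frequencies.max() + 5.0 * fwhm + 1.0)
        lo = min(50.0, max(0.0, sticks.frequencies.min() - 5.0 * fwhm - 1.0))
        grid = default_grid(lo, hi)
    pair = convolve(sticks, fwhm=fwhm, grid=grid)
    pair.meta.update(
        excitation_cm=excitation_cm, temperature=temperature, fwhm=fwhm
    )
    return pair


# ----------------------------------------------------------------------
# 3-column TSV with '#' metadata header

def write_spectrum(pair: SpectrumPair, path) -> None:
    lines = ["# collagen_roa spectrum"]
    for key in sorted(pair.meta):
        lines.append(f"# {key} = {pair.meta[key]}")
    lines.append("# wavenumber_cm-1\traman\troa")
    for g, r, o in zip(pair.grid, pair.raman, pair.roa):
        lines.append(f"{g:.4f}\t{r:.10e}\t{o:.10e}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_spectrum(path) -> SpectrumPair:
    meta: dict = {}
    grid, raman, roa = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line.lstrip("# ").partition("=")
                    try:
                        meta[key.strip()] = float(val)
                    except ValueError:
                        meta[key.strip()] = val.strip()
                continue
            g, r, o = line.split("\t")
            grid.append(float(g))
            raman.append(float(r))
            roa.append(float(o))
    return SpectrumPair(
        grid=np.array(grid), raman=np.array(raman), roa=np.array(roa), meta=meta
    )
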