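"""Backbone dihedrals, Ramachandran free-energy surfaces and
triplet segment-length statistics for peptide trajectories."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Geometry, GeometryError

KB_KJ_MOL = 0.008314462618  # Boltzmann constant, kJ/(mol·K)

__all__ = [
    "dihedral",
    "DihedralSeries",
    "backbone_dihedrals",
    "FreeEnergySurface",
    "ramachandran_surface",
    "segment_lengths",
]


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, IUPAC convention.

    Zero for a planar *cis* (eclipsed) arrangement, 180° for *trans*;
    the sign flips under reflection and is preserved by proper rigid
    motions.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    if min(np.linalg.norm(b) for b in (b1, b2, b3)) < 1e-10:
        raise GeometryError("coincident points in dihedral")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise GeometryError("collinear points in dihedral")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = np.degrees(np.arctan2(m @ n2, n1 @ n2))
    return 180.0 if np.isclose(ang, -180.0) else float(ang)


@dataclass
class DihedralSeries:
    """Per-residue φ/ψ time series in degrees.

    ``phi[t, r]`` / ``psi[t, r]`` are NaN where the dihedral does not
    exist (the chain-terminal residues); ``labels[r]`` is the
    ``(chain_id, residue_index, residue_code)`` triple.
    """

    phi: np.ndarray
    psi: np.ndarray
    labels: list[tuple[str, int, str]]

    @property
    def n_snapshots(self) -> int:
        return self.phi.shape[0]


def backbone_dihedrals(trajectory: list[Geometry]) -> DihedralSeries:
    """Measure φ (C⁻¹–N–Cα–C) and ψ (N–Cα–C–N⁺¹) for every residue of
    every snapshot.  All snapshots must share the first snapshot's
    labelling."""
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    ref = trajectory[0]
    residues = ref.residues()
    labels = [(c, r, code) for c, r, code, _ in residues]
    quads_phi: list[tuple[int, ...] | None] = []
    quads_psi: list[tuple[int, ...] | None] = []
    for c, r, _, _ in residues:
        n = ref.atom_index(c, r, "N")
        ca = ref.atom_index(c, r, "CA")
        cc = ref.atom_index(c, r, "C")
        c_prev = ref.atom_index(c, r - 1, "C")
        n_next = ref.atom_index(c, r + 1, "N")
        quads_phi.append((c_prev, n, ca, cc) if c_prev >= 0 else None)
        quads_psi.append((n, ca, cc, n_next) if n_next >= 0 else None)
    n_res = len(labels)
    phi = np.full((len(trajectory), n_res), np.nan)
    psi = np.full((len(trajectory), n_res), np.nan)
    for t, snap in enumerate(trajectory):
        x = snap.coords
        for r in range(n_res):
            if quads_phi[r] is not None:
                i, j, k, l = quads_phi[r]
                phi[t, r] = dihedral(x[i], x[j], x[k], x[l])
            if quads_psi[r] is not None:
                i, j, k, l = quads_psi[r]
                psi[t, r] = dihedral(x[i], x[j], x[k], x[l])
    return DihedralSeries(phi=phi, psi=psi, labels=labels)


@dataclass
class FreeEnergySurface:
    """Periodic (φ, ψ) free-energy surface G = −k_B·T·ln(n/n_max).

    Empty bins carry ``+inf``; the most populated bin is exactly zero.
    """

    phi_edges: np.ndarray
    psi_edges: np.ndarray
    counts: np.ndarray
    free_energy: np.ndarray
    temperature: float

    @property
    def minimum_bin(self) -> tuple[float, float]:
        """(φ, ψ) centre of the global minimum bin."""
        i, j = np.unravel_index(np.argmax(self.counts), self.counts.shape)
        return (
            float(0.5 * (self.phi_edges[i] + self.phi_edges[i + 1])),
            float(0.5 * (self.psi_edges[j] + self.psi_edges[j + 1])),
        )


def _wrap(angles: np.ndarray) -> np.ndarray:
    """Wrap degrees into (−180, 180]."""
    a = np.mod(np.asarray(angles, dtype=float) + 180.0, 360.0) - 180.0
    a[np.isclose(a, -180.0)] = 180.0
    return a


def ramachandran_surface(
    series: DihedralSeries,
    residue_selector=None,
    bins: int = 36,
    temperature: float = 300.0,
) -> FreeEnergySurface:
    """Periodic 2-D (φ, ψ) histogram over selected residues, converted
    to a free-energy surface at the given temperature.

    ``residue_selector`` is ``None`` (all residues with both dihedrals),
    a residue code like ``"Pro"``, or a callable on the label triple.
    """
    if residue_selector is None:
        mask = np.ones(len(series.labels), dtype=bool)
    elif callable(residue_selector):
        mask = np.array([bool(residue_selector(lbl)) for lbl in series.labels])
    else:
        mask = np.array([lbl[2] == residue_selector for lbl in series.labels])
    if not mask.any():
        raise ValueError("residue selection is empty")
    phi = series.phi[:, mask].ravel()
    psi = series.psi[:, mask].ravel()
    ok = ~(np.isnan(phi) | np.isnan(psi))
    phi, psi = _wrap(phi[ok]), _wrap(psi[ok])
    if len(phi) == 0:
        raise ValueError("no defined (phi, psi) samples in selection")
    edges = np.linspace(-180.0, 180.0, bins + 1)
    counts, pe, se = np.histogram2d(phi, psi, bins=[edges, edges])
    with np.errstate(divide="ignore"):
        g = -KB_KJ_MOL * temperature * np.log(counts / counts.max())
    g[counts == 0] = np.inf
    return FreeEnergySurface(
        phi_edges=pe, psi_edges=se, counts=counts, free_energy=g,
        temperature=temperature,
    )


def segment_lengths(
    trajectory: list[Geometry],
    triplet_spec: tuple[str, str, str] | str,
    bins: int = 30,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cα(i)→Cα(i+3) distances over every occurrence of a residue
    triplet, per snapshot.

    ``triplet_spec`` is e.g. ``("Pro", "Hyp", "Gly")`` or the string
    ``"Pro-Hyp-Gly"``.  Returns ``(lengths, counts, bin_edges)`` where
    ``lengths`` pools all matches and snapshots.
    """
    if isinstance(triplet_spec, str):
        triplet_spec = tuple(triplet_spec.split("-"))
    if len(triplet_spec) != 3:
        raise ValueError("triplet_spec must name exactly three residues")
    ref = trajectory[0]
    residues = ref.residues()
    by_chain: dict[str, list[tuple[int, str]]] = {}
    for c, r, code, _ in residues:
        by_chain.setdefault(c, []).append((r, code))
    pairs: list[tuple[int, int]] = []  # (CA_i, CA_{i+3}) atom indices
    for c, res_list in by_chain.items():
        res_list.sort()
        codes = [code for _, code in res_list]
        ids = [r for r, _ in res_list]
        for k in range(len(codes) - 3):
            if tuple(codes[k : k + 3]) == tuple(triplet_spec):
                a = ref.atom_index(c, ids[k], "CA")
                b = ref.atom_index(c, ids[k + 3], "CA")
                if a >= 0 and b >= 0:
                    pairs.append((a, b))
    if not pairs:
        raise ValueError(f"triplet pattern {'-'.join(triplet_spec)} not found")
    lengths = np.array(
        [
            np.linalg.norm(snap.coords[a] - snap.coords[b])
            for snap in trajectory
            for a, b in pairs
        ]
    )
    if np.ptp(lengths) < 1e-6:  # rigid body: all lengths identical
        v = float(np.median(lengths))
        # offset the range so the common value sits inside a bin, not on
        # an edge where rounding could split it
        counts, edges = np.histogram(lengths, bins=bins, range=(v - 0.51, v + 0.49))
    else:
        counts, edges = np.histogram(lengths, bins=bins)
    return lengths, counts, edges
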