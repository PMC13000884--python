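"""Cartesian property-tensor transfer between similar geometries.

Per-atom derivative tensors (dipole, electric-dipole polarizability α,
electric-dipole–magnetic-dipole G′ and electric-dipole–electric-
quadrupole A) computed on small capped fragments are mapped onto a
parent or snapshot geometry: for every atom a best-fit (Kabsch) proper
rotation between its local neighbourhood in the fragment and in the
target is found, each tensor is rotated with one copy of the rotation
per Cartesian axis, and contributions from all fragments containing
the atom are averaged.  Hessian 3×3 blocks are stitched pairwise;
blocks for atom pairs never co-resident in a fragment are zero (the
long-range force constants are dropped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fragmentation import Fragment
from .geometry import Geometry, GeometryError

__all__ = [
    "PropertyTensorSet",
    "LocalFrameMatch",
    "kabsch_rotation",
    "local_rotation",
    "rotate_cartesian_tensor",
    "transfer",
    "mirror_image",
    "save_tensor_set",
    "load_tensor_set",
    "geometry_checksum",
]


@dataclass
class PropertyTensorSet:
    """Per-atom Cartesian property-tensor derivatives for one geometry.

    Shapes for ``N`` atoms (last axis is always the displacement
    component β of the owning atom):

    - ``hessian``: (3N, 3N), symmetric
    - ``dipole_deriv``: (N, 3, 3) — μ_i × β
    - ``alpha_deriv``: (N, 3, 3, 3) — α_ij × β, symmetric in i, j
    - ``gprime_deriv``: (N, 3, 3, 3) — G′_ij × β
    - ``a_deriv``: (N, 3, 3, 3, 3) — A_ijk × β, symmetric in j, k
    """

    hessian: np.ndarray
    dipole_deriv: np.ndarray
    alpha_deriv: np.ndarray
    gprime_deriv: np.ndarray
    a_deriv: np.ndarray

    @property
    def n_atoms(self) -> int:
        return self.dipole_deriv.shape[0]

    def validate(self, geometry: Geometry | None = None, rtol: float = 1e-10) -> None:
        n = self.n_atoms
        if geometry is not None and geometry.n_atoms != n:
            raise GeometryError("tensor set does not match geometry atom count")
        if self.hessian.shape != (3 * n, 3 * n):
            raise GeometryError("hessian has wrong shape")
        scale = max(np.abs(self.hessian).max(), 1e-300)
        if np.abs(self.hessian - self.hessian.T).max() > rtol * scale:
            raise GeometryError("hessian is not symmetric")
        if np.abs(self.alpha_deriv - self.alpha_deriv.transpose(0, 2, 1, 3)).max() > (
            rtol * max(np.abs(self.alpha_deriv).max(), 1e-300)
        ):
            raise GeometryError("alpha derivative not symmetric in i, j")
        if np.abs(self.a_deriv - self.a_deriv.transpose(0, 1, 3, 2, 4)).max() > (
            rtol * max(np.abs(self.a_deriv).max(), 1e-300)
        ):
            raise GeometryError("A derivative not symmetric in j, k")

    def copy(self) -> "PropertyTensorSet":
        return PropertyTensorSet(
            hessian=self.hessian.copy(),
            dipole_deriv=self.dipole_deriv.copy(),
            alpha_deriv=self.alpha_deriv.copy(),
            gprime_deriv=self.gprime_deriv.copy(),
            a_deriv=self.a_deriv.copy(),
        )

    # ------------------------------------------------------------------
    def rotated(self, rotation: np.ndarray) -> "PropertyTensorSet":
        """The tensor set after a global proper rotation of the molecule."""
        R = _check_rotation(rotation, allow_improper=False)
        return self._transformed(R, det=1.0)

    def _transformed(self, R: np.ndarray, det: float) -> "PropertyTensorSet":
        n = self.n_atoms
        h = self.hessian.reshape(n, 3, n, 3)
        h2 = np.einsum("ij,ajbk,lk->aibl", R, h, R, optimize=True)
        return PropertyTensorSet(
            hessian=h2.reshape(3 * n, 3 * n),
            dipole_deriv=np.einsum("ij,ajb,cb->aic", R, self.dipole_deriv, R,
                                   optimize=True),
            alpha_deriv=np.einsum("ip,jq,apqb,cb->aijc", R, R, self.alpha_deriv,
                                  R, optimize=True),
            gprime_deriv=det * np.einsum("ip,jq,apqb,cb->aijc", R, R,
                                         self.gprime_deriv, R, optimize=True),
            a_deriv=np.einsum("ip,jq,kr,apqrb,cb->aijkc", R, R, R, self.a_deriv,
                              R, optimize=True),
        )


def mirror_image(
    geometry: Geometry, tensors: PropertyTensorSet
) -> tuple[Geometry, PropertyTensorSet]:
    """The enantiomeric system: coordinates reflected through the xy
    plane and tensors transformed accordingly.

    Polar tensors (Hessian, dipole, α, A) pick up one copy of the
    reflection per Cartesian axis; the axial G′ tensor acquires an
    extra factor det(S) = −1, which is what flips the sign of every
    chirality-odd observable downstream.
    """
    S = np.diag([1.0, 1.0, -1.0])
    mirrored_geom = geometry.with_coords(geometry.coords @ S)
    return mirrored_geom, tensors._transformed(S, det=-1.0)


@dataclass
class LocalFrameMatch:
    """Best-fit local rotation for one atom's neighbourhood."""

    atom_index: int
    rotation: np.ndarray
    rmsd: float
    support: np.ndarray


def _check_rotation(R: np.ndarray, allow_improper: bool = False) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3) or np.abs(R @ R.T - np.eye(3)).max() > 1e-8:
        raise ValueError("matrix is not orthogonal")
    if not allow_improper and np.linalg.det(R) < 0:
        raise ValueError("improper rotation (det = -1) rejected")
    return R


def kabsch_rotation(
    source: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, float]:
    """Least-squares proper rotation R with R·(source−c) ≈ target−c′.

    Returns ``(R, rmsd)``.  The determinant is forced to +1 (mirror
    fits are never returned silently).
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    src_c = src - src.mean(axis=0)
    tgt_c = tgt - tgt.mean(axis=0)
    H = src_c.T @ tgt_c
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    rmsd = float(np.sqrt(((src_c @ R.T - tgt_c) ** 2).sum(axis=1).mean()))
    return R, rmsd


def local_rotation(
    source: Geometry,
    target: Geometry,
    atom_map: np.ndarray,
    atom: int,
    n_neighbors: int = 12,
) -> LocalFrameMatch:
    """Best-fit proper rotation aligning the source neighbourhood of
    ``atom`` onto the corresponding target neighbourhood.

    The support is the atom itself plus its ``n_neighbors`` nearest
    mapped atoms in the source geometry (ties broken by lower index).
    ``atom_map[i]`` gives the target index of source atom ``i`` (−1
    for unmapped atoms such as caps).
    """
    atom_map = np.asarray(atom_map, dtype=int)
    if atom_map[atom] < 0:
        raise GeometryError(f"atom {atom} is not mapped to the target")
    mapped = np.nonzero(atom_map >= 0)[0]
    others = mapped[mapped != atom]
    if len(others) < 3:
        raise GeometryError(f"atom {atom}: fewer than 3 mapped neighbors")
    dists = np.linalg.norm(source.coords[others] - source.coords[atom], axis=1)
    # stable sort on (distance, index) implements the lower-index tie break
    order = np.lexsort((others, dists))
    support = np.concatenate([[atom], others[order[:n_neighbors]]])
    src = source.coords[support]
    tgt = target.coords[atom_map[support]]
    if np.linalg.matrix_rank(src - src.mean(axis=0), tol=1e-8) < 2:
        raise GeometryError(f"atom {atom}: collinear neighborhood support")
    R, rmsd = kabsch_rotation(src, tgt)
    return LocalFrameMatch(atom_index=atom, rotation=R, rmsd=rmsd, support=support)


def rotate_cartesian_tensor(T: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Rotate a rank-n Cartesian tensor: one copy of R per axis.

    Rank-2 case: ``R · T · Rᵀ``.
    """
    R = _check_rotation(R, allow_improper=True)
    T = np.asarray(T, dtype=float)
    if any(s != 3 for s in T.shape):
        raise ValueError("every axis of T must have length 3")
    out = T
    for axis in range(T.ndim):
        out = np.tensordot(R, np.moveaxis(out, axis, 0), axes=([1], [0]))
        out = np.moveaxis(out, 0, axis)
    return out


def _fragment_weights(fragment: Fragment) -> np.ndarray:
    """Per-atom transfer weight: 1 + distance (in amide units) of the
    atom's residue from the nearer fragment edge.  Interior residues
    of a fragment therefore dominate the average."""
    geom = fragment.geometry
    s, e = fragment.amide_range
    # residues spanned are s .. e (chain-local ids relative to window)
    res = np.array(
        [int(r) if not c else -1
         for r, c in zip(geom.residue_indices, fragment.is_cap)]
    )
    first = res[res >= 0].min()
    last = res[res >= 0].max()
    w = np.ones(geom.n_atoms)
    for i in range(geom.n_atoms):
        if res[i] >= 0:
            w[i] = 1.0 + min(res[i] - first, last - res[i])
    return w


def transfer(
    fragments: list[tuple[Fragment, PropertyTensorSet]],
    target: Geometry,
    n_neighbors: int = 12,
    weighting: str = "edge-distance",
    enforce_sum_rule: bool = True,
) -> PropertyTensorSet:
    """Stitch fragment tensor sets onto ``target``.

    Every target atom must be mapped by at least one fragment.  Per-atom
    tensors are weighted averages of the locally rotated fragment
    contributions; Hessian blocks (a, b) average over fragments holding
    both atoms and are rotated as ``R_a · H_ab · R_bᵀ``; the result is
    symmetrized.

    With ``enforce_sum_rule`` the diagonal Hessian blocks are rebuilt
    from the acoustic sum rule H_aa = −Σ_{b≠a} H_ab, restoring the
    translational invariance that block-wise averaging (and the capped
    fragment edges) would otherwise break.  For inputs that already
    satisfy the sum rule — any translation-invariant force field —
    this is exact on self-transfer.
    """
    if weighting not in ("edge-distance", "uniform"):
        raise ValueError(f"unknown weighting {weighting!r}")
    n = target.n_atoms
    covered = np.zeros(n, dtype=bool)
    for fr, ts in fragments:
        ts.validate(fr.geometry)
        covered[fr.mapped_parent_atoms] = True
    if not covered.all():
        missing = np.nonzero(~covered)[0]
        raise GeometryError(
            f"target atoms not covered by any fragment: {missing.tolist()[:20]}"
        )

    dip = np.zeros((n, 3, 3))
    alp = np.zeros((n, 3, 3, 3))
    gpr = np.zeros((n, 3, 3, 3))
    ad = np.zeros((n, 3, 3, 3, 3))
    wsum = np.zeros(n)
    hess = np.zeros((n, 3, n, 3))
    hwsum = np.zeros((n, n))

    for fr, ts in fragments:
        geom = fr.geometry
        amap = fr.atom_map
        frag_atoms = np.nonzero(~fr.is_cap)[0]
        w_atom = (
            _fragment_weights(fr)
            if weighting == "edge-distance"
            else np.ones(geom.n_atoms)
        )
        # local rotations for every mapped atom of this fragment
        rots = np.empty((len(frag_atoms), 3, 3))
        for k, i in enumerate(frag_atoms):
            match = local_rotation(geom, target, amap, int(i), n_neighbors)
            rots[k] = match.rotation
        parents = amap[frag_atoms]
        w = w_atom[frag_atoms]

        # β (displacement) axis and value axes all rotate
        dip_f = np.einsum("kip,kpb,kqb->kiq", rots, ts.dipole_deriv[frag_atoms],
                          rots, optimize=True)
        alp_f = np.einsum("kip,kjq,kpqb,krb->kijr", rots, rots,
                          ts.alpha_deriv[frag_atoms], rots, optimize=True)
        gpr_f = np.einsum("kip,kjq,kpqb,krb->kijr", rots, rots,
                          ts.gprime_deriv[frag_atoms], rots, optimize=True)
        ad_f = np.einsum("kip,kjq,klr,kpqrb,ksb->kijls", rots, rots, rots,
                         ts.a_deriv[frag_atoms], rots, optimize=True)
        np.add.at(dip, parents, w[:, None, None] * dip_f)
        np.add.at(alp, parents, w[:, None, None, None] * alp_f)
        np.add.at(gpr, parents, w[:, None, None, None] * gpr_f)
        np.add.at(ad, parents, w[:, None, None, None, None] * ad_f)
        np.add.at(wsum, parents, w)

        # Hessian blocks within the fragment
        hfrag = ts.hessian.reshape(geom.n_atoms, 3, geom.n_atoms, 3)
        hfrag = hfrag[np.ix_(frag_atoms, range(3), frag_atoms, range(3))]
        hrot = np.einsum("aij,ajbk,blk->aibl", rots, hfrag, rots, optimize=True)
        wpair = w[:, None] * w[None, :]
        hess[np.ix_(parents, range(3), parents, range(3))] += (
            wpair[:, None, :, None] * hrot
        )
        hwsum[np.ix_(parents, parents)] += wpair

    dip /= wsum[:, None, None]
    alp /= wsum[:, None, None, None]
    gpr /= wsum[:, None, None, None]
    ad /= wsum[:, None, None, None, None]
    nz = hwsum > 0
    scale = np.where(nz, hwsum, 1.0)
    hess /= scale[:, None, :, None]
    if enforce_sum_rule:
        for a in range(n):
            off = hess[a].sum(axis=1) - hess[a, :, a, :]
            hess[a, :, a, :] = -off
    H = hess.reshape(3 * n, 3 * n)
    H = 0.5 * (H + H.T)

    result = PropertyTensorSet(
        hessian=H, dipole_deriv=dip, alpha_deriv=alp, gprime_deriv=gpr, a_deriv=ad
    )
    # enforce exact index symmetries that averaging preserves only to rounding
    result.alpha_deriv = 0.5 * (
        result.alpha_deriv + result.alpha_deriv.transpose(0, 2, 1, 3)
    )
    result.a_deriv = 0.5 * (result.a_deriv + result.a_deriv.transpose(0, 1, 3, 2, 4))
    return result


# ----------------------------------------------------------------------
# serialization: JSON for small systems, NumPy .npz for large ones

_TENSOR_FIELDS = ("hessian", "dipole_deriv", "alpha_deriv", "gprime_deriv", "a_deriv")


def geometry_checksum(geometry: Geometry) -> str:
    """SHA-256 over elements and coordinates rounded to 10⁻⁶ Å."""
    import hashlib

    h = hashlib.sha256()
    h.update(",".join(str(e) for e in geometry.elements).encode())
    h.update(np.round(geometry.coords, 6).tobytes())
    return h.hexdigest()


def save_tensor_set(
    tensors: PropertyTensorSet, path, geometry: Geometry | None = None
) -> None:
    """Write a tensor set; ``.json`` gives a readable container,
    anything else a compressed ``.npz``.  The geometry checksum guards
    against applying tensors to the wrong structure."""
    import json
    from pathlib import Path

    path = Path(path)
    checksum = geometry_checksum(geometry) if geometry is not None else ""
    if path.suffix == ".json":
        payload = {name: getattr(tensors, name).tolist() for name in _TENSOR_FIELDS}
        payload["geometry_checksum"] = checksum
        with open(path, "w") as fh:
            json.dump(payload, fh)
    else:
        arrays = {name: getattr(tensors, name) for name in _TENSOR_FIELDS}
        np.savez_compressed(
            path, geometry_checksum=np.array(checksum), **arrays
        )


def load_tensor_set(path, geometry: Geometry | None = None) -> PropertyTensorSet:
    """Read a tensor set written by :func:`save_tensor_set`, verifying
    the geometry checksum when a geometry is supplied."""
    import json
    from pathlib import Path

    path = Path(path)
    if path.suffix == ".json":
        with open(path) as fh:
            payload = json.load(fh)
        checksum = payload.pop("geometry_checksum", "")
        ts = PropertyTensorSet(
            **{name: np.asarray(payload[name], dtype=float) for name in _TENSOR_FIELDS}
        )
    else:
        with np.load(path) as data:
            checksum = str(data["geometry_checksum"])
            ts = PropertyTensorSet(**{name: data[name] for name in _TENSOR_FIELDS})
    if geometry is not None and checksum and checksum != geometry_checksum(geometry):
        raise GeometryError("tensor set checksum does not match the geometry")
    return ts
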