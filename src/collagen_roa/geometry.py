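"""Molecular geometries with chain/residue/amide-unit labelling.

The :class:`Geometry` container is deliberately light: element symbols,
monoisotopic masses, Cartesian coordinates in Å and per-atom labels
(chain, residue index, residue code, atom name).  Amide units — one
C(=O)–N group per peptide bond — are derived from the labels and drive
the overlapping-fragment machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Monoisotopic masses (Da) of the most abundant isotope.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
}

MIN_ATOM_SEPARATION = 0.5  # Å; below this two atoms are considered clashing


class GeometryError(ValueError):
    """Raised for inconsistent or degenerate molecular geometries."""


@dataclass
class Geometry:
    """A labelled molecular geometry.

    Parameters
    ----------
    elements
        Element symbols, shape ``(N,)``.
    coords
        Cartesian coordinates in Å, shape ``(N, 3)``.
    masses
        Atomic masses in Da; defaults to monoisotopic masses by element.
    chain_ids, residue_indices, residue_codes, atom_names
        Per-atom labels.  ``residue_indices`` are 0-based within a chain.
    """

    elements: np.ndarray
    coords: np.ndarray
    masses: np.ndarray | None = None
    chain_ids: np.ndarray | None = None
    residue_indices: np.ndarray | None = None
    residue_codes: np.ndarray | None = None
    atom_names: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.elements)
        if self.coords.shape != (n, 3):
            raise GeometryError(
                f"coords shape {self.coords.shape} inconsistent with {n} atoms"
            )
        if self.masses is None:
            try:
                self.masses = np.array(
                    [MONOISOTOPIC_MASS[e] for e in self.elements], dtype=float
                )
            except KeyError as exc:  # pragma: no cover - defensive
                raise GeometryError(f"no tabulated mass for element {exc}") from exc
        else:
            self.masses = np.asarray(self.masses, dtype=float)
        for name in ("chain_ids", "residue_indices", "residue_codes", "atom_names"):
            val = getattr(self, name)
            if val is not None:
                arr = np.asarray(val, dtype=object)
                if len(arr) != n:
                    raise GeometryError(f"{name} length mismatch")
                setattr(self, name, arr)

    # ------------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def is_labeled(self) -> bool:
        return (
            self.chain_ids is not None
            and self.residue_indices is not None
            and self.residue_codes is not None
            and self.atom_names is not None
        )

    def copy(self) -> "Geometry":
        g = replace(self)
        g.coords = self.coords.copy()
        g.masses = self.masses.copy()
        return g

    def with_coords(self, coords: np.ndarray) -> "Geometry":
        g = self.copy()
        g.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        if g.coords.shape != self.coords.shape:
            raise GeometryError("with_coords: shape mismatch")
        return g

    # ------------------------------------------------------------------
    def check_clashes(self, min_separation: float = MIN_ATOM_SEPARATION) -> None:
        """Raise :class:`GeometryError` if any two atoms are closer than
        ``min_separation`` Å."""
        from scipy.spatial.distance import pdist

        if self.n_atoms < 2:
            return
        d = pdist(self.coords)
        if d.min() < min_separation:
            raise GeometryError(
                f"steric clash: minimum interatomic distance {d.min():.3f} Å "
                f"< {min_separation} Å; consider different rise parameters"
            )

    def atom_index(self, chain_id: str, residue_index: int, atom_name: str) -> int:
        """Index of a uniquely labelled atom; -1 if absent."""
        mask = (
            (self.chain_ids == chain_id)
            & (self.residue_indices == residue_index)
            & (self.atom_names == atom_name)
        )
        idx = np.nonzero(mask)[0]
        return int(idx[0]) if len(idx) else -1

    def residues(self) -> list[tuple[str, int, str, np.ndarray]]:
        """Ordered list of ``(chain_id, residue_index, residue_code,
        atom_indices)`` grouped along the chains."""
        if not self.is_labeled:
            raise GeometryError("geometry has no residue labels")
        out: list[tuple[str, int, str, np.ndarray]] = []
        seen: dict[tuple[str, int], int] = {}
        for i in range(self.n_atoms):
            key = (str(self.chain_ids[i]), int(self.residue_indices[i]))
            if key not in seen:
                seen[key] = len(out)
                out.append((key[0], key[1], str(self.residue_codes[i]), []))
        for i in range(self.n_atoms):
            key = (str(self.chain_ids[i]), int(self.residue_indices[i]))
            out[seen[key]][3].append(i)
        return [(c, r, code, np.array(idx, dtype=int)) for c, r, code, idx in out]

    def amide_units(self) -> list[np.ndarray]:
        """Atom-index groups, one per peptide bond, ordered along the chains.

        An amide unit is the C(=O)–N group joining residue *i* to residue
        *i + 1* of the same chain: indices ``[C_i, O_i, N_{i+1}]``.
        """
        res = self.residues()
        by_key = {(c, r): idx for c, r, _, idx in res}
        units: list[np.ndarray] = []
        for c, r, _, idx in res:
            nxt = by_key.get((c, r + 1))
            if nxt is None:
                continue
            ci = self.atom_index(c, r, "C")
            oi = self.atom_index(c, r, "O")
            ni = self.atom_index(c, r + 1, "N")
            if ci < 0 or ni < 0:
                raise GeometryError(
                    f"cannot form amide unit after residue {r} of chain {c}: "
                    "missing backbone C or N"
                )
            unit = [ci] + ([oi] if oi >= 0 else []) + [ni]
            units.append(np.array(unit, dtype=int))
        return units


# ----------------------------------------------------------------------
# XYZ read/write (two-line header + "El x y z" records)

def write_xyz(geometry: Geometry, path, comment: str = "") -> None:
    lines = [str(geometry.n_atoms), comment.replace("\n", " ")]
    for el, (x, y, z) in zip(geometry.elements, geometry.coords):
        lines.append(f"{el:<2s} {x:18.10f} {y:18.10f} {z:18.10f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_xyz(path) -> Geometry:
    with open(path) as fh:
        lines = fh.read().splitlines()
    n = int(lines[0].strip())
    elements, coords = [], []
    for line in lines[2 : 2 + n]:
        parts = line.split()
        elements.append(parts[0])
        coords.append([float(v) for v in parts[1:4]])
    return Geometry(elements=np.array(elements, dtype=object), coords=np.array(coords))


def write_xyz_trajectory(geometries: list[Geometry], path) -> None:
    """Concatenated multi-frame XYZ."""
    chunks = []
    for i, g in enumerate(geometries):
        lines = [str(g.n_atoms), f"frame {i}"]
        for el, (x, y, z) in zip(g.elements, g.coords):
            lines.append(f"{el:<2s} {x:18.10f} {y:18.10f} {z:18.10f}")
        chunks.append("\n".join(lines))
    with open(path, "w") as fh:
        fh.write("\n".join(chunks) + "\n")


def read_xyz_trajectory(path) -> list[Geometry]:
    with open(path) as fh:
        lines = fh.read().splitlines()
    out, i = [], 0
    while i < len(lines) and lines[i].strip():
        n = int(lines[i].strip())
        elements, coords = [], []
        for line in lines[i + 2 : i + 2 + n]:
            parts = line.split()
            elements.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
        out.append(
            Geometry(elements=np.array(elements, dtype=object), coords=np.array(coords))
        )
        i += 2 + n
    return out


# ----------------------------------------------------------------------
# PDB read/write through biotite (labels preserved; 1-based residue ids)

_PDB_RES_NAMES = {"Pro": "PRO", "Hyp": "HYP", "Gly": "GLY", "Ala": "ALA"}
_PDB_RES_CODES = {v: k for k, v in _PDB_RES_NAMES.items()}


def _to_atom_array(geometry: Geometry):
    import biotite.structure as struc

    n = geometry.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = geometry.coords.astype(np.float32)
    arr.element = np.array([str(e).upper() for e in geometry.elements])
    if geometry.is_labeled:
        arr.chain_id = np.array([str(c) for c in geometry.chain_ids])
        arr.res_id = np.array(
            [int(r) + 1 for r in geometry.residue_indices], dtype=int
        )
        arr.res_name = np.array(
            [_PDB_RES_NAMES.get(str(c), str(c)[:3].upper()) for c in geometry.residue_codes]
        )
        arr.atom_name = np.array([str(a) for a in geometry.atom_names])
    else:
        arr.chain_id = np.full(n, "A")
        arr.res_id = np.ones(n, dtype=int)
        arr.res_name = np.full(n, "UNK")
        arr.atom_name = arr.element
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def _from_atom_array(arr) -> Geometry:
    codes = np.array(
        [_PDB_RES_CODES.get(str(rn), str(rn)) for rn in arr.res_name], dtype=object
    )
    elements = np.array([e.capitalize() for e in arr.element], dtype=object)
    return Geometry(
        elements=elements,
        coords=np.asarray(arr.coord, dtype=float),
        chain_ids=np.array([str(c) for c in arr.chain_id], dtype=object),
        residue_indices=np.array([int(r) - 1 for r in arr.res_id], dtype=object),
        residue_codes=codes,
        atom_names=np.array([str(a) for a in arr.atom_name], dtype=object),
    )


def write_pdb(geometry: Geometry | list[Geometry], path) -> None:
    """Write a single- or multi-model PDB file (chains A/B/C …)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile()
    if isinstance(geometry, Geometry):
        pdb.set_structure(_to_atom_array(geometry))
    else:
        arrays = [_to_atom_array(g) for g in geometry]
        stack = struc.stack(arrays)
        pdb.set_structure(stack)
    pdb.write(str(path))


def read_pdb(path, model: int | None = 1) -> Geometry | list[Geometry]:
    """Read a PDB file; ``model=None`` returns every model as a list."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    if model is not None:
        return _from_atom_array(pdb.get_structure(model=model))
    stack = pdb.get_structure()
    return [_from_atom_array(stack[i]) for i in range(stack.stack_depth())]
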