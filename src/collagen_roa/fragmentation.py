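"""Cutting labelled peptide geometries into overlapping amide-window
fragments.

The parent chain is viewed as a sequence of amide units (peptide
bonds); a window of ``w`` consecutive amides, advanced one amide at a
time, defines a fragment.  A fragment owns every residue that
contributes an atom to any amide unit in its window; severed backbone
bonds are chemically capped (hydrogen caps by default, placed along
the severed bond at 1.09 Å).  Every non-cap fragment atom carries a
map back to its parent atom, which is what the tensor-transfer
machinery consumes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import MONOISOTOPIC_MASS, Geometry, GeometryError, read_xyz, write_xyz

__all__ = [
    "Fragment",
    "FragmentScheme",
    "enumerate_windows",
    "cut_fragment",
    "fragment_chain",
    "fragment_geometry",
    "write_fragment_set",
    "read_fragment_set",
]

H_CAP_BOND = 1.09  # Å, cap hydrogen along the severed bond direction
C_CAP_BOND = 1.50  # Å, methyl-carbon cap alternative


@dataclass
class Fragment:
    """A capped fragment with its atom map back to the parent.

    ``atom_map[i]`` is the parent atom index of fragment atom ``i`` or
    ``-1`` for cap atoms; ``is_cap`` flags the caps.  ``amide_range``
    is the half-open (start, end) window of parent amide-unit indices
    this fragment covers, and ``chain_id`` the chain it was cut from.
    """

    geometry: Geometry
    atom_map: np.ndarray
    is_cap: np.ndarray
    amide_range: tuple[int, int]
    chain_id: str

    @property
    def mapped_parent_atoms(self) -> np.ndarray:
        return self.atom_map[~self.is_cap]

    def __post_init__(self) -> None:
        self.atom_map = np.asarray(self.atom_map, dtype=int)
        self.is_cap = np.asarray(self.is_cap, dtype=bool)
        if len(self.atom_map) != self.geometry.n_atoms:
            raise GeometryError("atom_map length mismatch")
        if np.any((self.atom_map < 0) & ~self.is_cap):
            raise GeometryError("non-cap atom without a parent mapping")
        if np.any((self.atom_map >= 0) & self.is_cap):
            raise GeometryError("cap atom carries a parent mapping")


@dataclass
class FragmentScheme:
    """An ordered set of overlapping fragments cut with one window size."""

    window: int
    fragments: list[Fragment]

    def coverage(self, n_parent_atoms: int) -> np.ndarray:
        """How many fragments contain each parent atom."""
        cover = np.zeros(n_parent_atoms, dtype=int)
        for fr in self.fragments:
            cover[fr.mapped_parent_atoms] += 1
        return cover


def enumerate_windows(n_amides: int, window: int) -> list[tuple[int, int]]:
    """Half-open 0-based amide windows of width ``window``, stride 1.

    For ``M`` amides and window ``w`` there are exactly ``M − w + 1``
    windows: (0, w), (1, w+1), …
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > n_amides:
        raise ValueError(
            f"window of {window} amide units exceeds the chain's {n_amides} amides"
        )
    return [(s, s + window) for s in range(n_amides - window + 1)]


def _chain_amides(parent: Geometry) -> dict[str, list[np.ndarray]]:
    """Amide units grouped by chain, in chain order."""
    units = parent.amide_units()
    out: dict[str, list[np.ndarray]] = {}
    for unit in units:
        chain = str(parent.chain_ids[unit[0]])
        out.setdefault(chain, []).append(unit)
    return out


def cut_fragment(
    parent: Geometry,
    amide_range: tuple[int, int],
    chain_id: str | None = None,
    capping: str = "hydrogen",
) -> Fragment:
    """Cut the residues spanned by an amide-unit window out of ``parent``.

    ``amide_range`` is half-open over the amide units of one chain
    (the single/first chain if ``chain_id`` is omitted).  Amide unit
    *k* joins residue *k* to residue *k+1*, so the window (s, e) spans
    residues s … e inclusive; each severed backbone bond gets one cap
    atom along the old bond direction.
    """
    if capping not in ("hydrogen", "methyl"):
        raise ValueError(f"unknown capping scheme {capping!r}")
    if not parent.is_labeled:
        raise GeometryError("parent geometry lacks residue labels")
    chain_units = _chain_amides(parent)
    if chain_id is None:
        chain_id = sorted(chain_units)[0]
    if chain_id not in chain_units:
        raise GeometryError(f"chain {chain_id!r} has no amide units")
    units = chain_units[chain_id]
    s, e = amide_range
    if not (0 <= s < e <= len(units)):
        raise ValueError(
            f"amide range {amide_range} invalid for chain {chain_id} "
            f"with {len(units)} amide units"
        )

    # residue ids (within the chain) spanned by the window
    chain_res = sorted(
        {int(parent.residue_indices[i]) for i in range(parent.n_atoms)
         if str(parent.chain_ids[i]) == chain_id}
    )
    first_res = chain_res[0] + s
    last_res = chain_res[0] + e  # inclusive
    keep = [
        i
        for i in range(parent.n_atoms)
        if str(parent.chain_ids[i]) == chain_id
        and first_res <= int(parent.residue_indices[i]) <= last_res
    ]
    keep = np.array(keep, dtype=int)

    elements = list(parent.elements[keep])
    coords = [parent.coords[i] for i in keep]
    masses = list(parent.masses[keep])
    chain_ids = list(parent.chain_ids[keep])
    res_idx = list(parent.residue_indices[keep])
    res_codes = list(parent.residue_codes[keep])
    atom_names = list(parent.atom_names[keep])
    atom_map = list(keep)
    is_cap = [False] * len(keep)

    cap_el = "H" if capping == "hydrogen" else "C"
    cap_bond = H_CAP_BOND if capping == "hydrogen" else C_CAP_BOND

    def add_cap(inside_idx: int, outside_idx: int, res_of: int) -> None:
        a = parent.coords[inside_idx]
        b = parent.coords[outside_idx]
        direction = (b - a) / np.linalg.norm(b - a)
        elements.append(cap_el)
        coords.append(a + cap_bond * direction)
        masses.append(MONOISOTOPIC_MASS[cap_el])
        chain_ids.append(chain_id)
        res_idx.append(res_of)
        res_codes.append("CAP")
        atom_names.append("HC" if capping == "hydrogen" else "CC")
        atom_map.append(-1)
        is_cap.append(True)

    # N-side cut: N of first_res was bonded to C of first_res-1
    n_first = parent.atom_index(chain_id, first_res, "N")
    c_before = parent.atom_index(chain_id, first_res - 1, "C")
    if c_before >= 0:
        add_cap(n_first, c_before, first_res)
    # C-side cut: C of last_res was bonded to N of last_res+1
    c_last = parent.atom_index(chain_id, last_res, "C")
    n_after = parent.atom_index(chain_id, last_res + 1, "N")
    if n_after >= 0:
        add_cap(c_last, n_after, last_res)

    geom = Geometry(
        elements=np.array(elements, dtype=object),
        coords=np.array(coords),
        masses=np.array(masses),
        chain_ids=np.array(chain_ids, dtype=object),
        residue_indices=np.array(res_idx, dtype=object),
        residue_codes=np.array(res_codes, dtype=object),
        atom_names=np.array(atom_names, dtype=object),
    )
    return Fragment(
        geometry=geom,
        atom_map=np.array(atom_map, dtype=int),
        is_cap=np.array(is_cap, dtype=bool),
        amide_range=(s, e),
        chain_id=chain_id,
    )


def fragment_chain(
    parent: Geometry, window: int, chain_id: str, capping: str = "hydrogen"
) -> list[Fragment]:
    n_amides = len(_chain_amides(parent)[chain_id])
    return [
        cut_fragment(parent, rng, chain_id, capping)
        for rng in enumerate_windows(n_amides, window)
    ]


def fragment_geometry(
    parent: Geometry, window: int = 4, capping: str = "hydrogen"
) -> FragmentScheme:
    """Cut every chain of ``parent`` into overlapping ``window``-amide
    fragments (windows never span a chain break)."""
    chain_units = _chain_amides(parent)
    fragments: list[Fragment] = []
    for chain_id in sorted(chain_units):
        fragments.extend(fragment_chain(parent, window, chain_id, capping))
    return FragmentScheme(window=window, fragments=fragments)


# ----------------------------------------------------------------------
# serialization: directory of XYZ files + one JSON manifest

def write_fragment_set(scheme: FragmentScheme, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"window": scheme.window, "fragments": []}
    for i, fr in enumerate(scheme.fragments):
        name = f"fragment_{i:04d}.xyz"
        write_xyz(fr.geometry, directory / name,
                  comment=f"chain {fr.chain_id} amides {fr.amide_range}")
        manifest["fragments"].append(
            {
                "file": name,
                "chain_id": fr.chain_id,
                "amide_range": list(fr.amide_range),
                "atom_map": fr.atom_map.tolist(),
                "is_cap": fr.is_cap.astype(int).tolist(),
            }
        )
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def read_fragment_set(directory, parent: Geometry | None = None) -> FragmentScheme:
    """Read a fragment directory written by :func:`write_fragment_set`.

    If ``parent`` is given, its labels are copied onto the mapped
    fragment atoms (XYZ files carry no labels)."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    fragments = []
    for entry in manifest["fragments"]:
        geom = read_xyz(directory / entry["file"])
        atom_map = np.array(entry["atom_map"], dtype=int)
        is_cap = np.array(entry["is_cap"], dtype=bool)
        if parent is not None:
            n = geom.n_atoms
            chain_ids = np.empty(n, dtype=object)
            res_idx = np.empty(n, dtype=object)
            res_codes = np.empty(n, dtype=object)
            atom_names = np.empty(n, dtype=object)
            for i in range(n):
                p = atom_map[i]
                if p >= 0:
                    chain_ids[i] = parent.chain_ids[p]
                    res_idx[i] = parent.residue_indices[p]
                    res_codes[i] = parent.residue_codes[p]
                    atom_names[i] = parent.atom_names[p]
                else:
                    chain_ids[i] = entry["chain_id"]
                    res_idx[i] = -1
                    res_codes[i] = "CAP"
                    atom_names[i] = "HC"
            geom.chain_ids = chain_ids
            geom.residue_indices = res_idx
            geom.residue_codes = res_codes
            geom.atom_names = atom_names
        fragments.append(
            Fragment(
                geometry=geom,
                atom_map=atom_map,
                is_cap=is_cap,
                amide_range=tuple(entry["amide_range"]),
                chain_id=entry["chain_id"],
            )
        )
    return FragmentScheme(window=manifest["window"], fragments=fragments)


def fragment_set_checksum(directory) -> str:
    """SHA-256 over the sorted byte contents of a fragment directory."""
    directory = Path(directory)
    h = hashlib.sha256()
    for path in sorted(directory.iterdir()):
        h.update(path.name.encode())
        h.update(path.read_bytes())
    return h.hexdigest()
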