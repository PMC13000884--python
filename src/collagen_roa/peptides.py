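"""Collagen-type peptide sequences, formulas, masses and helix building.

The sequences handled here are the short repetitive collagen models
built from Pro (P), 4-hydroxyproline Hyp (H/X), Gly (G) and Ala (A),
written in triplet notation such as ``(PHG)9PHA`` or ``D-(PPG)10``
(the ``D-`` prefix makes every chiral residue D).  From a parsed
sequence the module derives the molecular formula and monoisotopic
mass, and builds idealized polyproline-II (PPII) single helices or
three-stranded triple helices.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .geometry import MONOISOTOPIC_MASS, Geometry, GeometryError

__all__ = [
    "PeptideSequence",
    "MolecularFormula",
    "ParseError",
    "parse_triplet_notation",
    "sequence_to_formula",
    "monoisotopic_mass",
    "build_helix",
    "RESIDUE_COMPOSITIONS",
]


class ParseError(ValueError):
    """Raised for malformed triplet-notation peptide strings."""


#: One-letter codes used in triplet notation.
_LETTER_TO_CODE = {"P": "Pro", "H": "Hyp", "X": "Hyp", "G": "Gly", "A": "Ala"}

#: Residue (amino-acid minus water) elemental compositions.
RESIDUE_COMPOSITIONS: dict[str, dict[str, int]] = {
    "Pro": {"C": 5, "H": 7, "N": 1, "O": 1},
    "Hyp": {"C": 5, "H": 7, "N": 1, "O": 2},
    "Gly": {"C": 2, "H": 3, "N": 1, "O": 1},
    "Ala": {"C": 3, "H": 5, "N": 1, "O": 1},
}

_ACHIRAL = {"Gly"}


@dataclass(frozen=True)
class PeptideSequence:
    """An ordered list of ``(residue_code, chirality)`` pairs.

    Chirality is ``"L"`` or ``"D"`` for Pro/Hyp/Ala and ``"achiral"``
    for Gly.  Termini are the free ``H-`` amine and ``-OH`` acid.
    """

    residues: tuple[tuple[str, str], ...]
    n_terminus: str = "H-"
    c_terminus: str = "-OH"

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ParseError("peptide sequence must contain at least one residue")
        for code, chir in self.residues:
            if code not in RESIDUE_COMPOSITIONS:
                raise ParseError(f"unknown residue code {code!r}")
            if code in _ACHIRAL and chir != "achiral":
                raise ParseError(f"{code} must be achiral, got {chir!r}")
            if code not in _ACHIRAL and chir not in ("L", "D"):
                raise ParseError(f"{code} must be L or D, got {chir!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def codes(self) -> list[str]:
        return [c for c, _ in self.residues]

    def mirrored(self) -> "PeptideSequence":
        """The enantiomeric sequence (all L ↔ D)."""
        flip = {"L": "D", "D": "L", "achiral": "achiral"}
        return PeptideSequence(tuple((c, flip[ch]) for c, ch in self.residues))

    def concat(self, other: "PeptideSequence") -> "PeptideSequence":
        """Condensation with one new peptide bond (loses one H2O)."""
        return PeptideSequence(self.residues + other.residues)


@dataclass(frozen=True)
class MolecularFormula:
    """Element → count map rendering in Hill order (C, H, alphabetical)."""

    element_counts: tuple[tuple[str, int], ...]

    @classmethod
    def from_dict(cls, counts: dict[str, int]) -> "MolecularFormula":
        clean = {e: int(n) for e, n in counts.items() if n != 0}
        if any(n < 0 for n in clean.values()):
            raise ValueError("negative element count")
        return cls(tuple(sorted(clean.items())))

    def as_dict(self) -> dict[str, int]:
        return dict(self.element_counts)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = self.as_dict()
        for e, n in other.element_counts:
            counts[e] = counts.get(e, 0) + n
        return MolecularFormula.from_dict(counts)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = self.as_dict()
        for e, n in other.element_counts:
            counts[e] = counts.get(e, 0) - n
        return MolecularFormula.from_dict(counts)

    def __str__(self) -> str:
        counts = self.as_dict()
        parts = []
        for e in ("C", "H"):
            if e in counts:
                n = counts.pop(e)
                parts.append(e + (str(n) if n > 1 else ""))
        for e in sorted(counts):
            n = counts[e]
            parts.append(e + (str(n) if n > 1 else ""))
        return "".join(parts)


WATER = MolecularFormula.from_dict({"H": 2, "O": 1})

_GROUP_RE = re.compile(r"\(([A-Za-z]+)\)(\d+)|([A-Za-z])")


def parse_triplet_notation(text: str) -> PeptideSequence:
    """Expand triplet notation like ``(PHG)9PHA`` into a residue list.

    A leading ``D-`` makes every chiral residue D; Gly is always
    achiral.  Unknown residue letters raise :class:`ParseError` naming
    the offending token.
    """
    s = text.strip().replace(" ", "")
    chirality = "L"
    if s.upper().startswith("D-"):
        chirality = "D"
        s = s[2:]
    if not s:
        raise ParseError(f"empty sequence in {text!r}")
    residues: list[tuple[str, str]] = []
    pos = 0
    while pos < len(s):
        m = _GROUP_RE.match(s, pos)
        if m is None:
            raise ParseError(f"cannot parse {s[pos:]!r} in {text!r}")
        if m.group(1) is not None:
            letters, mult = m.group(1), int(m.group(2))
        else:
            letters, mult = m.group(3), 1
        expanded = []
        for letter in letters:
            code = _LETTER_TO_CODE.get(letter.upper())
            if code is None:
                raise ParseError(f"unknown residue letter {letter!r} in {text!r}")
            expanded.append((code, "achiral" if code in _ACHIRAL else chirality))
        residues.extend(expanded * mult)
        pos = m.end()
    return PeptideSequence(tuple(residues))


def sequence_to_formula(seq: PeptideSequence) -> MolecularFormula:
    """Molecular formula: sum of residue compositions plus one water
    for the free H-/-OH termini.  Chirality does not enter."""
    total = WATER
    for code, _ in seq.residues:
        total = total + MolecularFormula.from_dict(RESIDUE_COMPOSITIONS[code])
    return total


def monoisotopic_mass(formula: MolecularFormula) -> float:
    """Monoisotopic mass in Da (most-abundant-isotope masses)."""
    mass = 0.0
    for e, n in formula.element_counts:
        if e not in MONOISOTOPIC_MASS:
            raise ValueError(f"no tabulated monoisotopic mass for element {e!r}")
        mass += n * MONOISOTOPIC_MASS[e]
    return mass


def sequence_mass(seq: PeptideSequence) -> float:
    return monoisotopic_mass(sequence_to_formula(seq))


# ----------------------------------------------------------------------
# Idealized PPII helix builder
#
# Internal coordinates (Å / degrees): N-CA 1.46, CA-C 1.52, C-N 1.33,
# C=O 1.23; backbone angles C(-1)-N-CA 121.7, N-CA-C 111.0,
# CA-C-N(+1) 116.2, CA-C-O 120.8.  Side chains are rigid idealized
# groups; the proline ring torsions below give an approximately closed
# Cγ-endo-like ring (CD–N 1.47 Å).

_BOND = {"N-CA": 1.46, "CA-C": 1.52, "C-N": 1.33, "C-O": 1.23, "C-C": 1.52, "C-OH": 1.41}
_ANGLE = {"C-N-CA": 121.7, "N-CA-C": 111.0, "CA-C-N": 116.2, "CA-C-O": 120.8}
# L-residue side-chain torsions (IUPAC sign); D residues negate them.
_CB_IMPROPER = -122.5      # torsion N-C-CA-CB
_PRO_CHI1 = 18.0764        # torsion N-CA-CB-CG
_PRO_CHI2 = -31.3139       # torsion CA-CB-CG-CD
_PRO_RING_ANGLE = 102.583
_HYP_OD_TORSION = _PRO_CHI2 + 120.0  # torsion CA-CB-CG-OD1 (4R-like)


def _place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Position d with |d−c| = bond, ∠(b,c,d) = angle and IUPAC torsion
    a-b-c-d = torsion (degrees)."""
    theta = np.radians(angle)
    phi = np.radians(-torsion)  # internal frame is left-handed w.r.t. IUPAC
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise GeometryError("collinear reference atoms in placement")
    n = n / nn
    nbc = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(theta),
            bond * np.cos(phi) * np.sin(theta),
            bond * np.sin(phi) * np.sin(theta),
        ]
    )
    return c + np.column_stack([bc, nbc, n]) @ d_local


def _build_chain(
    seq: PeptideSequence, phi: np.ndarray, psi: np.ndarray, chain_id: str
) -> tuple[list, np.ndarray]:
    """Build one strand; returns (atom records, coords)."""
    records: list[tuple[str, int, str, str]] = []  # element, res idx, code, name
    coords: list[np.ndarray] = []

    def add(element, res_idx, code, name, xyz):
        records.append((element, res_idx, code, name))
        coords.append(np.asarray(xyz, dtype=float))

    n_prev = ca_prev = c_prev = None
    for i, (code, chir) in enumerate(seq.residues):
        sign = -1.0 if chir == "D" else 1.0
        if i == 0:
            n_i = np.zeros(3)
            ca_i = np.array([_BOND["N-CA"], 0.0, 0.0])
            ang = np.radians(_ANGLE["N-CA-C"])
            c_i = ca_i + _BOND["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
        else:
            n_i = _place_atom(
                n_prev, ca_prev, c_prev, _BOND["C-N"], _ANGLE["CA-C-N"], psi[i - 1]
            )
            ca_i = _place_atom(
                ca_prev, c_prev, n_i, _BOND["N-CA"], _ANGLE["C-N-CA"], 180.0
            )
            c_i = _place_atom(
                c_prev, n_i, ca_i, _BOND["CA-C"], _ANGLE["N-CA-C"], phi[i]
            )
        o_i = _place_atom(n_i, ca_i, c_i, _BOND["C-O"], _ANGLE["CA-C-O"], psi[i] + 180.0)
        add("N", i, code, "N", n_i)
        add("C", i, code, "CA", ca_i)
        add("C", i, code, "C", c_i)
        add("O", i, code, "O", o_i)
        if code in ("Ala", "Pro", "Hyp"):
            cb = _place_atom(n_i, c_i, ca_i, _BOND["C-C"], 110.0, sign * _CB_IMPROPER)
            add("C", i, code, "CB", cb)
        if code in ("Pro", "Hyp"):
            cg = _place_atom(
                n_i, ca_i, cb, _BOND["C-C"], _PRO_RING_ANGLE, sign * _PRO_CHI1
            )
            cd = _place_atom(
                ca_i, cb, cg, _BOND["C-C"], _PRO_RING_ANGLE, sign * _PRO_CHI2
            )
            add("C", i, code, "CG", cg)
            add("C", i, code, "CD", cd)
            if code == "Hyp":
                od = _place_atom(
                    ca_i, cb, cg, _BOND["C-OH"], 110.0, sign * _HYP_OD_TORSION
                )
                add("O", i, code, "OD1", od)
        n_prev, ca_prev, c_prev = n_i, ca_i, c_i

    chain_records = [(el, chain_id, ri, code, name) for el, ri, code, name in records]
    return chain_records, np.array(coords)


def _principal_axis_frame(coords: np.ndarray, ca_first: int, ca_last: int) -> np.ndarray:
    """Rotation matrix taking the chain's principal axis to +z, oriented
    N→C terminus."""
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if axis @ (coords[ca_last] - coords[ca_first]) < 0:
        axis = -axis
    # build right-handed frame (e1, e2, axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return np.vstack([e1, e2, axis])


def build_helix(
    seq: PeptideSequence | str,
    phi: float | np.ndarray = -75.0,
    psi: float | np.ndarray = 150.0,
    n_chains: int = 1,
    stagger: int = 1,
    radial_offset: float = 4.0,
    check_clashes: bool = True,
) -> Geometry:
    """Build an idealized PPII single helix or three-stranded assembly.

    Parameters
    ----------
    seq
        Parsed sequence or triplet-notation string.
    phi, psi
        Backbone dihedrals in degrees, scalar or per-residue arrays.
        Defaults are the canonical PPII values (−75°, +150°).
    n_chains
        1 (single strand) or 3 (triple helix, chains A/B/C related by
        120° rotation about the common axis).
    stagger
        Mutual inter-chain stagger in residues (0, 1 or 2); one residue
        by default, as in the collagen superhelix.
    radial_offset
        Distance (Å) of each strand axis from the superhelix axis.
    """
    if isinstance(seq, str):
        seq = parse_triplet_notation(seq)
    n_res = len(seq)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (n_res,)).copy()
    psi = np.broadcast_to(np.asarray(psi, dtype=float), (n_res,)).copy()
    for arr, name in ((phi, "phi"), (psi, "psi")):
        if np.any(arr <= -180.0) or np.any(arr > 180.0):
            raise ValueError(f"{name} must lie in (-180, 180] degrees")
    if n_chains not in (1, 3):
        raise ValueError("n_chains must be 1 or 3")
    if n_chains == 3 and stagger not in (0, 1, 2):
        raise ValueError("stagger must be 0, 1 or 2 residues")

    records, coords = _build_chain(seq, phi, psi, "A")
    if n_chains == 1:
        geom = _assemble(records, coords)
        if check_clashes:
            geom.check_clashes()
        return geom

    # orient the strand along +z, offset radially, then place rotated copies
    ca_idx = [k for k, r in enumerate(records) if r[4] == "CA"]
    frame = _principal_axis_frame(coords, ca_idx[0], ca_idx[-1])
    local = (coords - coords.mean(axis=0)) @ frame.T
    local[:, 0] += radial_offset
    z_ca = local[ca_idx, 2]
    rise = (z_ca[-1] - z_ca[0]) / max(len(ca_idx) - 1, 1)

    all_records: list = []
    all_coords: list[np.ndarray] = []
    for k, chain_id in enumerate("ABC"):
        ang = np.radians(120.0 * k)
        rot = np.array(
            [
                [np.cos(ang), -np.sin(ang), 0.0],
                [np.sin(ang), np.cos(ang), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        shifted = local @ rot.T
        shifted[:, 2] += k * stagger * rise
        all_coords.append(shifted)
        all_records.extend(
            [(el, chain_id, ri, code, name) for el, _, ri, code, name in records]
        )
    geom = _assemble(all_records, np.vstack(all_coords))
    if check_clashes:
        geom.check_clashes()
    return geom


def _assemble(records, coords) -> Geometry:
    elements = np.array([r[0] for r in records], dtype=object)
    return Geometry(
        elements=elements,
        coords=coords,
        chain_ids=np.array([r[1] for r in records], dtype=object),
        residue_indices=np.array([r[2] for r in records], dtype=object),
        residue_codes=np.array([r[3] for r in records], dtype=object),
        atom_names=np.array([r[4] for r in records], dtype=object),
    )
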