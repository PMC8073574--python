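"""Backbone dihedral kinematics and least-RMSD comparison of conformations.

The degrees of freedom of the sampler are the phi/psi torsions about each
residue's N-CA and CA-C bonds.  Rotations propagate C-terminally: changing a
torsion rigidly rotates every atom on the carbonyl side of the bond, up to
the next chain break, so the N-terminal part of the molecule stays fixed.
Chain gaps act as rotation barriers and make the adjacent torsions undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import ATOM_ORDER
from .geometry import rmsd_to_many, rotate_about_axis, superpose, torsion, wrap_angle
from .structure import ResiduePairing, Structure

__all__ = [
    "DihedralVector",
    "Conformation",
    "compute_dihedrals",
    "set_dihedral",
    "superpose",
    "lrmsd",
    "paired_ca_coords",
]


@dataclass
class DihedralVector:
    """Per-residue phi/psi torsions in degrees; NaN marks undefined entries
    (chain termini and gap-adjacent torsions)."""

    phi: np.ndarray
    psi: np.ndarray

    def copy(self) -> "DihedralVector":
        return DihedralVector(self.phi.copy(), self.psi.copy())

    def defined(self, residue_index: int, kind: str) -> bool:
        arr = self.phi if kind == "phi" else self.psi
        return bool(np.isfinite(arr[residue_index]))


def _batch_torsion(p0, p1, p2, p3) -> np.ndarray:
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2n)
    return np.degrees(np.arctan2(y, x))


def _dihedrals_from_structure(structure: Structure) -> DihedralVector:
    m = structure.n_residues
    phi = np.full(m, np.nan)
    psi = np.full(m, np.nan)
    idx = structure._atom_index
    coords = structure.coords
    gap = structure.gap_after

    n_i = idx[:, ATOM_ORDER["N"]]
    ca_i = idx[:, ATOM_ORDER["CA"]]
    c_i = idx[:, ATOM_ORDER["C"]]

    # phi(i) = torsion(C(i-1), N(i), CA(i), C(i)) where residue i-1 bonds i
    rows = np.array([i for i in range(1, m) if not gap[i - 1]], dtype=int)
    if rows.size:
        phi[rows] = _batch_torsion(
            coords[c_i[rows - 1]], coords[n_i[rows]], coords[ca_i[rows]], coords[c_i[rows]]
        )
    # psi(i) = torsion(N(i), CA(i), C(i), N(i+1)) where residue i bonds i+1
    rows = np.array([i for i in range(m - 1) if not gap[i]], dtype=int)
    if rows.size:
        psi[rows] = _batch_torsion(
            coords[n_i[rows]], coords[ca_i[rows]], coords[c_i[rows]], coords[n_i[rows + 1]]
        )
    return DihedralVector(phi, psi)


class Conformation:
    """A Structure plus a cached, coordinate-consistent dihedral vector.

    The cache is what the search perturbs and compares against the goal;
    it is refreshed whenever coordinates change through Cartesian-space
    operations (e.g. energy minimisation).
    """

    def __init__(self, structure: Structure, dihedrals: DihedralVector | None = None):
        self.structure = structure
        self.dihedrals = dihedrals if dihedrals is not None else _dihedrals_from_structure(structure)

    @property
    def coords(self) -> np.ndarray:
        return self.structure.coords

    @property
    def n_residues(self) -> int:
        return self.structure.n_residues

    def with_coords(self, coords: np.ndarray) -> "Conformation":
        """New Conformation from replaced coordinates; dihedrals recomputed."""
        return Conformation(self.structure.with_coords(coords))


def compute_dihedrals(conformation: Conformation | Structure) -> DihedralVector:
    """Recompute phi/psi from coordinates (IUPAC sign convention, degrees)."""
    structure = conformation.structure if isinstance(conformation, Conformation) else conformation
    return _dihedrals_from_structure(structure)


def _moving_atoms(structure: Structure, residue_index: int, kind: str) -> np.ndarray:
    """Flat indices of atoms rotated by a phi/psi change at ``residue_index``.

    phi moves C, O and CB of the residue itself plus every downstream residue
    up to the next chain gap; psi moves only O of the residue plus the
    downstream residues (CB stays on the nitrogen side of the CA-C bond).
    """
    idx = structure._atom_index
    own = ["C", "O", "CB"] if kind == "phi" else ["O"]
    movers = [idx[residue_index, ATOM_ORDER[a]] for a in own if idx[residue_index, ATOM_ORDER[a]] >= 0]
    gap = structure.gap_after
    j = residue_index
    while j < structure.n_residues - 1 and not gap[j]:
        j += 1
        movers.extend(int(a) for a in idx[j] if a >= 0)
    return np.array(movers, dtype=int)


def set_dihedral(
    conformation: Conformation,
    residue_index: int,
    angle_kind: str,
    new_value: float,
) -> Conformation:
    """Return a new conformation with the named torsion set to ``new_value``.

    All atoms C-terminal to the rotated bond (up to the next chain gap) are
    rotated rigidly about the bond axis; bond lengths, bond angles and all
    other torsions are untouched.
    """
    structure = conformation.structure
    if not 0 <= residue_index < structure.n_residues:
        raise IndexError(f"residue index {residue_index} out of range")
    if angle_kind not in ("phi", "psi"):
        raise ValueError(f"angle_kind must be 'phi' or 'psi', got {angle_kind!r}")
    if not conformation.dihedrals.defined(residue_index, angle_kind):
        raise ValueError(f"{angle_kind} is undefined at residue {residue_index}")

    idx = structure._atom_index
    if angle_kind == "phi":
        a0 = idx[residue_index, ATOM_ORDER["N"]]
        a1 = idx[residue_index, ATOM_ORDER["CA"]]
        current = conformation.dihedrals.phi[residue_index]
    else:
        a0 = idx[residue_index, ATOM_ORDER["CA"]]
        a1 = idx[residue_index, ATOM_ORDER["C"]]
        current = conformation.dihedrals.psi[residue_index]

    target = wrap_angle(new_value)
    # a right-hand rotation by +delta about the bond axis increases the torsion
    delta_rot = target - current
    coords = structure.coords.copy()
    movers = _moving_atoms(structure, residue_index, angle_kind)
    coords[movers] = rotate_about_axis(
        coords[movers], coords[a0], coords[a1] - coords[a0], delta_rot
    )
    dihedrals = conformation.dihedrals.copy()
    if angle_kind == "phi":
        dihedrals.phi[residue_index] = target
    else:
        dihedrals.psi[residue_index] = target
    return Conformation(structure.with_coords(coords), dihedrals)


def paired_ca_coords(
    a: Conformation | Structure, b: Conformation | Structure, pairing: ResiduePairing
):
    """CA coordinate arrays of the paired residues of both conformations."""
    sa = a.structure if isinstance(a, Conformation) else a
    sb = b.structure if isinstance(b, Conformation) else b
    ca_a = sa.coords[sa.ca_indices[pairing.start_indices]]
    ca_b = sb.coords[sb.ca_indices[pairing.goal_indices]]
    return ca_a, ca_b


def lrmsd(
    a: Conformation | Structure, b: Conformation | Structure, pairing: ResiduePairing | None = None
) -> float:
    """Least RMSD over CA atoms of paired residues, after optimal rigid
    superposition."""
    if pairing is None:
        sa = a.structure if isinstance(a, Conformation) else a
        n = sa.n_residues
        pairing = ResiduePairing(pairs=[(i, i) for i in range(n)])
    ca_a, ca_b = paired_ca_coords(a, b, pairing)
    return superpose(ca_a, ca_b)[2]


def lrmsd_to_many(centered_ca: np.ndarray, centered_stack: np.ndarray) -> np.ndarray:
    """Batched lRMSD of one centered CA set against a stack of centered sets."""
    return rmsd_to_many(centered_ca, centered_stack)
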