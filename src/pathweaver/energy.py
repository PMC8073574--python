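"""Coarse-grained potential, bounded steepest-descent relaxation, energy gate.

The total potential is the sum of six terms::

    E_total = E_HB + E_burial + E_water + E_bond + E_angle + E_VdW

Bond, angle and van-der-Waals terms are harmonic/Lennard-Jones forms over
the retained atom classes (N, CA, C, O, CB), with the Lennard-Jones
repulsion clamped at short range so that even badly clashed inputs have
finite energy ("soft collisions").  The hydrogen-bond, burial and
water-mediated terms are simplified knowledge-based forms (square wells and
a contact-count sigmoid) behind one parameter object, so a more detailed
potential can be swapped in without touching the search.  Units are nominal
kcal/mol; only relative values matter because the sole consumer is the
per-residue acceptance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .constants import (
    ATOM_ORDER,
    HYDROPHOBIC_RESIDUES,
    IDEAL_BOND_ANGLES,
    IDEAL_BOND_LENGTHS,
    KYTE_DOOLITTLE,
)
from .kinematics import Conformation

__all__ = [
    "EnergyBreakdown",
    "EnergyParams",
    "total_energy",
    "minimize",
    "energy_gate",
    "bonded_vdw_energy",
    "bonded_vdw_gradient",
]


@dataclass(frozen=True)
class EnergyBreakdown:
    """Per-term decomposition; ``total`` is always the plain sum of the six
    terms in a fixed order."""

    e_hb: float
    e_burial: float
    e_water: float
    e_bond: float
    e_angle: float
    e_vdw: float

    @property
    def total(self) -> float:
        return self.e_hb + self.e_burial + self.e_water + self.e_bond + self.e_angle + self.e_vdw


def _default_sigma() -> dict:
    return {"N": 3.25, "CA": 3.40, "C": 3.40, "O": 2.96, "CB": 3.40}


def _default_epsilon() -> dict:
    return {"N": 0.17, "CA": 0.09, "C": 0.09, "O": 0.21, "CB": 0.12}


@dataclass(frozen=True)
class EnergyParams:
    """Tunable parameters of the coarse-grained potential.

    ``vdw_softening`` is the fraction of sigma below which the repulsion is
    clamped to a constant, keeping the energy finite for overlapping atoms.
    """

    k_bond: float = 300.0            # kcal/mol/A^2
    k_angle: float = 80.0            # kcal/mol/rad^2
    bond_r0: dict = field(default_factory=lambda: dict(IDEAL_BOND_LENGTHS))
    angle_theta0: dict = field(default_factory=lambda: dict(IDEAL_BOND_ANGLES))
    lj_sigma: dict = field(default_factory=_default_sigma)
    lj_epsilon: dict = field(default_factory=_default_epsilon)
    vdw_softening: float = 0.8
    vdw_cutoff: float = 8.0
    # 1-4 pairs (exactly three bonds apart) use scaled LJ parameters, the
    # usual force-field device for near-contacts fixed by bonded geometry
    lj_14_sigma_scale: float = 0.75
    lj_14_epsilon_scale: float = 0.5
    hb_dist_min: float = 2.6         # O...N window, Angstrom
    hb_dist_max: float = 3.5
    hb_angle_min: float = 90.0       # CA-O...N angle, degrees
    hb_epsilon: float = 1.0
    hb_min_seq_sep: int = 3
    burial_weight: float = 0.5
    burial_radius: float = 8.0
    burial_midpoint: float = 6.0
    burial_slope: float = 2.0
    water_min: float = 6.5           # CB-CB shell, Angstrom
    water_max: float = 9.5
    water_epsilon: float = 0.05
    water_min_seq_sep: int = 2

    def __post_init__(self):
        if not 0.0 < self.vdw_softening <= 1.0:
            raise ValueError("vdw_softening must be in (0, 1]")
        if self.k_bond < 0 or self.k_angle < 0:
            raise ValueError("force constants must be non-negative")
        if any(s <= 0 for s in self.lj_sigma.values()):
            raise ValueError("LJ radii must be positive")

    @classmethod
    def from_dict(cls, data: dict) -> "EnergyParams":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown energy parameters: {sorted(unknown)}")
        base = cls()
        merged = {}
        for key, value in data.items():
            current = getattr(base, key)
            if isinstance(current, dict):
                new = dict(current)
                new.update(value)
                merged[key] = new
            else:
                merged[key] = value
        return replace(base, **merged)

    @classmethod
    def from_yaml(cls, text: str) -> "EnergyParams":
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)


# -- topology (bond lists, angle triples, nonbonded exclusions) ---------------


class _Topology:
    """Bonded-term index tables for one chain topology, shared by all
    conformations derived from the same structure."""

    def __init__(self, structure):
        idx = structure._atom_index
        gap = structure.gap_after
        m = structure.n_residues

        def a(r, name):
            return int(idx[r, ATOM_ORDER[name]])

        bonds, bond_kinds = [], []
        for r in range(m):
            bonds += [(a(r, "N"), a(r, "CA")), (a(r, "CA"), a(r, "C")), (a(r, "C"), a(r, "O"))]
            bond_kinds += [("N", "CA"), ("CA", "C"), ("C", "O")]
            if a(r, "CB") >= 0:
                bonds.append((a(r, "CA"), a(r, "CB")))
                bond_kinds.append(("CA", "CB"))
            if r + 1 < m and not gap[r]:
                bonds.append((a(r, "C"), a(r + 1, "N")))
                bond_kinds.append(("C", "N"))
        self.bonds = np.array(bonds, dtype=int)
        self.bond_kinds = bond_kinds

        angles, angle_kinds = [], []
        for r in range(m):
            angles.append((a(r, "N"), a(r, "CA"), a(r, "C")))
            angle_kinds.append(("N", "CA", "C"))
            angles.append((a(r, "CA"), a(r, "C"), a(r, "O")))
            angle_kinds.append(("CA", "C", "O"))
            if a(r, "CB") >= 0:
                angles += [
                    (a(r, "N"), a(r, "CA"), a(r, "CB")),
                    (a(r, "C"), a(r, "CA"), a(r, "CB")),
                ]
                angle_kinds += [("N", "CA", "CB"), ("C", "CA", "CB")]
            if r + 1 < m and not gap[r]:
                angles += [
                    (a(r, "CA"), a(r, "C"), a(r + 1, "N")),
                    (a(r, "O"), a(r, "C"), a(r + 1, "N")),
                    (a(r, "C"), a(r + 1, "N"), a(r + 1, "CA")),
                ]
                angle_kinds += [("CA", "C", "N"), ("O", "C", "N"), ("C", "N", "CA")]
        self.angles = np.array(angles, dtype=int)
        self.angle_kinds = angle_kinds

        # nonbonded exclusions: pairs separated by fewer than 3 bonds
        n_atoms = structure.n_atoms
        neighbors = [[] for _ in range(n_atoms)]
        for i, j in self.bonds:
            neighbors[i].append(j)
            neighbors[j].append(i)
        excluded = set()
        pairs14 = set()
        for i in range(n_atoms):
            for j in neighbors[i]:          # 1-2
                excluded.add((min(i, j), max(i, j)))
                for k in neighbors[j]:      # 1-3
                    if k != i:
                        excluded.add((min(i, k), max(i, k)))
                    for l in neighbors[k]:  # 1-4 candidates
                        if l != i and l != j:
                            pairs14.add((min(i, l), max(i, l)))
        pairs14 -= excluded
        self.excluded_codes = np.sort(
            np.array([i * n_atoms + j for i, j in excluded], dtype=np.int64)
        )
        self.pair14_codes = np.sort(
            np.array(sorted(i * n_atoms + j for i, j in pairs14), dtype=np.int64)
        )
        self.n_atoms = n_atoms

        # per-residue contact atom for burial (CB, falling back to CA for Gly)
        cb = idx[:, ATOM_ORDER["CB"]]
        ca = idx[:, ATOM_ORDER["CA"]]
        self.contact_atoms = np.where(cb >= 0, cb, ca)
        self.cb_atoms = cb
        self.o_atoms = idx[:, ATOM_ORDER["O"]]
        self.n_atoms_per_res = idx[:, ATOM_ORDER["N"]]
        self.ca_atoms = ca
        self.res_names = structure.residue_names


def get_topology(structure) -> _Topology:
    """Cached bonded-topology tables for a structure (shared across
    conformations produced by ``with_coords``)."""
    topo = getattr(structure, "_topology", None)
    if topo is None:
        topo = _Topology(structure)
        structure._topology = topo
    return topo


def _nonbonded_pairs(coords: np.ndarray, topo: _Topology, cutoff: float):
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return pairs
    codes = pairs[:, 0].astype(np.int64) * topo.n_atoms + pairs[:, 1]
    keep = ~np.isin(codes, topo.excluded_codes, assume_unique=False)
    return pairs[keep]


def _lj_params_for_pairs(topo, pairs, params: EnergyParams):
    names = topo._atom_names
    sig = np.array([params.lj_sigma[str(n)] for n in names])
    eps = np.array([params.lj_epsilon[str(n)] for n in names])
    sig_ij = 0.5 * (sig[pairs[:, 0]] + sig[pairs[:, 1]])
    eps_ij = np.sqrt(eps[pairs[:, 0]] * eps[pairs[:, 1]])
    codes = pairs[:, 0].astype(np.int64) * topo.n_atoms + pairs[:, 1]
    is14 = np.isin(codes, topo.pair14_codes)
    sig_ij = np.where(is14, params.lj_14_sigma_scale * sig_ij, sig_ij)
    eps_ij = np.where(is14, params.lj_14_epsilon_scale * eps_ij, eps_ij)
    return sig_ij, eps_ij


def _lj_energy(r, sig, eps, softening):
    """Soft Lennard-Jones: standard 12-6 above ``softening*sigma``, clamped
    to its value at ``softening*sigma`` below it (finite for r -> 0)."""
    r_floor = np.maximum(r, softening * sig)
    x6 = (sig / r_floor) ** 6
    return 4.0 * eps * (x6 * x6 - x6)


def _bond_energy(coords, topo, params, grad=None) -> float:
    i, j = topo.bonds[:, 0], topo.bonds[:, 1]
    d = coords[i] - coords[j]
    r = np.linalg.norm(d, axis=1)
    r0 = np.array([params.bond_r0[k] for k in topo.bond_kinds])
    dev = r - r0
    if grad is not None:
        f = (2.0 * params.k_bond * dev / r)[:, None] * d
        np.add.at(grad, i, f)
        np.add.at(grad, j, -f)
    return float(np.sum(params.k_bond * dev * dev))


def _angle_energy(coords, topo, params, grad=None) -> float:
    ai, aj, ak = topo.angles[:, 0], topo.angles[:, 1], topo.angles[:, 2]
    u = coords[ai] - coords[aj]
    v = coords[ak] - coords[aj]
    ru = np.linalg.norm(u, axis=1)
    rv = np.linalg.norm(v, axis=1)
    cosang = np.clip(np.einsum("ij,ij->i", u, v) / (ru * rv), -1.0, 1.0)
    theta = np.arccos(cosang)
    theta0 = np.radians(np.array([params.angle_theta0[k] for k in topo.angle_kinds]))
    dev = theta - theta0
    if grad is not None:
        sin = np.sqrt(np.maximum(1.0 - cosang * cosang, 1e-12))
        dtheta_di = (cosang[:, None] * u / ru[:, None] - v / rv[:, None]) / (ru * sin)[:, None]
        dtheta_dk = (cosang[:, None] * v / rv[:, None] - u / ru[:, None]) / (rv * sin)[:, None]
        coeff = (2.0 * params.k_angle * dev)[:, None]
        np.add.at(grad, ai, coeff * dtheta_di)
        np.add.at(grad, ak, coeff * dtheta_dk)
        np.add.at(grad, aj, -coeff * (dtheta_di + dtheta_dk))
    return float(np.sum(params.k_angle * dev * dev))


def _vdw_energy(coords, topo, params, pairs=None, grad=None) -> float:
    if pairs is None:
        pairs = _nonbonded_pairs(coords, topo, params.vdw_cutoff)
    if len(pairs) == 0:
        return 0.0
    sig, eps = _lj_params_for_pairs(topo, pairs, params)
    d = coords[pairs[:, 0]] - coords[pairs[:, 1]]
    r = np.linalg.norm(d, axis=1)
    within = r <= params.vdw_cutoff
    e = np.where(within, _lj_energy(r, sig, eps, params.vdw_softening), 0.0)
    if grad is not None:
        r_soft = params.vdw_softening * sig
        active = within & (r > r_soft)
        x6 = np.where(active, (sig / np.maximum(r, 1e-12)) ** 6, 0.0)
        dedr = np.where(active, 4.0 * eps * (-12.0 * x6 * x6 + 6.0 * x6) / r, 0.0)
        f = (dedr / np.maximum(r, 1e-12))[:, None] * d
        np.add.at(grad, pairs[:, 0], f)
        np.add.at(grad, pairs[:, 1], -f)
    return float(np.sum(e))


def _hb_energy(coords, topo, params) -> float:
    o = topo.o_atoms
    n = topo.n_atoms_per_res
    ca = topo.ca_atoms
    d_on = cdist(coords[o], coords[n])
    m = len(o)
    sep = np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
    window = (
        (d_on >= params.hb_dist_min)
        & (d_on <= params.hb_dist_max)
        & (sep >= params.hb_min_seq_sep)
    )
    oi, nj = np.nonzero(window)
    if len(oi) == 0:
        return 0.0
    v1 = coords[ca[oi]] - coords[o[oi]]
    v2 = coords[n[nj]] - coords[o[oi]]
    cosang = np.einsum("ij,ij->i", v1, v2) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
    )
    angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return float(-params.hb_epsilon * np.count_nonzero(angles > params.hb_angle_min))


def _burial_water_energy(coords, topo, params) -> tuple[float, float]:
    contact = coords[topo.contact_atoms]
    m = len(contact)
    d = cdist(contact, contact)
    sep = np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
    eligible = sep >= 2
    counts = np.count_nonzero(eligible & (d <= params.burial_radius), axis=1)
    hydro = np.array([(KYTE_DOOLITTLE[str(r)] + 4.5) / 9.0 for r in topo.res_names])
    sigmoid = 1.0 / (1.0 + np.exp(-(counts - params.burial_midpoint) / params.burial_slope))
    e_burial = float(-params.burial_weight * np.sum(hydro * sigmoid))

    has_cb = topo.cb_atoms >= 0
    iu, ju = np.triu_indices(m, k=1)
    shell = (
        (sep[iu, ju] >= params.water_min_seq_sep)
        & has_cb[iu] & has_cb[ju]
        & (d[iu, ju] >= params.water_min)
        & (d[iu, ju] <= params.water_max)
    )
    e_water = float(-params.water_epsilon * np.count_nonzero(shell))
    return e_burial, e_water


def _topo_with_names(structure):
    topo = get_topology(structure)
    # atom names are needed by the LJ mixing rules; cache on the topology
    if not hasattr(topo, "_atom_names"):
        topo._atom_names = structure.atom_names
    return topo


def total_energy(conformation: Conformation, params: EnergyParams | None = None) -> EnergyBreakdown:
    """Evaluate the six-term potential for one conformation."""
    params = params or EnergyParams()
    structure = conformation.structure
    topo = _topo_with_names(structure)
    coords = structure.coords
    e_bond = _bond_energy(coords, topo, params)
    e_angle = _angle_energy(coords, topo, params)
    e_vdw = _vdw_energy(coords, topo, params)
    e_hb = _hb_energy(coords, topo, params)
    e_burial, e_water = _burial_water_energy(coords, topo, params)
    return EnergyBreakdown(
        e_hb=e_hb, e_burial=e_burial, e_water=e_water,
        e_bond=e_bond, e_angle=e_angle, e_vdw=e_vdw,
    )


def bonded_vdw_energy(coords, structure, params: EnergyParams, pairs=None) -> float:
    """Bond + angle + van-der-Waals energy (the minimisation target)."""
    topo = _topo_with_names(structure)
    return (
        _bond_energy(coords, topo, params)
        + _angle_energy(coords, topo, params)
        + _vdw_energy(coords, topo, params, pairs=pairs)
    )


def bonded_vdw_gradient(coords, structure, params: EnergyParams, pairs=None) -> np.ndarray:
    """Analytic Cartesian gradient of the minimisation target."""
    topo = _topo_with_names(structure)
    grad = np.zeros_like(coords)
    _bond_energy(coords, topo, params, grad=grad)
    _angle_energy(coords, topo, params, grad=grad)
    _vdw_energy(coords, topo, params, pairs=pairs, grad=grad)
    return grad


def minimize(
    conformation: Conformation,
    params: EnergyParams | None = None,
    max_steps: int = 10,
    initial_step: float = 0.01,
    max_halvings: int = 5,
) -> Conformation:
    """Bounded steepest descent on the bond + angle + VdW terms.

    At most ``max_steps`` accepted steps of fixed initial length
    ``initial_step`` (Angstrom) along the normalised negative gradient; a
    step that raises the target energy is halved up to ``max_halvings``
    times and then rejected, which ends the relaxation.  The hydrogen-bond,
    burial and water terms are deliberately excluded: the relaxation only
    resolves local clashes and bonded-geometry strain without re-scoring
    the global packing.
    """
    params = params or EnergyParams()
    structure = conformation.structure
    topo = _topo_with_names(structure)
    coords = structure.coords.copy()
    # one neighbour list for the whole relaxation; total displacement is
    # bounded by max_steps * initial_step, well inside the margin
    margin = max_steps * initial_step + 0.1
    pairs = _nonbonded_pairs(coords, topo, params.vdw_cutoff + margin)

    energy = bonded_vdw_energy(coords, structure, params, pairs=pairs)
    moved = False
    for _ in range(max_steps):
        grad = bonded_vdw_gradient(coords, structure, params, pairs=pairs)
        gnorm = float(np.linalg.norm(grad))
        if gnorm < 1e-10:
            break
        direction = -grad / gnorm
        step = initial_step
        accepted = False
        for _ in range(max_halvings + 1):
            trial = coords + step * direction
            trial_energy = bonded_vdw_energy(trial, structure, params, pairs=pairs)
            if trial_energy < energy:
                coords, energy, accepted, moved = trial, trial_energy, True, True
                break
            step *= 0.5
        if not accepted:
            break
    if not moved:
        return conformation
    return conformation.with_coords(coords)


def energy_gate(e: EnergyBreakdown, n_residues: int, k: float = 5.0) -> bool:
    """Accept a conformation iff its total energy is strictly below
    ``k`` times the number of residues."""
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    return e.total < k * n_residues
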