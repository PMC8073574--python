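"""Synthetic, download-free test inputs: ideal-geometry peptides with
prescribed backbone torsions, and transition pairs with engineered hinges.

Peptides are built by sequential internal-coordinate (NeRF-style) placement
with the ideal bond lengths and angles of :mod:`pathweaver.constants`, so a
freshly built peptide sits exactly at the minimum of the bonded energy terms
and its recomputed phi/psi reproduce the requested values to numerical
precision.  Transition pairs differ from their start conformation only at
the named hinge torsions, so the ground-truth flexible region is known by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import (
    CB_PLACEMENT_TORSION,
    IDEAL_BOND_ANGLES,
    IDEAL_BOND_LENGTHS,
    OMEGA_TRANS,
    STANDARD_RESIDUES_1TO3,
)
from .geometry import place_atom
from .kinematics import Conformation
from .structure import Structure

__all__ = ["FixtureSpec", "build_peptide", "make_transition_pair", "two_domain_pair"]


@dataclass
class FixtureSpec:
    """Recipe for a synthetic peptide.

    ``phi``/``psi`` may be scalars (applied to every residue) or per-residue
    sequences; ``None`` draws random-coil torsions from ``seed``.  ``phi[0]``
    and ``psi[-1]`` are not degrees of freedom of a chain but are still used
    to orient the first residue frame and the terminal carbonyl oxygen.
    """

    n_residues: int
    sequence: str | None = None
    phi: float | list | np.ndarray | None = None
    psi: float | list | np.ndarray | None = None
    hinge_residues: frozenset = field(default_factory=frozenset)
    seed: int = 0

    def resolved(self):
        seq = self.sequence if self.sequence is not None else "A" * self.n_residues
        if len(seq) != self.n_residues:
            raise ValueError("sequence length does not match n_residues")
        bad = [c for c in seq if c not in STANDARD_RESIDUES_1TO3]
        if bad:
            raise ValueError(f"invalid sequence letter(s): {sorted(set(bad))}")
        if not set(self.hinge_residues) <= set(range(self.n_residues)):
            raise ValueError("hinge_residues outside the residue range")
        rng = np.random.default_rng(self.seed)

        def expand(values, low, high):
            if values is None:
                return rng.uniform(low, high, size=self.n_residues)
            arr = np.broadcast_to(np.asarray(values, dtype=float), (self.n_residues,))
            return arr.copy()

        phi = expand(self.phi, -150.0, -50.0)
        psi = expand(self.psi, -60.0, 160.0)
        return seq, phi, psi


def build_peptide(spec: FixtureSpec) -> Conformation:
    """Construct an ideal-geometry chain realising the spec's torsions."""
    seq, phi, psi = spec.resolved()
    n = spec.n_residues
    blen = IDEAL_BOND_LENGTHS
    bang = IDEAL_BOND_ANGLES

    coords: list[np.ndarray] = []
    names: list[str] = []
    atom_res: list[int] = []

    n_pos = np.array([0.0, 0.0, 0.0])
    ca_pos = np.array([blen[("N", "CA")], 0.0, 0.0])
    # pseudo-atom frame for the very first carbonyl carbon
    c_pos = place_atom(
        np.array([0.0, -1.0, 0.0]), n_pos, ca_pos, blen[("CA", "C")], bang[("N", "CA", "C")], 180.0
    )
    prev = None
    for i in range(n):
        if i > 0:
            n_pos = place_atom(
                prev["N"], prev["CA"], prev["C"],
                blen[("C", "N")], bang[("CA", "C", "N")], psi[i - 1],
            )
            ca_pos = place_atom(
                prev["CA"], prev["C"], n_pos,
                blen[("N", "CA")], bang[("C", "N", "CA")], OMEGA_TRANS,
            )
            c_pos = place_atom(
                prev["C"], n_pos, ca_pos,
                blen[("CA", "C")], bang[("N", "CA", "C")], phi[i],
            )
        o_pos = place_atom(
            n_pos, ca_pos, c_pos, blen[("C", "O")], bang[("CA", "C", "O")], psi[i] - 180.0
        )
        residue_atoms = {"N": n_pos, "CA": ca_pos, "C": c_pos, "O": o_pos}
        if seq[i] != "G":
            residue_atoms["CB"] = place_atom(
                c_pos, n_pos, ca_pos,
                blen[("CA", "CB")], bang[("N", "CA", "CB")], CB_PLACEMENT_TORSION,
            )
        for name, pos in residue_atoms.items():
            coords.append(pos)
            names.append(name)
            atom_res.append(i)
        prev = residue_atoms

    structure = Structure(
        coords=np.array(coords),
        atom_names=np.array(names),
        atom_residue_index=np.array(atom_res),
        residue_numbers=np.arange(1, n + 1),
        residue_names=np.array([STANDARD_RESIDUES_1TO3[c] for c in seq]),
        chain_id="A",
    )
    return Conformation(structure)


def make_transition_pair(spec: FixtureSpec, hinge_deltas: dict) -> tuple[Conformation, Conformation]:
    """Build (start, goal) differing only at the spec's hinge torsions.

    ``hinge_deltas`` maps a hinge residue index to a ``(dphi, dpsi)`` pair of
    torsion offsets in degrees (either entry may be ``None``).  By
    construction the true flexible residues of the transition are exactly
    the hinge residues.
    """
    seq, phi, psi = spec.resolved()
    for res_i, deltas in hinge_deltas.items():
        if res_i not in spec.hinge_residues:
            raise ValueError(f"torsion offset on non-hinge residue {res_i}")
        dphi, dpsi = deltas
        if dphi is not None:
            phi[res_i] += dphi
        if dpsi is not None:
            psi[res_i] += dpsi
    start = build_peptide(
        FixtureSpec(spec.n_residues, seq, *_resolved_args(spec), spec.hinge_residues, spec.seed)
    )
    goal_spec = FixtureSpec(spec.n_residues, seq, phi, psi, spec.hinge_residues, spec.seed)
    goal = build_peptide(goal_spec)
    return start, goal


def _resolved_args(spec: FixtureSpec):
    _, phi, psi = spec.resolved()
    return phi, psi


def two_domain_pair(
    n_residues: int = 20,
    hinge: tuple[int, ...] = (8, 9, 10),
    hinge_deltas: dict | None = None,
    decoy_offset_range: tuple[float, float] = (5.5, 9.0),
    seed: int = 0,
) -> tuple[Conformation, Conformation, frozenset]:
    """Two helical domains joined by an extended glycine hinge, plus a goal
    conformation produced by large hinge rotations and small "decoy" torsion
    offsets on the domain residues.

    The decoy offsets emulate what distinguishes two experimentally solved
    conformations of a real protein: nearly every torsion differs from its
    counterpart by more than a few degrees, but only the hinge rotations
    produce large-scale motion.  An unguided sampler therefore wastes moves
    on domain torsions, while a rigidity-guided one concentrates on the
    hinge.  Returns ``(start, goal, hinge_residues)``.
    """
    hinge_set = frozenset(hinge)
    seq = "".join("G" if i in hinge_set else ("L" if i % 3 == 1 else "A") for i in range(n_residues))
    phi = np.array([-120.0 if i in hinge_set else -57.0 for i in range(n_residues)])
    psi = np.array([130.0 if i in hinge_set else -47.0 for i in range(n_residues)])
    start = build_peptide(FixtureSpec(n_residues, seq, phi, psi, hinge_set, seed))

    if hinge_deltas is None:
        mid = sorted(hinge_set)
        # a large, open-to-close style hinge rotation spread over the hinge
        defaults = [(None, 90.0), (-70.0, None), (None, 50.0)]
        hinge_deltas = {r: d for r, d in zip(mid, defaults)}
    rng = np.random.default_rng(seed)
    phi_g, psi_g = phi.copy(), psi.copy()
    lo, hi = decoy_offset_range
    # crankshaft-compensated decoys: +delta on psi(i), -delta on phi(i+1)
    # deform locally (small lever effect) while every affected torsion still
    # differs from its counterpart by more than the eligibility cutoff
    for i in range(n_residues - 1):
        if i in hinge_set or (i + 1) in hinge_set:
            continue
        delta = rng.choice([-1.0, 1.0]) * rng.uniform(lo, hi)
        psi_g[i] += delta
        phi_g[i + 1] -= delta
    for res_i, (dphi, dpsi) in hinge_deltas.items():
        if dphi is not None:
            phi_g[res_i] += dphi
        if dpsi is not None:
            psi_g[res_i] += dpsi
    goal = build_peptide(FixtureSpec(n_residues, seq, phi_g, psi_g, hinge_set, seed))
    return start, goal, hinge_set
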