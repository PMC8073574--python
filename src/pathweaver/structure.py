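"""Coarse-grained protein structures: PDB input/output and residue pairing.

The model keeps the backbone heavy atoms N, CA, C, O and the C-beta of every
non-glycine residue.  Heteroatoms, waters, hydrogens, alternate locations
(other than the highest-occupancy one) and non-standard residues are
discarded on input.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .constants import (
    ATOM_ORDER,
    PEPTIDE_BOND_MAX_LENGTH,
    RETAINED_ATOMS,
    STANDARD_RESIDUES_3TO1,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "Structure",
    "ResiduePairing",
    "PDBParseError",
    "read_structure",
    "write_structure",
    "write_path",
    "read_path",
    "pair_residues",
]


class PDBParseError(ValueError):
    """Raised when a PDB text cannot be interpreted."""


@dataclass(frozen=True)
class AtomRecord:
    """One retained atom of the coarse-grained model."""

    serial: int
    name: str
    residue_number: int
    residue_name: str
    chain_id: str
    position: np.ndarray
    element: str
    insertion_code: str = ""


class Structure:
    """Array-backed coarse-grained structure of a single protein chain.

    Atoms are stored grouped by residue, each residue in the canonical
    order N, CA, C, O, CB; glycine has no CB.  Residue indices used
    throughout the package are 0-based positions along the chain, while the
    original PDB residue numbers (plus insertion codes) are preserved for
    reporting.
    """

    def __init__(
        self,
        coords: np.ndarray,
        atom_names: np.ndarray,
        atom_residue_index: np.ndarray,
        residue_numbers: np.ndarray,
        residue_names: np.ndarray,
        chain_id: str = "A",
        insertion_codes: np.ndarray | None = None,
        serials: np.ndarray | None = None,
    ):
        self.coords = np.asarray(coords, dtype=float)
        self.atom_names = np.asarray(atom_names, dtype="U2")
        self.atom_residue_index = np.asarray(atom_residue_index, dtype=int)
        self.residue_numbers = np.asarray(residue_numbers, dtype=int)
        self.residue_names = np.asarray(residue_names, dtype="U3")
        self.chain_id = chain_id
        n_res = len(self.residue_numbers)
        if insertion_codes is None:
            insertion_codes = np.full(n_res, "", dtype="U1")
        self.insertion_codes = np.asarray(insertion_codes, dtype="U1")
        if serials is None:
            serials = np.arange(1, len(self.coords) + 1)
        self.serials = np.asarray(serials, dtype=int)
        self._validate()
        self._index_atoms()

    # -- construction helpers -------------------------------------------------

    def _validate(self) -> None:
        if len(self.coords) == 0:
            raise ValueError("structure has no atoms")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if len(self.coords) != len(self.atom_names) or len(self.coords) != len(
            self.atom_residue_index
        ):
            raise ValueError("atom array lengths disagree")
        unknown = set(np.unique(self.atom_names)) - set(RETAINED_ATOMS)
        if unknown:
            raise ValueError(f"unsupported atom names: {sorted(unknown)}")

    def _index_atoms(self) -> None:
        n_res = self.n_residues
        index = np.full((n_res, len(RETAINED_ATOMS)), -1, dtype=int)
        for i, (name, res_i) in enumerate(zip(self.atom_names, self.atom_residue_index)):
            index[res_i, ATOM_ORDER[str(name)]] = i
        missing = [
            int(r)
            for r in range(n_res)
            if any(index[r, ATOM_ORDER[a]] < 0 for a in ("N", "CA", "C"))
        ]
        if missing:
            raise ValueError(f"residues missing N/CA/C backbone atoms: {missing}")
        for r in range(n_res):
            has_cb = index[r, ATOM_ORDER["CB"]] >= 0
            if self.residue_names[r] == "GLY" and has_cb:
                raise ValueError(f"glycine residue {r} carries a CB atom")
            if self.residue_names[r] != "GLY" and not has_cb:
                raise ValueError(
                    f"non-glycine residue {r} ({self.residue_names[r]}) lacks a CB atom"
                )
        self._atom_index = index
        # chain gaps: peptide bond C(i)-N(i+1) must exist and be short
        gap = np.zeros(n_res, dtype=bool)
        for r in range(n_res - 1):
            c_i = index[r, ATOM_ORDER["C"]]
            n_next = index[r + 1, ATOM_ORDER["N"]]
            dist = np.linalg.norm(self.coords[c_i] - self.coords[n_next])
            gap[r] = dist > PEPTIDE_BOND_MAX_LENGTH
        gap[n_res - 1] = True
        self.gap_after = gap

    # -- views ----------------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def n_residues(self) -> int:
        return len(self.residue_numbers)

    @property
    def residues(self) -> list[tuple[int, str]]:
        return list(zip(self.residue_numbers.tolist(), self.residue_names.tolist()))

    @property
    def sequence(self) -> str:
        return "".join(STANDARD_RESIDUES_3TO1.get(str(r), "X") for r in self.residue_names)

    @property
    def atoms(self) -> list[AtomRecord]:
        records = []
        for i in range(self.n_atoms):
            name = str(self.atom_names[i])
            r = int(self.atom_residue_index[i])
            records.append(
                AtomRecord(
                    serial=int(self.serials[i]),
                    name=name,
                    residue_number=int(self.residue_numbers[r]),
                    residue_name=str(self.residue_names[r]),
                    chain_id=self.chain_id,
                    position=self.coords[i].copy(),
                    element=name[0],
                    insertion_code=str(self.insertion_codes[r]),
                )
            )
        return records

    def atom_index(self, residue_index: int, atom_name: str) -> int:
        """Flat atom index of ``atom_name`` in residue ``residue_index``; -1 if absent."""
        return int(self._atom_index[residue_index, ATOM_ORDER[atom_name]])

    @property
    def ca_indices(self) -> np.ndarray:
        return self._atom_index[:, ATOM_ORDER["CA"]]

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with replaced coordinates (topology shared)."""
        new = object.__new__(Structure)
        new.coords = np.asarray(coords, dtype=float)
        for name in (
            "atom_names",
            "atom_residue_index",
            "residue_numbers",
            "residue_names",
            "chain_id",
            "insertion_codes",
            "serials",
            "_atom_index",
            "gap_after",
        ):
            setattr(new, name, getattr(self, name))
        return new

    def same_topology(self, other: "Structure") -> bool:
        return (
            self.n_atoms == other.n_atoms
            and np.array_equal(self.atom_names, other.atom_names)
            and np.array_equal(self.atom_residue_index, other.atom_residue_index)
            and np.array_equal(self.residue_numbers, other.residue_numbers)
            and np.array_equal(self.residue_names, other.residue_names)
        )


@dataclass
class ResiduePairing:
    """One-to-one, order-preserving correspondence between residues of two
    structures of the same protein (0-based residue indices)."""

    pairs: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def start_indices(self) -> np.ndarray:
        return np.array([p[0] for p in self.pairs], dtype=int)

    @property
    def goal_indices(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs], dtype=int)


# -- PDB input ----------------------------------------------------------------


def _scan_for_malformed_lines(pdb_text: str, chain_id: str) -> bool:
    """Pre-scan ATOM records: raise a line-numbered error on malformed
    coordinate fields; return whether the chain has any ATOM record."""
    seen = False
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith("ATOM"):
            continue
        if len(line) >= 22 and line[21] != chain_id:
            continue
        seen = True
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: truncated ATOM record")
        for lo, hi in ((30, 38), (38, 46), (46, 54)):
            try:
                float(line[lo:hi])
            except ValueError as exc:
                raise PDBParseError(
                    f"line {lineno}: malformed coordinate field {line[lo:hi]!r}"
                ) from exc
    return seen


def _structure_from_atom_array(arr, chain_id: str) -> Structure:
    mask = (
        (arr.chain_id == chain_id)
        & np.isin(arr.res_name, list(STANDARD_RESIDUES_3TO1))
        & np.isin(arr.atom_name, list(RETAINED_ATOMS))
        & ~arr.hetero
    )
    arr = arr[mask]
    if arr.array_length() == 0:
        raise PDBParseError(f"empty chain: no usable ATOM records for chain {chain_id!r}")

    ins = arr.ins_code if "ins_code" in arr.get_annotation_categories() else np.full(
        arr.array_length(), "", dtype="U1"
    )
    keys = list(zip(arr.res_id.tolist(), ins.tolist()))
    order = sorted(set(keys), key=lambda k: (k[0], k[1]))

    res_numbers, res_names, ins_codes = [], [], []
    coords, names, atom_res, serials = [], [], [], []
    dropped = []
    for key in order:
        sel = [i for i, k in enumerate(keys) if k == key]
        res_name = str(arr.res_name[sel[0]])
        per_atom: dict[str, int] = {}
        for i in sel:
            per_atom.setdefault(str(arr.atom_name[i]), i)  # first wins (altloc resolved upstream)
        required = ["N", "CA", "C", "O"] + ([] if res_name == "GLY" else ["CB"])
        if any(a not in per_atom for a in required):
            dropped.append(key)
            continue
        res_index = len(res_numbers)
        res_numbers.append(int(key[0]))
        res_names.append(res_name)
        ins_codes.append(str(key[1]))
        for a in RETAINED_ATOMS:
            if a in per_atom:
                i = per_atom[a]
                coords.append(arr.coord[i])
                names.append(a)
                atom_res.append(res_index)
                serials.append(len(serials) + 1)
    if dropped:
        logger.warning(
            "dropped %d residue(s) with incomplete backbone: %s",
            len(dropped),
            ", ".join(f"{num}{code}".strip() for num, code in dropped[:20]),
        )
    if not res_numbers:
        raise PDBParseError(f"empty chain: no complete residues in chain {chain_id!r}")
    return Structure(
        coords=np.array(coords),
        atom_names=np.array(names),
        atom_residue_index=np.array(atom_res),
        residue_numbers=np.array(res_numbers),
        residue_names=np.array(res_names),
        chain_id=chain_id,
        insertion_codes=np.array(ins_codes),
        serials=np.array(serials),
    )


def read_structure(pdb_text: str, chain_id: str = "A") -> Structure:
    """Parse PDB text into the coarse-grained model of one chain.

    Only N, CA, C, O and CB atoms of standard amino acids are retained;
    alternate locations are resolved to the highest-occupancy variant, and
    residues missing any backbone atom (or CB in a non-glycine) are dropped
    with a logged warning.
    """
    if not _scan_for_malformed_lines(pdb_text, chain_id):
        raise PDBParseError(f"empty chain: no ATOM records for chain {chain_id!r}")
    try:
        pdb = PDBFile.read(io.StringIO(pdb_text))
        arr = pdb.get_structure(model=1, altloc="occupancy")
    except PDBParseError:
        raise
    except Exception as exc:  # biotite raises several error types
        raise PDBParseError(f"could not parse PDB text: {exc}") from exc
    return _structure_from_atom_array(arr, chain_id)


def read_path(pdb_text: str, chain_id: str = "A") -> list[Structure]:
    """Parse a multi-model PDB text into one Structure per model."""
    pdb = PDBFile.read(io.StringIO(pdb_text))
    n_models = pdb.get_model_count()
    return [
        _structure_from_atom_array(
            pdb.get_structure(model=k, altloc="occupancy"), chain_id
        )
        for k in range(1, n_models + 1)
    ]


# -- PDB output ---------------------------------------------------------------


def _to_atom_array(structure: Structure):
    n = structure.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = structure.coords.astype(np.float32)
    arr.chain_id = np.full(n, structure.chain_id, dtype="U4")
    arr.res_id = structure.residue_numbers[structure.atom_residue_index]
    arr.ins_code = structure.insertion_codes[structure.atom_residue_index]
    arr.res_name = structure.residue_names[structure.atom_residue_index]
    arr.atom_name = structure.atom_names
    arr.element = np.array([n[0] for n in structure.atom_names], dtype="U2")
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def _ensure_ter_end(text: str) -> str:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    has_models = any(ln.startswith("MODEL") for ln in lines)
    if not has_models:
        if not any(ln.startswith("TER") for ln in lines):
            tail = []
            while lines and lines[-1].startswith("END"):
                tail.append(lines.pop())
            lines.append("TER")
            lines.extend(reversed(tail))
    if not lines[-1].startswith("END"):
        lines.append("END")
    return "\n".join(lines) + "\n"


def write_structure(structure: Structure) -> str:
    """Serialise a Structure to single-model PDB text (3-decimal coordinates)."""
    if structure.n_atoms == 0:
        raise ValueError("cannot write an empty structure")
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(structure))
    buf = io.StringIO()
    pdb.write(buf)
    return _ensure_ter_end(buf.getvalue())


def write_path(conformations) -> str:
    """Serialise an ordered list of same-topology Structures as multi-model PDB.

    Model numbers are 1-based and follow the path order, so the trajectory
    can be animated directly by any molecular viewer.
    """
    structures = [
        c.structure if hasattr(c, "structure") else c for c in conformations
    ]
    if not structures:
        raise ValueError("cannot write an empty path")
    first = structures[0]
    for k, s in enumerate(structures[1:], start=2):
        if not first.same_topology(s):
            raise ValueError(f"topology mismatch between model 1 and model {k}")
    stack = struc.stack([_to_atom_array(s) for s in structures])
    pdb = PDBFile()
    pdb.set_structure(stack)
    buf = io.StringIO()
    pdb.write(buf)
    text = buf.getvalue()
    if "MODEL" not in text:
        # a single-model stack is still written as an explicit MODEL block
        lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("END")]
        text = "\n".join(["MODEL        1", *lines, "ENDMDL"]) + "\n"
    return _ensure_ter_end(text)


# -- residue pairing ----------------------------------------------------------


def pair_residues(start: Structure, goal: Structure) -> ResiduePairing:
    """Pair residues of two conformations of the same protein.

    Residues sharing a PDB residue number (and insertion code) are paired
    wherever the residue names agree there; if the shared numbering is
    unreliable (names agree at fewer than 80% of the shared numbers), the
    longest common ungapped block of the two sequences is used instead.
    Unpaired residues take no part in lRMSD or perturbation.
    """
    key_start = {
        (int(n), str(c)): i
        for i, (n, c) in enumerate(zip(start.residue_numbers, start.insertion_codes))
    }
    key_goal = {
        (int(n), str(c)): i
        for i, (n, c) in enumerate(zip(goal.residue_numbers, goal.insertion_codes))
    }
    shared = sorted(set(key_start) & set(key_goal))
    by_number = [
        (key_start[k], key_goal[k])
        for k in shared
        if start.residue_names[key_start[k]] == goal.residue_names[key_goal[k]]
    ]
    if shared and len(by_number) >= 3 and len(by_number) >= 0.8 * len(shared):
        pairs = by_number
    else:
        pairs = _longest_common_block(start.sequence, goal.sequence)
    if len(pairs) < 3:
        raise ValueError(
            "incompatible structures: fewer than 3 residues could be paired"
        )
    return ResiduePairing(pairs=pairs)


def _longest_common_block(seq_a: str, seq_b: str) -> list[tuple[int, int]]:
    """Longest common contiguous substring, as index pairs (O(n*m) DP)."""
    n, m = len(seq_a), len(seq_b)
    best_len, best_end_a, best_end_b = 0, 0, 0
    prev = np.zeros(m + 1, dtype=int)
    for i in range(1, n + 1):
        cur = np.zeros(m + 1, dtype=int)
        for j in range(1, m + 1):
            if seq_a[i - 1] == seq_b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best_len:
                    best_len, best_end_a, best_end_b = int(cur[j]), i, j
        prev = cur
    return [
        (best_end_a - best_len + k, best_end_b - best_len + k)
        for k in range(best_len)
    ]
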