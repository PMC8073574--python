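"""Shared chemical constants for the coarse-grained (backbone + C-beta) model.

The ideal-geometry table below is used both by the synthetic peptide builder
and as the equilibrium values of the bonded energy terms, so that an
ideal-geometry peptide sits exactly at the minimum of the bond and angle
potentials.
"""

from __future__ import annotations

# Atom names retained by the coarse-grained model, in canonical within-residue order.
RETAINED_ATOMS = ("N", "CA", "C", "O", "CB")
ATOM_ORDER = {name: i for i, name in enumerate(RETAINED_ATOMS)}

# Ideal bond lengths, Angstrom.
IDEAL_BOND_LENGTHS: dict[tuple[str, str], float] = {
    ("N", "CA"): 1.458,
    ("CA", "C"): 1.525,
    ("C", "N"): 1.329,   # peptide bond to the next residue
    ("C", "O"): 1.231,
    ("CA", "CB"): 1.530,
}

# Ideal bond angles, degrees.  C-CA-CB is the value realised by placing CB at
# the tetrahedral torsion below given N-CA-C and N-CA-CB; freezing it keeps
# the angle potential at its minimum for ideal-geometry peptides.
IDEAL_BOND_ANGLES: dict[tuple[str, str, str], float] = {
    ("N", "CA", "C"): 111.0,
    ("CA", "C", "N"): 116.6,
    ("C", "N", "CA"): 121.7,
    ("CA", "C", "O"): 120.5,
    ("O", "C", "N"): 122.9,
    ("N", "CA", "CB"): 110.5,
    ("C", "CA", "CB"): 110.2202436846256,
}

# Improper torsion C(i)-N(i)-CA(i)-CB(i) fixing L-chirality of the C-beta.
CB_PLACEMENT_TORSION = -122.6
# Peptide bond torsion (trans).
OMEGA_TRANS = 180.0

STANDARD_RESIDUES_3TO1: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
STANDARD_RESIDUES_1TO3 = {v: k for k, v in STANDARD_RESIDUES_3TO1.items()}

# Residues whose C-beta takes part in hydrophobic contacts.
HYDROPHOBIC_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO"}

# Kyte-Doolittle hydropathy, used as the burial-term weight.
KYTE_DOOLITTLE: dict[str, float] = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5,
    "MET": 1.9, "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8,
    "TRP": -0.9, "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5,
    "GLN": -3.5, "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

# Maximum C(i)-N(i+1) distance regarded as a peptide bond; beyond this the
# chain is treated as broken (a gap).
PEPTIDE_BOND_MAX_LENGTH = 1.8
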