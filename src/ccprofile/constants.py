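"""Chemical tables and pinned numeric constants shared across modules."""

from __future__ import annotations

import math

# --- amino acids -----------------------------------------------------------

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

# Common chemically modified residues resolved to their parent letter.
# Used to embed observed coordinate residues into the SEQRES sequence.
MODIFIED_TO_ONE: dict[str, str] = {
    "MSE": "M",   # selenomethionine
    "SEC": "C",   # selenocysteine (U has no superposition semantics; fall back)
    "PYL": "K",   # pyrrolysine
    "CSO": "C", "CSD": "C", "CME": "C", "OCS": "C", "CSX": "C",
    "SEP": "S", "TPO": "T", "PTR": "Y",
    "KCX": "K", "LLP": "K", "MLY": "K",
    "HYP": "P", "PCA": "E", "FME": "M",
    "CGU": "E", "CXM": "M", "SAC": "S", "AIB": "A", "DAL": "A",
}

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# --- nucleic acids ---------------------------------------------------------

NUCLEOTIDE_IDS = {
    "A", "C", "G", "U", "I",
    "DA", "DC", "DG", "DT", "DU", "DI",
}

# --- solvent / artifact components ----------------------------------------

WATER_IDS = {"HOH", "DOD", "WAT"}

# Crystallization artifacts excluded from binding-target consideration.
DEFAULT_PSEUDO_LIGANDS = frozenset(
    {"LA", "LU", "MSE", "OS", "PT", "RE", "SM", "SR", "WO4", "XE", "YB"}
)

# Monoatomic / simple ions for target categorization (single heavy atom
# components are classified as ions regardless of membership here).
ION_IDS = {
    "NA", "K", "MG", "CA", "ZN", "CL", "MN", "FE", "FE2", "CU", "CU1",
    "CO", "NI", "CD", "HG", "BR", "IOD", "F", "LI", "RB", "CS", "BA",
    "AL", "PB", "AG", "AU", "SO4", "PO4", "NO3", "CO3",
}

HYDROGEN_ELEMENTS = {"H", "D"}

# --- sequence mapping (gapless Karlin-Altschul statistics) -----------------

# Ungapped BLOSUM62 parameters, natural-log units.
KA_LAMBDA = 0.318
KA_K = 0.13
EVALUE_THRESHOLD = 1e-3
IDENTITY_THRESHOLD = 95.0

# --- hydropathy ------------------------------------------------------------

# Kyte-Doolittle residue hydropathy scale.
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

HYDROPATHY_WINDOW = 15

# --- conservation ----------------------------------------------------------

LN20 = math.log(20.0)
DEFAULT_CLUSTER_THETA = 0.8

# --- secondary structure (hydrogen-bond pattern assignment) ----------------

# Electrostatic H-bond model: E = Q * (1/rON + 1/rCH - 1/rOH - 1/rCN)
DSSP_Q = 0.084 * 332.0          # kcal/mol * Angstrom
DSSP_HBOND_CUTOFF = -0.5        # kcal/mol
DSSP_BEND_KAPPA = 70.0          # degrees
CHAIN_BREAK_CA_DIST = 4.5       # Angstrom
NH_BOND_LENGTH = 1.0            # Angstrom, geometric amide H placement

# --- profiles ---------------------------------------------------------------

CCP_HALF_WINDOW = 10            # 21-residue sliding window
CCP_MIN_COMMON = 3
SITE_CUTOFF = 5.0               # Angstrom, binding-site flag
NAME_CUTOFF = 3.0               # Angstrom, target-name association
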