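"""Deterministic synthetic structures and alignments for testing.

Backbones are grown with ideal bond lengths/angles from (phi, psi) torsions,
so helix/extended/sheet geometries are exact and reproducible.  Hinge pairs
emulate an open/closed conformational change: the bound copy has its
C-terminal segment rotated about an axis through the hinge C-alpha and a
ligand planted at a stated distance from a stated residue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .constants import AA_ALPHABET, ONE_TO_THREE
from .seq_profiles import MSA
from .structure_io import (
    Atom,
    ProteinStructure,
    Residue,
    StructureFile,
    write_pdb,
)

# ideal backbone geometry, Angstrom / degrees
BOND_N_CA = 1.46
BOND_CA_C = 1.52
BOND_C_N = 1.33
BOND_C_O = 1.23
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 117.0
ANGLE_C_N_CA = 121.0
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

TORSIONS = {
    "helix": (-57.0, -47.0),
    "extended": (-139.0, 135.0),
    "flat": (180.0, 180.0),   # exactly periodic planar zigzag (sheet building)
}

# Rigid placement of an antiparallel partner strand against a flat 8-residue
# strand, tuned once so the hydrogen-bond register forms a ladder; longer
# strands shift by whole 2-residue repeats to keep the register.
SHEET_PARTNER_SHIFT = np.array([15.6, 3.0, 0.0])


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           r: float, theta_deg: float, phi_deg: float) -> np.ndarray:
    """Place atom D from A-B-C with bond length r(C-D), angle B-C-D, torsion A-B-C-D."""
    theta = math.radians(theta_deg)
    phi = math.radians(phi_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [-r * math.cos(theta), r * math.sin(theta) * math.cos(phi),
         r * math.sin(theta) * math.sin(phi)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _backbone_coords(length: int, phi: float, psi: float) -> list[dict[str, np.ndarray]]:
    """N/CA/C/O coordinates of an ideal chain with uniform (phi, psi)."""
    coords: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(180.0 - ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, length):
        prev = coords[-1]
        n = _place(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi)
        ca = _place(prev["CA"], prev["C"], n, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c = _place(prev["C"], n, ca, BOND_CA_C, ANGLE_N_CA_C, phi)
        coords.append({"N": n, "CA": ca, "C": c})
    for i, res in enumerate(coords):
        if i + 1 < len(coords):
            res["O"] = _place(res["N"], res["CA"], res["C"], BOND_C_O,
                              ANGLE_CA_C_O, psi + 180.0)
        else:
            res["O"] = _place(res["N"], res["CA"], res["C"], BOND_C_O,
                              ANGLE_CA_C_O, psi + 180.0)
    return coords


@dataclass
class FixtureSpec:
    length: int = 60
    geometry: str = "helix"              # "helix" | "extended"
    sequence: Optional[str] = None       # default poly-alanine
    hinge_position: int = 30             # 1-based residue of the hinge
    hinge_angle_deg: float = 30.0
    ligands: Sequence[tuple[str, int, float]] = ()   # (comp id, anchor residue, distance)
    deleted_free: Sequence[tuple[int, int]] = ()     # coordinate gaps in the free copy
    deleted_bound: Sequence[tuple[int, int]] = ()
    seed: int = 0
    free_id: str = "1FRE"
    bound_id: str = "1BND"
    chain_id: str = "A"

    def resolved_sequence(self) -> str:
        if self.sequence is not None:
            seq = self.sequence.upper()
            if len(seq) != self.length:
                raise ValueError("sequence length disagrees with spec length")
            return seq
        return "A" * self.length


def _build_chain(
    spec: FixtureSpec,
    file_id: str,
    coords: list[dict[str, np.ndarray]],
    deleted: Sequence[tuple[int, int]],
) -> ProteinStructure:
    seq = spec.resolved_sequence()
    gone = set()
    for lo, hi in deleted:
        gone.update(range(lo, hi + 1))
    observed: dict[int, Residue] = {}
    for i, res_coords in enumerate(coords, start=1):
        if i in gone:
            continue
        name3 = ONE_TO_THREE.get(seq[i - 1], "UNK")
        atoms = [Atom(name, "O" if name == "O" else name[0], xyz)
                 for name, xyz in res_coords.items()]
        observed[i] = Residue(name3, spec.chain_id, i, atoms=atoms)
    return ProteinStructure(
        file_id=file_id,
        chain_id=spec.chain_id,
        seqres=seq,
        observed=observed,
        seqres3=tuple(ONE_TO_THREE.get(ch, "UNK") for ch in seq),
    )


def make_backbone(spec: FixtureSpec) -> StructureFile:
    """A single ideal-geometry chain as a parsed :class:`StructureFile`."""
    if spec.length < 4:
        raise ValueError("need length >= 4")
    phi, psi = TORSIONS[spec.geometry]
    coords = _backbone_coords(spec.length, phi, psi)
    chain = _build_chain(spec, spec.free_id, coords, spec.deleted_free)
    return StructureFile(id=spec.free_id, polymer_chains=[chain])


def _rotate_tail(
    coords: list[dict[str, np.ndarray]], hinge: int, angle_deg: float, seed: int
) -> list[dict[str, np.ndarray]]:
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    axis = rng.normal(size=3)
    axis = axis / np.linalg.norm(axis)
    rot = Rotation.from_rotvec(math.radians(angle_deg) * axis)
    pivot = coords[hinge - 1]["CA"]
    out = []
    for i, res in enumerate(coords, start=1):
        if i <= hinge:
            out.append({k: v.copy() for k, v in res.items()})
        else:
            out.append({k: rot.apply(v - pivot) + pivot for k, v in res.items()})
    return out


def _plant_ligand(
    comp_id: str,
    anchor: dict[str, np.ndarray],
    distance: float,
    centroid: np.ndarray,
    chain_id: str,
    number: int,
    natoms: int = 3,
) -> Residue:
    """Het residue whose nearest atom sits exactly ``distance`` from the
    anchor residue's CA, further atoms strung outward along the normal."""
    ca = anchor["CA"]
    direction = ca - centroid
    norm = np.linalg.norm(direction)
    direction = direction / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
    element = comp_id[0] if comp_id[0].isalpha() else "C"
    atoms = [
        Atom(f"X{k + 1}", element, ca + (distance + 0.9 * k) * direction)
        for k in range(max(1, natoms))
    ]
    return Residue(comp_id, chain_id, number, is_het=True, atoms=atoms)


def make_hinge_pair(spec: FixtureSpec) -> tuple[StructureFile, StructureFile]:
    """(free, bound) pair: bound copy hinge-rotated with planted ligands.

    The free file has no het groups, so the bound file's inventory is a
    strict superset and the two satisfy the pairing conditions.
    """
    if not 1 < spec.hinge_position < spec.length:
        raise ValueError("hinge must be inside the chain")
    phi, psi = TORSIONS[spec.geometry]
    coords = _backbone_coords(spec.length, phi, psi)
    free_chain = _build_chain(spec, spec.free_id, coords, spec.deleted_free)
    free = StructureFile(id=spec.free_id, polymer_chains=[free_chain])

    bound_coords = _rotate_tail(coords, spec.hinge_position, spec.hinge_angle_deg, spec.seed)
    bound_chain = _build_chain(spec, spec.bound_id, bound_coords, spec.deleted_bound)
    bound = StructureFile(id=spec.bound_id, polymer_chains=[bound_chain])
    centroid = np.mean([r["CA"] for r in bound_coords], axis=0)
    for k, lig in enumerate(spec.ligands, start=1):
        comp_id, anchor_pos, distance = lig[:3]
        natoms = lig[3] if len(lig) > 3 else 3
        bound.het_residues.append(
            _plant_ligand(comp_id, bound_coords[anchor_pos - 1], distance,
                          centroid, "L", 900 + k, natoms=natoms)
        )
    return free, bound


def write_fixture(sf: StructureFile, path: str | Path) -> Path:
    """Serialize a fixture StructureFile as PDB text."""
    path = Path(path)
    write_pdb(
        sf.polymer_chains[:1], path, het=[sf.het_residues],
        remarks=[f"fixture {sf.id}"], header_id=sf.id,
    )
    return path


def make_antiparallel_sheet(
    n_per_strand: int = 8, file_id: str = "1SHT", chain_id: str = "A"
) -> StructureFile:
    """One chain holding two antiparallel flat strands that hydrogen-bond
    into a ladder (core residues assign as strand).

    ``n_per_strand`` must be even so the partner shift is a whole number of
    2-residue repeats.
    """
    import math as _math

    from scipy.spatial.transform import Rotation

    if n_per_strand < 4 or n_per_strand % 2:
        raise ValueError("n_per_strand must be even and >= 4")
    n = n_per_strand
    coords1 = _backbone_coords(n, *TORSIONS["flat"])
    repeat = np.append(coords1[2]["CA"][:2] - coords1[0]["CA"][:2], 0.0)
    shift = SHEET_PARTNER_SHIFT + ((n - 8) / 2) * repeat
    rot = Rotation.from_rotvec(_math.pi * np.array([0.0, 0.0, 1.0]))
    coords2 = [{k: rot.apply(v) + shift for k, v in r.items()} for r in coords1]
    observed: dict[int, Residue] = {}
    for i, rc in enumerate(coords1 + coords2, start=1):
        atoms = [Atom(name, "O" if name == "O" else name[0], xyz)
                 for name, xyz in rc.items()]
        observed[i] = Residue("ALA", chain_id, i, atoms=atoms)
    chain = ProteinStructure(
        file_id=file_id, chain_id=chain_id, seqres="A" * (2 * n),
        observed=observed, seqres3=("ALA",) * (2 * n),
    )
    return StructureFile(id=file_id, polymer_chains=[chain])


# ---------------------------------------------------------------------------
# synthetic alignments
# ---------------------------------------------------------------------------


def make_msa(
    L: int,
    n: int,
    conserved_positions: Sequence[int] = (),
    families: int = 1,
    seed: int = 0,
    mutation_rate: float = 0.5,
) -> MSA:
    """Synthetic gap-free alignment; row 0 is the reference.

    Conserved positions carry one amino-acid type in every row; other
    positions mutate away from a family consensus.  With ``families`` >= 2,
    rows split into groups with high within-family and low between-family
    identity, for independent-count weighting tests.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    alphabet = list(AA_ALPHABET)
    conserved = set(conserved_positions)
    consensi = [rng.choice(alphabet, size=L) for _ in range(max(1, families))]
    for pos in conserved:
        for fam in consensi[1:]:
            fam[pos - 1] = consensi[0][pos - 1]
    rows: list[str] = []
    for r in range(n):
        fam = consensi[r % len(consensi)]
        row = fam.copy()
        for i in range(L):
            if (i + 1) in conserved:
                continue
            if r > 0 and rng.random() < mutation_rate:
                row[i] = rng.choice(alphabet)
        rows.append("".join(row))
    rows[0] = "".join(consensi[0])
    ids = [f"seq{r}" for r in range(n)]
    ids[0] = "ref"
    return MSA(ids, rows, ref_row=0)


def write_msa_fasta(msa: MSA, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for rid, row in zip(msa.ids, msa.rows):
            fh.write(f">{rid}\n{row}\n")
    return path
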