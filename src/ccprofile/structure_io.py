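"""PDB-format reading and writing.

Parses SEQRES/MODRES/ATOM/HETATM/REMARK records into a light-weight object
model: :class:`StructureFile` holds polymer chains (:class:`ProteinStructure`),
non-polymer het groups and file-level metadata.  Only MODEL 1 of multi-model
files is read.  Writing emits fixed-width PDB v3.3 records and supports a
two-state (MODEL 1 / MODEL 2) output for superposed pairs.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .constants import (
    HYDROGEN_ELEMENTS,
    MODIFIED_TO_ONE,
    NUCLEOTIDE_IDS,
    THREE_TO_ONE,
    WATER_IDS,
)


class PDBParseError(ValueError):
    """Unparseable record or unsatisfiable structural constraint."""


class ChainNotFoundError(KeyError):
    """A requested chain is absent or has no usable SEQRES."""


class MappingError(ValueError):
    """Observed residues cannot be embedded into SEQRES without mismatch."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise PDBParseError(f"non-finite coordinates for atom {self.name!r}")
        if not self.element:
            raise PDBParseError(f"empty element for atom {self.name!r}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element in HYDROGEN_ELEMENTS


@dataclass
class Residue:
    name3: str
    chain_id: str
    number: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)
    is_het: bool = False

    @property
    def author_id(self) -> tuple[int, str]:
        return (self.number, self.icode)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def one_letter(self) -> str:
        return residue_one_letter(self.name3)


def heavy_atoms(residue: Residue) -> list[Atom]:
    """Atoms of ``residue`` whose element is not hydrogen or deuterium."""
    return residue.heavy_atoms()


def residue_one_letter(name3: str, modres: Mapping[str, str] | None = None) -> str:
    """Translate a 3-letter component id to a one-letter amino acid.

    Modified residues fall back to their parent; unknown components map to X.
    """
    name3 = name3.strip().upper()
    if modres and name3 in modres:
        return modres[name3]
    if name3 in THREE_TO_ONE:
        return THREE_TO_ONE[name3]
    if name3 in MODIFIED_TO_ONE:
        return MODIFIED_TO_ONE[name3]
    return "X"


@dataclass
class ProteinStructure:
    """One polymer chain: SEQRES sequence plus observed coordinate residues.

    ``observed`` maps 1-based SEQRES indices to residues; SEQRES indices
    without coordinates are the disordered set.
    """

    file_id: str
    chain_id: str
    seqres: str
    observed: dict[int, Residue] = field(default_factory=dict)
    seqres3: tuple[str, ...] = ()
    kind: str = "protein"  # "protein" | "nucleic"

    def __post_init__(self) -> None:
        for idx in self.observed:
            if not 1 <= idx <= len(self.seqres):
                raise PDBParseError(
                    f"observed index {idx} outside SEQRES of length {len(self.seqres)}"
                )

    @property
    def disordered(self) -> set[int]:
        return set(range(1, len(self.seqres) + 1)) - set(self.observed)

    def ca_coords(self, idx: int) -> Optional[np.ndarray]:
        res = self.observed.get(idx)
        if res is None:
            return None
        ca = res.atom("CA")
        return None if ca is None else ca.coords


@dataclass
class StructureFile:
    id: str
    polymer_chains: list[ProteinStructure] = field(default_factory=list)
    het_residues: list[Residue] = field(default_factory=list)
    waters: int = 0
    resolution: Optional[float] = None
    ph: Optional[float] = None
    temperature: Optional[float] = None

    @property
    def het_groups(self) -> Counter:
        """Multiset of (component id, heavy atom count) across het residues."""
        return Counter(
            (r.name3, len(r.heavy_atoms())) for r in self.het_residues
        )

    def chain(self, chain_id: str) -> ProteinStructure:
        for ch in self.polymer_chains:
            if ch.chain_id == chain_id:
                return ch
        raise ChainNotFoundError(
            f"chain {chain_id!r} not found (or lacks SEQRES) in {self.id}"
        )


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _infer_element(name_field: str, element_field: str) -> str:
    elem = element_field.strip().upper()
    if elem:
        return elem
    name = name_field.strip().lstrip("0123456789")
    if not name:
        return "X"
    if name[0] in ("H", "D") and (len(name_field.strip()) == 4 or name[0] == "H"):
        return name[0]
    # two-letter elements keep both chars only when the raw field starts in col 13
    if len(name) >= 2 and name[:2] in {"FE", "MG", "ZN", "MN", "CU", "NA", "CL", "CA"} \
            and not name_field.startswith(" "):
        return name[:2]
    return name[0]


def _parse_float(text: str) -> Optional[float]:
    text = text.strip()
    if not text:
        return None
    try:
        return float(text)
    except ValueError:
        return None


def read_pdb(path: str | Path, file_id: str | None = None) -> StructureFile:
    """Parse a PDB-format text file into a :class:`StructureFile`.

    Altloc conflicts are resolved to the highest-occupancy atom (ties keep
    the first occurrence); only MODEL 1 is read; water residues are counted
    rather than stored.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    header_id: Optional[str] = None
    seqres3: dict[str, list[str]] = {}
    modres: dict[str, str] = {}
    resolution: Optional[float] = None
    ph: Optional[float] = None
    temperature: Optional[float] = None

    # residue key -> Residue; atom selection handles altlocs
    residues: dict[tuple, Residue] = {}
    residue_order: list[tuple] = []
    best_alt: dict[tuple, tuple[float, int]] = {}  # (res key, atom name) -> (occ, position)

    in_model = 0
    for lineno, line in enumerate(lines, start=1):
        rec = line[:6]
        try:
            if rec == "HEADER":
                token = line[62:66].strip()
                if token:
                    header_id = token
            elif rec == "SEQRES":
                chain = line[11]
                comps = line[19:70].split()
                seqres3.setdefault(chain, []).extend(comps)
            elif rec == "MODRES":
                het = line[12:15].strip()
                std = line[24:27].strip()
                if het and std in THREE_TO_ONE:
                    modres[het] = THREE_TO_ONE[std]
            elif rec.startswith("REMARK"):
                remark_no = line[6:10].strip()
                if remark_no == "2" and "RESOLUTION." in line:
                    resolution = _parse_float(line.split("RESOLUTION.")[1].replace("ANGSTROMS.", ""))
                elif remark_no == "200":
                    upper = line.upper()
                    if "PH " in upper and ":" in line:
                        val = _parse_float(line.split(":")[-1])
                        if val is not None and "TEMPERATURE" not in upper:
                            ph = val
                    if "TEMPERATURE" in upper and ":" in line:
                        val = _parse_float(line.split(":")[-1])
                        if val is not None:
                            temperature = val
            elif rec == "MODEL ":
                in_model = int(line[10:14].strip() or "1")
            elif rec == "ENDMDL":
                in_model = 0
            elif rec in ("ATOM  ", "HETATM"):
                if in_model > 1:
                    continue
                name = line[12:16]
                altloc = line[16].strip()
                name3 = line[17:20].strip()
                chain = line[21]
                resseq = int(line[22:26])
                icode = line[26].strip()
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                occ = _parse_float(line[54:60])
                occ = 1.0 if occ is None else occ
                element = _infer_element(name, line[76:78] if len(line) >= 78 else "")
                key = (chain, resseq, icode, name3, rec == "HETATM")
                if key not in residues:
                    residues[key] = Residue(
                        name3=name3, chain_id=chain, number=resseq,
                        icode=icode, is_het=(rec == "HETATM"),
                    )
                    residue_order.append(key)
                res = residues[key]
                atom_key = (key, name.strip())
                prev = best_alt.get(atom_key)
                if prev is None:
                    best_alt[atom_key] = (occ, len(res.atoms))
                    res.atoms.append(Atom(name.strip(), element, (x, y, z), altloc, occ))
                elif occ > prev[0]:
                    best_alt[atom_key] = (occ, prev[1])
                    res.atoms[prev[1]] = Atom(name.strip(), element, (x, y, z), altloc, occ)
        except (ValueError, IndexError) as exc:
            raise PDBParseError(f"{path.name}:{lineno}: unparseable record: {exc}") from exc

    sid = file_id or header_id or path.stem.upper()[:4]
    sf = StructureFile(
        id=sid, resolution=resolution, ph=ph, temperature=temperature,
    )
    if sf.resolution is not None and sf.resolution <= 0:
        sf.resolution = None

    # split residues into polymer / water / het
    chain_residues: dict[str, list[Residue]] = {}
    for key in residue_order:
        res = residues[key]
        comp = res.name3
        chain = res.chain_id
        in_seqres = comp in set(seqres3.get(chain, ()))
        if comp in WATER_IDS:
            sf.waters += 1
        elif (not res.is_het) or in_seqres:
            chain_residues.setdefault(chain, []).append(res)
        else:
            sf.het_residues.append(res)

    all_chains = sorted(set(seqres3) | set(chain_residues))
    for chain in all_chains:
        obs = chain_residues.get(chain, [])
        comps3 = seqres3.get(chain)
        if comps3 is None:
            # coordinate-only chain: derive SEQRES from observed residues
            comps3 = [r.name3 for r in obs]
        if not comps3:
            continue
        kind = _polymer_kind(comps3)
        if kind == "nucleic":
            seq = "".join(c[-1] if c in NUCLEOTIDE_IDS else "X" for c in comps3)
            ps = ProteinStructure(
                file_id=sid, chain_id=chain, seqres=seq,
                seqres3=tuple(comps3), kind="nucleic",
            )
            ps.observed = {i + 1: r for i, r in enumerate(obs)} if len(obs) == len(comps3) else {}
            sf.polymer_chains.append(ps)
            continue
        seq = "".join(residue_one_letter(c, modres) for c in comps3)
        assignment = map_observed_to_seqres(obs, seq, modres)
        ps = ProteinStructure(
            file_id=sid, chain_id=chain, seqres=seq,
            observed=assignment, seqres3=tuple(comps3),
        )
        sf.polymer_chains.append(ps)
    return sf


def _polymer_kind(comps3: Sequence[str]) -> str:
    nuc = sum(1 for c in comps3 if c in NUCLEOTIDE_IDS)
    return "nucleic" if nuc > len(comps3) / 2 else "protein"


# ---------------------------------------------------------------------------
# observed -> SEQRES mapping
# ---------------------------------------------------------------------------


def map_observed_to_seqres(
    observed: Sequence[Residue],
    seqres: str,
    modres: Mapping[str, str] | None = None,
) -> dict[int, Residue]:
    """Assign each observed residue a 1-based SEQRES index.

    Strategy: (1) constant-offset scan over author numbers (handles renumbered
    deposits and internal disordered gaps), (2) in-order letter embedding as a
    fallback when insertion codes or erratic numbering defeat the scan.
    Raises :class:`MappingError` when no mismatch-free embedding exists.
    """
    if not observed:
        return {}
    letters = [residue_one_letter(r.name3, modres) for r in observed]
    n = len(seqres)

    def compatible(pos: int, letter: str) -> bool:
        return seqres[pos - 1] == letter or letter == "X" or seqres[pos - 1] == "X"

    nums = [r.number for r in observed]
    monotone = all(b > a for a, b in zip(nums, nums[1:]))
    no_icodes = all(not r.icode for r in observed)
    if monotone and no_icodes:
        deltas = sorted(
            range(1 - min(nums), n - max(nums) + 1),
            key=lambda d: (abs(d), d),
        )
        for delta in deltas:
            if all(compatible(num + delta, let) for num, let in zip(nums, letters)):
                return {num + delta: res for num, res in zip(nums, observed)}

    # greedy in-order embedding (leftmost)
    assignment: dict[int, Residue] = {}
    pos = 1
    for res, let in zip(observed, letters):
        while pos <= n and not compatible(pos, let):
            pos += 1
        if pos > n:
            raise MappingError(
                f"observed residues not embeddable in SEQRES "
                f"(chain {observed[0].chain_id!r}, stuck at {res.name3} {res.number})"
            )
        assignment[pos] = res
        pos += 1
    return assignment


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2 or (name and name[0].isdigit()):
        return f"{name:<4s}"[:4]
    return f" {name:<3s}"


def _atom_line(rec: str, serial: int, atom: Atom, res: Residue) -> str:
    x, y, z = atom.coords
    return (
        f"{rec:<6s}{serial:>5d} {_format_atom_name(atom.name, atom.element)}"
        f"{atom.altloc or ' ':1s}{res.name3:>3s} {res.chain_id:1s}"
        f"{res.number:>4d}{res.icode or ' ':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
        f"          {atom.element:>2s}"
    )


def _seqres_lines(chain: ProteinStructure) -> list[str]:
    comps = list(chain.seqres3) or [
        # reconstruct from one-letter codes when 3-letter codes are absent
        _one_to_three(c) for c in chain.seqres
    ]
    lines = []
    for i in range(0, len(comps), 13):
        block = comps[i : i + 13]
        lines.append(
            f"SEQRES {i // 13 + 1:>3d} {chain.chain_id:1s} {len(comps):>4d}  "
            + " ".join(f"{c:>3s}" for c in block)
        )
    return lines


def _one_to_three(letter: str) -> str:
    from .constants import ONE_TO_THREE

    return ONE_TO_THREE.get(letter, "UNK")


def write_pdb(
    models: Sequence[ProteinStructure],
    path: str | Path,
    het: Sequence[Sequence[Residue]] | None = None,
    remarks: Iterable[str] = (),
    header_id: Optional[str] = None,
) -> None:
    """Write one or two chains as a PDB file.

    Two models produce a two-state file: MODEL 1 = before, MODEL 2 = after
    (caller is responsible for having transformed the coordinates).
    """
    if not models:
        raise ValueError("no models to write")
    for m in models:
        for res in m.observed.values():
            for a in res.atoms:
                if not np.all(np.isfinite(a.coords)):
                    raise ValueError("non-finite coordinates")
    out: list[str] = []
    if header_id:
        out.append(f"{'HEADER':<6s}{'':56s}{header_id[:4]:>4s}")
    for text in remarks:
        out.append(f"REMARK 999 {text}"[:80])
    for chain in models[:1]:
        out.extend(_seqres_lines(chain))
    for imodel, chain in enumerate(models, start=1):
        out.append(f"MODEL     {imodel:>4d}")
        serial = 1
        last_res = None
        for idx in sorted(chain.observed):
            res = chain.observed[idx]
            for atom in res.atoms:
                out.append(_atom_line("ATOM", serial, atom, res))
                serial += 1
            last_res = res
        if last_res is not None:
            out.append(
                f"TER   {serial:>5d}      {last_res.name3:>3s} "
                f"{last_res.chain_id:1s}{last_res.number:>4d}{last_res.icode or ' ':1s}"
            )
            serial += 1
        if het is not None and imodel <= len(het):
            for res in het[imodel - 1]:
                for atom in res.atoms:
                    out.append(_atom_line("HETATM", serial, atom, res))
                    serial += 1
        out.append("ENDMDL")
    out.append("END")
    Path(path).write_text("\n".join(out) + "\n")


def transform_structure(
    chain: ProteinStructure, rotation: np.ndarray, translation: np.ndarray
) -> ProteinStructure:
    """Return a deep copy of ``chain`` with all atoms rigidly transformed."""
    new_obs: dict[int, Residue] = {}
    for idx, res in chain.observed.items():
        atoms = [
            Atom(a.name, a.element, rotation @ a.coords + translation, a.altloc, a.occupancy)
            for a in res.atoms
        ]
        new_obs[idx] = Residue(res.name3, res.chain_id, res.number, res.icode, atoms, res.is_het)
    return ProteinStructure(
        file_id=chain.file_id, chain_id=chain.chain_id, seqres=chain.seqres,
        observed=new_obs, seqres3=chain.seqres3, kind=chain.kind,
    )


def longest_disordered_run(
    chain: ProteinStructure, start: int = 1, end: int | None = None
) -> tuple[int, int]:
    """Longest run of disordered SEQRES positions within [start, end].

    Returns the (first, last) 1-based positions of the run; ties keep the
    earliest run.  Raises ValueError when no position in range is disordered.
    """
    end = len(chain.seqres) if end is None else min(end, len(chain.seqres))
    disordered = chain.disordered
    best: tuple[int, int] | None = None
    run_start: int | None = None
    for i in range(start, end + 2):
        if i <= end and i in disordered:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            if best is None or (i - 1 - run_start) > (best[1] - best[0]):
                best = (run_start, i - 1)
            run_start = None
    if best is None:
        raise ValueError("no disordered positions in range")
    return best
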