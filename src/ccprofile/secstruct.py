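"""Secondary-structure assignment from backbone hydrogen-bond patterns.

Implements the classic dictionary method: a geometric amide hydrogen is
placed from the previous residue's C=O, an electrostatic bond energy
E = 0.084*332*(1/rON + 1/rCH - 1/rOH - 1/rCN) defines hydrogen bonds at
E < -0.5 kcal/mol, and n-turn / bridge patterns yield the raw eight classes
{G, H, I, E, B, T, S, C}.  The eight classes merge to three (G,I -> H;
T,B,S -> C), and two overlay classes mark disordered (D: in SEQRES, no
coordinates) and null (N: in the reference, outside SEQRES) positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .constants import (
    CHAIN_BREAK_CA_DIST,
    DSSP_BEND_KAPPA,
    DSSP_HBOND_CUTOFF,
    DSSP_Q,
    NH_BOND_LENGTH,
)
from .profile import Profile, new_profile
from .refmap import DISORDERED, NULL, OBSERVED, ResidueMap
from .structure_io import ProteinStructure

RAW_CLASSES = "GHIEBTSC"
MERGED = {"G": "H", "H": "H", "I": "H", "E": "E", "B": "C", "T": "C", "S": "C", "C": "C"}


def merge_3class(symbol: str) -> str:
    """Merge an eight-class symbol into {H, E, C}."""
    try:
        return MERGED[symbol]
    except KeyError:
        raise ValueError(f"unknown secondary-structure symbol {symbol!r}") from None


@dataclass
class _BackboneResidue:
    seqres_idx: int
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray
    h: Optional[np.ndarray] = None   # geometric amide H; None at chain starts
    is_pro: bool = False


def _extract_backbone(structure: ProteinStructure) -> tuple[list[_BackboneResidue], list[int]]:
    """Ordered backbone residues plus SEQRES indices lacking backbone atoms."""
    out: list[_BackboneResidue] = []
    incomplete: list[int] = []
    for idx in sorted(structure.observed):
        res = structure.observed[idx]
        atoms = {name: res.atom(name) for name in ("N", "CA", "C", "O")}
        if any(a is None for a in atoms.values()):
            incomplete.append(idx)
            continue
        out.append(
            _BackboneResidue(
                seqres_idx=idx,
                n=atoms["N"].coords, ca=atoms["CA"].coords,
                c=atoms["C"].coords, o=atoms["O"].coords,
                is_pro=res.name3.strip().upper() == "PRO",
            )
        )
    return out, incomplete


def _chain_break(a: _BackboneResidue, b: _BackboneResidue) -> bool:
    if b.seqres_idx != a.seqres_idx + 1:
        return True
    return float(np.linalg.norm(b.ca - a.ca)) > CHAIN_BREAK_CA_DIST


def _place_hydrogens(residues: list[_BackboneResidue]) -> None:
    # H along the previous residue's O->C direction, 1.0 A from N
    for prev, cur in zip(residues, residues[1:]):
        if _chain_break(prev, cur) or cur.is_pro:
            continue
        co = prev.c - prev.o
        norm = float(np.linalg.norm(co))
        if norm > 1e-9:
            cur.h = cur.n + NH_BOND_LENGTH * co / norm


def hbond_energy(donor: _BackboneResidue, acceptor: _BackboneResidue) -> float:
    """Electrostatic N-H...O=C bond energy in kcal/mol (donor provides N-H)."""
    if donor.h is None:
        return 0.0
    r_on = float(np.linalg.norm(acceptor.o - donor.n))
    r_ch = float(np.linalg.norm(acceptor.c - donor.h))
    r_oh = float(np.linalg.norm(acceptor.o - donor.h))
    r_cn = float(np.linalg.norm(acceptor.c - donor.n))
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return -9.9  # clashing atoms: treat as a (bad) bond like the original
    return DSSP_Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _hbond_set(residues: list[_BackboneResidue]) -> set[tuple[int, int]]:
    """(donor index, acceptor index) pairs over list positions."""
    n = len(residues)
    bonds: set[tuple[int, int]] = set()
    cas = np.asarray([r.ca for r in residues])
    for i in range(n):
        if residues[i].h is None:
            continue
        # distance prefilter: CA-CA < 9 A
        close = np.where(np.linalg.norm(cas - cas[i], axis=1) < 9.0)[0]
        for j in close:
            # sequence-adjacent donors/acceptors share covalent geometry and
            # are never true hydrogen bonds; patterns need separation >= 2
            if abs(i - j) < 2:
                continue
            if hbond_energy(residues[i], residues[j]) < DSSP_HBOND_CUTOFF:
                bonds.add((i, int(j)))
    return bonds


def assign_8class(structure: ProteinStructure) -> dict[int, str]:
    """Raw eight-class assignment keyed by SEQRES index.

    Residues with missing backbone atoms are assigned C.  Chain breaks
    (non-consecutive SEQRES indices or CA-CA > 4.5 A) terminate hydrogen-bond
    patterns.
    """
    residues, incomplete = _extract_backbone(structure)
    raw: dict[int, str] = {idx: "C" for idx in incomplete}
    n = len(residues)
    if n == 0:
        return raw
    _place_hydrogens(residues)
    bonds = _hbond_set(residues)

    def contiguous(i: int, j: int) -> bool:
        if i > j:
            i, j = j, i
        return all(not _chain_break(residues[k], residues[k + 1]) for k in range(i, j))

    # n-turns: hbond from donor i+k to acceptor i
    turn = {3: set(), 4: set(), 5: set()}
    for k in (3, 4, 5):
        for i in range(n - k):
            if (i + k, i) in bonds and contiguous(i, i + k):
                turn[k].add(i)

    symbols = [""] * n

    def claim(i: int, sym: str) -> None:
        if not symbols[i]:
            symbols[i] = sym

    # alpha helix: two consecutive 4-turns at i-1, i -> residues i..i+3
    for i in range(1, n - 4 + 1):
        if i - 1 in turn[4] and i in turn[4]:
            for k in range(i, i + 4):
                claim(k, "H")

    # bridges
    par: set[int] = set()
    anti: set[int] = set()
    bridge_partner: dict[int, set[int]] = {}
    for i in range(1, n - 1):
        for j in range(1, n - 1):
            if abs(i - j) < 3:
                continue
            p = ((i - 1, j) in bonds and (j, i + 1) in bonds) or (
                (j - 1, i) in bonds and (i, j + 1) in bonds
            )
            a = ((i, j) in bonds and (j, i) in bonds) or (
                (i - 1, j + 1) in bonds and (j - 1, i + 1) in bonds
            )
            if p or a:
                (par if p else anti).add(i)
                bridge_partner.setdefault(i, set()).add(j)
    bridged = sorted(par | anti)
    # ladders: bridges at consecutive positions extend to strands (E);
    # isolated bridges are B
    in_ladder: set[int] = set()
    for i in bridged:
        if (i - 1 in bridge_partner and any(abs(p - q) <= 1 for p in bridge_partner[i] for q in bridge_partner[i - 1])) or (
            i + 1 in bridge_partner and any(abs(p - q) <= 1 for p in bridge_partner[i] for q in bridge_partner[i + 1])
        ):
            in_ladder.add(i)
    for i in bridged:
        claim(i, "E" if i in in_ladder else "B")

    # 3/10 helix: two consecutive 3-turns
    for i in range(1, n - 3 + 1):
        if i - 1 in turn[3] and i in turn[3]:
            for k in range(i, i + 3):
                claim(k, "G")
    # pi helix: two consecutive 5-turns
    for i in range(1, n - 5 + 1):
        if i - 1 in turn[5] and i in turn[5]:
            for k in range(i, i + 5):
                claim(k, "I")

    # turns: interior of any single n-turn
    for k in (3, 4, 5):
        for i in turn[k]:
            for m in range(i + 1, i + k):
                claim(m, "T")

    # bends: kappa (angle CA(i-2)->CA(i) vs CA(i)->CA(i+2)) > 70 degrees
    for i in range(2, n - 2):
        if not contiguous(i - 2, i + 2):
            continue
        u = residues[i].ca - residues[i - 2].ca
        v = residues[i + 2].ca - residues[i].ca
        den = float(np.linalg.norm(u) * np.linalg.norm(v))
        if den < 1e-9:
            continue
        kappa = math.degrees(math.acos(max(-1.0, min(1.0, float(np.dot(u, v)) / den))))
        if kappa > DSSP_BEND_KAPPA:
            claim(i, "S")

    for i, r in enumerate(residues):
        raw[r.seqres_idx] = symbols[i] or "C"
    return raw


# ---------------------------------------------------------------------------
# overlay onto the reference ruler
# ---------------------------------------------------------------------------


def overlay_disorder(
    rmap: ResidueMap,
    which: int,
    raw: dict[int, str] | None = None,
) -> Profile:
    """Five-class per-reference-position profile for structure 1 or 2.

    N outside the mapped interval, D for disordered positions, otherwise the
    merged three-class symbol.  ``raw`` may carry an externally produced
    eight-class track (keyed by SEQRES index) to bypass the internal assigner.
    """
    structure = rmap.s1 if which == 1 else rmap.s2
    if raw is None:
        raw = assign_8class(structure)
    L = len(rmap.ref)
    profile = new_profile(
        rmap.ref.id, L, kind="category", name=f"ss_{'before' if which == 1 else 'after'}"
    )
    for i in range(1, L + 1):
        status = rmap.status(which, i)
        if status == NULL:
            profile.values[i - 1] = "N"
        elif status == DISORDERED:
            profile.values[i - 1] = "D"
        else:
            idx = rmap.seqres_index(which, i)
            profile.values[i - 1] = merge_3class(raw.get(idx, "C"))
    return profile


def loop_fraction(profile: Profile) -> Optional[float]:
    """Percentage of C among ordered (H/E/C) positions; None if none exist."""
    counts = {"H": 0, "E": 0, "C": 0}
    for v in profile.values:
        if v in counts:
            counts[v] += 1
    total = sum(counts.values())
    if total == 0:
        return None
    return 100.0 * counts["C"] / total


# ---------------------------------------------------------------------------
# classic .dssp file ingestion
# ---------------------------------------------------------------------------


def read_dssp(path: str | Path, chain_id: str) -> dict[tuple[int, str], str]:
    """Parse a classic .dssp output file.

    Returns (author residue number, insertion code) -> raw symbol for the
    requested chain; blank symbols become C.
    """
    lines = Path(path).read_text().splitlines()
    try:
        start = next(i for i, l in enumerate(lines) if l.startswith("  #  RESIDUE"))
    except StopIteration:
        raise ValueError(f"{path}: not a classic .dssp file (missing header)") from None
    out: dict[tuple[int, str], str] = {}
    for line in lines[start + 1 :]:
        if len(line) < 17 or line[13] == "!":
            continue
        if line[11] != chain_id:
            continue
        number = int(line[5:10])
        icode = line[10].strip()
        symbol = line[16].strip() or "C"
        out[(number, icode)] = symbol
    return out


def dssp_to_raw(structure: ProteinStructure, dssp: dict[tuple[int, str], str]) -> dict[int, str]:
    """Rekey an ingested .dssp track from author numbering to SEQRES indices."""
    raw: dict[int, str] = {}
    for idx, res in structure.observed.items():
        symbol = dssp.get((res.number, res.icode))
        if symbol is not None:
            raw[idx] = symbol if symbol in MERGED else "C"
    return raw
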