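"""Before/after structure pairing and binding-target extraction.

Two chains form a pair when (i) they live in different files, (ii) both map
validly onto the reference with overlapping intervals and (iii) the after
file's molecular inventory is a strict superset of the before file's.  The
extra molecules of the after file are the binding targets, with waters and
pseudo ligands excluded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .constants import DEFAULT_PSEUDO_LIGANDS, ION_IDS, WATER_IDS
from .refmap import ReferenceSequence, map_fragment
from .structure_io import ProteinStructure, Residue, StructureFile


def is_excluded(component_id: str, pseudo_ligands: frozenset[str] = DEFAULT_PSEUDO_LIGANDS) -> bool:
    """True for waters and pseudo ligands (crystallization artifacts)."""
    cid = component_id.strip().upper()
    return cid in WATER_IDS or cid in pseudo_ligands


@dataclass
class BindingTarget:
    """An extra molecule in the after-binding file, absent before binding."""

    category: str                       # protein | nucleic acid | ligand | ion
    name: str                           # component id, or chain id for polymers
    het_residue: Optional[Residue] = None
    chain: Optional[ProteinStructure] = None

    def heavy_atom_coords(self) -> list[np.ndarray]:
        if self.het_residue is not None:
            return [a.coords for a in self.het_residue.heavy_atoms()]
        assert self.chain is not None
        coords = []
        for res in self.chain.observed.values():
            coords.extend(a.coords for a in res.heavy_atoms())
        return coords


def categorize_target(
    het_residue: Optional[Residue] = None,
    chain: Optional[ProteinStructure] = None,
) -> str:
    if chain is not None:
        return "protein" if chain.kind == "protein" else "nucleic acid"
    assert het_residue is not None
    cid = het_residue.name3.strip().upper()
    if len(het_residue.heavy_atoms()) == 1 or cid in ION_IDS:
        return "ion"
    return "ligand"


@dataclass
class PairCandidate:
    before: ProteinStructure
    after: ProteinStructure
    before_file: StructureFile
    after_file: StructureFile
    targets: list[BindingTarget] = field(default_factory=list)

    @property
    def worse_resolution(self) -> Optional[float]:
        values = [
            r for r in (self.before_file.resolution, self.after_file.resolution)
            if r is not None
        ]
        return max(values) if values else None


# ---------------------------------------------------------------------------
# inventories
# ---------------------------------------------------------------------------


def _polymer_inventory(sf: StructureFile) -> Counter:
    return Counter(("polymer", ch.seqres) for ch in sf.polymer_chains)


def _het_inventory(sf: StructureFile, pseudo_ligands) -> Counter:
    return Counter(
        ("het", r.name3.strip().upper())
        for r in sf.het_residues
        if not is_excluded(r.name3, pseudo_ligands)
    )


def inventory_superset(
    F1: StructureFile,
    F2: StructureFile,
    pivot_after: Optional[ProteinStructure] = None,
    pivot_before: Optional[ProteinStructure] = None,
    pseudo_ligands: frozenset[str] = DEFAULT_PSEUDO_LIGANDS,
) -> tuple[bool, list[BindingTarget]]:
    """Does F1 contain every molecule of F2 plus at least one extra?

    Polymer chains compare by exact SEQRES string, het groups by component-id
    multiset; waters and pseudo ligands never count.  The paired chains
    themselves (``pivot_after`` in F1, ``pivot_before`` in F2) are exempt from
    the identity requirement: one instance of each is removed before the
    comparison.  Returns (flag, extras-as-binding-targets).
    """
    inv1 = _polymer_inventory(F1) + _het_inventory(F1, pseudo_ligands)
    inv2 = _polymer_inventory(F2) + _het_inventory(F2, pseudo_ligands)
    if pivot_after is not None:
        inv1.subtract({("polymer", pivot_after.seqres): 1})
        inv1 += Counter()  # drop zero/negative entries
    if pivot_before is not None:
        inv2.subtract({("polymer", pivot_before.seqres): 1})
        inv2 += Counter()
    missing = inv2 - inv1
    if missing:
        return False, []
    extra = inv1 - inv2
    if not extra:
        return False, []
    return True, _extras_to_targets(F1, extra, pivot_after, pseudo_ligands)


def _extras_to_targets(
    F1: StructureFile,
    extra: Counter,
    pivot_after: Optional[ProteinStructure],
    pseudo_ligands,
) -> list[BindingTarget]:
    targets: list[BindingTarget] = []
    remaining = Counter(extra)
    for ch in F1.polymer_chains:
        if ch is pivot_after:
            continue
        key = ("polymer", ch.seqres)
        if remaining[key] > 0:
            remaining[key] -= 1
            targets.append(
                BindingTarget(category=categorize_target(chain=ch), name=ch.chain_id, chain=ch)
            )
    for res in F1.het_residues:
        if is_excluded(res.name3, pseudo_ligands):
            continue
        key = ("het", res.name3.strip().upper())
        if remaining[key] > 0:
            remaining[key] -= 1
            targets.append(
                BindingTarget(
                    category=categorize_target(het_residue=res),
                    name=res.name3.strip().upper(),
                    het_residue=res,
                )
            )
    return targets


# ---------------------------------------------------------------------------
# pair enumeration
# ---------------------------------------------------------------------------


def find_pairs(
    files: Sequence[StructureFile],
    ref: ReferenceSequence,
    pseudo_ligands: frozenset[str] = DEFAULT_PSEUDO_LIGANDS,
) -> list[PairCandidate]:
    """Enumerate every valid (before, after) chain pair across ``files``."""
    # cache fragment mappings per distinct SEQRES
    mapping_cache: dict[str, object] = {}

    def mapping(seq: str):
        if seq not in mapping_cache:
            mapping_cache[seq] = map_fragment(seq, ref)
        return mapping_cache[seq]

    pairs: list[PairCandidate] = []
    for before_file in files:
        for after_file in files:
            if before_file is after_file or before_file.id == after_file.id:
                continue
            for before in before_file.polymer_chains:
                if before.kind != "protein":
                    continue
                m_before = mapping(before.seqres)
                if not m_before.valid:
                    continue
                for after in after_file.polymer_chains:
                    if after.kind != "protein":
                        continue
                    m_after = mapping(after.seqres)
                    if not m_after.valid:
                        continue
                    lo = max(m_before.interval[0], m_after.interval[0])
                    hi = min(m_before.interval[1], m_after.interval[1])
                    if lo > hi:
                        continue
                    ok, targets = inventory_superset(
                        after_file, before_file,
                        pivot_after=after, pivot_before=before,
                        pseudo_ligands=pseudo_ligands,
                    )
                    if ok:
                        pairs.append(
                            PairCandidate(before, after, before_file, after_file, targets)
                        )
    return pairs
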