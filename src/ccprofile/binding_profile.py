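"""Potential binding-target-site profile.

A reference position is flagged when any heavy atom of its residue in the
bound-state structure lies within the site cutoff (default 5 A) of any heavy
atom of a binding target; target names are associated to residues within the
tighter name cutoff (default 3 A).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .constants import NAME_CUTOFF, SITE_CUTOFF
from .pairing import BindingTarget
from .profile import Profile, new_profile
from .refmap import OBSERVED, ResidueMap
from .structure_io import ProteinStructure


def _target_atom_array(targets) -> tuple[np.ndarray, list[str]]:
    coords, names = [], []
    for t in targets:
        for atom in t.heavy_atom_coords():
            coords.append(atom)
            names.append(t.name)
    if not coords:
        return np.empty((0, 3)), []
    return np.asarray(coords), names


def _bound_residue(rmap: ResidueMap, bound: ProteinStructure, i: int):
    which = 1 if rmap.s1 is bound else 2
    if rmap.status(which, i) != OBSERVED:
        return None
    return rmap.residue(which, i)


def binding_site_profile(
    rmap: ResidueMap,
    bound: ProteinStructure,
    targets: list[BindingTarget],
    cutoff: float = SITE_CUTOFF,
) -> Profile:
    """Boolean per-position profile of proximity to binding targets.

    Positions without an observed residue in the bound structure are null;
    an empty target list yields an all-false (not null) profile at observed
    positions.
    """
    L = len(rmap.ref)
    profile = new_profile(rmap.ref.id, L, kind="boolean", name="binding_flag")
    coords, _ = _target_atom_array(targets)
    tree = cKDTree(coords) if len(coords) else None
    for i in range(1, L + 1):
        res = _bound_residue(rmap, bound, i)
        if res is None:
            continue
        if tree is None:
            profile.values[i - 1] = False
            continue
        pts = np.asarray([a.coords for a in res.heavy_atoms()])
        if len(pts) == 0:
            profile.values[i - 1] = False
            continue
        dmin = tree.query(pts, k=1)[0].min()
        profile.values[i - 1] = bool(dmin <= cutoff)
    return profile


def associate_names(
    rmap: ResidueMap,
    bound: ProteinStructure,
    targets: list[BindingTarget],
    cutoff: float = NAME_CUTOFF,
) -> Profile:
    """Per-position sorted, deduplicated target names within the name cutoff."""
    L = len(rmap.ref)
    profile = new_profile(rmap.ref.id, L, kind="names", name="binding_names")
    coords, names = _target_atom_array(targets)
    tree = cKDTree(coords) if len(coords) else None
    for i in range(1, L + 1):
        res = _bound_residue(rmap, bound, i)
        if res is None:
            continue
        found: set[str] = set()
        if tree is not None:
            pts = np.asarray([a.coords for a in res.heavy_atoms()])
            if len(pts):
                for idxs in tree.query_ball_point(pts, r=cutoff):
                    found.update(names[k] for k in idxs)
        profile.values[i - 1] = sorted(found)
    return profile
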