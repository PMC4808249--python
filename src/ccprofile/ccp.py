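"""Conformational change profile: sliding-window superposition RMSD.

A 21-residue window (10 leading, 10 trailing) slides along the reference
sequence; at each position the C-alpha coordinates of residues observed in
both structures inside the window are rigidly superposed and the resulting
RMSD is the profile value.  Positions not observed in both structures are
null, as are windows with too few common residues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import CCP_HALF_WINDOW, CCP_MIN_COMMON
from .profile import Profile, new_profile
from .refmap import OBSERVED, ResidueMap
from .superpose import superpose


@dataclass
class CCPConfig:
    half_window: int = CCP_HALF_WINDOW
    min_common: int = CCP_MIN_COMMON
    estimator: str = "reweighted"  # "reweighted" | "least_squares"
    atom_set: tuple[str, ...] = ("CA",)

    def __post_init__(self) -> None:
        if self.half_window < 1:
            raise ValueError("half_window must be >= 1")
        if self.min_common < 3:
            raise ValueError("min_common must be >= 3")


def window_positions(rmap: ResidueMap, i: int, config: CCPConfig) -> list[int]:
    """Reference positions contributing to the window centred at ``i``.

    The window is truncated at the termini, never wrapped; only positions
    observed in both structures (with the configured atoms present) count.
    """
    L = len(rmap.ref)
    lo = max(1, i - config.half_window)
    hi = min(L, i + config.half_window)
    out = []
    for j in range(lo, hi + 1):
        if _paired_coords(rmap, j, config) is not None:
            out.append(j)
    return out


def _paired_coords(rmap: ResidueMap, j: int, config: CCPConfig):
    if rmap.status(1, j) != OBSERVED or rmap.status(2, j) != OBSERVED:
        return None
    r1, r2 = rmap.residue(1, j), rmap.residue(2, j)
    c1, c2 = [], []
    for name in config.atom_set:
        a1, a2 = r1.atom(name), r2.atom(name)
        if a1 is None or a2 is None:
            return None
        c1.append(a1.coords)
        c2.append(a2.coords)
    return c1, c2


def _collect(rmap: ResidueMap, positions, config: CCPConfig):
    X, Y = [], []
    for j in positions:
        pair = _paired_coords(rmap, j, config)
        if pair is not None:
            X.extend(pair[0])
            Y.extend(pair[1])
    return np.asarray(X), np.asarray(Y)


def compute_ccp(rmap: ResidueMap, config: CCPConfig | None = None) -> Profile:
    """The conformational change profile of a structure pair."""
    config = config or CCPConfig()
    L = len(rmap.ref)
    profile = new_profile(rmap.ref.id, L, kind="real", units="angstrom", name="ccp")
    common = set(rmap.doubly_observed())
    for i in range(1, L + 1):
        if i not in common:
            continue
        positions = window_positions(rmap, i, config)
        if len(positions) < config.min_common:
            continue
        X, Y = _collect(rmap, positions, config)
        result = superpose(X, Y, estimator=config.estimator)
        profile.values[i - 1] = result.rmsd
    return profile


def global_rmsd(rmap: ResidueMap, config: CCPConfig | None = None) -> float:
    """Single-superposition unweighted RMSD over all doubly observed residues."""
    config = config or CCPConfig()
    positions = rmap.doubly_observed()
    X, Y = _collect(rmap, positions, config)
    if len(X) < 3:
        raise ValueError(f"only {len(X)} common residues; need >= 3")
    return superpose(X, Y, estimator=config.estimator).rmsd
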