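"""Rigid-body superposition: exact weighted least squares (Kabsch) and an
iteratively reweighted variant that down-weights variable regions.

The reported RMSD is always the unweighted RMSD over all paired points under
the final transform, so profiles from the two estimators are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np


class UnderdeterminedError(ValueError):
    """Fewer than three point pairs."""


@dataclass
class SuperpositionResult:
    rotation: np.ndarray      # 3x3, proper
    translation: np.ndarray   # 3-vector: y ~ R @ x + t
    rmsd: float               # unweighted, Angstrom
    per_point_dev2: np.ndarray
    iterations: int = 1
    converged: bool = True

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _check_pairing(X: np.ndarray, Y: np.ndarray, weights) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("X and Y must be equal-shape (n, 3) arrays")
    if len(X) < 3:
        raise UnderdeterminedError("underdetermined: need >= 3 point pairs")
    if weights is None:
        w = np.ones(len(X))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(X),) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    return X, Y, w


def _fit(X: np.ndarray, Y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted Kabsch fit mapping X onto Y; returns (R, t)."""
    wn = w / w.sum()
    xc = wn @ X
    yc = wn @ Y
    H = (X - xc).T @ ((Y - yc) * wn[:, None])
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    return R, t


def _unweighted_rmsd(X, Y, R, t) -> tuple[float, np.ndarray]:
    dev2 = np.sum((X @ R.T + t - Y) ** 2, axis=1)
    return float(np.sqrt(dev2.mean())), dev2


def kabsch(
    X: np.ndarray, Y: np.ndarray, weights: Optional[np.ndarray] = None
) -> SuperpositionResult:
    """Optimal rigid superposition of X onto Y (proper rotation enforced)."""
    X, Y, w = _check_pairing(X, Y, weights)
    R, t = _fit(X, Y, w)
    rmsd, dev2 = _unweighted_rmsd(X, Y, R, t)
    return SuperpositionResult(R, t, rmsd, dev2)


def ml_superpose(
    X: np.ndarray,
    Y: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> SuperpositionResult:
    """Iteratively reweighted superposition.

    Weights w_i = 1 / (d_i^2 + c) with c = max(0.01 * mean(d^2), 1e-6)
    recomputed after each fit, so variable regions are progressively
    down-weighted.  Reported rmsd is the unweighted RMSD under the final
    transform; it is therefore >= the Kabsch rmsd by construction.
    """
    X, Y, w = _check_pairing(X, Y, None)
    R, t = _fit(X, Y, w)
    rmsd, dev2 = _unweighted_rmsd(X, Y, R, t)
    if rmsd < 1e-12:
        return SuperpositionResult(R, t, rmsd, dev2, iterations=1, converged=True)
    converged = False
    iterations = 1
    for iterations in range(2, max_iter + 1):
        c = max(0.01 * dev2.mean(), 1e-6)
        w = 1.0 / (dev2 + c)
        R, t = _fit(X, Y, w)
        new_rmsd, dev2 = _unweighted_rmsd(X, Y, R, t)
        if abs(new_rmsd - rmsd) < tol:
            rmsd = new_rmsd
            converged = True
            break
        rmsd = new_rmsd
    else:
        iterations = max_iter
    if rmsd == 0.0:
        converged = True
    return SuperpositionResult(R, t, rmsd, dev2, iterations=iterations, converged=converged)


def superpose(
    X: np.ndarray, Y: np.ndarray, estimator: str = "reweighted", **kwargs
) -> SuperpositionResult:
    if estimator == "least_squares":
        return kabsch(X, Y)
    if estimator == "reweighted":
        return ml_superpose(X, Y, **kwargs)
    raise ValueError(f"unknown estimator {estimator!r}")
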