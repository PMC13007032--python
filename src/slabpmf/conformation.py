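"""Rigid-body superposition and backbone RMSD.

Conformational change of the chain solute is measured as the
root-mean-square deviation of its backbone atoms from a reference
extended conformation, after removing overall translation and rotation
with the Kabsch algorithm (SVD-based least-squares proper rotation;
reflections are corrected, so a mirror image keeps a nonzero RMSD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class DegeneracyError(ValueError):
    """Reference geometry is collinear/degenerate; rotation underdetermined."""


@dataclass
class AlignmentResult:
    """Optimal proper rotation, translation and resulting RMSD (Å).

    The aligned coordinates are ``coords @ rotation.T + translation``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self) -> None:
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be nonnegative")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def kabsch_align(
    coords: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> AlignmentResult:
    """Least-squares optimal superposition of ``coords`` onto ``reference``.

    Centroids are aligned, the optimal proper rotation is obtained from
    the SVD of the weighted covariance matrix with reflection correction,
    and the RMSD of the aligned coordinates is returned.  Weights default
    to uniform.
    """
    x = np.asarray(coords, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    w = w / w.sum()

    xc = x - (w[:, None] * x).sum(axis=0)
    yc = y - (w[:, None] * y).sum(axis=0)

    # Degenerate (collinear) geometry leaves the rotation about the line free.
    _, sing, _ = np.linalg.svd(yc * w[:, None])
    if sing[1] < 1e-9 * max(sing[0], 1.0):
        raise DegeneracyError("collinear reference geometry")

    cov = (w[:, None] * xc).T @ yc
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T

    aligned = xc @ rotation.T
    rmsd = float(np.sqrt((w * ((aligned - yc) ** 2).sum(axis=1)).sum()))
    translation = (w[:, None] * y).sum(axis=0) - (w[:, None] * x).sum(axis=0) @ rotation.T
    return AlignmentResult(rotation=rotation, translation=translation, rmsd=rmsd)


def backbone_rmsd(
    coords: np.ndarray,
    reference: np.ndarray,
    subset=None,
) -> float:
    """RMSD over the backbone subset after aligning on that subset.

    ``subset`` lists the backbone atom indices (for a carboxylate solute
    the headgroup carbon is included; a sulfonate headgroup contributes
    its sulfur).  Returns √[(1/N) Σᵢ ‖xᵢ − xᵢ*‖²] in Å.
    """
    x = np.asarray(coords, dtype=float)
    y = np.asarray(reference, dtype=float)
    if subset is not None:
        subset = np.asarray(subset, dtype=int)
        if subset.size == 0:
            raise ValueError("subset must be nonempty")
        x, y = x[subset], y[subset]
    return kabsch_align(x, y).rmsd
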