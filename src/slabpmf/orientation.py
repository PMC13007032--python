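"""Orientational order parameter of a chain solute at a slab interface.

The solute direction v₁ is the mean of normalised 1,3-vectors along its
backbone (x_{k+1} − x_{k−1}, k = 2..n_c−1), pointing from the tail
terminus toward the headgroup.  The local slab direction v₂ is the
resultant of normalised 1,3-vectors of slab-chain fragments inside a
cylinder centred on the solute (radius 13 Å in xy, lower z bound 18 Å
above the slab centre of mass, upper bound at the slab-solvent
interface); to stop chain folds cancelling each other, each fragment
vector is flipped so as to grow the resultant, and the final resultant
is constrained to point within 90° of +z — slab chains are chemically
identical at both ends, so the sign is purely conventional.

The order parameter is  S_v = (3⟨cos²θ⟩ − 1)/2  where θ is the angle
between v₁ and v₂: 1 for parallel alignment, −0.5 for perpendicular,
0 for isotropic orientations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import Configuration


class EmptyRegionError(RuntimeError):
    """No slab fragments inside the cylindrical sampling region."""


class DegenerateGeometryError(ValueError):
    """Coincident atoms produced a zero-length 1,3-vector."""


@dataclass(frozen=True)
class CylinderSpec:
    """Cylindrical sampling region around the solute.

    ``radius`` in the xy-plane (default 13 Å); the lower z bound sits
    ``z_lower_offset_from_slab_com`` (default 18 Å) above the slab centre
    of mass, and ``z_upper`` is the nearest interface position (GDS).
    """

    radius: float = 13.0
    z_lower_offset_from_slab_com: float = 18.0
    z_upper: float | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("cylinder radius must be positive")


@dataclass
class OrientationRecord:
    """Per-frame orientation observation."""

    frame: int
    v1: np.ndarray
    v2: np.ndarray
    theta: float          # degrees
    s_v: float
    xi: float             # Å, interface coordinate

    def __post_init__(self) -> None:
        for v in (self.v1, self.v2):
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ValueError("orientation vectors must be unit length")
        if not -0.5 - 1e-12 <= self.s_v <= 1.0 + 1e-12:
            raise ValueError("S_v out of [-0.5, 1]")


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateGeometryError("zero-length vector")
    return v / n


def solute_vector(coords: np.ndarray, backbone_indices=None) -> np.ndarray:
    """Mean normalised 1,3-vector of the solute backbone, unit length.

    ``backbone_indices`` selects the backbone atoms in chain order from
    tail to head (for a carboxylated solute the functional-group carbon is
    excluded; a sulfonate headgroup contributes no backbone atom at all).
    With the tail-to-head ordering the result points from the tail
    terminus toward the headgroup.
    """
    coords = np.asarray(coords, dtype=float)
    x = coords if backbone_indices is None else coords[np.asarray(backbone_indices)]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 backbone atoms, got {n}")
    d = x[2:] - x[:-2]                       # x_{k+1} − x_{k−1}, k=2..n−1
    norms = np.linalg.norm(d, axis=1)
    if np.any(norms < 1e-12):
        raise DegenerateGeometryError("coincident backbone atoms")
    return _unit((d / norms[:, None]).mean(axis=0))


def select_cylinder(
    config: Configuration,
    solute_com_xy: tuple[float, float],
    cyl: CylinderSpec,
    slab_species: str = "PE",
    slab_com_z: float | None = None,
) -> list[np.ndarray]:
    """Slab-chain 1,3-fragments whose central atom lies in the cylinder.

    Returns a list of (3, 3) coordinate triplets (k−1, k, k+1 along each
    slab chain).  Membership is decided by the central atom: xy distance
    to the cylinder axis ≤ radius under minimum-image convention, and z
    within [slab_com_z + offset, z_upper].  An empty result is legal.
    """
    if cyl.z_upper is None:
        raise ValueError("cylinder z_upper (interface position) not set")
    idx = config.select(slab_species)
    if idx.size == 0:
        raise ValueError(f"no atoms of slab species {slab_species!r}")
    if slab_com_z is None:
        slab_com_z = float(config.com(idx)[2])
    z_lo = slab_com_z + cyl.z_lower_offset_from_slab_com
    z_hi = cyl.z_upper
    if z_lo >= z_hi:
        raise ValueError(f"cylinder has no z extent: [{z_lo:.2f}, {z_hi:.2f}]")

    lx, ly = config.box[0], config.box[1]
    ax = np.asarray(solute_com_xy, dtype=float)
    pos = config.positions
    mol = config.molecule_ids
    fragments: list[np.ndarray] = []
    for chain_id in np.unique(mol[idx]):
        chain = idx[mol[idx] == chain_id]     # file order = chain order
        if chain.size < 3:
            continue
        p = pos[chain]
        centers = p[1:-1]
        dxy = centers[:, :2] - ax
        dxy[:, 0] -= lx * np.round(dxy[:, 0] / lx)     # minimum image in xy
        dxy[:, 1] -= ly * np.round(dxy[:, 1] / ly)
        inside = (np.hypot(dxy[:, 0], dxy[:, 1]) <= cyl.radius) \
            & (centers[:, 2] >= z_lo) & (centers[:, 2] <= z_hi)
        for k in np.flatnonzero(inside):
            fragments.append(p[k:k + 3])
    return fragments


def fragment_vectors(fragments: list[np.ndarray]) -> np.ndarray:
    """Normalised 1,3-vectors (x_{k+1} − x_{k−1}) of fragment triplets."""
    vs = []
    for frag in fragments:
        frag = np.asarray(frag, dtype=float)
        vs.append(_unit(frag[2] - frag[0]))
    return np.asarray(vs)


def slab_vector(fragments: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Resultant slab direction from fragment 1,3-vectors, unit length.

    Fragment vectors are accumulated greedily: the first is flipped to
    nonnegative z, and each subsequent vector is reversed when its dot
    product with the running resultant is negative, so antiparallel
    fragments reinforce instead of cancelling.  The final resultant is
    flipped to make an angle < 90° with +z (a z-component of exactly zero
    is left as accumulated).
    """
    if isinstance(fragments, np.ndarray) and fragments.ndim == 2:
        vs = fragments.astype(float)
        vs = vs / np.linalg.norm(vs, axis=1)[:, None]
    else:
        if len(fragments) == 0:
            raise EmptyRegionError("no fragments in the sampling region")
        vs = fragment_vectors(fragments)
    if len(vs) == 0:
        raise EmptyRegionError("no fragments in the sampling region")

    first = vs[0] if vs[0, 2] >= 0 else -vs[0]
    resultant = first.copy()
    for v in vs[1:]:
        resultant += v if np.dot(v, resultant) >= 0 else -v
    if resultant[2] < 0:
        resultant = -resultant
    return _unit(resultant)


def order_parameter(v1: np.ndarray, v2: np.ndarray) -> tuple[float, float]:
    """Angle θ (degrees) between unit vectors and per-frame S_v.

    S_v = (3 cos²θ − 1)/2; ensemble averaging over frames belongs in
    :func:`orientation_profile`.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise ValueError("zero-length orientation vector")
    c = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
    theta = float(np.degrees(np.arccos(c)))
    return theta, (3.0 * c * c - 1.0) / 2.0


def orientation_profile(
    records: list[OrientationRecord],
    xi_bins: np.ndarray,
    confidence: float = 0.95,
    n_blocks: int = 10,
) -> dict:
    """Bin orientation records along ξ: mean S_v with a t confidence band.

    Per bin, ⟨cos²θ⟩ is averaged over frames and mapped through
    S_v = (3⟨cos²θ⟩ − 1)/2.  ``records`` is either a flat record list
    (one replica) or a list of record lists (one per replica).  The
    confidence interval is a Student-t interval across per-replica bin
    means where multiple replicas exist, else across ``n_blocks``
    contiguous block means within the single series.  Angle quartiles
    (for boxplots) are emitted per bin; empty bins are NaN, not errors.
    """
    if not records:
        raise ValueError("no orientation records")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    replicas = records if isinstance(records[0], (list, tuple)) else [records]
    if any(len(r) == 0 for r in replicas):
        raise ValueError("empty replica record list")
    flat = [r for rep in replicas for r in rep]
    xi_bins = np.asarray(xi_bins, dtype=float)
    nb = len(xi_bins) - 1
    theta = np.array([r.theta for r in flat])
    cos2 = np.cos(np.radians(theta)) ** 2
    which = np.digitize(np.array([r.xi for r in flat]), xi_bins) - 1
    rep_id = np.repeat(np.arange(len(replicas)), [len(r) for r in replicas])

    tcrit = lambda k: stats.t.ppf(0.5 + confidence / 2.0, df=k - 1)  # noqa: E731
    mean_sv = np.full(nb, np.nan)
    ci_lo = np.full(nb, np.nan)
    ci_hi = np.full(nb, np.nan)
    counts = np.zeros(nb, dtype=int)
    quartiles = np.full((nb, 3), np.nan)
    for b in range(nb):
        sel = which == b
        counts[b] = int(sel.sum())
        if counts[b] == 0:
            continue
        c2 = cos2[sel]
        quartiles[b] = np.percentile(theta[sel], [25, 50, 75])
        if len(replicas) >= 2:
            rep_means = [
                (3.0 * c2[rep_id[sel] == i].mean() - 1.0) / 2.0
                for i in range(len(replicas))
                if np.any(rep_id[sel] == i)
            ]
            rep_means = np.array(rep_means)
            mean_sv[b] = rep_means.mean()
            if len(rep_means) >= 2:
                sem = rep_means.std(ddof=1) / np.sqrt(len(rep_means))
                ci_lo[b] = mean_sv[b] - tcrit(len(rep_means)) * sem
                ci_hi[b] = mean_sv[b] + tcrit(len(rep_means)) * sem
            else:
                ci_lo[b] = ci_hi[b] = mean_sv[b]
        else:
            mean_sv[b] = (3.0 * c2.mean() - 1.0) / 2.0
            # Block means over the frame-ordered series within the bin.
            k = min(n_blocks, counts[b])
            if k >= 2:
                blocks = np.array_split(c2, k)
                bm = np.array([(3.0 * blk.mean() - 1.0) / 2.0 for blk in blocks])
                sem = bm.std(ddof=1) / np.sqrt(k)
                ci_lo[b] = mean_sv[b] - tcrit(k) * sem
                ci_hi[b] = mean_sv[b] + tcrit(k) * sem
            else:
                ci_lo[b] = ci_hi[b] = mean_sv[b]
    return {
        "bin_centers": 0.5 * (xi_bins[:-1] + xi_bins[1:]),
        "mean_s_v": mean_sv,
        "ci_lower": ci_lo,
        "ci_upper": ci_hi,
        "n": counts,
        "theta_quartiles": quartiles,
        "confidence": confidence,
    }
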