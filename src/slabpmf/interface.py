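"""Density profiles, tanh interface fits and Gibbs dividing surfaces.

The polymer slab and the surrounding solvent each have a characteristic
mass-density profile along z.  The slab follows

    ρ_PE(z) = ½ ρ_b,PE tanh[2(z − h₁)/D₁] − ½ ρ_b,PE tanh[2(z − h₂)/D₁]

and the solvent the complementary form

    ρ_w(z) = ρ_b,w − ½ ρ_b,w tanh[2(z − h₃)/D₂] + ½ ρ_b,w tanh[2(z − h₄)/D₂]

with bulk densities ρ_b, interface positions h_j and widths D.  The Gibbs
dividing surface (GDS) is where the two fitted curves intersect; it is the
natural zero for the solute-interface reaction coordinate ξ, taken
negative toward the slab interior and positive toward bulk solvent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, curve_fit

from .constants import AVOGADRO
from .core import Configuration, Trajectory


class FitError(RuntimeError):
    """Nonlinear interface fit failed; message carries diagnostics."""


class NoCrossingError(RuntimeError):
    """The slab and solvent density curves do not intersect in a bracket."""


@dataclass
class DensityProfile:
    """Mass density (g cm⁻³) binned along one box axis."""

    bin_centers: np.ndarray
    density: np.ndarray
    species: str
    frames_averaged: int
    axis: str = "z"

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(self.density < -1e-12):
            raise ValueError("density must be nonnegative")


@dataclass
class InterfaceFit:
    """Fitted tanh parameters for one component.

    ``model`` is "pe_slab" (two rising/falling branches sharing ρ_b and D)
    or "solvent" (the complementary depleted-slab form).  ``positions``
    holds (h₁, h₂) or (h₃, h₄) respectively.
    """

    model: str
    rho_b: float
    positions: tuple[float, float]
    width: float
    residual_rms: float

    def __post_init__(self) -> None:
        if self.model not in ("pe_slab", "solvent"):
            raise ValueError(f"unknown interface model {self.model!r}")
        if self.rho_b <= 0 or self.width <= 0:
            raise ValueError("bulk density and width must be positive")
        if self.positions[0] >= self.positions[1]:
            raise ValueError("interface positions must be ordered")

    def __call__(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        h_lo, h_hi = self.positions
        if self.model == "pe_slab":
            return pe_slab_model(z, self.rho_b, h_lo, h_hi, self.width)
        return solvent_model(z, self.rho_b, h_lo, h_hi, self.width)


@dataclass
class GibbsSurfaces:
    """The two slab-solvent crossing planes along z."""

    z_lower: float
    z_upper: float

    def __post_init__(self) -> None:
        if not self.z_lower < self.z_upper:
            raise ValueError("lower GDS must lie below upper GDS")


def pe_slab_model(z, rho_b, h1, h2, d):
    """Slab density: ½ρ_b tanh[2(z−h1)/D] − ½ρ_b tanh[2(z−h2)/D]."""
    return 0.5 * rho_b * (np.tanh(2.0 * (z - h1) / d) - np.tanh(2.0 * (z - h2) / d))


def solvent_model(z, rho_b, h3, h4, d):
    """Solvent density: ρ_b − ½ρ_b tanh[2(z−h3)/D] + ½ρ_b tanh[2(z−h4)/D]."""
    return rho_b * (1.0 - 0.5 * np.tanh(2.0 * (z - h3) / d)
                    + 0.5 * np.tanh(2.0 * (z - h4) / d))


_AXES = {"x": 0, "y": 1, "z": 2}


def density_profile(
    trajectory: Trajectory | Configuration,
    species: str,
    axis: str = "z",
    n_bins: int = 100,
) -> DensityProfile:
    """Frame-averaged mass density of one species along a box axis.

    ``species`` is a species label (unknown labels raise) or an explicit
    atom-index array (an empty selection yields a zero profile with a
    warning).  Coordinates are wrapped periodically along the axis; each
    bin's density is the summed atomic mass in the bin divided by the bin
    slab volume, converted from g mol⁻¹ Å⁻³ to g cm⁻³.
    """
    frames = trajectory.frames if isinstance(trajectory, Trajectory) else [trajectory]
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}")
    ax = _AXES[axis]
    box = frames[0].box
    length = box[ax]
    cross_section = box.prod() / length
    edges = np.linspace(0.0, length, n_bins + 1)
    bin_volume_cm3 = (cross_section * (edges[1] - edges[0])) * 1e-24

    if isinstance(species, str):
        if len(frames[0].select(species)) == 0:
            known = sorted(set(frames[0].species.tolist()))
            raise ValueError(f"unknown species {species!r}; present: {known}")
        selector = lambda fr: fr.select(species)  # noqa: E731
        label = species
    else:
        indices = np.asarray(species, dtype=int)
        if indices.size == 0:
            warnings.warn("empty atom selection; returning a zero profile")
            return DensityProfile(0.5 * (edges[:-1] + edges[1:]),
                                  np.zeros(n_bins), "<empty>", len(frames), axis)
        selector = lambda fr: indices  # noqa: E731
        label = f"<{indices.size} atoms>"

    mass_hist = np.zeros(n_bins)
    for fr in frames:
        idx = selector(fr)
        coord = np.mod(fr.positions[idx, ax], length)
        mass_hist += np.histogram(coord, bins=edges, weights=fr.masses[idx])[0]
    density = mass_hist / (len(frames) * AVOGADRO * bin_volume_cm3)
    return DensityProfile(0.5 * (edges[:-1] + edges[1:]), density,
                          label, len(frames), axis)


def _initial_guess(profile: DensityProfile, model: str) -> tuple:
    z, rho = profile.bin_centers, profile.density
    if model == "pe_slab":
        rho_b = float(rho.max())
        half = 0.5 * rho_b
        above = rho >= half
        idx = np.flatnonzero(above)
        h1, h2 = float(z[idx[0]]), float(z[idx[-1]])
    else:
        rho_b = float(np.median(rho[rho > 0.5 * rho.max()])) if np.any(rho > 0) else float(rho.max())
        half = 0.5 * rho_b
        below = rho <= half
        idx = np.flatnonzero(below)
        h1, h2 = float(z[idx[0]]), float(z[idx[-1]])
    if h2 - h1 < 1e-9:
        h1, h2 = float(z[len(z) // 4]), float(z[3 * len(z) // 4])
    d0 = max(0.05 * (h2 - h1), (z[1] - z[0]))
    return rho_b, h1, h2, d0


def fit_interface(
    profile: DensityProfile,
    model: str,
    initial_guess: tuple | None = None,
) -> InterfaceFit:
    """Nonlinear least-squares fit of the tanh model to a density profile.

    The default initial guess places the interfaces at the half-maximum
    crossings of the profile.  Both interfaces share one bulk density and
    one width, exactly as in the model forms above.
    """
    z, rho = profile.bin_centers, profile.density
    if len(z) < 8:
        raise ValueError("need at least 8 bins to fit an interface model")
    if float(np.ptp(rho)) <= 1e-12 * max(1.0, float(np.max(np.abs(rho)))):
        raise ValueError("density profile is flat; no interface to fit")
    fn = pe_slab_model if model == "pe_slab" else solvent_model
    if model not in ("pe_slab", "solvent"):
        raise ValueError(f"unknown interface model {model!r}")
    p0 = initial_guess if initial_guess is not None else _initial_guess(profile, model)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(fn, z, rho, p0=p0, maxfev=20_000)
    except RuntimeError as exc:
        raise FitError(f"{model} interface fit did not converge from p0={p0}: {exc}") from exc
    rho_b, h_lo, h_hi, d = popt
    d = abs(float(d))
    if h_lo > h_hi:
        h_lo, h_hi = h_hi, h_lo
    resid = rho - fn(z, rho_b, h_lo, h_hi, d)
    return InterfaceFit(model=model, rho_b=float(rho_b),
                        positions=(float(h_lo), float(h_hi)),
                        width=d, residual_rms=float(np.sqrt(np.mean(resid**2))))


def gibbs_surfaces(pe_fit: InterfaceFit, solvent_fit: InterfaceFit) -> GibbsSurfaces:
    """Root-find the two z positions where the fitted curves intersect.

    Each crossing is bracketed around the corresponding interface pair and
    solved to 1e-4 Å with Brent's method.
    """
    if pe_fit.model != "pe_slab" or solvent_fit.model != "solvent":
        raise ValueError("expected (pe_slab, solvent) fits in that order")

    def delta(z):
        return pe_fit(z) - solvent_fit(z)

    h1, h2 = pe_fit.positions
    h3, h4 = solvent_fit.positions
    d = max(pe_fit.width, solvent_fit.width)
    brackets = [
        (min(h1, h3) - 2 * d, max(h1, h3) + 2 * d),   # lower interface
        (min(h2, h4) - 2 * d, max(h2, h4) + 2 * d),   # upper interface
    ]
    roots = []
    for lo, hi in brackets:
        zs = np.linspace(lo, hi, 512)
        vals = delta(zs)
        sign_change = np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)
        if sign_change.size == 0:
            raise NoCrossingError(
                f"slab and solvent curves do not cross in [{lo:.2f}, {hi:.2f}] Å"
            )
        j = sign_change[0]
        roots.append(brentq(delta, zs[j], zs[j + 1], xtol=1e-6))
    return GibbsSurfaces(z_lower=float(roots[0]), z_upper=float(roots[1]))


def rereference(
    xi_prime: np.ndarray | float,
    surfaces: GibbsSurfaces,
    slab_com_z: float,
) -> np.ndarray | float:
    """Convert raw COM-COM separations ξ′ to the interface coordinate ξ.

    ``xi_prime`` is the z-distance between the solute and slab centres of
    mass; the solute's absolute position is ``slab_com_z + ξ′``.  ξ is the
    signed z-distance from the *nearest* Gibbs dividing surface: negative
    toward the slab interior, positive toward bulk solvent.  A solute
    exactly midway between the surfaces is assigned to the upper one.
    """
    z = slab_com_z + np.asarray(xi_prime, dtype=float)
    d_low = np.abs(z - surfaces.z_lower)
    d_up = np.abs(z - surfaces.z_upper)
    use_upper = d_up <= d_low                     # tie -> upper surface
    # Toward solvent is +z above the upper surface, -z below the lower one.
    xi_up = z - surfaces.z_upper
    xi_low = surfaces.z_lower - z
    out = np.where(use_upper, xi_up, xi_low)
    return out if out.ndim else float(out)
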