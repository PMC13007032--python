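"""Synthetic slab + solvent particle systems with known ground truth.

The generator builds a coarse-grained polymer slab immersed in solvent
whose z-density profiles follow the tanh interface forms *exactly* in
expectation:

* Slab chains are straight bead chains spanning the nominal slab
  [h₁, h₂], rigidly shifted along z by a logistic random offset of scale
  D₁/4.  The superposed chain density is then the boxcar convolved with
  the logistic density, which is exactly
  ½ρ_b[tanh(2(z−h₁)/D₁) − tanh(2(z−h₂)/D₁)] — the slab interface model.
* Solvent beads are drawn independently from the complementary solvent
  tanh profile by inverse-CDF sampling.

A chain solute with controllable position ξ₀ (relative to the upper
Gibbs dividing surface), tilt θ₀ and conformation is embedded, so every
downstream estimate (density fit, GDS, order parameter, RMSD) has an
analytic truth to be compared against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import AVOGADRO
from .core import Configuration
from .interface import GibbsSurfaces, InterfaceFit, gibbs_surfaces, solvent_model

#: Bead masses, g mol⁻¹: CH₂-like slab bead, water-like solvent bead,
#: CF₂-like solute bead.
MASS_SLAB_BEAD = 14.027
MASS_SOLVENT_BEAD = 18.015
MASS_SOLUTE_BEAD = 50.008

#: Backbone geometry of the all-anti zigzag: C-C bond length and the
#: tetrahedral backbone angle give an axial rise of b·√(2/3) per bond.
BOND_LENGTH = 1.54
_ZIGZAG_HALF_WIDTH = BOND_LENGTH / np.sqrt(3.0)
_ZIGZAG_RISE = BOND_LENGTH * np.sqrt(2.0 / 3.0)


@dataclass(frozen=True)
class SlabSystemSpec:
    """Geometry, densities and solute placement of a synthetic slab system.

    ``h1 < h2`` bound the slab, ``h3 < h4`` bound the solvent depletion
    region; the two intervals must overlap so that the slab and solvent
    density curves cross (normally h₃ ≈ h₁ and h₄ ≈ h₂).  Densities in
    g cm⁻³, lengths in Å, tilt in degrees.
    """

    box: tuple[float, float, float] = (40.0, 40.0, 110.0)
    rho_pe: float = 0.93
    rho_w: float = 1.00
    h1: float = 33.0
    h2: float = 77.0
    h3: float = 33.0
    h4: float = 77.0
    d1: float = 4.0
    d2: float = 4.0
    chain_tilt_jitter: float = 8.0       # deg std of slab-chain polar angle
    solute_n_c: int = 8
    solute_xi0: float = 0.0              # Å from the upper GDS
    solute_tilt0: float = 0.0            # deg from +z
    solute_conformation: str = "extended"
    seed: int = 0
    chain_length: int | None = None      # beads; default spans the slab

    def __post_init__(self) -> None:
        if not (self.h1 < self.h2 and self.h3 < self.h4):
            raise ValueError("interface positions must satisfy h1<h2 and h3<h4")
        if self.h4 <= self.h1 or self.h2 <= self.h3:
            raise ValueError("slab (h1,h2) and solvent-depletion (h3,h4) "
                             "intervals must overlap for the curves to cross")
        if self.d1 <= 0 or self.d2 <= 0:
            raise ValueError("interfacial widths must be positive")
        if self.rho_pe <= 0 or self.rho_w <= 0:
            raise ValueError("bulk densities must be positive")
        if self.solute_n_c < 3:
            raise ValueError("solute chain needs at least 3 beads")
        if any(L <= 0 for L in self.box):
            raise ValueError("box lengths must be positive")

    def pe_fit(self) -> InterfaceFit:
        """The generating slab density curve as an InterfaceFit."""
        return InterfaceFit("pe_slab", self.rho_pe, (self.h1, self.h2),
                            self.d1, 0.0)

    def solvent_fit(self) -> InterfaceFit:
        """The generating solvent density curve as an InterfaceFit."""
        return InterfaceFit("solvent", self.rho_w, (self.h3, self.h4),
                            self.d2, 0.0)


def analytic_surfaces(spec: SlabSystemSpec) -> GibbsSurfaces:
    """Gibbs dividing surfaces of the *generating* density curves."""
    return gibbs_surfaces(spec.pe_fit(), spec.solvent_fit())


def make_oriented_chain(
    n_c: int,
    tilt: float = 0.0,
    conformation: str = "extended",
    seed: int = 0,
    noise_amplitude: float = 0.25,
    azimuth: float = 0.0,
) -> np.ndarray:
    """Bead coordinates of an all-anti zigzag chain, tilted from +z.

    The extended form has every 1,3-vector exactly along the chain axis,
    so its resultant direction is the axis; the axis makes angle ``tilt``
    (degrees) with +z after rotation about the y axis (then about z by
    ``azimuth``).  ``perturbed`` adds seeded Gaussian coordinate noise of
    ``noise_amplitude`` Å; zero amplitude reproduces the extended form
    bit-for-bit.  Atom order is tail (index 0) to head (index n_c−1).
    """
    if n_c < 3:
        raise ValueError("chain needs at least 3 beads")
    if conformation not in ("extended", "perturbed"):
        raise ValueError(f"unknown conformation {conformation!r}")
    k = np.arange(n_c)
    coords = np.column_stack([
        _ZIGZAG_HALF_WIDTH * 0.5 * (-1.0) ** k,
        np.zeros(n_c),
        _ZIGZAG_RISE * k,
    ])
    coords -= coords.mean(axis=0)
    if conformation == "perturbed" and noise_amplitude > 0:
        rng = np.random.default_rng(seed)
        coords = coords + noise_amplitude * rng.standard_normal(coords.shape)
    t = np.radians(tilt)
    rot_y = np.array([[np.cos(t), 0.0, np.sin(t)],
                      [0.0, 1.0, 0.0],
                      [-np.sin(t), 0.0, np.cos(t)]])
    a = np.radians(azimuth)
    rot_z = np.array([[np.cos(a), -np.sin(a), 0.0],
                      [np.sin(a), np.cos(a), 0.0],
                      [0.0, 0.0, 1.0]])
    return coords @ rot_y.T @ rot_z.T


def _solvent_count_and_cdf(spec: SlabSystemSpec, n_grid: int = 4096):
    lx, ly, lz = spec.box
    z = np.linspace(0.0, lz, n_grid)
    rho = solvent_model(z, spec.rho_w, spec.h3, spec.h4, spec.d2)  # g cm⁻³
    # mass per unit z: ρ(z)·A, with A in Å² and z in Å -> grams via 1e-24 cm³/Å³
    mass_per_z = rho * lx * ly * 1e-24                             # g Å⁻¹
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (mass_per_z[1:] + mass_per_z[:-1])
                                           * np.diff(z))])
    total_mass = cum[-1]                                           # g
    n = int(round(total_mass * AVOGADRO / MASS_SOLVENT_BEAD))
    return n, z, cum / cum[-1]


def make_interface_system(spec: SlabSystemSpec) -> Configuration:
    """Build one frame of the slab + solvent + solute system.

    Raises ``ValueError`` when the box cannot hold the particle counts the
    requested densities imply (bead packing beyond ~1 per 4 Å³).
    """
    lx, ly, lz = spec.box
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))

    # ---- slab chains -----------------------------------------------------
    thickness = spec.h2 - spec.h1
    if spec.chain_length is not None:
        n_beads_chain = int(spec.chain_length)
        if n_beads_chain < 2:
            raise ValueError("chain_length must be >= 2 beads")
    else:
        n_beads_chain = max(int(round(thickness / _ZIGZAG_RISE)), 2)
    # Beads own equal z-segments of the slab: the continuum limit of the
    # bead density is then exactly the boxcar over [h1, h2], whose logistic
    # smearing (below) is exactly the tanh interface form.
    rise = thickness / n_beads_chain

    slab_volume_cm3 = lx * ly * thickness * 1e-24
    n_slab_beads = int(round(spec.rho_pe * slab_volume_cm3 * AVOGADRO
                             / MASS_SLAB_BEAD))
    n_chains = max(int(round(n_slab_beads / n_beads_chain)), 1)
    if n_chains * n_beads_chain > lx * ly * thickness / 4.0:
        raise ValueError("box too small for the requested slab density")

    positions, species, masses, charges, mol_ids, bonds = [], [], [], [], [], []
    atom_offset = 0
    jitter = np.radians(spec.chain_tilt_jitter)
    for c in range(n_chains):
        x0, y0 = rng.uniform(0, lx), rng.uniform(0, ly)
        z0 = spec.h1 + rng.logistic(0.0, spec.d1 / 4.0)
        polar = abs(rng.normal(0.0, jitter)) if jitter > 0 else 0.0
        azim = rng.uniform(0.0, 2.0 * np.pi)
        direction = np.array([np.sin(polar) * np.cos(azim),
                              np.sin(polar) * np.sin(azim),
                              np.cos(polar)])
        k = np.arange(n_beads_chain)[:, None]
        chain = np.array([x0, y0, z0]) + (k + 0.5) * rise * direction
        positions.append(chain)
        species.extend(["PE"] * n_beads_chain)
        masses.extend([MASS_SLAB_BEAD] * n_beads_chain)
        charges.extend([0.0] * n_beads_chain)
        mol_ids.extend([c] * n_beads_chain)
        bonds.extend((atom_offset + i, atom_offset + i + 1)
                     for i in range(n_beads_chain - 1))
        atom_offset += n_beads_chain

    # ---- solvent ---------------------------------------------------------
    n_w, z_grid, cdf = _solvent_count_and_cdf(spec)
    if n_w > lx * ly * lz / 4.0:
        raise ValueError("box too small for the requested solvent density")
    zw = np.interp(rng.random(n_w), cdf, z_grid)
    w_pos = np.column_stack([rng.uniform(0, lx, n_w),
                             rng.uniform(0, ly, n_w), zw])
    positions.append(w_pos)
    species.extend(["W"] * n_w)
    masses.extend([MASS_SOLVENT_BEAD] * n_w)
    charges.extend([0.0] * n_w)
    w_mol0 = n_chains
    mol_ids.extend(range(w_mol0, w_mol0 + n_w))
    atom_offset += n_w

    # ---- solute ----------------------------------------------------------
    surfaces = analytic_surfaces(spec)
    chain = make_oriented_chain(
        spec.solute_n_c, spec.solute_tilt0, spec.solute_conformation,
        seed=int(rng.integers(2**31)),
        azimuth=float(np.degrees(rng.uniform(0.0, 2.0 * np.pi))),
    )
    target = np.array([lx / 2.0, ly / 2.0, surfaces.z_upper + spec.solute_xi0])
    chain = chain - chain.mean(axis=0) + target
    positions.append(chain)
    species.extend(["PFAS"] * spec.solute_n_c)
    masses.extend([MASS_SOLUTE_BEAD] * spec.solute_n_c)
    # Anionic solute: nominal per-bead partial charges summing to about −1
    # (exact correction is a separate utility, as for force-field charges).
    charges.extend([-1.0 / spec.solute_n_c] * spec.solute_n_c)
    solute_mol = w_mol0 + n_w
    mol_ids.extend([solute_mol] * spec.solute_n_c)
    bonds.extend((atom_offset + i, atom_offset + i + 1)
                 for i in range(spec.solute_n_c - 1))

    return Configuration(
        positions=np.vstack(positions),
        species=np.array(species),
        masses=np.array(masses),
        charges=np.array(charges),
        molecule_ids=np.array(mol_ids),
        box=np.array([lx, ly, lz]),
        bonds=np.array(bonds, dtype=int).reshape(-1, 2),
    )


def make_trajectory_frames(spec: SlabSystemSpec, n_frames: int) -> list[Configuration]:
    """Independent frames differing only in their derived seeds."""
    if n_frames < 1:
        raise ValueError("need at least one frame")
    children = np.random.SeedSequence(spec.seed).spawn(n_frames)
    frames = []
    for child in children:
        sub = int(child.generate_state(1)[0] % (2**31))
        frames.append(make_interface_system(
            _replace_seed(spec, sub)))
    return frames


def _replace_seed(spec: SlabSystemSpec, seed: int) -> SlabSystemSpec:
    from dataclasses import replace

    return replace(spec, seed=seed)
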