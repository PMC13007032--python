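"""In-memory containers for particle configurations and trajectories."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Configuration:
    """One frame of a particle system.

    Attributes
    ----------
    positions : (n, 3) float array, Å
    species : (n,) str array — species labels (e.g. "PE", "W", "SOL")
    masses : (n,) float array, g mol⁻¹
    charges : (n,) float array, e
    molecule_ids : (n,) int array — chain / molecule membership
    box : (3,) float array — orthorhombic box lengths (Lx, Ly, Lz), Å
    bonds : (m, 2) int array — 0-based chain connectivity (may be empty)
    """

    positions: np.ndarray
    species: np.ndarray
    masses: np.ndarray
    charges: np.ndarray
    molecule_ids: np.ndarray
    box: np.ndarray
    bonds: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.species = np.asarray(self.species)
        self.masses = np.asarray(self.masses, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        self.box = np.asarray(self.box, dtype=float)
        self.bonds = np.asarray(self.bonds, dtype=int).reshape(-1, 2)
        n = len(self.positions)
        if self.positions.shape != (n, 3):
            raise ValueError(f"positions must be (n, 3), got {self.positions.shape}")
        for name in ("species", "masses", "charges", "molecule_ids"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != n atoms {n}")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def select(self, species: str) -> np.ndarray:
        """Indices of atoms with the given species label."""
        return np.flatnonzero(self.species == species)

    def com(self, indices: np.ndarray | None = None) -> np.ndarray:
        """Mass-weighted centre of mass of the selected atoms (no wrapping)."""
        idx = np.arange(self.n_atoms) if indices is None else np.asarray(indices)
        m = self.masses[idx]
        return (self.positions[idx] * m[:, None]).sum(axis=0) / m.sum()


@dataclass
class Trajectory:
    """Ordered sequence of frames with consistent atom count and ordering."""

    frames: list[Configuration]
    source_format: str = "memory"
    timestep: float | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        n0 = self.frames[0].n_atoms
        for i, fr in enumerate(self.frames):
            if fr.n_atoms != n0:
                raise ValueError(
                    f"frame {i} has {fr.n_atoms} atoms, expected {n0}"
                )

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> Configuration:
        return self.frames[i]
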