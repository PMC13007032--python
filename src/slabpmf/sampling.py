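"""Biased sampling of 1D reaction-coordinate windows.

Umbrella sampling restrains the reaction coordinate ξ′ around a window
centre ξᵢ′ with a harmonic bias w_i(ξ′) = (k/2)(ξ′ − ξᵢ′)².  Here the
molecular-dynamics engine is replaced by a seeded Metropolis Monte Carlo
sampler of the stationary distribution ∝ exp(−[A(ξ) + w_i(ξ)]/k_BT): only
that distribution, not the dynamics, enters the histogram reweighting
downstream.

The sampler runs a fixed ensemble of independent walkers in lockstep
(vectorised proposals), discards a burn-in during which the step size is
tuned to a 30–50 % acceptance rate, and then interleaves the walkers'
post-burn-in states into a single series.  Identical spec + seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_TEMPERATURE, kT
from .profiles import AnalyticProfileSpec, evaluate_profile

#: Number of lockstep Metropolis walkers per window.
N_WALKERS = 32

#: Fraction of the per-walker chain length discarded as burn-in.
BURN_IN_FRACTION = 0.10


@dataclass(frozen=True)
class BiasSpec:
    """Harmonic window bias w(ξ′) = (k/2)(ξ′ − center)².

    ``center`` in Å; ``force_constant`` k in kJ mol⁻¹ Å⁻².  Use
    :meth:`from_kcal` when the constant is quoted in kcal mol⁻¹ Å⁻².
    """

    center: float
    force_constant: float

    def __post_init__(self) -> None:
        if self.force_constant < 0:
            raise ValueError(f"force constant must be >= 0, got {self.force_constant}")

    @classmethod
    def from_kcal(cls, center: float, force_constant_kcal: float) -> "BiasSpec":
        from .constants import KCAL_TO_KJ

        return cls(center, force_constant_kcal * KCAL_TO_KJ)

    def energy(self, xi) -> np.ndarray | float:
        """Bias energy in kJ mol⁻¹ at ξ′ (scalar or array)."""
        return 0.5 * self.force_constant * (np.asarray(xi, dtype=float) - self.center) ** 2


@dataclass
class WindowSamples:
    """Per-window biased time series of the reaction coordinate."""

    bias: BiasSpec
    samples: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE
    replica_id: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError("window has no samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("window samples must be finite")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def _total_energy(spec: AnalyticProfileSpec, bias: BiasSpec, x: np.ndarray) -> np.ndarray:
    return evaluate_profile(spec, x) + bias.energy(x)


def sample_window(
    spec: AnalyticProfileSpec,
    bias: BiasSpec,
    n_samples: int,
    temperature: float = DEFAULT_TEMPERATURE,
    seed: int | np.random.SeedSequence = 0,
    burn_in_fraction: float = BURN_IN_FRACTION,
    n_walkers: int = N_WALKERS,
) -> np.ndarray:
    """Draw ``n_samples`` values of ξ′ from exp(−[A + w]/k_BT) on the domain.

    Proposals falling outside the profile domain are rejected, so the
    domain acts as a hard wall.  Walkers start at the bias centre (clipped
    to the domain) plus Gaussian scatter of one thermal width.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    beta = 1.0 / kT(temperature)  # validates temperature
    lo, hi = spec.domain
    n_walkers = int(min(n_walkers, n_samples))
    rng = np.random.default_rng(seed)

    steps_per_walker = int(np.ceil(n_samples / n_walkers))
    burn_in = max(int(np.ceil(burn_in_fraction * steps_per_walker)), 50)

    # Initial thermal width: bias curvature if biased, else the domain span.
    if bias.force_constant > 0:
        sigma0 = np.sqrt(1.0 / (beta * bias.force_constant))
    else:
        sigma0 = 0.25 * (hi - lo)
    x0 = np.clip(bias.center, lo, hi)
    x = np.clip(x0 + sigma0 * rng.standard_normal(n_walkers), lo, hi)
    energy = _total_energy(spec, bias, x)

    step = np.full(n_walkers, 2.0 * sigma0)

    def sweep(n_steps: int, collect: bool, tune_every: int = 0):
        nonlocal x, energy, step
        out = np.empty((n_steps, n_walkers)) if collect else None
        accepted = np.zeros(n_walkers)
        since_tune = 0
        for t in range(n_steps):
            prop = x + step * (2.0 * rng.random(n_walkers) - 1.0)
            inside = (prop >= lo) & (prop <= hi)
            e_prop = np.where(
                inside, _total_energy(spec, bias, np.clip(prop, lo, hi)), np.inf
            )
            accept = inside & (rng.random(n_walkers) < np.exp(
                np.clip(-beta * (e_prop - energy), -700.0, 0.0)
            ))
            x = np.where(accept, prop, x)
            energy = np.where(accept, e_prop, energy)
            accepted += accept
            since_tune += 1
            if tune_every and since_tune == tune_every:
                rate = accepted / tune_every
                step = np.where(rate < 0.30, step * 0.8, step)
                step = np.where(rate > 0.50, step * 1.25, step)
                accepted[:] = 0.0
                since_tune = 0
            if collect:
                out[t] = x
        return out

    sweep(burn_in, collect=False, tune_every=max(burn_in // 10, 10))
    series = sweep(steps_per_walker, collect=True)
    # Interleave walkers: row-major ravel keeps walkers independent streams.
    return series.ravel()[:n_samples].copy()


def generate_window_set(
    spec: AnalyticProfileSpec,
    centers,
    force_constant: float,
    n_samples: int,
    temperature: float = DEFAULT_TEMPERATURE,
    seed: int = 0,
    replica_id: int = 0,
    burn_in_fraction: float = BURN_IN_FRACTION,
) -> list[WindowSamples]:
    """One :class:`WindowSamples` per centre, with per-window seeds derived
    deterministically from the master seed.

    Duplicate centres are accepted and receive independent random streams.
    """
    centers = np.asarray(centers, dtype=float)
    if centers.size == 0:
        raise ValueError("centers must be nonempty")
    master = np.random.SeedSequence(entropy=seed, spawn_key=(replica_id,))
    children = master.spawn(len(centers))
    windows = []
    for c, child in zip(centers, children):
        bias = BiasSpec(center=float(c), force_constant=force_constant)
        xi = sample_window(
            spec, bias, n_samples, temperature, seed=child,
            burn_in_fraction=burn_in_fraction,
        )
        windows.append(
            WindowSamples(bias=bias, samples=xi, temperature=temperature,
                          replica_id=replica_id)
        )
    return windows
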