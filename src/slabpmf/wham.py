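"""Weighted Histogram Analysis Method (WHAM) for umbrella sampling.

Biased window histograms are combined into one unbiased probability
distribution by self-consistent iteration of

    P(ξ_j) = [Σ_i n_{ij}] / [Σ_i n_i exp((f_i − w_i(ξ_j)) / k_BT)]
    f_i    = −k_BT ln Σ_j P(ξ_j) exp(−w_i(ξ_j) / k_BT)

where n_{ij} are the per-window bin counts, n_i the per-window totals,
w_i the harmonic biases and f_i the window free-energy shifts.  The PMF is
−k_BT ln P(ξ_j), reported unshifted; zeroing against a bulk plateau and
replica averaging are separate steps.

All reweighting arithmetic runs in log space (logsumexp) so that stiff
biases far from their window centres cannot underflow.

Two solvers are provided: the fixed-point iteration above
(:func:`wham_solve`) and an independent route, direct minimisation of the
convex WHAM negative log-likelihood over the f_i with SciPy
(:func:`wham_solve_mle`).  They must agree to tight tolerance; the second
also serves as a cross-check of the first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .constants import DEFAULT_TEMPERATURE, kT
from .sampling import BiasSpec, WindowSamples


class ConvergenceError(RuntimeError):
    """WHAM iteration failed to reach tolerance; carries the last residual."""

    def __init__(self, message: str, residual: float, iterations: int):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations


@dataclass
class BiasedHistogramSet:
    """Per-window histograms on a shared uniform grid.

    ``counts`` is (n_windows, n_bins); ``n_total`` the per-window sample
    totals (out-of-range samples make ``counts.sum(1) < n_total`` and are
    tracked in ``n_out_of_range``).
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    biases: list[BiasSpec]
    n_total: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        self.n_total = np.asarray(self.n_total, dtype=float)
        if self.counts.shape != (len(self.biases), len(self.bin_edges) - 1):
            raise ValueError("counts shape does not match windows x bins")
        if np.any(self.counts < 0):
            raise ValueError("negative histogram counts")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_windows(self) -> int:
        return len(self.biases)

    @property
    def n_out_of_range(self) -> np.ndarray:
        return self.n_total - self.counts.sum(axis=1)


@dataclass
class FreeEnergyProfile:
    """Binned PMF with optional per-bin uncertainty.

    ``pmf`` is NaN on bins with no counts (undefined rather than
    interpolated).  ``zero_reference`` records the plateau constant once
    :func:`zero_by_plateau` has been applied.
    """

    bin_centers: np.ndarray
    pmf: np.ndarray
    stderr: np.ndarray | None = None
    n_total: np.ndarray | None = None
    zero_reference: dict = field(default_factory=dict)
    window_free_energies: np.ndarray | None = None
    iterations: int | None = None
    residual: float | None = None
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.pmf = np.asarray(self.pmf, dtype=float)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.pmf)


def build_histograms(
    windows: list[WindowSamples],
    bin_edges,
) -> BiasedHistogramSet:
    """Histogram every window's samples onto a shared grid.

    Bins are half-open [edge_j, edge_{j+1}); a sample landing exactly on an
    interior edge goes to the right-hand bin.  Samples outside the grid are
    excluded from counts but kept in each window's total.
    """
    bin_edges = np.asarray(bin_edges, dtype=float)
    if bin_edges.ndim != 1 or len(bin_edges) < 2:
        raise ValueError("need at least two bin edges")
    if np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    if not windows:
        raise ValueError("no windows supplied")
    temps = {w.temperature for w in windows}
    if len(temps) > 1:
        raise ValueError("windows sampled at different temperatures")

    n_bins = len(bin_edges) - 1
    counts = np.zeros((len(windows), n_bins))
    for i, w in enumerate(windows):
        x = w.samples
        # np.digitize with right=False gives half-open [e_j, e_{j+1}) bins,
        # except the last edge; exclude samples at or beyond it explicitly.
        idx = np.digitize(x, bin_edges) - 1
        ok = (idx >= 0) & (idx < n_bins) & (x < bin_edges[-1])
        counts[i] = np.bincount(idx[ok], minlength=n_bins)
    return BiasedHistogramSet(
        bin_edges=bin_edges,
        counts=counts,
        biases=[w.bias for w in windows],
        n_total=np.array([w.samples.size for w in windows], dtype=float),
        temperature=temps.pop(),
    )


def window_overlap(hists: BiasedHistogramSet, threshold: float = 0.05) -> dict:
    """Overlap coefficient Σ_j min(p_j, q_j) for each adjacent window pair.

    Windows are taken in input order (sorted centres expected).  Pairs with
    overlap below ``threshold`` are flagged; insufficient overlap between
    neighbouring umbrella windows is the classic failure mode of WHAM.
    """
    if hists.n_windows < 2:
        raise ValueError("overlap needs at least two windows")
    totals = hists.counts.sum(axis=1)
    overlaps, flagged = [], []
    for i in range(hists.n_windows - 1):
        p = hists.counts[i] / totals[i] if totals[i] > 0 else hists.counts[i]
        q = hists.counts[i + 1] / totals[i + 1] if totals[i + 1] > 0 else hists.counts[i + 1]
        ov = float(np.minimum(p, q).sum())
        overlaps.append(ov)
        if ov < threshold:
            flagged.append((i, i + 1))
    return {"overlap": np.array(overlaps), "flagged_pairs": flagged,
            "threshold": threshold}


def _bias_matrix(hists: BiasedHistogramSet) -> np.ndarray:
    """w_i evaluated at bin centres (midpoint rule), shape (windows, bins)."""
    centers = hists.bin_centers
    return np.stack([b.energy(centers) for b in hists.biases])


def wham_solve(
    hists: BiasedHistogramSet,
    temperature: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 100_000,
) -> FreeEnergyProfile:
    """Self-consistent WHAM solution of the biased histogram set.

    Iterates until max_i |Δf_i| < tol·k_BT.  Returns the unshifted PMF
    −k_BT ln P with NaN on empty bins, plus the converged window free
    energies f_i (gauge: f_0 = 0), the iteration count and final residual.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if temperature is None:
        temperature = hists.temperature
    kt = kT(temperature)

    w = _bias_matrix(hists)                      # (I, J)
    n_ij = hists.counts
    n_j = n_ij.sum(axis=0)                       # per-bin totals
    n_i = n_ij.sum(axis=1)                       # per-window in-range totals
    live = n_i > 0
    if not np.any(live):
        raise ValueError("all windows empty on this grid")
    occupied = n_j > 0

    log_n_i = np.where(live, np.log(np.where(live, n_i, 1.0)), -np.inf)
    log_n_j = np.log(n_j[occupied])
    bw = -w[:, occupied] / kt                    # −w_ij/kT on occupied bins

    g = np.zeros(hists.n_windows)                # g_i = f_i / kT
    residual = np.inf
    for iteration in range(1, max_iter + 1):
        # log P_j = log N_j − logsumexp_i [log n_i + g_i + bw_ij]
        denom = logsumexp(log_n_i[:, None] + g[:, None] + bw, axis=0)
        log_p = log_n_j - denom
        log_p -= logsumexp(log_p)                # Σ_j P_j = 1
        g_new = -logsumexp(log_p[None, :] + bw, axis=1)
        g_new -= g_new[0]                        # gauge fix
        residual = float(np.max(np.abs(g_new - g)))
        g = g_new
        if residual < tol:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {residual:.3e} kT, tol {tol:.1e} kT)",
            residual=residual, iterations=max_iter,
        )

    pmf = np.full(len(n_j), np.nan)
    pmf[occupied] = -kt * log_p
    return FreeEnergyProfile(
        bin_centers=hists.bin_centers,
        pmf=pmf,
        n_total=n_j,
        window_free_energies=g * kt,
        iterations=iteration,
        residual=residual,
        temperature=temperature,
    )


def wham_solve_mle(
    hists: BiasedHistogramSet,
    temperature: float | None = None,
    gtol: float = 1e-10,
) -> FreeEnergyProfile:
    """WHAM by direct minimisation of the negative log-likelihood.

    The WHAM equations are the stationarity conditions of the convex
    function  κ(g) = Σ_j N_j ln Σ_i n_i exp(g_i + bw_ij) − Σ_i n_i g_i
    over the reduced free energies g_i = f_i/k_BT (one gauge degree fixed).
    Solving with a quasi-Newton minimiser is an algorithmically independent
    route to the same solution as :func:`wham_solve`.
    """
    if temperature is None:
        temperature = hists.temperature
    kt = kT(temperature)
    w = _bias_matrix(hists)
    n_ij = hists.counts
    n_j = n_ij.sum(axis=0)
    n_i = n_ij.sum(axis=1)
    occupied = n_j > 0
    live = n_i > 0
    log_n_i = np.where(live, np.log(np.where(live, n_i, 1.0)), -np.inf)
    bw = -w[:, occupied] / kt
    n_jo = n_j[occupied]

    n_tot = n_i.sum()

    def objective(g_free: np.ndarray):
        g = np.concatenate([[0.0], g_free])
        a = log_n_i[:, None] + g[:, None] + bw   # (I, Jo)
        lse = logsumexp(a, axis=0)
        val = (np.dot(n_jo, lse) - np.dot(n_i, g)) / n_tot
        # gradient: Σ_j N_j softmax_i(a) − n_i
        soft = np.exp(a - lse[None, :])
        grad = (soft @ n_jo - n_i) / n_tot
        return float(val), grad[1:], soft

    x0 = np.zeros(hists.n_windows - 1)
    res = minimize(lambda x: objective(x)[:2], x0, jac=True,
                   method="L-BFGS-B",
                   options={"gtol": 1e-12, "ftol": 0.0, "maxiter": 50_000})
    x = res.x
    # Newton polish with the analytic Hessian (objective is convex; the
    # gauge g_0 = 0 makes the reduced Hessian positive definite).
    for _ in range(50):
        _, grad, soft = objective(x)
        if np.max(np.abs(grad)) < gtol:
            break
        hess = (soft * n_jo[None, :]) @ soft.T
        np.fill_diagonal(hess, hess.diagonal()
                         - (soft * n_jo[None, :]).sum(axis=1))
        hess = -hess[1:, 1:] / n_tot
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            break
        x = x + step
    g = np.concatenate([[0.0], x])

    denom = logsumexp(log_n_i[:, None] + g[:, None] + bw, axis=0)
    log_p = np.log(n_jo) - denom
    log_p -= logsumexp(log_p)
    pmf = np.full(len(n_j), np.nan)
    pmf[occupied] = -kt * log_p
    return FreeEnergyProfile(
        bin_centers=hists.bin_centers,
        pmf=pmf,
        n_total=n_j,
        window_free_energies=g * kt,
        iterations=int(res.nit),
        residual=float(np.max(np.abs(res.jac))) if res.jac is not None else None,
        temperature=temperature,
    )


def zero_by_plateau(
    profile: FreeEnergyProfile,
    plateau_range: tuple[float, float] | None = None,
) -> FreeEnergyProfile:
    """Zero the PMF against its bulk plateau.

    Fits a constant (the arithmetic mean) to the defined bins inside
    ``plateau_range`` and subtracts it everywhere, so the PMF reads zero at
    large separations where the interaction has decayed.  Default range:
    the last 20 % of defined bins (the high-ξ, bulk-solvent side).
    """
    defined = profile.defined
    if plateau_range is None:
        idx = np.flatnonzero(defined)
        if idx.size < 2:
            raise ValueError("fewer than two defined bins")
        tail = idx[-max(int(np.ceil(0.2 * idx.size)), 2):]
        mask = np.zeros_like(defined)
        mask[tail] = True
        plateau_range = (float(profile.bin_centers[tail[0]]),
                         float(profile.bin_centers[tail[-1]]))
    else:
        lo, hi = plateau_range
        mask = defined & (profile.bin_centers >= lo) & (profile.bin_centers <= hi)
    if mask.sum() < 2:
        raise ValueError("plateau range contains fewer than two defined bins")
    constant = float(np.mean(profile.pmf[mask]))
    return FreeEnergyProfile(
        bin_centers=profile.bin_centers,
        pmf=profile.pmf - constant,
        stderr=profile.stderr,
        n_total=profile.n_total,
        zero_reference={"plateau_range": tuple(plateau_range),
                        "constant": constant, "n_bins": int(mask.sum())},
        window_free_energies=profile.window_free_energies,
        iterations=profile.iterations,
        residual=profile.residual,
        temperature=profile.temperature,
    )


def combine_replicas(profiles: list[FreeEnergyProfile]) -> FreeEnergyProfile:
    """Per-bin mean and sample standard deviation across replica PMFs.

    Replicas must share the bin grid and already be plateau-zeroed; the
    inter-replica standard deviation is the reported uncertainty.  Bins
    undefined in any replica are undefined in the output.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two replicas")
    grid = profiles[0].bin_centers
    for p in profiles[1:]:
        if p.bin_centers.shape != grid.shape or not np.allclose(p.bin_centers, grid):
            raise ValueError("replica bin grids differ")
    stack = np.stack([p.pmf for p in profiles])
    defined = np.all(np.isfinite(stack), axis=0)
    mean = np.where(defined, stack.mean(axis=0), np.nan)
    sd = np.where(defined, stack.std(axis=0, ddof=1), np.nan)
    n_total = None
    if all(p.n_total is not None for p in profiles):
        n_total = np.sum([p.n_total for p in profiles], axis=0)
    return FreeEnergyProfile(
        bin_centers=grid, pmf=mean, stderr=sd, n_total=n_total,
        zero_reference={"replicas": len(profiles)},
        temperature=profiles[0].temperature,
    )
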