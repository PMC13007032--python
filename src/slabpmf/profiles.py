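"""Analytic ground-truth free-energy profiles A(ξ).

These profiles stand in for the unknown potential of mean force that a
biased-sampling reconstruction must recover: synthetic window samples are
drawn from exp(−[A(ξ) + w_i(ξ)]/k_BT) so every downstream estimate can be
compared to a known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_FORMS = ("flat", "harmonic", "double_well", "tabulated")


@dataclass(frozen=True)
class AnalyticProfileSpec:
    """A 1D free-energy profile on a closed domain.

    Parameters
    ----------
    form : {"flat", "harmonic", "double_well", "tabulated"}
    params : dict
        ``harmonic``: ``a`` (kJ mol⁻¹ Å⁻²), optional ``center`` (Å, default 0);
        A(ξ) = ½·a·(ξ−center)².
        ``double_well``: ``barrier`` (kJ mol⁻¹), ``well_separation`` (Å,
        distance between the two minima), optional ``center``;
        A(ξ) = barrier · [((ξ−center)² − b²)/b²]² with b = well_separation/2,
        so the minima sit at center ± b and the barrier between them has the
        stated height.
        ``tabulated``: ``xi`` (strictly increasing abscissa, Å) and
        ``energy`` (kJ mol⁻¹); linear interpolation between nodes.
        ``flat``: no parameters.
    domain : (ξ_min, ξ_max) closed interval in Å.
    """

    form: str
    domain: tuple[float, float]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.form not in _FORMS:
            raise ValueError(f"unknown profile form {self.form!r}; one of {_FORMS}")
        lo, hi = self.domain
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError(f"domain must be a nonempty finite interval, got {self.domain}")
        if self.form == "tabulated":
            xi = np.asarray(self.params["xi"], dtype=float)
            en = np.asarray(self.params["energy"], dtype=float)
            if xi.ndim != 1 or xi.shape != en.shape or len(xi) < 2:
                raise ValueError("tabulated profile needs matching 1D xi/energy arrays, >= 2 nodes")
            if np.any(np.diff(xi) <= 0):
                raise ValueError("tabulated abscissa must be strictly increasing")
            if not np.all(np.isfinite(en)):
                raise ValueError("tabulated energies must be finite")


def evaluate_profile(spec: AnalyticProfileSpec, xi) -> np.ndarray | float:
    """Evaluate A(ξ) in kJ mol⁻¹ at ξ (scalar or array, Å).

    Raises
    ------
    ValueError
        If any ξ lies outside the spec's domain.
    """
    x = np.asarray(xi, dtype=float)
    lo, hi = spec.domain
    if np.any(x < lo) or np.any(x > hi):
        raise ValueError(f"ξ outside domain [{lo}, {hi}]")
    if spec.form == "flat":
        out = np.zeros_like(x)
    elif spec.form == "harmonic":
        a = float(spec.params["a"])
        c = float(spec.params.get("center", 0.0))
        out = 0.5 * a * (x - c) ** 2
    elif spec.form == "double_well":
        barrier = float(spec.params["barrier"])
        b = float(spec.params["well_separation"]) / 2.0
        c = float(spec.params.get("center", 0.0))
        u = ((x - c) ** 2 - b**2) / b**2
        out = barrier * u**2
    else:  # tabulated
        nodes = np.asarray(spec.params["xi"], dtype=float)
        energy = np.asarray(spec.params["energy"], dtype=float)
        out = np.interp(x, nodes, energy)
    return out if out.ndim else float(out)
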