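# Methods

This note records the models implemented in `slabpmf`, the numerical
choices behind them, and what the synthetic validation does and does not
demonstrate about real simulation data.

## Biased sampling model

Umbrella-sampling analysis only uses the *stationary* distribution of
each restrained window, ∝ exp(−[A(ξ) + w_i(ξ)]/k_BT), never its
dynamics. The synthetic generator therefore replaces restrained MD with
Metropolis Monte Carlo on analytic free-energy profiles A(ξ) (flat,
harmonic, double-well, tabulated). Implementation details:

- **Walker ensemble.** `sample_window` runs 32 independent walkers in
  lockstep (vectorised proposals) and interleaves their post-burn-in
  states. This trades a shorter per-walker chain for throughput; for the
  1D potentials used here the burn-in (10 % of the per-walker length,
  minimum 50 sweeps) comfortably equilibrates walkers initialised at the
  bias centre with one thermal width of scatter.
- **Step size** is tuned during burn-in toward a 30–50 % acceptance
  rate, per window. Proposals outside the profile domain are rejected
  (hard walls).
- **Determinism.** All randomness flows through `numpy` `SeedSequence`;
  window and replica streams are spawned from the master seed, so equal
  spec + seed reproduces outputs bit for bit.
- **Validation.** For purely quadratic total potentials the stationary
  distribution is Gaussian with known mean and variance; the tests check
  both to a few standard errors, inflated ~4× for the Metropolis
  autocorrelation within each walker chain. Statistical test envelopes
  throughout the suite account for this correlation — i.i.d. multinomial
  bounds are too tight for MC series by roughly a factor 2 in the
  per-bin deviation.

Constants: k_B = 0.0083144621 kJ mol⁻¹ K⁻¹, default T = 300 K, default
bias force constant 41.84 kJ mol⁻¹ Å⁻² (10 kcal mol⁻¹ Å⁻², converted
with 4.184 kJ/kcal).

## WHAM

`wham_solve` iterates the standard self-consistent equations on a
uniform grid (default bin width 0.2 Å), with the bias evaluated at bin
centres (midpoint rule). All reweighting runs in log space (logsumexp),
so stiff biases far from their centres cannot underflow. Initialisation
f_i = 0; gauge fixed by f_0 = 0; bins with zero total counts are
excluded from normalisation and reported as NaN rather than
interpolated. Convergence: max|Δf_i| < tol·k_BT, default tol 10⁻⁶,
max 10⁵ iterations; non-convergence raises with the residual attached.
Note that the fixed-point iteration stalls near 10⁻⁹ k_BT in float64, so
tolerances below that are unattainable; and the converged-f error can
exceed the last Δf when window overlap is marginal (slow contraction).

`wham_solve_mle` is an independent route: the WHAM equations are the
stationarity conditions of a convex likelihood in the reduced free
energies g_i = f_i/k_BT, which is minimised by L-BFGS followed by
exact-Hessian Newton polishing (the Hessian is a small I×I matrix built
from softmax weights). The two solvers agree to better than 10⁻⁶ k_BT on
well-posed instances. Identifiability caveat: when adjacent windows
share no histogram support the likelihood decouples and relative f_i
between disconnected groups is undetermined — comparisons between
solvers are only meaningful with overlap, which `window_overlap`
quantifies (coefficient Σ_j min(p_j, q_j) per adjacent pair, flag
threshold 0.05 by default).

**Zeroing.** The PMF zero is a fitted constant (arithmetic mean) over a
plateau range, subtracted everywhere. The default range is the last 20 %
of defined bins — the bulk-solvent side — and is overridable; the
double-well demo in `analysis/` instead zeroes on the locally flat well
region, since that profile has no bulk plateau.

**Uncertainty** is the per-bin sample standard deviation across ≥ 2
independent replicas (no bootstrap, no autocorrelation-based
inefficiency weighting); bins undefined in any replica are undefined in
the combination.

## Synthetic slab systems

`make_interface_system` builds one frame of a coarse-grained slab +
solvent + solute box whose z-density profiles follow the tanh interface
models *exactly* in expectation:

- **Slab chains** are straight bead chains (bead mass 14.027 g mol⁻¹,
  axial spacing ≈ the 1.257 Å all-anti backbone rise) spanning [h₁, h₂],
  each rigidly shifted in z by a logistic random offset of scale D₁/4.
  Since the logistic CDF is ½[1 + tanh(u/2s)], the boxcar-convolved
  chain density is exactly ½ρ_b[tanh(2(z−h₁)/D₁) − tanh(2(z−h₂)/D₁)].
  Beads own equal z-segments (placed at segment midpoints) so the bulk
  amplitude is exact as well. Chain tilt jitter (default 8° half-normal
  polar angle, emulating imperfect lamellar alignment) slightly
  contracts the apparent slab thickness — at 8° the fitted h₂ sits
  ~0.3 Å inside the nominal value, within the validation tolerances.
- **Solvent beads** (18.015 g mol⁻¹) are drawn independently from the
  complementary solvent tanh profile by inverse-CDF sampling on a fine
  grid; xy positions are uniform.
- **Solute**: an all-anti zigzag of CF₂-like beads (C–C 1.54 Å,
  tetrahedral angle), built by `make_oriented_chain` with a controllable
  tilt θ₀ from +z, optional seeded Gaussian coordinate noise
  ("perturbed" conformation, default amplitude 0.25 Å), and per-bead
  partial charges summing to −1. Its centre of mass is placed at
  ξ₀ from the upper Gibbs dividing surface of the *generating* curves,
  so ξ has an exact construction value.

Default geometry: 40 × 40 × 110 Å box, slab on (33, 77) Å (thick enough
that the 18 Å cylinder offset leaves a sampling region below the
interface), ρ_b,slab = 0.93 and ρ_b,solvent = 1.00 g cm⁻³, D = 4 Å —
representative of a semicrystalline polyethylene slab in water.

What the generator does **not** emulate: molecular force fields,
excluded volume, capillary-wave roughening, solvent structuring at the
interface, solute-slab coupling (the solute does not perturb the slab),
or any dynamics. Passing the round-trip tests therefore demonstrates
correctness of the *analysis operators* — binning, fitting,
root-finding, vector conventions — not fidelity of any physical model.

## Interface fits and the GDS

Mass density per bin = Σ(atomic masses)/(bin slab volume), averaged over
frames, converted to g cm⁻³ via Avogadro's number; coordinates are
wrapped along the binning axis; the box is assumed fixed (NVT). Default
100 bins. The tanh models are fitted by Levenberg–Marquardt
(`scipy.optimize.curve_fit`) with initial guesses at the half-maximum
crossings; both branches share one ρ_b and one D, exactly as the model
forms state. The GDS is the root of ρ_slab − ρ_solvent, bracketed around
each interface pair, solved by Brent's method to 10⁻⁶ Å (validated
against a 10⁻³ Å grid scan).

ξ is the signed z-distance to the *nearest* GDS, negative toward the
slab interior on both sides; a solute exactly midway is assigned to the
upper surface. Reflection through the slab midplane consequently
preserves ξ.

## Orientation analysis

`solute_vector` averages normalised 1,3-vectors over the backbone in
tail-to-head order (a carboxylate headgroup carbon is excluded from the
backbone list; a sulfonate headgroup contributes no carbon, so all tail
carbons enter and the sulfur never does). `select_cylinder` keeps slab
fragments whose *central* atom lies within the cylinder (xy distance
under the minimum image, z within [slab COM + 18 Å, GDS]); membership by
central atom avoids double-clipping partial fragments.

The literal "maximise the resultant magnitude" sign assignment is a 2ⁿ
combinatorial search; `slab_vector` uses the greedy
accumulate-and-flip rule (first vector flipped to nonnegative z, each
subsequent vector reversed when its dot with the running resultant is
negative, final resultant flipped to within 90° of +z; an exactly
horizontal resultant is left as accumulated). Tests retain the
exhaustive oracle for n ≤ 15 fragments: for fragment sets scattered up
to ~0.3 (unit-vector perturbation) about a common axis — the regime an
aligned slab produces — greedy and exhaustive solutions coincide; at
larger scatter the greedy direction can deviate by a few degrees.

S_v is computed per frame from θ = arccos(v₁·v₂) and ensemble-averaged
as ⟨cos²θ⟩ within each ξ-bin (averaging cos²θ then applying the affine
map equals averaging per-frame S_v). Confidence intervals are Student-t:
across per-replica bin means when ≥ 2 replicas exist, otherwise across
10 contiguous block means within the series.

## RMSD

Kabsch superposition by SVD of the covariance matrix with reflection
correction (det = +1 enforced; mirror images keep nonzero RMSD), equal
atom weights (no mass weighting), collinear references rejected as
degenerate. `backbone_rmsd` aligns on the designated backbone subset
and evaluates √[(1/N)Σ‖x_i − x_i*‖²] on it; the reference is the
all-anti extended conformation from `make_oriented_chain`.

## Net-charge correction

Fitted partial charges typically miss the formal molecular charge by a
rounding residue. `correct_net_charge` applies the minimal uniform
shift (target − Σq)/n, computing sums with `math.fsum` and iteratively
absorbing the final floating-point remainder into one entry so the
corrected charges sum to the target exactly.

## Problem sizes

The validation suite uses 25 windows × 5·10⁴ samples for the double-well
recovery (RMSE ≈ 0.2 kJ mol⁻¹ against truth), ≤ 5-window instances for
solver cross-checks, 8–10 frames of ~6·10³-particle slabs for the
interface and orientation round-trips, and 10⁵ draws for isotropic
averages — sizes at which the statistical envelopes derived above are
meaningful while the full suite runs in well under a minute of compute
per heavy test.

## Known limitations

- Single 1D reaction coordinate; no MBAR generalisation, no 2D WHAM.
- Replica uncertainty ignores within-replica autocorrelation.
- The slab generator's tilt jitter biases the fitted interface width
  upward slightly; exact round-trips require zero jitter.
- LAMMPS-dump support covers orthorhombic boxes and the common column
  dialects (x/xs/xu); triclinic boxes are not parsed.
- The cylinder's lower bound assumes the slab is thick enough that
  slab COM + 18 Å lies below the interface; thinner slabs raise an
  empty-region condition rather than adapting the bound.
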