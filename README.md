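# slabpmf

Analysis toolkit for umbrella-sampling simulations of a chain solute
(e.g. an anionic perfluoroalkyl contaminant) at a polymer-slab / water
interface. It implements the full post-processing chain such studies
need — free-energy reconstruction, interface location, orientational
order, conformational change — together with a synthetic-data generator
whose outputs have analytic ground truth, so every stage can be
validated end to end without running molecular dynamics.

## What it computes

**Potential of mean force (WHAM).** Umbrella sampling restrains the
reaction coordinate ξ′ (the z-distance between the solute and slab
centres of mass) in window *i* with a harmonic bias
w_i(ξ′) = (k/2)(ξ′ − ξ′_i)². The biased window histograms are combined
by the Weighted Histogram Analysis Method,

    P(ξ_j) = [Σ_i n_ij] / [Σ_i n_i exp((f_i − w_i(ξ_j))/k_BT)]
    f_i    = −k_BT ln Σ_j P(ξ_j) exp(−w_i(ξ_j)/k_BT)

iterated to self-consistency; the PMF is −k_BT ln P, zeroed against its
bulk-solvent plateau, with uncertainties from independent replicas. A
second solver (direct minimisation of the convex WHAM likelihood)
provides an independent cross-check.

**Gibbs dividing surface.** The slab and solvent mass-density profiles
along z are fitted with hyperbolic-tangent models

    ρ_slab(z) = ½ρ_b[tanh(2(z−h₁)/D₁) − tanh(2(z−h₂)/D₁)]
    ρ_w(z)    = ρ_b,w[1 − ½tanh(2(z−h₃)/D₂) + ½tanh(2(z−h₄)/D₂)]

and the Gibbs dividing surface (GDS) is where the two curves intersect.
The reaction coordinate is re-referenced to ξ, the signed distance from
the nearest GDS (negative toward the slab interior).

**Orientational order parameter.** The solute direction v₁ is the mean
normalised 1,3-vector along its backbone; the local slab direction v₂
is the flip-consistent resultant of slab-chain 1,3-vectors inside a
cylinder around the solute (radius 13 Å, from 18 Å above the slab
centre of mass up to the GDS). The order parameter is
S_v = (3⟨cos²θ⟩ − 1)/2: 1 for parallel, −0.5 for perpendicular, 0 for
isotropic.

**Backbone RMSD.** Conformational change against an extended reference,
after optimal (Kabsch) removal of rigid translation and rotation.

## Worked example

The numbered drivers under `analysis/` run the whole chain on synthetic
systems with known truth (bulky intermediates go to `scratch/`, tables
to `results/`):

```
$ python analysis/01_sample_windows.py
replica 0 adjacent-window overlap: min 0.081, median 0.107; 0 pairs below 0.05
wrote 4 x 25 window series to scratch/windows

$ python analysis/02_wham_pmf.py
replica 0: 3953 iterations, reference constant 8.321 kJ/mol
...
PMF written to results/pmf.tsv; RMSE vs generating profile 0.182 kJ/mol over 98 well-sampled bins
barrier height recovered 12.72 kJ/mol (generating 12.47); mean replica SD 0.128 kJ/mol

$ python analysis/03_interface_gds.py
slab fit: rho_b 0.934 g/cm3 (generating 0.93), h (33.07, 76.74) A, D 4.17 A
solvent fit: rho_b 1.000 g/cm3 (generating 1.0)
GDS: z = 33.11, 76.76 A (generating 33.07, 76.93)

$ python analysis/04_orientation_rmsd.py
8 frames: mean theta 30.33 deg, mean S_v 0.616 (tilt-30° expectation 0.625), mean backbone RMSD 0.3539 A
```

Reading the output: 25 windows of 5·10⁴ biased samples per replica
reconstruct a 12.47 kJ/mol (5 k_BT) double-well barrier to 0.18 kJ/mol
RMSE; the density fits recover the generating bulk densities and
interface positions, so the GDS lands within a fraction of an ångström
of its construction; and a solute built with a 30° tilt yields a mean
S_v consistent with the analytic value (3cos²30° − 1)/2 = 0.625.

The same stages are available as a CLI (`slabpmf generate|wham|gds|
makeslab|pipeline`) and as library functions (`slabpmf.wham_solve`,
`slabpmf.fit_interface`, `slabpmf.order_parameter`, ...).

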