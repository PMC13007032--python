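"""Locate the slab-solvent interface of a synthetic slab system.

Generates frames of the coarse-grained polymer-slab + solvent system
(solute tilted 30° at the upper interface), bins the mass density of
each component along z, fits the tanh interface models, and intersects
them to obtain the Gibbs dividing surfaces.  The fitted parameters are
compared against the generating values.
"""

import sys
from pathlib import Path

from slabpmf import (SlabSystemSpec, Trajectory, analytic_surfaces,
                     density_profile, fit_interface, gibbs_surfaces)
from slabpmf.io import write_table, write_xyz, write_yaml
from slabpmf.slab import make_trajectory_frames

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 42
OUT = Path("results")
OUT.mkdir(exist_ok=True)

spec = SlabSystemSpec(seed=SEED, solute_tilt0=30.0, solute_xi0=0.0,
                      solute_conformation="perturbed")
frames = make_trajectory_frames(spec, 8)
Path("scratch").mkdir(exist_ok=True)
write_xyz(Path("scratch") / "slab.xyz", frames)
traj = Trajectory(frames=frames)

pe_prof = density_profile(traj, "PE")
w_prof = density_profile(traj, "W")
pe_fit = fit_interface(pe_prof, "pe_slab")
w_fit = fit_interface(w_prof, "solvent")
surf = gibbs_surfaces(pe_fit, w_fit)
truth = analytic_surfaces(spec)

write_table(OUT / "density.tsv", {
    "z": pe_prof.bin_centers, "rho_pe": pe_prof.density,
    "rho_w": w_prof.density})
write_yaml(OUT / "gds.yaml", {
    "seed": SEED, "n_frames": len(frames),
    "pe": {"rho_b": pe_fit.rho_b, "h": list(pe_fit.positions),
           "D": pe_fit.width, "rms_residual": pe_fit.residual_rms},
    "water": {"rho_b": w_fit.rho_b, "h": list(w_fit.positions),
              "D": w_fit.width, "rms_residual": w_fit.residual_rms},
    "z_lower": surf.z_lower, "z_upper": surf.z_upper,
    "z_lower_generating": truth.z_lower, "z_upper_generating": truth.z_upper})

print(f"slab fit: rho_b {pe_fit.rho_b:.3f} g/cm3 (generating {spec.rho_pe}), "
      f"h ({pe_fit.positions[0]:.2f}, {pe_fit.positions[1]:.2f}) A, "
      f"D {pe_fit.width:.2f} A")
print(f"solvent fit: rho_b {w_fit.rho_b:.3f} g/cm3 (generating {spec.rho_w})")
print(f"GDS: z = {surf.z_lower:.2f}, {surf.z_upper:.2f} A "
      f"(generating {truth.z_lower:.2f}, {truth.z_upper:.2f})")
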