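"""End-to-end analysis pipeline over synthetic ground-truth systems.

Stages: generate biased window samples on an analytic profile →
histogram → WHAM → plateau zeroing → replica statistics → slab system
generation → density fits and Gibbs dividing surfaces → interface
re-referencing → orientation order parameter → backbone RMSD.  Every
stage writes TSV/YAML artifacts stamped with a hash of the resolved
configuration, and all randomness derives from the single config seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml

from . import io
from .conformation import backbone_rmsd
from .constants import DEFAULT_FORCE_CONSTANT, DEFAULT_TEMPERATURE
from .interface import density_profile, fit_interface, gibbs_surfaces, rereference
from .orientation import (CylinderSpec, OrientationRecord, order_parameter,
                          orientation_profile, select_cylinder, slab_vector,
                          solute_vector)
from .profiles import AnalyticProfileSpec
from .sampling import generate_window_set
from .slab import SlabSystemSpec, make_interface_system, make_oriented_chain
from .wham import (build_histograms, combine_replicas, wham_solve,
                   window_overlap, zero_by_plateau)

DEFAULT_CONFIG = {
    "seed": 0,
    "temperature": DEFAULT_TEMPERATURE,
    "profile": {"form": "double_well",
                "domain": [-10.0, 10.0],
                "params": {"barrier": 12.47, "well_separation": 10.0}},
    "windows": {"centers": "auto", "n_windows": 25,
                "force_constant": DEFAULT_FORCE_CONSTANT,
                "n_samples": 20000, "replicas": 4},
    "wham": {"bin_width": 0.2, "tol": 1e-6, "max_iter": 100000,
             "plateau_range": None},
    "slab": {"n_frames": 4, "solute_xi0": 0.0, "solute_tilt0": 30.0},
    "cylinder": {"radius": 13.0, "z_lower_offset": 18.0},
    "orientation": {"xi_bins": [-8.0, 8.0, 17]},
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(source) -> dict:
    """Resolve a config mapping or YAML path against the defaults."""
    if source is None:
        cfg = {}
    elif isinstance(source, (str, Path)):
        cfg = io.read_yaml(source) or {}
    else:
        cfg = dict(source)
    merged = _merge(DEFAULT_CONFIG, cfg)
    if merged.get("temperature") is None:
        raise ValueError("config missing temperature")
    if float(merged["temperature"]) <= 0:
        raise ValueError("temperature must be positive")
    return merged


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def run_pipeline(config=None, outdir="pipeline_out") -> dict:
    """Run every stage and write artifacts under ``outdir``.

    Returns a summary dict (also written as ``run_log.yaml``) holding the
    config hash, per-stage timings, convergence diagnostics and headline
    numbers (well depth, GDS positions, mean order parameter, RMSD).
    """
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    log: dict = {"config_hash": chash, "seed": cfg["seed"], "stages": {}}
    temperature = float(cfg["temperature"])
    rng_root = np.random.SeedSequence(int(cfg["seed"]))
    seed_wham, seed_slab = (int(s.generate_state(1)[0] % 2**31)
                            for s in rng_root.spawn(2))

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log["stages"][name] = {}
                return self

            def __exit__(self, exc_type, exc, tb):
                log["stages"][name]["seconds"] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return _Timer()

    # ---- umbrella sampling + WHAM ---------------------------------------
    with stage("windows"):
        pcfg = cfg["profile"]
        profile = AnalyticProfileSpec(form=pcfg["form"],
                                      domain=tuple(pcfg["domain"]),
                                      params=pcfg.get("params", {}))
        wcfg = cfg["windows"]
        lo, hi = profile.domain
        centers = (np.linspace(lo, hi, int(wcfg["n_windows"]))
                   if wcfg["centers"] == "auto" else np.asarray(wcfg["centers"]))
        replicas = []
        for r in range(int(wcfg["replicas"])):
            replicas.append(generate_window_set(
                profile, centers, float(wcfg["force_constant"]),
                int(wcfg["n_samples"]), temperature,
                seed=seed_wham, replica_id=r))
        for r, wins in enumerate(replicas):
            for w in wins:
                io.write_window_series(
                    outdir / f"window_r{r}_c{w.bias.center:+.3f}.dat",
                    np.arange(w.samples.size), w.samples)

    with stage("wham"):
        hcfg = cfg["wham"]
        edges = np.arange(lo, hi + hcfg["bin_width"], hcfg["bin_width"])
        zeroed = []
        for wins in replicas:
            hists = build_histograms(wins, edges)
            prof = wham_solve(hists, temperature, tol=float(hcfg["tol"]),
                              max_iter=int(hcfg["max_iter"]))
            pr = hcfg["plateau_range"]
            zeroed.append(zero_by_plateau(prof, tuple(pr) if pr else None))
        overlap = window_overlap(build_histograms(replicas[0], edges))
        combined = combine_replicas(zeroed) if len(zeroed) > 1 else zeroed[0]
        io.write_table(outdir / "pmf.tsv", {
            "bin_center": combined.bin_centers,
            "pmf": combined.pmf,
            "stderr": (combined.stderr if combined.stderr is not None
                       else np.full_like(combined.pmf, np.nan)),
            "n_total": combined.n_total,
        })
        io.write_yaml(outdir / "pmf_meta.yaml", {
            "config_hash": chash, "temperature": temperature,
            "tol": hcfg["tol"],
            "iterations": [p.iterations for p in zeroed],
            "plateau_constant": [p.zero_reference["constant"] for p in zeroed],
            "min_overlap": float(overlap["overlap"].min()),
        })
        well = combined.pmf[combined.defined]
        log["stages"]["wham"].update({
            "well_depth": float(np.nanmin(well)),
            "min_overlap": float(overlap["overlap"].min()),
        })

    # ---- slab system, GDS, orientation, RMSD ----------------------------
    with stage("slab"):
        scfg = cfg["slab"]
        spec = SlabSystemSpec(seed=seed_slab,
                              solute_xi0=float(scfg["solute_xi0"]),
                              solute_tilt0=float(scfg["solute_tilt0"]))
        from .slab import make_trajectory_frames
        frames = make_trajectory_frames(spec, int(scfg["n_frames"]))
        io.write_xyz(outdir / "slab.xyz", frames)

    with stage("gds"):
        from .core import Trajectory
        traj = Trajectory(frames=frames)
        pe_prof = density_profile(traj, "PE")
        w_prof = density_profile(traj, "W")
        pe_fit = fit_interface(pe_prof, "pe_slab")
        w_fit = fit_interface(w_prof, "solvent")
        surfaces = gibbs_surfaces(pe_fit, w_fit)
        io.write_table(outdir / "density.tsv", {
            "z": pe_prof.bin_centers, "rho_pe": pe_prof.density,
            "rho_w": w_prof.density})
        io.write_yaml(outdir / "gds.yaml", {
            "config_hash": chash,
            "pe": {"rho_b": pe_fit.rho_b, "h": list(pe_fit.positions),
                   "D": pe_fit.width, "rms": pe_fit.residual_rms},
            "water": {"rho_b": w_fit.rho_b, "h": list(w_fit.positions),
                      "D": w_fit.width, "rms": w_fit.residual_rms},
            "z_lower": surfaces.z_lower, "z_upper": surfaces.z_upper})
        log["stages"]["gds"].update({"z_lower": surfaces.z_lower,
                                     "z_upper": surfaces.z_upper})

    with stage("orientation"):
        ccfg = cfg["cylinder"]
        records = []
        reference = make_oriented_chain(spec.solute_n_c, 0.0, "extended")
        rmsds = []
        for fi, fr in enumerate(frames):
            sol = fr.select("PFAS")
            coords = fr.positions[sol]
            v1 = solute_vector(coords)
            com = fr.com(sol)
            slab_com_z = float(fr.com(fr.select("PE"))[2])
            cyl = CylinderSpec(radius=float(ccfg["radius"]),
                               z_lower_offset_from_slab_com=float(ccfg["z_lower_offset"]),
                               z_upper=surfaces.z_upper)
            fragments = select_cylinder(fr, (com[0], com[1]), cyl,
                                        slab_com_z=slab_com_z)
            if not fragments:
                continue
            v2 = slab_vector(fragments)
            theta, s_v = order_parameter(v1, v2)
            xi = float(rereference(com[2] - slab_com_z, surfaces, slab_com_z))
            records.append(OrientationRecord(frame=fi, v1=v1, v2=v2,
                                             theta=theta, s_v=s_v, xi=xi))
            rmsds.append(backbone_rmsd(coords, reference))
        if not records:
            raise ValueError("no frames produced orientation records")
        io.write_table(outdir / "orientation.tsv", {
            "frame": [r.frame for r in records],
            "xi": [r.xi for r in records],
            "theta": [r.theta for r in records],
            "s_v": [r.s_v for r in records],
            "rmsd": rmsds})
        blo, bhi, nb = cfg["orientation"]["xi_bins"]
        prof = orientation_profile(records, np.linspace(blo, bhi, int(nb)))
        io.write_table(outdir / "orientation_profile.tsv", {
            "xi": prof["bin_centers"], "s_v": prof["mean_s_v"],
            "ci_lower": prof["ci_lower"], "ci_upper": prof["ci_upper"],
            "n": prof["n"]})
        log["stages"]["orientation"].update({
            "mean_s_v": float(np.mean([r.s_v for r in records])),
            "mean_rmsd": float(np.mean(rmsds)),
            "n_records": len(records)})

    log["config"] = cfg
    with open(outdir / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=False)
    return log
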