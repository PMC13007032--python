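"""File I/O: extended XYZ, LAMMPS dump, window time series, tables.

The extended-XYZ dialect written here carries, per atom:
``species x y z mass charge molecule_id``; the comment line holds the
orthorhombic box as ``box=Lx,Ly,Lz``.  The LAMMPS-dump reader maps
columns by the ITEM: ATOMS header and supports x/y/z, scaled xs/ys/zs
(unscaled by the box) and unwrapped xu/yu/zu coordinate variants.
Window series are colvars-style whitespace-separated numeric columns
(step, ξ′) with ``#`` comments.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import Configuration, Trajectory


class ParseError(ValueError):
    """Malformed input file; message carries the file and line number."""


# ---------------------------------------------------------------- charges

def correct_net_charge(charges, target: float) -> np.ndarray:
    """Uniformly shift partial charges so they sum to ``target`` exactly.

    Fitted partial charges often miss the formal molecular charge by a
    rounding residue; a minimal uniform correction (the same shift on
    every atom) restores it.  The residual sum is computed with
    compensated (fsum) summation and the largest-magnitude entry absorbs
    the final floating-point remainder, so the corrected sum equals the
    target exactly.
    """
    q = np.asarray(charges, dtype=float).copy()
    if q.size == 0:
        raise ValueError("charge array is empty")
    shift = (target - math.fsum(q)) / q.size
    q += shift
    # Absorb the floating-point remainder into one entry, iterating because
    # the absorbing addition itself rounds; terminates in a few steps.
    i = int(np.argmax(np.abs(q)))
    for _ in range(10):
        residue = target - math.fsum(q)
        if residue == 0.0:
            break
        q[i] += residue
    return q


# ---------------------------------------------------------- window series

def write_window_series(path, steps, xi) -> None:
    """Write a two-column (step, ξ′) plain-text series, colvars style."""
    steps = np.asarray(steps)
    xi = np.asarray(xi, dtype=float)
    with open(path, "w") as fh:
        fh.write("# step xi_prime\n")
        for s, x in zip(steps, xi):
            fh.write(f"{int(s)} {x:.10g}\n")


def read_window_series(path, column: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Read (step, ξ′) pairs from a colvars-style text file.

    ``column`` selects which data column (0-based) holds ξ′; comment
    lines starting with ``#`` are skipped.
    """
    steps, values = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) <= column:
                raise ParseError(f"{path}:{lineno}: expected at least "
                                 f"{column + 1} columns, got {len(parts)}")
            try:
                steps.append(float(parts[0]))
                values.append(float(parts[column]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric value: {s!r}") from exc
    if not values:
        raise ParseError(f"{path}: no numeric rows")
    return np.asarray(steps), np.asarray(values)


# ----------------------------------------------------------- extended XYZ

def write_xyz(path, frames: list[Configuration] | Configuration) -> None:
    """Write one or more frames as extended XYZ (with mass/charge columns)."""
    if isinstance(frames, Configuration):
        frames = [frames]
    with open(path, "w") as fh:
        for fr in frames:
            fh.write(f"{fr.n_atoms}\n")
            bx = ",".join(f"{v:.10g}" for v in fr.box)
            fh.write(f"box={bx} columns=species:x:y:z:mass:charge:molecule\n")
            for i in range(fr.n_atoms):
                x, y, z = fr.positions[i]
                fh.write(f"{fr.species[i]} {x:.8f} {y:.8f} {z:.8f} "
                         f"{fr.masses[i]:.6f} {fr.charges[i]:.8f} "
                         f"{fr.molecule_ids[i]}\n")


def read_xyz(path) -> Trajectory:
    """Read an extended-XYZ trajectory written by :func:`write_xyz`."""
    frames: list[Configuration] = []
    with open(path) as fh:
        lines = fh.readlines()
    i, lineno = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"{path}:{i + 1}: expected atom count") from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        box = None
        for token in comment.split():
            if token.startswith("box="):
                box = np.array([float(v) for v in token[4:].split(",")])
        if box is None:
            raise ParseError(f"{path}:{i + 2}: comment line lacks box=Lx,Ly,Lz")
        if i + 2 + n > len(lines):
            raise ParseError(f"{path}: truncated frame {len(frames)} "
                             f"(needs {n} atoms, file ends early)")
        sp, pos, mass, chg, mol = [], [], [], [], []
        for j in range(n):
            lineno = i + 2 + j
            parts = lines[lineno].split()
            if len(parts) < 7:
                raise ParseError(f"{path}:{lineno + 1}: expected 7 columns")
            try:
                sp.append(parts[0])
                pos.append([float(parts[1]), float(parts[2]), float(parts[3])])
                mass.append(float(parts[4]))
                chg.append(float(parts[5]))
                mol.append(int(parts[6]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno + 1}: bad atom line") from exc
        frames.append(Configuration(
            positions=np.array(pos), species=np.array(sp),
            masses=np.array(mass), charges=np.array(chg),
            molecule_ids=np.array(mol), box=box,
        ))
        i += 2 + n
    if not frames:
        raise ParseError(f"{path}: no frames found")
    return Trajectory(frames=frames, source_format="xyz_extended")


# ------------------------------------------------------------ LAMMPS dump

def write_lammps_dump(path, frames: list[Configuration] | Configuration,
                      timesteps=None) -> None:
    """Write frames in LAMMPS dump format (id type x y z q mass mol)."""
    if isinstance(frames, Configuration):
        frames = [frames]
    if timesteps is None:
        timesteps = range(len(frames))
    with open(path, "w") as fh:
        for ts, fr in zip(timesteps, frames):
            type_map = {s: t + 1 for t, s in
                        enumerate(dict.fromkeys(fr.species.tolist()))}
            fh.write("ITEM: TIMESTEP\n")
            fh.write(f"{int(ts)}\n")
            fh.write("ITEM: NUMBER OF ATOMS\n")
            fh.write(f"{fr.n_atoms}\n")
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for L in fr.box:
                fh.write(f"0.0 {L:.10g}\n")
            fh.write("ITEM: ATOMS id type element x y z q mass mol\n")
            for i in range(fr.n_atoms):
                x, y, z = fr.positions[i]
                fh.write(f"{i + 1} {type_map[fr.species[i]]} {fr.species[i]} "
                         f"{x:.8f} {y:.8f} {z:.8f} {fr.charges[i]:.8f} "
                         f"{fr.masses[i]:.6f} {fr.molecule_ids[i] + 1}\n")


_COORD_VARIANTS = (("x", "y", "z"), ("xs", "ys", "zs"), ("xu", "yu", "zu"))


def read_lammps_dump(path, masses_by_type: dict | None = None) -> Trajectory:
    """Read a LAMMPS dump trajectory, mapping columns by header.

    Coordinates may be plain (x y z), scaled (xs ys zs, unscaled by the
    box) or unwrapped (xu yu zu).  When the dump lacks mass/element
    columns, ``masses_by_type`` supplies masses and type numbers become
    species labels.  Atoms are sorted by id; dump ids and mol ids are
    1-based, internal indices 0-based.
    """
    with open(path) as fh:
        lines = fh.readlines()
    frames: list[Configuration] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        if not lines[i].startswith("ITEM: TIMESTEP"):
            raise ParseError(f"{path}:{i + 1}: expected ITEM: TIMESTEP")
        try:
            n = int(lines[i + 3].strip())
            lo_hi = [lines[i + 5 + k].split()[:2] for k in range(3)]
            box = np.array([float(b) - float(a) for a, b in lo_hi])
            origin = np.array([float(a) for a, _ in lo_hi])
            header = lines[i + 8].split()
        except (IndexError, ValueError) as exc:
            raise ParseError(f"{path}:{i + 1}: malformed frame header") from exc
        if header[:2] != ["ITEM:", "ATOMS"]:
            raise ParseError(f"{path}:{i + 9}: expected ITEM: ATOMS")
        cols = {name: k for k, name in enumerate(header[2:])}
        coord_cols = next((v for v in _COORD_VARIANTS
                           if all(c in cols for c in v)), None)
        if coord_cols is None:
            raise ParseError(f"{path}:{i + 9}: no coordinate columns found")
        scaled = coord_cols[0] == "xs"
        if i + 9 + n > len(lines):
            raise ParseError(f"{path}: truncated frame {len(frames)}")
        rows = []
        for j in range(n):
            parts = lines[i + 9 + j].split()
            if len(parts) != len(cols):
                raise ParseError(f"{path}:{i + 10 + j}: expected "
                                 f"{len(cols)} columns, got {len(parts)}")
            rows.append(parts)
        get = lambda name, cast=float: np.array(  # noqa: E731
            [cast(r[cols[name]]) for r in rows])
        try:
            ids = get("id", int) if "id" in cols else np.arange(1, n + 1)
            pos = np.column_stack([get(c) for c in coord_cols])
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric atom data in frame "
                             f"{len(frames)}") from exc
        if scaled:
            pos = pos * box
        else:
            pos = pos - origin
        types = get("type", int) if "type" in cols else np.ones(n, dtype=int)
        if "element" in cols:
            species = np.array([r[cols["element"]] for r in rows])
        else:
            species = np.array([str(t) for t in types])
        if "mass" in cols:
            masses = get("mass")
        elif masses_by_type:
            masses = np.array([masses_by_type[t] for t in types])
        else:
            masses = np.ones(n)
        charges = get("q") if "q" in cols else np.zeros(n)
        mols = get("mol", int) - 1 if "mol" in cols else np.zeros(n, dtype=int)
        order = np.argsort(ids)
        frames.append(Configuration(
            positions=pos[order], species=species[order],
            masses=masses[order], charges=charges[order],
            molecule_ids=mols[order], box=box,
        ))
        i += 9 + n
    if not frames:
        raise ParseError(f"{path}: no frames found")
    return Trajectory(frames=frames, source_format="lammps_dump")


def read_trajectory(path, fmt: str | None = None, **kw) -> Trajectory:
    """Read a trajectory, inferring the format from content if not given."""
    path = Path(path)
    if fmt is None:
        with open(path) as fh:
            first = fh.readline()
        fmt = "lammps_dump" if first.startswith("ITEM:") else "xyz_extended"
    if fmt == "xyz_extended":
        return read_xyz(path)
    if fmt == "lammps_dump":
        return read_lammps_dump(path, **kw)
    raise ValueError(f"unknown trajectory format {fmt!r}")


# ------------------------------------------------------------ tables/YAML

def write_table(path, columns: dict) -> None:
    """Write named columns as a TSV table."""
    pd.DataFrame(columns).to_csv(path, sep="\t", index=False,
                                 float_format="%.10g", na_rep="nan")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_yaml(path, data: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
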