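"""Structure, trajectory and configuration I/O.

Structures are read and written as PDB or GRO and trajectories as XYZ
(plain text) or DCD (binary) through MDAnalysis; coordinates are converted
between the package's internal nm and the formats' native units at this
boundary.  Run configuration lives in a YAML file whose keys are validated
against a fixed schema (unknown keys are rejected by name), and every CLI
run emits a JSON manifest (config hash, seed, package versions) sufficient
to reproduce deterministic outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

import MDAnalysis as mda

from .engine import SystemFrame, Trajectory

NM_PER_ANGSTROM = 0.1

#: residue names mapped to species tags when reading structures
_SPECIES_BY_RESNAME = {
    "SOL": "solvent", "HOH": "solvent", "WAT": "solvent", "LJS": "solvent",
    "LIG": "ligand", "UNL": "ligand", "MOL": "ligand",
}


class ConfigError(ValueError):
    """Configuration file problem, naming the offending key."""


# ---------------------------------------------------------------------------
# structures


def _species_from_resnames(resnames: np.ndarray) -> np.ndarray:
    return np.array([_SPECIES_BY_RESNAME.get(r.upper(), "receptor")
                     for r in resnames], dtype="U8")


def read_structure(path: str | Path, fmt: Optional[str] = None):
    """Read a PDB or GRO structure into a SystemFrame plus an atom table.

    Coordinates are converted to nm.  The atom table (pandas DataFrame with
    name, resname, resid, species) carries the addressing needed to resolve
    site definitions such as ("VAL18", "CB").
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).upper()
    if fmt not in ("PDB", "GRO"):
        raise ValueError(f"unsupported structure format {fmt!r}")
    try:
        u = mda.Universe(str(path), format=fmt)
    except Exception as exc:
        raise ValueError(f"failed to parse {path} as {fmt}: {exc}") from exc
    atoms = u.atoms
    try:
        masses = atoms.masses.astype(float)
        if np.any(~np.isfinite(masses)) or np.all(masses == 0):
            raise ValueError
    except Exception:
        masses = np.full(len(atoms), 18.0)
    species = _species_from_resnames(atoms.resnames)
    box = u.dimensions[:3] * NM_PER_ANGSTROM if u.dimensions is not None and \
        np.all(u.dimensions[:3] > 0) else np.full(3, 100.0)
    frame = SystemFrame(
        positions=atoms.positions * NM_PER_ANGSTROM,
        velocities=np.zeros((len(atoms), 3)),
        masses=masses, species=species, box=np.asarray(box, dtype=float),
    )
    table = pd.DataFrame({
        "name": atoms.names, "resname": atoms.resnames,
        "resid": atoms.resids, "species": species,
    })
    return frame, table


def write_structure(frame: SystemFrame, path: str | Path,
                    atom_table: Optional[pd.DataFrame] = None) -> None:
    """Write a SystemFrame as PDB or GRO (decided by extension)."""
    path = Path(path)
    n = frame.n_particles
    u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n),
                           trajectory=True)
    if atom_table is not None:
        u.add_TopologyAttr("names", list(atom_table["name"]))
        u.add_TopologyAttr("resnames", list(atom_table["resname"]))
        if "resid" in atom_table:
            u.add_TopologyAttr("resids", list(atom_table["resid"]))
    else:
        u.add_TopologyAttr("names", [s[:1].upper() for s in frame.species])
        u.add_TopologyAttr("resnames",
                           ["LJS" if s == "solvent" else
                            "LIG" if s == "ligand" else "REC"
                            for s in frame.species])
    u.atoms.positions = frame.positions / NM_PER_ANGSTROM
    u.dimensions = np.array([*(frame.box / NM_PER_ANGSTROM), 90.0, 90.0, 90.0])
    u.atoms.write(str(path))


# ---------------------------------------------------------------------------
# trajectories


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write trajectory positions as XYZ (text) or DCD (binary), Å units."""
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower()
    if fmt not in ("xyz", "dcd"):
        raise ValueError(f"unsupported trajectory format {fmt!r}")
    n = traj.positions.shape[1]
    u = mda.Universe.empty(n, trajectory=True)
    u.add_TopologyAttr("names", ["X"] * n)
    dt_ps = float(traj.times[1] - traj.times[0]) if traj.n_frames > 1 else 1.0
    with mda.Writer(str(path), n_atoms=n, dt=dt_ps) as w:
        for i in range(traj.n_frames):
            u.atoms.positions = traj.positions[i] / NM_PER_ANGSTROM
            if traj.box is not None:
                u.dimensions = np.array([*(traj.box / NM_PER_ANGSTROM),
                                         90.0, 90.0, 90.0])
            w.write(u.atoms)


def read_trajectory(path: str | Path, stride: int = 1,
                    species: Optional[np.ndarray] = None,
                    masses: Optional[np.ndarray] = None,
                    box: Optional[np.ndarray] = None,
                    dt_ps: Optional[float] = None) -> Trajectory:
    """Read an XYZ or DCD trajectory into a Trajectory (nm / ps).

    Metadata a coordinate file cannot carry (species, masses, box) may be
    supplied explicitly; sensible defaults are used otherwise.  ``stride``
    keeps every stride-th frame.
    """
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower()
    if fmt == "xyz":
        reader = mda.coordinates.XYZ.XYZReader(str(path))
    elif fmt == "dcd":
        reader = mda.coordinates.DCD.DCDReader(str(path))
    else:
        raise ValueError(f"unsupported trajectory format {fmt!r}")
    positions, times = [], []
    with reader:
        for k, ts in enumerate(reader):
            if k % stride:
                continue
            positions.append(ts.positions.copy() * NM_PER_ANGSTROM)
            times.append(ts.time if dt_ps is None else k * dt_ps)
    positions = np.array(positions)
    if positions.size == 0:
        positions = positions.reshape(0, 0, 3)
    n = positions.shape[1] if len(positions) else 0
    return Trajectory(
        positions=positions,
        velocities=np.zeros_like(positions),
        times=np.asarray(times, dtype=float),
        steps=np.arange(len(positions)) * stride,
        masses=np.full(n, 18.0) if masses is None else np.asarray(masses, float),
        species=np.full(n, "solvent") if species is None else np.asarray(species),
        box=np.full(3, 100.0) if box is None else np.asarray(box, float),
    )


# ---------------------------------------------------------------------------
# configuration

_CONFIG_SCHEMA: dict = {
    "seed": int,
    "total_steps": int,
    "sample_stride": int,
    "engine": {
        "timestep": float, "temperature": float, "thermostat": str,
        "thermostat_tau": float, "lj_epsilon": float, "lj_sigma": float,
        "cutoff": float,
    },
    "system": {
        "n_particles": int, "box_edge": float, "mass": float,
    },
    "forcing": {
        "n_interval": int, "v_max_m_s": float, "t_int_multiplier": float,
        "cycles_per_wave": int, "pulses_per_cycle": int,
        "boundary_depth": float, "face_order": list,
    },
    "analysis": {
        "axis": str, "period_ps": float, "grid_points": int,
        "grid_spacing": float, "half_width": float, "threshold": float,
    },
    "sites": list,
    "outputs": {"trajectory": str, "energies": str, "summary": str},
}


def _validate(block: dict, schema: dict, prefix: str = "") -> None:
    for key, value in block.items():
        if key not in schema:
            raise ConfigError(f"unknown configuration key {prefix + key!r}")
        expected = schema[key]
        if isinstance(expected, dict):
            if not isinstance(value, dict):
                raise ConfigError(f"{prefix + key!r} must be a mapping")
            _validate(value, expected, prefix + key + ".")


def load_config(path: str | Path) -> dict:
    """Load and validate a YAML run configuration (unknown keys rejected)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("configuration root must be a mapping")
    _validate(cfg, _CONFIG_SCHEMA)
    return cfg


def dump_config(cfg: dict, path: str | Path) -> None:
    _validate(cfg, _CONFIG_SCHEMA)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# schedules and manifests


def write_schedule_table(schedule, path: str | Path) -> None:
    """Export a pulse schedule as a plain-text (step, face, increment) table."""
    df = pd.DataFrame([(ev.step, ev.face, ev.increment)
                       for ev in schedule.events],
                      columns=["step", "face", "increment"])
    df.to_csv(path, index=False)


def read_schedule_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_manifest(path: str | Path, config: dict, seed: Optional[int]) -> None:
    """Reproducibility manifest: config hash, seed, package versions."""
    import sklearn
    import scipy

    from . import __version__

    payload = {
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()).hexdigest(),
        "config": config,
        "seed": seed,
        "versions": {
            "sonomd": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "MDAnalysis": mda.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
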