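"""Minimal periodic Lennard-Jones solvent engine with a forcing hook.

The engine integrates a monatomic LJ fluid (optionally with tethered
"receptor" particles and freely diffusing "ligand" particles) with
velocity-Verlet, under Berendsen or stochastic velocity-rescaling (Bussi)
thermostats, and applies the hypersound pulse schedule between integration
and thermostatting.  It is a reduced stand-in for an explicit-water box:
forcing and all downstream analyses are fluid-agnostic.

Units: nm, ps, amu, K; energies in amu·nm²/ps² (= kJ/mol) internally,
converted to kcal/mol in the emitted energy trace.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .constants import INTERNAL_TO_KCAL, KB_INTERNAL, KJ_PER_KCAL
from .forcing import PulseSchedule, ShockWaveParams, apply_pulse, build_schedule, \
    select_boundary_solvent

SPECIES = ("solvent", "receptor", "ligand")


@dataclass
class SystemFrame:
    """State of the particle system at one instant."""

    positions: np.ndarray        # (n, 3) nm, wrapped into [0, box)
    velocities: np.ndarray       # (n, 3) nm/ps
    masses: np.ndarray           # (n,) amu
    species: np.ndarray          # (n,) str tags from SPECIES
    box: np.ndarray              # (3,) orthorhombic edges, nm
    time: float = 0.0            # ps
    step: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.species = np.asarray(self.species, dtype="U8")
        self.box = np.asarray(self.box, dtype=float)
        n = len(self.positions)
        if not (len(self.velocities) == len(self.masses) == len(self.species) == n):
            raise ValueError("positions, velocities, masses, species must be congruent")
        if np.any(self.box <= 0):
            raise ValueError("box edges must be positive")

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    def copy(self) -> "SystemFrame":
        return SystemFrame(self.positions.copy(), self.velocities.copy(),
                           self.masses.copy(), self.species.copy(),
                           self.box.copy(), self.time, self.step)

    def wrapped(self) -> "SystemFrame":
        out = self.copy()
        out.positions %= out.box
        return out

    def kinetic_energy(self) -> float:
        """Total kinetic energy, amu·nm²/ps² (= kJ/mol)."""
        return 0.5 * float(np.sum(self.masses * np.sum(self.velocities**2, axis=1)))

    def temperature(self) -> float:
        """Instantaneous kinetic temperature, K (3N degrees of freedom)."""
        return 2.0 * self.kinetic_energy() / (3 * self.n_particles * KB_INTERNAL)


@dataclass
class EngineConfig:
    """Integration, interaction and thermostat settings."""

    timestep: float = 0.002          # ps (2 fs)
    temperature: float = 298.0       # K
    thermostat: str = "velocity_rescale"   # berendsen | velocity_rescale | none
    thermostat_tau: float = 0.1      # ps
    lj_epsilon: float = 0.5          # kcal/mol
    lj_sigma: float = 0.5            # nm
    cutoff: float = 1.25             # nm
    seed: int = 0
    forcing: Optional[ShockWaveParams] = None
    receptor_tether_k: float = 1000.0  # kcal/mol/nm², harmonic tether on receptor

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.thermostat not in ("berendsen", "velocity_rescale", "none"):
            raise ValueError(f"unknown thermostat {self.thermostat!r}")
        if self.thermostat != "none" and self.thermostat_tau <= 0:
            raise ValueError("thermostat_tau must be positive when thermostat active")


@dataclass
class Trajectory:
    """Frames sampled at a fixed stride, plus times and steps."""

    positions: np.ndarray            # (T, n, 3)
    velocities: np.ndarray           # (T, n, 3)
    times: np.ndarray                # (T,) ps
    steps: np.ndarray                # (T,)
    masses: np.ndarray = None
    species: np.ndarray = None
    box: np.ndarray = None

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def frame(self, i: int) -> SystemFrame:
        return SystemFrame(self.positions[i].copy(), self.velocities[i].copy(),
                           self.masses.copy(), self.species.copy(), self.box.copy(),
                           float(self.times[i]), int(self.steps[i]))


# ---------------------------------------------------------------------------
# forces


def _pair_lists(positions: np.ndarray, box: np.ndarray, cutoff: float):
    """Pairs within cutoff under periodic boundaries.

    Brute-force O(n²) below 500 particles, periodic KD-tree above.
    """
    n = len(positions)
    if n < 500:
        ii, jj = np.triu_indices(n, k=1)
        d = positions[ii] - positions[jj]
        d -= box * np.round(d / box)
        r2 = np.sum(d * d, axis=1)
        keep = r2 < cutoff * cutoff
        return ii[keep], jj[keep], d[keep], r2[keep]
    tree = cKDTree(positions, boxsize=box)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    ii, jj = pairs[:, 0], pairs[:, 1]
    d = positions[ii] - positions[jj]
    d -= box * np.round(d / box)
    r2 = np.sum(d * d, axis=1)
    keep = r2 < cutoff * cutoff
    return ii[keep], jj[keep], d[keep], r2[keep]


def lj_forces(frame: SystemFrame, config: EngineConfig):
    """12-6 Lennard-Jones forces and potential energy.

    The potential is shifted so U(cutoff) = 0; forces are the exact negative
    gradient of the returned (shifted) energy.  Energies in amu·nm²/ps².
    Receptor particles are harmonically tethered to their wrapped positions'
    lattice sites only through `run_simulation`; this function is pure LJ.
    """
    eps = config.lj_epsilon * KJ_PER_KCAL    # to internal units
    sig = config.lj_sigma
    rc = config.cutoff
    if rc >= float(np.min(frame.box)) / 2:
        raise ValueError("cutoff must be below half the smallest box edge")
    pos = frame.positions % frame.box
    ii, jj, d, r2 = _pair_lists(pos, frame.box, rc)
    forces = np.zeros_like(frame.positions)
    if len(ii) == 0:
        return forces, 0.0
    if np.any(r2 < 1e-12):
        raise FloatingPointError(
            f"overlapping particles (r < 1e-6 nm) in pairs {np.nonzero(r2 < 1e-12)[0][:5]}"
        )
    inv_r2 = sig * sig / r2
    inv_r6 = inv_r2**3
    inv_r12 = inv_r6**2
    u_shift = 4.0 * eps * ((sig / rc) ** 12 - (sig / rc) ** 6)
    energy = float(np.sum(4.0 * eps * (inv_r12 - inv_r6) - u_shift))
    # f_ij = 24 eps (2 (sig/r)^12 - (sig/r)^6) / r^2 * d
    fmag = 24.0 * eps * (2.0 * inv_r12 - inv_r6) / r2
    fv = fmag[:, None] * d
    np.add.at(forces, ii, fv)
    np.add.at(forces, jj, -fv)
    return forces, energy


def _tether_forces(frame: SystemFrame, anchors: np.ndarray, k_internal: float):
    """Harmonic restraints pinning receptor particles near fixed anchor points."""
    forces = np.zeros_like(frame.positions)
    idx = np.nonzero(frame.species == "receptor")[0]
    if len(idx) == 0 or k_internal == 0:
        return forces, 0.0
    d = frame.positions[idx] - anchors
    d -= frame.box * np.round(d / frame.box)
    forces[idx] = -k_internal * d
    return forces, 0.5 * k_internal * float(np.sum(d * d))


# ---------------------------------------------------------------------------
# integration and thermostats


def velocity_verlet_step(frame: SystemFrame, forces: np.ndarray,
                         config: EngineConfig,
                         force_fn: Callable[[SystemFrame], tuple]):
    """One velocity-Verlet update; returns (new frame, new forces, potential)."""
    if not (np.all(np.isfinite(frame.positions)) and np.all(np.isfinite(frame.velocities))):
        raise FloatingPointError("non-finite state entering integrator")
    dt = config.timestep
    inv_m = 1.0 / frame.masses[:, None]
    out = frame.copy()
    half_v = frame.velocities + 0.5 * dt * forces * inv_m
    out.positions = (frame.positions + dt * half_v) % frame.box
    new_forces, potential = force_fn(out)
    out.velocities = half_v + 0.5 * dt * new_forces * inv_m
    out.time = frame.time + dt
    out.step = frame.step + 1
    if not np.all(np.isfinite(out.positions)):
        raise FloatingPointError("non-finite coordinates after integration step")
    return out, new_forces, potential


def thermostat_scale(frame: SystemFrame, config: EngineConfig,
                     rng: Optional[np.random.Generator] = None) -> SystemFrame:
    """Rescale velocities toward the target temperature.

    Berendsen: λ = sqrt(1 + (dt/τ)(T₀/T − 1)), deterministic weak coupling.
    velocity_rescale: Bussi stochastic velocity rescaling — the kinetic
    energy relaxes toward the canonical distribution with time constant τ;
    requires a seeded Generator.
    """
    if config.thermostat == "none":
        return frame
    kin = frame.kinetic_energy()
    if kin <= 0.0:
        return frame  # λ undefined; skip scaling
    n_dof = 3 * frame.n_particles
    target_kin = 0.5 * n_dof * KB_INTERNAL * config.temperature
    c = np.exp(-config.timestep / config.thermostat_tau)
    if config.thermostat == "berendsen":
        t_inst = 2.0 * kin / (n_dof * KB_INTERNAL)
        lam2 = 1.0 + (config.timestep / config.thermostat_tau) * (
            config.temperature / t_inst - 1.0)
        lam = np.sqrt(max(lam2, 0.0))
    else:
        if rng is None:
            raise ValueError("velocity_rescale thermostat needs a random generator")
        r1 = rng.standard_normal()
        sum_sq = rng.chisquare(n_dof - 1) if n_dof > 1 else 0.0
        new_kin = (kin
                   + (1.0 - c) * (target_kin * (r1 * r1 + sum_sq) / n_dof - kin)
                   + 2.0 * r1 * np.sqrt(kin * target_kin * (1.0 - c) * c / n_dof))
        lam = np.sqrt(max(new_kin, 0.0) / kin)
    out = frame.copy()
    out.velocities *= lam
    return out


# ---------------------------------------------------------------------------
# orchestration


def run_simulation(initial: SystemFrame, config: EngineConfig, total_steps: int,
                   sample_stride: int = 10,
                   energy_stride: Optional[int] = None) -> tuple[Trajectory, pd.DataFrame]:
    """Integrate ``total_steps`` steps; return sampled trajectory + energy trace.

    Per step: forces → velocity-Verlet → scheduled pulses (if any) →
    thermostat.  The pulse selection is recomputed from current positions at
    every pulse step.  Runs are reproducible from (config.seed, initial).

    ``energy_stride`` defaults to the forcing pulse interval N (or
    ``sample_stride`` without forcing) so barrier analyses see uniform
    sampling. Energy columns are kcal/mol.
    """
    rng = np.random.default_rng(config.seed)
    schedule: Optional[PulseSchedule] = None
    if config.forcing is not None:
        schedule = build_schedule(config.forcing, total_steps + 1)
    if energy_stride is None:
        energy_stride = config.forcing.n_interval if config.forcing else sample_stride

    frame = initial.wrapped()
    step_offset = frame.step          # schedule is relative to the run start
    anchors = frame.positions[frame.species == "receptor"].copy()
    k_tether = config.receptor_tether_k * KJ_PER_KCAL

    def force_fn(fr: SystemFrame):
        f, u = lj_forces(fr, config)
        ft, ut = _tether_forces(fr, anchors, k_tether)
        return f + ft, u + ut

    forces, potential = force_fn(frame)

    pos_out, vel_out, t_out, s_out = [], [], [], []
    erows = []

    def sample(fr: SystemFrame, pot: float) -> None:
        if fr.step % sample_stride == 0:
            pos_out.append(fr.positions.copy())
            vel_out.append(fr.velocities.copy())
            t_out.append(fr.time)
            s_out.append(fr.step)
        if fr.step % energy_stride == 0:
            kin = fr.kinetic_energy()
            erows.append((fr.step, fr.time, kin * INTERNAL_TO_KCAL,
                          pot * INTERNAL_TO_KCAL, fr.temperature()))

    sample(frame, potential)
    for _ in range(total_steps):
        frame, forces, potential = velocity_verlet_step(frame, forces, config, force_fn)
        if schedule is not None:
            for ev in schedule.events_at(frame.step - step_offset):
                sel = select_boundary_solvent(frame, ev.face,
                                              config.forcing.boundary_depth)
                frame = apply_pulse(frame, ev.face, ev.increment, sel)
        frame = thermostat_scale(frame, config, rng)
        sample(frame, potential)

    traj = Trajectory(
        positions=np.array(pos_out), velocities=np.array(vel_out),
        times=np.array(t_out), steps=np.array(s_out),
        masses=frame.masses.copy(), species=frame.species.copy(), box=frame.box.copy(),
    )
    energies = pd.DataFrame(
        erows, columns=["step", "time_ps", "kinetic", "potential", "temperature"])
    return traj, energies
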