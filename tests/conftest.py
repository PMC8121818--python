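"""Shared fixtures.

The expensive forced-wave simulation is session-scoped: one elongated-box
LJ run drives a hypersound wave packet from the X0 face and is reused by
the engine tests and the acceptance checks.
"""

import numpy as np
import pytest

import sonomd as smd
from sonomd.constants import KB_INTERNAL
from sonomd.engine import EngineConfig, SystemFrame, run_simulation
from sonomd.wavefield import WaveProfile


def make_elongated_box(box, n, temperature, seed, lattice=(18, 6, 6)):
    """Lattice-filled LJ fluid in an orthorhombic box."""
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    nx, ny, nz = lattice
    gx, gy, gz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    lat = (np.stack([gx, gy, gz], -1).reshape(-1, 3) + 0.5) * \
        (box / np.array(lattice))
    pos = (lat[:n] + rng.normal(0, 0.02, (n, 3))) % box
    sv = np.sqrt(KB_INTERNAL * temperature / 18.0)
    vel = rng.normal(0, sv, (n, 3))
    vel -= vel.mean(axis=0)
    return SystemFrame(pos, vel, np.full(n, 18.0), np.full(n, "solvent"), box)


@pytest.fixture(scope="session")
def forced_wave_run():
    """Equilibrated 534-particle LJ fluid in a 9x3x3 nm box, hit by a
    3-cycle hypersound wave packet from the X0 face, then left to recover
    under a Berendsen thermostat for 4 ps.

    Returns a dict with the equilibrium profile statistics, the
    block-averaged density profiles during the wave passage, and the energy
    trace of the forced run.
    """
    box = np.array([9.0, 3.0, 3.0])
    n = 534
    frame = make_elongated_box(box, n, 298.0, seed=11)
    eq_cfg = EngineConfig(thermostat="berendsen", thermostat_tau=0.05, seed=11)
    traj_eq, _ = run_simulation(frame, eq_cfg, 1500, sample_stride=25)
    eq_frame = traj_eq.frame(traj_eq.n_frames - 1)

    grid = np.arange(1.2, 4.8, 0.15)
    half_width = 0.3
    eq_profiles = np.array([
        smd.density_profile(traj_eq.frame(i), "X", grid, half_width).density
        for i in range(20, traj_eq.n_frames)])
    nb = (len(eq_profiles) // 4) * 4
    sigma_eq = eq_profiles[:nb].reshape(-1, 4, len(grid)).mean(axis=1).std()

    params = smd.ShockWaveParams(n_interval=20, v_max=0.8, t_int=2000,
                                 cycles_per_wave=2, boundary_depth=1.0,
                                 face_order=("X0",))
    cfg = EngineConfig(thermostat="berendsen", thermostat_tau=0.1, seed=12,
                       forcing=params)
    total = params.wave_steps + params.t_int
    traj, energies = run_simulation(eq_frame, cfg, total, sample_stride=10)

    profiles = []
    for b in range(0, traj.n_frames - 3, 4):
        idx = list(range(b, b + 4))
        dens = np.mean([smd.density_profile(traj.frame(i), "X", grid,
                                            half_width).density
                        for i in idx], axis=0)
        profiles.append(WaveProfile(
            "X", grid, half_width, dens, np.full(len(grid), np.nan),
            float(np.mean(traj.times[idx]) - traj.times[0])))
    return {
        "n": n, "box": box, "grid": grid, "half_width": half_width,
        "bulk_density": n * 18.0 / float(np.prod(box)),
        "sigma_eq": float(sigma_eq),
        "profiles": profiles,
        "trajectory": traj,
        "energies": energies,
        "total_steps": total,
        "target_temperature": 298.0,
        "params": params,
    }
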