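"""Synthetic test-input generators with known ground truth.

Every generator is deterministic under a fixed seed and returns, alongside
the data, a manifest dict recording the planted truths (rates, speeds,
cluster labels, barrier heights, diffusion constants) so analysis tests
never infer ground truth from the data themselves.  The generators emulate
the *shape* of the real inputs — a solvated box, binding trajectories at a
known rate, a translating density pulse, clustered pose scores, an energy
trace with a transition barrier — not the chemistry of any particular
protein–ligand system.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .constants import CM2_S_PER_NM2_PS, KB_INTERNAL
from .engine import SystemFrame, Trajectory
from .wavefield import WaveProfile


def build_lj_box(n: int, box_edge: float, temperature: float, seed: int,
                 mass: float = 18.0, jitter: float = 0.05) -> SystemFrame:
    """Lattice-perturbed LJ solvent box with Maxwell–Boltzmann velocities.

    Particles sit on a cubic lattice with Gaussian positional jitter;
    velocities are drawn at the requested temperature with the net momentum
    removed (then rescaled back to the exact target kinetic energy).
    """
    rng = np.random.default_rng(seed)
    per_side = math.ceil(n ** (1 / 3))
    if per_side**3 < n:
        per_side += 1
    spacing = box_edge / per_side
    if spacing < 0.1:
        raise ValueError("density too high: lattice spacing below 0.1 nm")
    idx = np.arange(per_side)
    gx, gy, gz = np.meshgrid(idx, idx, idx, indexing="ij")
    lattice = (np.stack([gx, gy, gz], axis=-1).reshape(-1, 3) + 0.5) * spacing
    positions = lattice[:n] + rng.normal(0.0, jitter * spacing, size=(n, 3))
    positions %= box_edge
    if temperature > 0:
        sigma_v = math.sqrt(KB_INTERNAL * temperature / mass)
        velocities = rng.normal(0.0, sigma_v, size=(n, 3))
        velocities -= velocities.mean(axis=0)
        target = 1.5 * n * KB_INTERNAL * temperature
        kin = 0.5 * mass * float(np.sum(velocities**2))
        if kin > 0:
            velocities *= math.sqrt(target / kin)
    else:
        velocities = np.zeros((n, 3))
    return SystemFrame(positions=positions, velocities=velocities,
                       masses=np.full(n, mass), species=np.full(n, "solvent"),
                       box=np.full(3, float(box_edge)))


def toy_receptor(box_edge: float, pocket_center: Optional[np.ndarray] = None,
                 anchor_spread: float = 0.4):
    """Three fixed anchor particles defining one binding pocket.

    Returns (anchor positions (3,3) nm, pocket center (3,)).  The pocket
    center sits midway between the anchors; a ligand pinned there satisfies
    the two-anchor contact criterion at the 0.5 nm cutoff.
    """
    if pocket_center is None:
        pocket_center = np.full(3, box_edge / 2.0)
    pocket_center = np.asarray(pocket_center, dtype=float)
    offsets = np.array([[1.0, 0.0, 0.0],
                        [-0.5, math.sqrt(3) / 2, 0.0],
                        [-0.5, -math.sqrt(3) / 2, 0.0]]) * anchor_spread
    return pocket_center + offsets, pocket_center


def brownian_binding_trajectories(n_runs: int, duration_ns: float,
                                  rate_per_s: float, d_cm2_s: float,
                                  box_edge: float, seed: int,
                                  frame_dt_ns: float = 0.5,
                                  coordinates: bool = True):
    """Overdamped random-walk ligands with Poisson-planted binding events.

    Each run holds one ligand diffusing with the planted diffusion constant;
    a binding event fires after an exponential waiting time with the planted
    rate, after which the ligand is pinned at the pocket center (satisfying
    the two-anchor contact criterion for the bundled toy receptor).  The
    manifest records the true event time of every run and the true binding
    probability 1 − exp(−rate·t).

    Returns (list of Trajectory | None, manifest).  With
    ``coordinates=False`` only the manifest is produced (cheap rate-recovery
    studies).
    """
    if rate_per_s * duration_ns * 1e-9 >= 1.0:
        raise ValueError("rate·duration must be below 1 (rare-event regime)")
    rng = np.random.default_rng(seed)
    anchors, pocket = toy_receptor(box_edge)
    d_nm2_ns = d_cm2_s / CM2_S_PER_NM2_PS * 1e3      # cm²/s → nm²/ns
    n_frames = int(round(duration_ns / frame_dt_ns)) + 1
    times_ns = np.arange(n_frames) * frame_dt_ns
    if rate_per_s > 0:
        event_times = rng.exponential(1.0 / rate_per_s, n_runs) * 1e9   # ns
    else:
        event_times = np.full(n_runs, np.inf)
    trajectories = []
    step_sd = math.sqrt(2.0 * d_nm2_ns * frame_dt_ns)
    for run in range(n_runs):
        if not coordinates:
            trajectories.append(None)
            continue
        start = rng.uniform(0, box_edge, 3)
        steps = rng.normal(0.0, step_sd, size=(n_frames, 3))
        steps[0] = 0.0
        path = start + np.cumsum(steps, axis=0)       # unwrapped coordinates
        bound = times_ns >= event_times[run]
        path[bound] = pocket
        n_lig = 1
        positions = np.concatenate(
            [np.broadcast_to(anchors, (n_frames, 3, 3)), path[:, None, :]], axis=1)
        species = np.array(["receptor"] * 3 + ["ligand"] * n_lig)
        trajectories.append(Trajectory(
            positions=positions,
            velocities=np.zeros_like(positions),
            times=times_ns * 1e3,          # ps
            steps=np.arange(n_frames),
            masses=np.full(4, 100.0),
            species=species,
            box=np.full(3, float(box_edge)),
        ))
    manifest = {
        "rate_per_s": rate_per_s,
        "duration_ns": duration_ns,
        "d_cm2_s": d_cm2_s,
        "event_times_ns": event_times.tolist(),
        "n_bound": int(np.sum(event_times <= duration_ns)),
        "n_runs": n_runs,
        "p_bind_true": float(1.0 - math.exp(-rate_per_s * duration_ns * 1e-9)),
        "pocket_center": pocket.tolist(),
        "anchors": anchors.tolist(),
        "seed": seed,
    }
    return trajectories, manifest


def moving_pulse_profiles(speed_m_s: float, times_ps: np.ndarray,
                          box_edge: float = 8.5, amplitude: float = 0.5,
                          bulk_density: float = 600.0, width: float = 0.5,
                          start_nm: float = 0.5,
                          grid: Optional[np.ndarray] = None):
    """Gaussian density bump translating at a planted speed.

    Produces one WaveProfile per requested time over a flat background of
    ``bulk_density`` (amu/nm³); the bump peak is bulk·(1+amplitude).  The
    manifest records the planted speed and the bump center at each time.
    """
    from .wavefield import default_grid
    if grid is None:
        grid = default_grid()
    speed_nm_ps = speed_m_s * 1e-3
    profiles, centers = [], []
    for t in np.asarray(times_ps, dtype=float):
        center = start_nm + speed_nm_ps * t
        centers.append(center)
        density = bulk_density * (1.0 + amplitude *
                                  np.exp(-0.5 * ((grid - center) / width) ** 2))
        profiles.append(WaveProfile(axis="X", grid=np.asarray(grid, float),
                                    half_width=0.2, density=density,
                                    k_dir=np.full(len(grid), np.nan), time=float(t)))
    manifest = {"speed_m_s": speed_m_s, "centers_nm": centers,
                "bulk_density": bulk_density, "amplitude": amplitude}
    return profiles, manifest


def planted_clusters(k: int, points_per_cluster: int, separation: float,
                     seed: int, n_dim: int = 3, sigma: float = 1.0):
    """Isotropic Gaussian blobs at scaled simplex vertices.

    ``separation`` is the center-to-center distance in units of ``sigma``.
    Returns (points, labels, manifest with the true centers).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    centers = np.zeros((k, n_dim))
    if k > 1:
        raw = rng.normal(size=(k, n_dim))
        raw -= raw.mean(axis=0)
        # orthonormalize a spread of directions, then scale to the separation
        q, _ = np.linalg.qr(raw.T)
        dirs = q.T[:k] if k <= n_dim else _simplex_directions(k, n_dim, rng)
        centers = dirs * separation * sigma / math.sqrt(2.0)
    points = np.concatenate([
        centers[j] + rng.normal(0.0, sigma, size=(points_per_cluster, n_dim))
        for j in range(k)])
    labels = np.repeat(np.arange(k), points_per_cluster)
    manifest = {"k": k, "centers": centers.tolist(), "sigma": sigma,
                "separation": separation, "seed": seed}
    return points, labels, manifest


def _simplex_directions(k: int, n_dim: int, rng: np.random.Generator) -> np.ndarray:
    """k well-spread unit directions when k exceeds the dimensionality."""
    dirs = rng.normal(size=(k, n_dim))
    for _ in range(200):      # crude repulsion relaxation
        g = dirs @ dirs.T
        np.fill_diagonal(g, 0.0)
        dirs -= 0.05 * g @ dirs
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return dirs


def barrier_trace(baseline: float, height: float, noise_sd: float,
                  contact_time: float, binding_time: float, seed: int,
                  t_end: Optional[float] = None, dt: float = 0.1):
    """Flat energy baseline with a Gaussian transition bump of planted height.

    The bump peaks midway between ``contact_time`` and ``binding_time``;
    i.i.d. Gaussian noise of ``noise_sd`` is added.  Returns
    (times, energies, manifest).
    """
    if height < 0:
        raise ValueError("height must be >= 0")
    rng = np.random.default_rng(seed)
    if t_end is None:
        t_end = binding_time + (binding_time - contact_time)
    times = np.arange(0.0, t_end + dt / 2, dt)
    peak = 0.5 * (contact_time + binding_time)
    width = max((binding_time - contact_time) / 6.0, dt)
    energy = baseline + height * np.exp(-0.5 * ((times - peak) / width) ** 2)
    energy += rng.normal(0.0, noise_sd, size=len(times))
    manifest = {"baseline": baseline, "height": height, "noise_sd": noise_sd,
                "contact_time": contact_time, "binding_time": binding_time,
                "peak_time": peak, "seed": seed}
    return times, energy, manifest
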