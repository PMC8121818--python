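"""Shock-wave characterization from trajectories.

Implements the slab observables used to demonstrate wave generation in a
perturbed solvent box: mass-density profiles on a fixed grid of plane
positions, the directional kinetic energy k_x (per-molecule mean of
½·M·v_x², which equals RT/2 at equilibrium), the instantaneous temperature
of a slab, the momentum-flux pressure with a van-der-Waals-style attraction
correction

    P = (2m / S·Δt) Σ_i v_x^i  −  a · (1/V_m)²

(the sum running over molecules that cross the YZ plane in the +x direction
during Δt; a in atm·L²·mol⁻², V_m in L/mol), wavefront tracking giving the
propagation speed, the speed × period wavelength, and MSD diffusion
constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import (CM2_S_PER_NM2_PS, INTERNAL_TO_KCAL, KG_PER_AMU,
                        M_S_PER_NM_PS, PA_PER_ATM, R_KCAL)
from .engine import SystemFrame, Trajectory

AXES = {"X": 0, "Y": 1, "Z": 2}


def default_grid(n_points: int = 82, spacing: float = 0.1,
                 start: float = 0.05) -> np.ndarray:
    """Default profile grid: 82 plane positions 0.1 nm apart from 0.05 nm."""
    return start + spacing * np.arange(n_points)


@dataclass
class WaveProfile:
    """Density and directional kinetic energy sampled on plane positions."""

    axis: str
    grid: np.ndarray                 # nm, strictly increasing
    half_width: float                # slab half-thickness, nm
    density: np.ndarray              # amu/nm³ per grid point
    k_dir: np.ndarray                # kcal/mol per grid point (NaN if empty slab)
    time: float = 0.0                # ps

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")


@dataclass
class PressureEstimate:
    """Momentum-flux pressure at one plane over one observation window."""

    plane_x: float       # nm
    delta_t: float       # ps
    term1: float         # Pa, flux term
    a: float             # atm·L²·mol⁻²
    v_m: float           # L/mol
    pressure: float      # Pa


@dataclass
class WavefrontTrack:
    """Wavefront plane crossings and the fitted propagation speed."""

    crossings: list = field(default_factory=list)   # (position nm, time ps)
    speed: Optional[float] = None                   # m/s
    wavelength: Optional[float] = None              # nm


def _slab_mask(coord: np.ndarray, center: float, half_width: float,
               edge: float) -> np.ndarray:
    """Membership in a periodic slab of ±half_width around center."""
    d = np.abs(coord - center)
    d = np.minimum(d, edge - d)   # periodic wrap
    return d <= half_width


def density_profile(frame: SystemFrame, axis: str = "X",
                    grid: Optional[np.ndarray] = None,
                    half_width: float = 0.2) -> WaveProfile:
    """Mass density in slabs of ±half_width around each grid plane.

    Slabs that straddle a periodic boundary wrap around it. Units amu/nm³.
    """
    ax = AXES[axis]
    if grid is None:
        grid = default_grid()
    coord = frame.positions[:, ax] % frame.box[ax]
    cross_section = float(np.prod(np.delete(frame.box, ax)))
    slab_volume = 2.0 * half_width * cross_section
    dens = np.empty(len(grid))
    kdir = np.full(len(grid), np.nan)
    v2 = frame.velocities[:, ax] ** 2
    for g, center in enumerate(grid):
        m = _slab_mask(coord, center, half_width, frame.box[ax])
        dens[g] = float(np.sum(frame.masses[m])) / slab_volume
        if np.any(m):
            kdir[g] = 0.5 * float(np.mean(frame.masses[m] * v2[m])) * INTERNAL_TO_KCAL
    return WaveProfile(axis=axis, grid=np.asarray(grid, dtype=float),
                       half_width=half_width, density=dens, k_dir=kdir,
                       time=frame.time)


def directional_kinetic_energy(frame: SystemFrame, axis: str = "X",
                               grid: Optional[np.ndarray] = None,
                               half_width: float = 0.2) -> np.ndarray:
    """Slab mean of ½·M·v_axis² in kcal/mol (NaN where the slab is empty).

    At equilibrium this is RT/2 per slab (≈0.298 kcal/mol at 300 K).
    """
    return density_profile(frame, axis, grid, half_width).k_dir


def instantaneous_temperature(k_dir: float | np.ndarray) -> float | np.ndarray:
    """Temperature of one translational degree of freedom: T = 2·k/R (k in kcal/mol)."""
    return 2.0 * np.asarray(k_dir, dtype=float) / R_KCAL if np.ndim(k_dir) \
        else 2.0 * float(k_dir) / R_KCAL


def calibrate_attraction_constant(term1_pa: float, p_ref_pa: float,
                                  v_m: float) -> float:
    """Attraction constant a (atm·L²·mol⁻²) from a reference pressure.

    Solves term1 − a·(1/V_m)² = P_ref for a, with pressures in Pa converted
    to atm.  The reference is typically the saturated vapor pressure of the
    solvent at the simulation temperature.
    """
    if v_m <= 0:
        raise ValueError("molar volume must be positive")
    if term1_pa < p_ref_pa:
        raise ValueError("flux term must be at least the reference pressure")
    return (term1_pa - p_ref_pa) / PA_PER_ATM * v_m * v_m


def flux_pressure(trajectory: Trajectory, plane_x: float, delta_t: float,
                  a: float, v_m: float, axis: str = "X",
                  t_start: float = 0.0) -> PressureEstimate:
    """Momentum-flux pressure at a plane over the window [t_start, t_start+Δt].

    Molecules crossing the plane in the +axis direction between consecutive
    frames contribute their +axis velocity to the flux term; the attraction
    correction a·(1/V_m)² is subtracted.  Sampling must be fine enough that
    no molecule crosses the plane twice between frames.
    """
    ax = AXES[axis]
    sel = (trajectory.times >= t_start - 1e-12) & \
          (trajectory.times <= t_start + delta_t + 1e-12)
    idx = np.nonzero(sel)[0]
    if len(idx) < 2:
        raise ValueError("observation window must span at least 2 frames")
    edge = float(trajectory.box[ax])
    plane = plane_x % edge
    vx_sum = 0.0  # nm/ps, over +axis crossers
    for k in range(len(idx) - 1):
        x0 = trajectory.positions[idx[k], :, ax] % edge
        x1 = trajectory.positions[idx[k + 1], :, ax] % edge
        d = x1 - x0
        d -= edge * np.round(d / edge)        # minimum-image displacement
        u = (plane - x0) % edge               # forward distance to the plane
        crossed_up = (d > 0) & (u > 0) & (u <= d)
        if np.any(crossed_up):
            vx_sum += float(np.sum(trajectory.velocities[idx[k + 1], crossed_up, ax]))
    mass = float(np.mean(trajectory.masses)) * KG_PER_AMU          # kg
    cross_section = float(np.prod(np.delete(trajectory.box, ax))) * 1e-18  # m²
    dt_s = delta_t * 1e-12
    term1 = 2.0 * mass / (cross_section * dt_s) * vx_sum * M_S_PER_NM_PS
    correction = a / (v_m * v_m) * PA_PER_ATM
    return PressureEstimate(plane_x=plane_x, delta_t=delta_t, term1=term1,
                            a=a, v_m=v_m, pressure=term1 - correction)


def track_wavefront(profiles: Sequence[WaveProfile], bulk_density: float,
                    threshold: float = 0.2,
                    period_ps: Optional[float] = None) -> WavefrontTrack:
    """Locate the wavefront in each profile and fit the propagation speed.

    The front position at each time is the largest grid position whose
    density exceeds bulk·(1+threshold), scanning from the source face at
    grid start.  Speed is the least-squares slope of position vs time in
    m/s (the finite difference when exactly two crossings exist).  If
    ``period_ps`` is given, the wavelength speed × period is attached.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profile snapshots")
    track = WavefrontTrack()
    level = bulk_density * (1.0 + threshold)
    for p in profiles:
        above = np.nonzero(p.density > level)[0]
        if len(above) == 0:
            continue
        # scan from the source face: the front is the far end of the
        # contiguous excess-density region nearest the source, which keeps
        # isolated noise spikes ahead of the wave from being mistaken for it
        end = above[0]
        for idx in above[1:]:
            if idx == end + 1:
                end = idx
            else:
                break
        track.crossings.append((float(p.grid[end]), float(p.time)))
    if len(track.crossings) >= 2:
        x = np.array([c[0] for c in track.crossings])
        t = np.array([c[1] for c in track.crossings])
        if np.ptp(t) > 0:
            slope = float(np.polyfit(t, x, 1)[0])       # nm/ps
            track.speed = slope * M_S_PER_NM_PS
            if period_ps is not None and track.speed > 0:
                track.wavelength = wavelength(track.speed, period_ps)
    return track


def wavelength(speed_m_s: float, period_ps: float) -> float:
    """λ = speed × period, in nm (2000 m/s × 1.6 ps = 3.2 nm)."""
    if speed_m_s < 0 or period_ps < 0:
        raise ValueError("speed and period must be non-negative")
    return speed_m_s / M_S_PER_NM_PS * period_ps


def msd_diffusion(trajectories: Sequence[Trajectory], species: str = "ligand",
                  fit_start: float = 0.0, fit_end: Optional[float] = None
                  ) -> tuple[float, float]:
    """Diffusion constant from the MSD slope, cm²/s, mean ± SD over replicas.

    Each replica's trajectory must carry unwrapped (periodicity-corrected)
    coordinates.  Per replica the MSD is averaged over the selected
    molecules, fitted by least squares on [fit_start, fit_end], and
    D = slope/6; the mean and sample SD across replicas are returned
    (SD 0.0 for a single replica).
    """
    d_vals = []
    for traj in trajectories:
        mask = traj.species == species
        if not np.any(mask):
            raise ValueError(f"no particles of species {species!r}")
        t = traj.times - traj.times[0]
        end = fit_end if fit_end is not None else float(t[-1])
        sel = (t >= fit_start) & (t <= end)
        if np.count_nonzero(sel) < 2:
            raise ValueError("fit window must contain at least 2 time points")
        disp = traj.positions[:, mask, :] - traj.positions[0, mask, :]
        msd = np.mean(np.sum(disp**2, axis=2), axis=1)   # nm²
        slope = float(np.polyfit(t[sel], msd[sel], 1)[0])  # nm²/ps
        d_vals.append(slope / 6.0 * CM2_S_PER_NM2_PS)
    d_vals = np.array(d_vals)
    sd = float(np.std(d_vals, ddof=1)) if len(d_vals) > 1 else 0.0
    return float(np.mean(d_vals)), sd
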