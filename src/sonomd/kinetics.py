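"""Kinetic-parameter estimation for protein–ligand association.

Under the pseudo-first-order approximation the bound fraction after time t
is [PL]/[P]0 = k_on·[L]0·t, so an association rate constant follows directly
from counting stable-binding runs.  The chain continues through the
Arrhenius relation k_on = A·exp(−E/RT): the activation energy E comes from
per-trajectory barriers (compared across ligands by a one-sided Welch
t-test), the frequency factor A from the diffusion-limited collision rate
A = 4π·N_A·(D_P + D_L)·R*·ρ with critical distance R* and steric factor ρ,
and the effective temperature of a perturbed run from inverting Arrhenius at
fixed E and A.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .constants import LITER_PER_NM3, N_AVOGADRO, R_KCAL


@dataclass(frozen=True)
class KineticCounts:
    """Binding outcome counts for one condition."""

    n_bound: int              # stable-binding runs
    n_runs: int               # total independent runs
    duration: float           # per-run simulated time, s
    ligand_conc: float        # [L]0, M
    protein_conc: Optional[float] = None   # [P]0, M (informational)

    def __post_init__(self) -> None:
        if not 0 <= self.n_bound <= self.n_runs:
            raise ValueError("need 0 <= n_bound <= n_runs")
        if self.duration <= 0 or self.ligand_conc <= 0:
            raise ValueError("duration and ligand_conc must be positive")


@dataclass
class KineticEstimate:
    """The full parameter set for one ligand/condition (Table-style fields)."""

    k_on: float                         # M^-1 s^-1
    e_act: Optional[float] = None       # kcal/mol
    e_act_sd: Optional[float] = None
    log_a: Optional[float] = None       # log10 of A (M^-1 s^-1)
    log_rho: Optional[float] = None     # log10 steric factor
    t_eff: Optional[float] = None       # K
    d_ligand: Optional[float] = None    # cm²/s
    d_ligand_sd: Optional[float] = None
    r_star: float = 1.0                 # nm


def ligand_concentration(n_ligands: int, box_volume_nm3: float) -> float:
    """Molar concentration of n ligand copies in a box of given volume (nm³)."""
    if n_ligands <= 0 or box_volume_nm3 <= 0:
        raise ValueError("inputs must be positive")
    return n_ligands / (N_AVOGADRO * box_volume_nm3 * LITER_PER_NM3)


def kon_from_counts(counts: KineticCounts) -> float:
    """k_on = (n_bound/n_runs) / ([L]0 · t), M⁻¹s⁻¹.

    A zero count returns the censored upper bound using one pseudo-count,
    with a warning; a bound fraction above 0.2 warns that the linearized
    pseudo-first-order model is strained.
    """
    frac = counts.n_bound / counts.n_runs
    if counts.n_bound == 0:
        warnings.warn("no bound runs: returning censored upper bound (1 pseudo-count)",
                      stacklevel=2)
        frac = 1.0 / counts.n_runs
    elif frac > 0.2:
        warnings.warn("bound fraction > 0.2: pseudo-first-order approximation strained",
                      stacklevel=2)
    return frac / (counts.ligand_conc * counts.duration)


def expected_bound_fraction(k_on: float, ligand_conc: float, duration: float) -> float:
    """Forward model: fraction = k_on·[L]0·t (dimensionless)."""
    if k_on < 0 or ligand_conc <= 0 or duration <= 0:
        raise ValueError("k_on must be >= 0; concentration and duration positive")
    frac = k_on * ligand_conc * duration
    if frac > 1:
        raise ValueError(f"predicted fraction {frac:.3g} > 1: linearized model invalid")
    return frac


def acceleration_factor(perturbed: tuple[int, int], conventional: tuple[int, int],
                        percent_decimals: Optional[int] = 1) -> float:
    """Ratio of binding probabilities, perturbed / conventional.

    By default both probabilities are expressed as percentages rounded to
    ``percent_decimals`` before dividing, matching the printed-table
    convention (e.g. 12.4%/0.7% = 17.7); pass ``percent_decimals=None``
    for the exact count ratio.
    """
    p_pert = perturbed[0] / perturbed[1]
    p_conv = conventional[0] / conventional[1]
    if percent_decimals is not None:
        p_pert = round(100.0 * p_pert, percent_decimals)
        p_conv = round(100.0 * p_conv, percent_decimals)
    if p_conv == 0:
        raise ZeroDivisionError("conventional probability rounds to zero")
    return p_pert / p_conv


def activation_energy(barriers_a: Optional[Sequence[float]] = None,
                      barriers_b: Optional[Sequence[float]] = None,
                      summary_a: Optional[tuple[float, float, int]] = None,
                      summary_b: Optional[tuple[float, float, int]] = None):
    """Per-group mean ± SD of activation barriers and a one-sided Welch test.

    Groups may be given as raw per-trajectory barriers or as summary
    statistics (mean, SD, n).  The test is Welch's unequal-variance two-sample
    t-test with alternative "group b > group a"; p comes from the t
    distribution with Welch–Satterthwaite degrees of freedom.

    Returns ((mean_a, sd_a, n_a), (mean_b, sd_b, n_b), p_one_sided).
    """
    def reduce(values, summary):
        if summary is not None:
            m, s, n = summary
        else:
            v = np.asarray(values, dtype=float)
            if len(v) < 2:
                raise ValueError("each group needs at least 2 values")
            m, s, n = float(np.mean(v)), float(np.std(v, ddof=1)), len(v)
        if n < 2:
            raise ValueError("each group needs n >= 2")
        return m, s, n

    a = reduce(barriers_a, summary_a)
    b = reduce(barriers_b, summary_b)
    res = stats.ttest_ind_from_stats(a[0], a[1], a[2], b[0], b[1], b[2],
                                     equal_var=False, alternative="less")
    return a, b, float(res.pvalue)


def frequency_factor(k_on: float, e_act: float, temperature: float) -> float:
    """Arrhenius prefactor A = k_on·exp(E/RT), M⁻¹s⁻¹."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return k_on * math.exp(e_act / (R_KCAL * temperature))


def effective_temperature(k_on: float, e_act: float, a_factor: float) -> float:
    """Invert Arrhenius at fixed E and A: T = E / (R·ln(A/k_on)), K."""
    if a_factor <= k_on:
        raise ValueError("frequency factor must exceed k_on for a positive solution")
    return e_act / (R_KCAL * math.log(a_factor / k_on))


def diffusion_limited_prefactor(d_protein: float, d_ligand: float,
                                r_star: float = 1.0) -> float:
    """Smoluchowski collision rate 4π·N_A·(D_P+D_L)·R*, in M⁻¹s⁻¹.

    D in cm²/s, R* in nm.  (D=0.17e-5 cm²/s, R*=1 nm gives ≈1.29e9.)
    """
    if d_protein < 0 or d_ligand < 0:
        raise ValueError("diffusion constants must be >= 0")
    if r_star <= 0:
        raise ValueError("R* must be positive")
    d_m2 = (d_protein + d_ligand) * 1e-4    # cm²/s → m²/s
    r_m = r_star * 1e-9
    rate_m3 = 4.0 * math.pi * N_AVOGADRO * d_m2 * r_m   # m³ mol⁻¹ s⁻¹
    return rate_m3 * 1e3                                # → M⁻¹ s⁻¹


def steric_factor(a_factor: float, d_protein: float, d_ligand: float,
                  r_star: float = 1.0) -> float:
    """log10 steric factor: log10(A / (4π·N_A·(D_P+D_L)·R*))."""
    pref = diffusion_limited_prefactor(d_protein, d_ligand, r_star)
    if pref <= 0 or a_factor <= 0:
        raise ValueError("prefactor and A must be positive")
    return math.log10(a_factor / pref)
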