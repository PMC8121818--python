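# Methods

## The forcing protocol

A hypersound shock wave is modelled as additive velocity pulses applied to
solvent molecules in a slab of depth 1 nm at one face of the periodic box.
The pulse speed at step-within-wave *m* (a multiple of the pulse interval
*N*) is ±v_max·cos(2π·m/16N): one acoustic cycle is 16 pulses over 16·N
steps, one wave is `cycles_per_wave` (default 5) cycles, and six waves run
back to back in the face order +X, +Y, +Z, −X, −Y, −Z before a recovery
delay of `t_int` steps (default 2400·N). The cosine argument is reduced as
an exact rational to the first quadrant before evaluation, so the 16
pulses of a cycle cancel exactly (their float values sum to zero in exact
summation) — the protocol injects zero net momentum per cycle by
construction.

Defaults follow the reference protocol: N = 50, v_max = 0.4 nm/ps
(400 m/s), t_int = 2400·N, 5×16 pulses, 1 nm boundary depth. The CLI
accepts v_max in m/s and converts.

Two details the protocol description leaves open, decided here:

- **Selection time.** The perturbed-molecule set is recomputed at every
  pulse step from current positions rather than frozen per wave; molecules
  drift appreciably over a 16·N-step cycle.
- **Delay placement.** `t_int` follows the complete six-wave series, not
  each wave.
- **Pulse/thermostat ordering.** Within a step: forces → velocity-Verlet
  update → scheduled pulses → thermostat.

The schedule is laid out relative to the start of the run, so a run
continued from an equilibrated frame (whose step counter is nonzero)
still begins with the first wave.

## The toy solvent engine

The solvent is a monatomic Lennard-Jones fluid (mass 18 amu, σ = 0.5 nm,
ε = 0.5 kcal/mol, cutoff 1.25 nm with the potential shifted to zero at the
cutoff), not water: the forcing and every downstream analysis are
fluid-agnostic, and a reduced fluid keeps all demonstrations on one CPU.
At 298 K and reduced density ~0.8 this fluid is a dense liquid with a
thermal speed (√(kT/m) ≈ 0.37 nm/ps) matching water's, so the reference
pulse amplitude has the same ratio to thermal motion as in the original
setting. Integration is velocity Verlet at 2 fs; pair interactions use a
brute-force O(n²) path below 500 particles and a periodic KD-tree above.
Optional "receptor" particles are tethered harmonically to their initial
sites; "ligand" particles are ordinary LJ particles with their own tag.

Thermostats: Berendsen (λ = √(1 + (dt/τ)(T₀/T − 1))) and Bussi stochastic
velocity rescaling (exact kinetic-energy propagator with a seeded
generator), both with τ defaulting to 0.1 ps. With the thermostat off,
total energy is conserved to <0.1% over 10⁴ steps for a bound dimer and
total momentum to machine precision.

## Wave-field estimators

- **Density profiles**: mass of molecules within ±0.2 nm (configurable) of
  each grid plane divided by slab volume; the default grid is 82 points at
  0.1 nm spacing. Slabs near a periodic boundary wrap.
- **Directional kinetic energy k_x**: the slab *mean of squares*
  ½·M·v_x², not ½·M·⟨v_x⟩². The literal mean-then-square form would vanish
  in bulk fluid and contradict the known RT/2 bulk value (≈0.298 kcal/mol
  at 300 K), which the mean-of-squares form reproduces; this reading is
  adopted deliberately.
- **Instantaneous temperature**: T = 2·k_x/R, one translational degree of
  freedom.
- **Flux pressure**: the momentum flux of +x-crossers through a YZ plane
  over a window Δt, minus an attraction correction a·(1/V_m)². The
  correction is written with the molar density 1/V_m (not N_A/V_m), which
  is the only reading dimensionally consistent with a in atm·L²·mol⁻².
  Calibrating a from the published inputs (flux term 1.298×10⁸ Pa, vapor
  pressure 0.032×10⁵ Pa, V_m = 0.0183 L/mol) gives 0.429 atm·L²·mol⁻²,
  ~1.4% above the published 0.423; the published rounding path is
  unstated, and the recomputed value is used as the oracle in tests with
  the published one checked at 2%. The estimator is validated against
  kinetic theory: on a free-flight Maxwell gas the flux term equals
  n·k_B·T (within sampling error), which fixes both the crossing
  convention (+axis crossers contribute +v_x) and the factor of 2.
- **Wavefront tracking**: the front at each time is the far end of the
  contiguous region with density > bulk·(1 + threshold) nearest the source
  face; scanning from the source keeps isolated noise spikes ahead of the
  wave from being mistaken for it. Speed is the least-squares slope of
  position vs time (the finite difference for two crossings); wavelength
  is speed × period. Peak-based tracking was the alternative; threshold
  scanning was chosen because it reproduces the printed two-point
  arithmetic exactly.
- **MSD diffusion**: single-origin MSD averaged over molecules, least
  squares slope over the fit window, D = slope/6, mean ± SD over replicas.

## Binding detection

A pocket is defined by (by default two) anchor atoms and a 5 Å cutoff.
"At least two distances below 5 Å" is read as: each distinct anchor atom
within the cutoff of some ligand heavy atom (two-point engagement); the
alternative any-two-pairs reading is provided as a mode. Boundary
semantics follow the sources: strict (<) for plain contact, inclusive (≤)
for the strict single-anchor criterion, strict (<) for the 9 Å
crystal-pose RMSD bound.

Contact series are merged into bound intervals with a debounce window
(default 0.1 ns): gaps at or below the debounce merge, shorter blips are
dropped unless they reach the trajectory end. Outcomes: `none` (no
interval), `transient` (all intervals end early), `stable` (final interval
persists to the end and lasts at least `min_stable_ns`, default 10 ns —
the original workflow instead extends such runs and confirms visually,
which is out of scope here).

Stable-complex windows use the ligand RMSF about the window mean over
consecutive 10-ns windows (<3 Å ⇒ stable); a trailing window short of full
coverage only by the frame spacing still counts. Barriers are read off a
smoothed (50-sample running mean, edge-corrected) potential-energy trace:
maximum over the transition interval (first contact → stable binding)
minus the unbound-window mean. The unbound baseline and transition bounds
are caller-supplied; no published procedure exists for them.

## Kinetics chain

R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹ and N_A = 6.02214×10²³ throughout.

- k_on = (n_bound/n_runs)/([L]₀·t). Zero counts return a censored
  upper bound from one pseudo-count, flagged by a warning; bound fractions
  above 0.2 warn that the linearization is strained.
- Ligand concentration from n/(N_A·V): 50 ligands in 592.7 nm³ give
  0.1401 M; the published 138 mM is used verbatim wherever it is an input,
  since its rounding path from the same numbers is unclear.
- The activation-energy comparison uses Welch's unequal-variance t-test,
  one-sided (second group greater). The Welch form reproduces the
  published p = 0.02 from the published summary statistics; the pooled
  form gives ≈0.01 and was rejected.
- Frequency factor A = k_on·e^{E/RT}; effective temperature
  T = E/(R·ln(A/k_on)); diffusion-limited prefactor 4π·N_A·(D_P+D_L)·R*
  (R* = 1 nm, D_P ≪ D_L assumed); steric factor log₁₀(A/prefactor).
  The published ±SD on log A comes from a per-trajectory averaging whose
  inputs are unavailable; only the point values are reproduced.
- Acceleration factors divide probabilities after rounding each to
  1-decimal percentages, matching the printed convention (17.7 =
  12.4/0.7); an exact-ratio mode is provided.

## Pose analysis

Superposition is a Kabsch SVD fit with the proper-rotation correction,
applied to all atoms. PCA diagonalizes the covariance of pooled,
superposed ligand coordinate vectors; variance fractions are over all
eigenvalues. X-means starts from one cluster and recursively splits
centroids by 2-means (k-means++ with 10 restarts, scikit-learn), accepting
splits that improve the spherical-Gaussian BIC of the region, capped at
k_max, with a final global refinement; it is deterministic under a fixed
seed. Pose ranks order clusters by centroid distance to the projected
crystal pose, ties broken by cluster size (larger first).

f_int counts, per residue, the stable windows whose mean structure has any
residue heavy atom within 5 Å of any mean-ligand atom, normalized by the
number of trajectories — so f_int may exceed 1 when a trajectory
contributes several stable windows; a fraction-of-windows mode is also
provided because the published normalization is ambiguous between the
two. Residues with f_int > 0.1 for *every* ligand are nonspecific; the
remaining residues with nonzero f_int are each ligand's specific sites,
ranked by f_int.

## Synthetic data

All test inputs are generated with planted ground truth recorded in a
manifest; analysis tests read truth only from manifests. Generators are
bit-reproducible under a fixed seed.

- **LJ boxes**: jittered lattice positions, Maxwell–Boltzmann velocities
  with net momentum removed and kinetic energy rescaled to the exact
  target.
- **Brownian binding**: one ligand per run performing an overdamped random
  walk with planted D; binding is an instantaneous Poisson event at a
  planted rate, after which the ligand is pinned at the pocket of a
  three-anchor toy receptor (satisfying the two-anchor contact criterion).
  The instantaneous-event model gives an exactly known rate for
  k_on-recovery tests, at the cost of not modelling diffusion-to-capture
  kinetics. Default conditions mirror the reference study where they
  apply: 100-ns runs, rare-event rates (rate·t < 1), D of order
  10⁻⁵ cm²/s.
- **Moving pulse**: a Gaussian density bump translating at a planted speed
  over a flat background — the oracle for wavefront tracking.
- **Planted clusters**: isotropic Gaussians at orthonormal directions
  scaled so the center separation is the requested multiple of σ.
- **Barrier traces**: flat baseline plus a Gaussian bump of planted height
  between contact and binding times, with i.i.d. noise.

What the generators do *not* emulate: real water structure and
electrostatics, protein flexibility, ligand chemistry, or
diffusion-limited encounter kinetics. Passing tests therefore demonstrate
the correctness of the estimators and protocol logic, not the biophysical
accuracy of the toy fluid.

## Problem sizes in the test suite

The wave-generation demonstration uses 534 particles in a 9×3×3 nm box —
elongated so the forward wave has a clean runway before the
backward-radiated wave wraps around the periodic boundary — equilibrated
for 3 ps, then driven with a 2-cycle wave packet from the X0 face at
N = 20 and v_max = 0.8 nm/ps and left to recover for 4 ps under a
Berendsen thermostat. The doubled amplitude (about twice the thermal
speed) is a deliberate demonstration choice: with ~30× fewer particles
than a solvated-protein box, slab-density counting noise would otherwise
drown the wave. Profiles are block-averaged over four frames before
tracking. Assertions: peak interior slab density exceeds bulk + 3σ of the
equilibrium block-averaged fluctuation, the tracked wavefront speed is
positive (≈1 km/s, the expected sound speed of this fluid), and the
post-wave kinetic temperature returns to within 2% of target. Rate,
cluster, barrier and diffusion recovery use 200–1000 planted runs.

## Known limitations

- No electrostatics, constraints, barostat or all-atom force fields; the
  engine is a demonstration substrate, not a production MD code.
- `stable` classification depends on trajectory length; the original
  extend-and-inspect step is replaced by the minimum-duration rule.
- The flux-pressure estimator assumes no molecule crosses the plane twice
  between frames; sample finely relative to the thermal speed.
- X-means cluster counts on real, non-Gaussian pose distributions are
  sensitive to the BIC variant; only planted-data recovery is asserted.
- f_int normalization follows the per-trajectory reading by default; both
  readings are exposed because the source text is ambiguous.
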