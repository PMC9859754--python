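# Methods

## Model definition

The microtubule is a one-dimensional lattice of sites of length a = 8.4 nm
(one tubulin heterodimer), indexed 0 (minus-end) to L−1 (plus-end).  The
state is: motor occupancy per site (0/1), a non-negative cargo stack height
per occupied site, and a nucleotide state per site (GTP, GDP-Pi or GDP).
Cargo exists only on bound motors; when a motor leaves, its whole stack
leaves with it.

Reactions and rates (all first-order, exponential waiting times):

| reaction | rate | condition |
|---|---|---|
| motor attachment | ω_a = κ_a·c | per empty site |
| motor detachment | ω_d (÷ s if stabilized) | per motor |
| motor hop i→i+1 | p, or p_slow into GTP/GDP-Pi when the cap is on | destination empty |
| terminal walk-off | rate of a fresh-GTP destination (÷ s if stabilized) | motor at site L−1 |
| train hop | destination rate of the leading motor | trains on; see below |
| first cargo on/off | k_c_on / k_c_off | stack 0 / stack exactly 1 |
| layer adsorb/desorb | k_m_on / k_m_off | stack ≥ 1 / stack ≥ 2 (topmost layer, LIFO) |
| hydrolysis GTP→GDP-Pi→GDP | k_h1, k_h2 | per site, cap on |
| growth | γ | appends one empty GTP site |

Conventions that were genuinely open and how they were fixed:

* **Hop rate by destination.**  The slowdown acts where the motor lands, so
  the jam forms at the fast→slow transition.  Governing by origin would
  shift the jam by one site; either is consistent if applied throughout.
* **Terminal walk-off.**  A motor (or train leader) at the plus-end-most
  site steps off the lattice at the hop rate of a hypothetical fresh GTP
  destination (p with the cap off, p_slow with it on).  This is the open
  exit boundary of TASEP: nothing retains the motor at the end, and the
  detachment rate at the terminal site is the ordinary ω_d.  With a
  detachment-only exit the end would become a hard wall — influx ρp ≈
  0.8 s⁻¹ against removal ω_d = 0.25 s⁻¹ — and a dense queue would form at
  the tip *without any cap*, contradicting the flat baseline profiles the
  trains/stabilization-only scenarios must show.
* **Stabilization = longer dwell of clustered motor-cargo.**  A cargo-
  bearing motor with at least one cargo-bearing neighbour leaves the lattice
  s-fold slower.  "Leaves" covers both detachment and the terminal walk-off
  — end departure terminates the dwell exactly like detachment; interior
  hop rates are never modified, so stabilization does not slow transport.
* **Trains are rigid.**  A train is a maximal run of adjacent cargo-bearing
  motors (cargo-free motors break runs).  The train advances as one unit at
  the hop rate of its leading motor's destination; internal exclusion holds
  by construction.  Cargo-free motors always move individually.
* **Hydrolysis is random**, i.e. site-autonomous with exponential waiting
  times, not vectorial.  With Poisson growth this gives a GTP survival at
  x sites behind the tip of (γ/(γ+k_h1))^x — exponential decay with
  constant ln(1+k_h1/γ), which equals the continuum k_h1/γ to ~4 % at the
  defaults (both inside the 10 % tolerance the tests use).
* **Growth and the co-moving window.**  Growth appends one empty GTP site
  regardless of tip occupancy and the minus-end never shrinks (default,
  `window=None`).  For long runs this is computationally unbounded — at
  γ = 3 sites/s a 27,000 s trajectory adds 81,000 sites — so production
  runs set `window = L0`: when the lattice reaches the window, growth drops
  the minus-end-most site (removing any motor on it).  This is the lattice
  seen from the tip; every observable here is tip-aligned and the bulk is a
  homogeneous Langmuir reservoir, so the window does not affect them.

## Parameters

Defaults, units and rationale (all configurable; `ModelParams`):

* a = 8.4 nm; L0 = 1000 sites; seed per run, no global RNG state.
* p = 20 s⁻¹ — one motor traverses the 1,000-site system in ≈ 50 s.
* p_slow = p/3 — the order of the motor slowdown observed on
  GTPγS-mimicked cap lattices.
* ω_d = 0.25 s⁻¹ — run length p/ω_d = 80 sites ≈ 0.7 µm.
* κ_a = 1.32·10⁻⁴ s⁻¹ nM⁻¹, so that 100 nM gives Langmuir occupancy
  ω_a/(ω_a+ω_d) = 0.05: the low-density (LD) phase of TASEP/LK, where bulk
  density is set by the Langmuir isotherm (Ω = ω_d·L/p = 12.5 ≫ 1).
* γ = 3 sites/s ≈ 1.5 µm/min growth.
* k_h1 = k_h2 = 0.25 s⁻¹ — mean GTP+GDP-Pi zone of 2γ/k_h = 24 sites
  ≈ 200 nm behind the tip, matching the tip analysis window.
* k_c_on = 2, k_c_off = 0.5 s⁻¹ — carrying fraction 0.8 at equilibrium;
  cargo is present in excess of motors in the reconstitutions this mimics.
* k_m_on = 1, k_m_off = 0.5 s⁻¹ — a net-adsorbing top layer, so stack
  height grows in proportion to motor dwell time.  This is the parameter
  regime in which multi-layer absorption does what it exists for:
  non-stoichiometric cargo accumulation.  With a zero-drift top layer
  (k_m_on = k_m_off) stacks grow only like √dwell and the stabilized
  scenario's end accumulation becomes barely super-linear.
* s = 3 — a three-fold dwell increase for clustered motor-cargo.

The tip window is 24 sites (round(200 nm / 8.4 nm)); the bulk lattice
window is sites 300–600 from the tip — beyond the cap region and clear of
the minus-end entry layer (≈ p/ω ≈ 70 sites).

## Simulation engine

`engine.step` is the plain direct-method Gillespie reference built on the
explicit propensity catalogue.  `engine.run_simulation` uses a numba kernel
implementing an exact thinning variant of the direct method: per-motor
reaction classes use the constant upper bound rate_max·n_motors, the waiting
time is drawn from the total bound rate, and a rejected candidate is a null
event that advances time only — this reproduces the exact trajectory law
(Poisson thinning) at O(1) cost per step.  Hydrolysis propensities are exact
(GTP/GDP-Pi counts maintained incrementally; the non-GDP zone lives within
~100 sites of the tip, so site selection scans a short window).

Snapshots are the lattice state at the scheduled times (states are piecewise
constant between events).  The desk-scale schedule is 2,000 s equilibration
followed by 500 snapshots at the 50 s traversal time; concentration sweeps
use 2,000 snapshots at 10 s spacing instead — the 24-site tip window
decorrelates within seconds, so denser sampling cuts the variance of the
non-linearity index about four-fold at equal simulated time.  These sizes
keep a full scenario run in the seconds range; the published-size schedule
(10⁵ s, 10⁴ snapshots) is ordinary configuration.

The kernel was validated against an independently enumerated 2⁶-state
master-equation generator (6-site static lattice, hop + Langmuir): the
time-averaged per-site density agrees within three batch-mean standard
errors; the pure-Python reference chain is checked the same way on a 4-site
lattice.

## Synthetic data

The generator emulates three assay readouts: (i) comet profiles — a shallow
smooth rise over the seed region, a flat lattice plateau, and an exponential
end peak (tip value = plateau + amplitude); kymographs rendered from
simulation snapshots map the motor channel to motor counts and the cargo
channel to total stack height, convolved with a Gaussian PSF (FWHM 0.3 µm,
0.107 µm pixels, typical TIRF values) plus background and Poisson or
Gaussian noise; (ii) two-channel condensate fields — non-overlapping disks
with per-disk intensities, client channel = recruitment factor × tag inside
condensates; (iii) linear traces with velocities drawn from a heavy-tailed
log-normal law (median 0.23 µm/s, σ_log = 1.1, so the across-trace s.d. is
a few-fold larger than the median) and Gaussian positional noise.

What the generators deliberately omit: camera gain statistics,
photobleaching, chromatic shift and drift, diffusive motor states, motile
condensates, and curved/crossing microtubules.  Passing round-trips
therefore demonstrate the correctness of the analysis arithmetic
(binning, alignment, normalization, segmentation, regression), not
robustness to every artefact of real microscopy data.

## Numerical and degenerate-case choices

* Alignment searches integer shifts in ±20 px; ties (e.g. flat profiles) go
  to the smallest |shift|; singleton bins get offset 0; the per-bin
  reference profile is drawn with the run's seed.  Bin averages are taken
  over the common support of all aligned members.
* End/lattice regions for profile statistics are explicit configuration
  intervals (defaults: comet = last 0.5–1 µm, lattice = 2–6 µm from the
  tip) rather than interactive choices.
* Rolling-ball background subtraction is the classical algorithm
  (scikit-image); output clipped at zero; radius must fit inside the image.
* Condensate segmentation keeps border-touching components and drops
  degenerate ones (< 2 px or zero minor axis); sub-threshold objects simply
  yield no record.
* Trace velocities are least-squares slopes over whole traces (not
  frame-to-frame displacements); SEM = s.d./√N; traces need ≥ 2 points and
  strictly increasing times.
* Concentration sweeps derive per-run seeds as base seed + index; fold
  changes use region means, not peaks, for robustness at low occupancy.
* An empty propensity catalogue raises in the reference path; the kernel
  treats a frozen state as constant-in-time (which is exact) when only
  sampling remains.

## Known limitations

Motor-cargo parameters beyond the printed anchors (traversal time, system
size, LD phase, the three-fold dwell factor, the ~200 nm cap zone) are the
package's own calibration: they were chosen to place the model in the
regime of pronounced, super-linear end accumulation for stabilized clusters
with a cap, and flat baselines otherwise — not to reproduce any specific
published curve.  Catastrophe/shrinkage, explicit autonomous end-trackers,
2-D/3-D lattice geometry and diffusive motor states are out of scope.  The
non-linearity index at desk-scale sampling carries a seed-to-seed spread of
roughly ±0.1; the acceptance script reports whatever the given seed yields.
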