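# tiptraffic

Stochastic lattice model of motor-driven cargo accumulation at growing
microtubule plus-ends, with the quantitative image-analysis procedures used
to read plus-end-tracking (+TIP) experiments — all exercised on synthetic
data with known ground truth.

## The problem

Kinesin-like motors (e.g. Tea2 in fission yeast) walk toward the growing
plus-end of microtubules carrying cargo adaptors (Tip1/CLIP-170).  In cells
and reconstitutions the cargo accumulates at the growing end far more than
one-per-motor stoichiometry allows, and its end intensity rises
*super-linearly* with motor concentration.  `tiptraffic` implements a
minimal model that asks which mechanisms can produce this: a traffic jam
where motors slow down on the fresh GTP cap, coherent movement of cargo
trains, and lateral stabilization of cargo clusters.

## The model

A microtubule is a 1-D lattice of 8.4 nm sites (one tubulin heterodimer),
indexed from the minus-end; it grows by appending fresh GTP sites at rate
γ.  Motors obey a totally asymmetric simple exclusion process with Langmuir
kinetics (TASEP/LK) in the low-density phase:

* attachment ω_a = κ_a·c per empty site (c = motor concentration, nM),
  detachment ω_d per motor, hops i→i+1 at rate p blocked by exclusion;
  a motor at the terminal site steps off the plus-end at its hop rate.
* **GTP cap** (`enable_cap`): two-step hydrolysis GTP→GDP-Pi→GDP at rates
  k_h1, k_h2 per site; motors hop into GTP/GDP-Pi sites at p_slow < p.
  The cap occupancy decays exponentially behind the tip with decay constant
  k_h1/γ, and the fast→slow transition jams traffic.
* **Cargo**: a motor binds a first cargo at k_c_on (off k_c_off); further
  layers adsorb/desorb on the exposed stack top at k_m_on/k_m_off (LIFO),
  so cargo occupation is not capped at one per motor.
* **Trains** (`enable_trains`): maximal runs of adjacent cargo-bearing
  motors advance as rigid units at the leading motor's destination rate.
* **Stabilization** (`enable_stabilization`): a cargo-bearing motor adjacent
  to another cargo-bearing motor leaves the lattice (detachment, or walk-off
  at the terminal site) s-fold slower (default s = 3).

Trajectories are exact continuous-time Monte Carlo (Gillespie; the
production kernel is an exact thinning sampler in numba, validated against
the brute-force master-equation solution of a small lattice).  Observables
are tip-aligned density profiles, mean occupations of a ~200 nm tip window
(24 sites) versus a bulk lattice window, concentration sweeps, and the
**non-linearity index** — the ratio of tip to lattice cargo fold-changes
between a low and a high motor concentration (1 = proportional, > 1 =
super-linear end accumulation).

The analysis side mirrors TIRF microscopy workflows: rolling-ball background
subtraction, length-binning (±0.64 µm) and integer-pixel alignment of comet
intensity profiles, averaged profiles and high/low-condition intensity
ratios, threshold segmentation of condensates (centroid, ellipse axes, mean
intensity per channel) with client-recruitment quantification, and median ±
SEM statistics of trace velocities.  The `synth` module generates every
input these stages need — kymographs, parametric comet profiles, two-channel
condensate images, particle traces — with serialized ground truth.

## Worked example

```bash
python examples/01_simulate_and_profile.py
```

```
events simulated:        26,821,505
motor density  tip=0.0938  lattice=0.0497  ratio=1.89
cargo occupation  tip=0.3833  lattice=0.1463  ratio=2.62
A ratio well above 1 is the motor traffic jam at the fast->slow transition;
without the cap both ratios sit near 1.
```

This simulates a 1,000-site growing lattice with the GTP cap enabled at the
100 nM-equivalent attachment rate (2,000 s equilibration, then 500 snapshots
50 s apart), and averages motor density and cargo occupation in the 24-site
tip window versus sites 300–600 behind the tip.  Motors pile up almost
two-fold where the lattice turns slow, and the cargo — free to stack in
layers — accumulates even more strongly.  The other examples cover the
scenario comparison and non-linearity index (`02`), comet-profile alignment
and condition ratios (`03`), condensate segmentation and client recruitment
(`04`), and trace velocity statistics (`05`).

A CLI wraps the same library functions
(`tiptraffic simulate|sweep|figure6|synth|profiles|condensates|velocities`);
every output directory carries a `manifest.json` with the configuration,
seeds and file digests that regenerate it.

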