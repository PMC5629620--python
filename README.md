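# neurocascade

A multitype Bellman–Harris branching-process model of the **early adult
hippocampal neurogenic cascade**: neural stem cells (NSCs) of the dentate
subgranular zone asymmetrically emit amplifying neuroprogenitors (ANPs),
which divide a bounded number of times, differentiate into neuroblasts
(NBs) and finally granule cells (GCs), with stage-specific apoptosis and
rapid microglial clearance of the dying cells.  The package is for
computational and systems neurobiologists who want to estimate the
experimentally inaccessible parameters of this cascade — apoptotic rates,
the ANP renewal probability, transit-time distributions — from BrdU
pulse-chase labeling curves, and to predict how neurogenesis responds to
perturbations of apoptosis.

## The model in brief

Each cell of type *i* lives a random transit time with a shifted-gamma law
*f(x | k, s, v)* (minimum *v*, mean *v + ks*) and, on leaving its stage,
produces offspring with expected-progeny matrix *m*: death at a stage end
with rate *d_i* routes to the apoptotic compartment, a surviving G2M cell
divides in two, and an ANP clone performs N divisions with
P(N = a) = 1 − p, P(N = a+i) = pⁱ(1 − p), P(N = b) = p^(b−a), so its
progeny count is X = 2^N and the expected division number is log₂E[X].
First moments solve the renewal equation

    M(t) = T(t) * [m M(t)] + [I − T(t)],      M = Σₖ (Tm)^{*k} * (I − T),

and under constant Poisson influx the steady state is
π = rate · e′(I − m)⁻¹E[T].  A BrdU pulse labels exactly the S-phase
occupancy of π; labeling curves are produced either analytically or by an
event-based simulator that traces every labeled lineage.  Fitting minimizes
the variance-weighted least squares Σ(E − S)²/σ² over the 40 non-zero
measurements with a genetic algorithm over the admissible parameter ranges;
the two influx scales are calibrated in closed form by linearity.

## Worked example

```python
import numpy as np
import neurocascade as nc
from neurocascade.dataprep import adjust_dataset, measurements
from neurocascade.inference import ExpectationEngine, calibrate_influx

obs, params = nc.load_fixtures()
meas = measurements(obs, adjust_dataset(obs))              # the 40 data points
engine = ExpectationEngine(np.unique(meas["time_h"]), step=0.25)
lam, mu = calibrate_influx(meas, *engine.unit_curves(params))
print(f"lambda = {lam:.1f} ANPs/h, mu = {mu:.2f} activations/h")

calibrated = params.replace_values(influx=lam, nsc_activation=mu)
curve = nc.simulate_labeling_curves(calibrated, [2.0, 24.0, 192.0, 768.0],
                                    n_replicates=10, rng=42)
print(curve.observables().round(0).to_string(index=False))

table = nc.run_scenarios(calibrated, (1.0, 0.75, 0.0), n_replicates=20, seed=11)
print(table.round(2).to_string(index=False))
```

prints

```
lambda = 166.6 ANPs/h, mu = 9.26 activations/h
 time_h  Total  Apop   NSC    ANP     NB    GC  Astro
    2.0 2894.0   4.0 312.0 2578.0    0.0   0.0    0.0
   24.0 5251.0  12.0 213.0 2540.0 2387.0   0.0   99.0
  192.0 3351.0  18.0   4.0   69.0 2909.0  42.0  308.0
  768.0  524.0   1.0   0.0    0.0   85.0 126.0  312.0
 multiplier  fold_total  fold_gc
       1.00        1.00     1.00
       0.75        3.34    10.99
       0.00       15.86    64.05
```

Reading the output: the calibrated influxes put ~2900 BrdU+ cells in the
labeled cohort (observed: 2690 ± 320 at 2 h), of which ~11% are NSCs; the
labeled population peaks around day 1–2 as ANP clones amplify, then drains
through the high-mortality neuroblast stage (d_NB = 0.97), leaving about a
hundred labeled granule cells at day 32.  The scenario table gives day-32
fold changes when every apoptotic rate is scaled by the multiplier: cutting
apoptosis by 25% roughly triples the total labeled population and yields
~11× more newborn granule cells; complete inhibition yields ~16× and ~64×.

A command-line interface mirrors the library:
`neurocascade simulate|prep|fit|predict|synth --help`.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes the package's headline quantities from scratch: the adjusted
day-1 ANP and NB proportions obtained by re-proportioning the double-labeled
observations (equal split of the excess), and the paired-simulation day-32
fold changes of total and granule-cell BrdU+ counts under complete and 25%
apoptosis inhibition (20 replicates, common random numbers).  The seed
controls all simulation randomness; results are written as JSON.
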