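# pbpkt

A configurable whole-body PBPK (physiologically based pharmacokinetic)
model **superstructure** with structural pruning, exposure scenarios,
Monte-Carlo virtual populations, and a CPU-time benchmarking harness for
model-implementation choices.

The package centres on a single maximal ODE model — **53 state variables**
(17 compartment amounts, 9 cumulative-metabolism accumulators, 13 cumulative
intake/elimination accumulators, 14 AUC accumulators) and **105 algebraic
output variables** — from which chemical-specific models are obtained by
switching compartments, metabolic pathways, exposure routes and
representation options on or off.  Unused parameters are zero and unused
compartments carry no blood flow; states whose derivatives are identically
zero under a configuration can be **pruned** without changing the retained
solution.

Two chemical fixtures ship with the package:

| model | template mapping | pruned states | stand-alone implementation |
|-------|-----------------|---------------|----------------------------|
| DCM (dichloromethane) | fat/liver/richly/slowly + metabolising lung, stomach-only GI | 34 of 53 | 21 states / 22 outputs |
| CF (chloroform)       | fat/liver/kidney/richly/slowly, two-segment GI, no lung | 33 of 53 | 19 states / 26 outputs |

The stand-alone implementations are dedicated minimal codes (fixed body
weight, no gating) that reproduce the template-implemented models to within
10⁻⁶ maximum absolute output discrepancy at solver tolerances 10⁻¹⁰.

## Representation options

* **Blood**: steady-state algebraic approximation vs explicit arterial and
  venous state variables.
* **Gas exchange**: steady-state (Ramsey–Andersen) relation vs an explicit
  air-side state, with or without an explicit lung tissue compartment.
* **Body weight**: time-varying input table, fixed value rescaled at every
  derivative call, or fixed value scaled once at initialisation (28
  parameters depend on body weight).
* **Conditionals**: each of the 32 registered conditional sites (4 in the
  initialise section, 28 in the dynamics section) can be evaluated as an
  if/else branch or as a multiplicative 0/1 switch; the two produce
  bit-identical trajectories.
* **Outputs**: full 105-entry output map or a reduced 76-entry map.

## Command line

```bash
pbpkt simulate --model dcm --impl template --scenario 3 --points 100 \
      --subjects 1 --seed 1 --out run.csv
pbpkt population --n 10000 --seed 42 --out pop.csv
pbpkt bench --experiment 6 --chemical dcm,cf --scenario 1 \
      --subjects 100 --reps 10 --seed 0 --out table.csv
pbpkt roster --config dcm --prune --out roster.csv
```

Exposure scenarios: (1) constant continuous inhalation, (2) constant
continuous oral infusion into the stomach lumen, (3) periodic inhalation
6 h/day 5 days/week, (4) six oral boluses/day — all over a two-week
(336 h) window.  Bolus doses are applied as instantaneous state jumps with
hard integrator (LSODA) restarts.  `bench --full-scale` switches to the
10 k/1 k-subject batch protocol (10 k for continuous, 1 k for periodic
scenarios); the default batch size of 100 suits CI.

## Layout

```
src/pbpkt/
  params_io.py          # parameter tables, validation, BW scaling, flow renormalisation
  template_engine.py    # the 53-state superstructure, conditional sites, pruning
  standalone_models.py  # dedicated DCM/CF implementations + discrepancy metric
  exposure.py           # the four scenarios, forcing + bolus events
  population.py         # seeded virtual-subject sampling
  simulator.py          # LSODA driver with event restarts and output grids
  benchmark.py          # the eight timing experiments, Welch comparisons
  fixtures.py, data/    # shipped DCM/CF/human parameter CSVs
  cli.py                # the `pbpkt` console entry point
```

Parameter files are CSV with header `name,value,units` (see
`src/pbpkt/data/`).  The fixture parameter values are plausible human
parameterisations assembled for structural and timing work, not a
reproduction of any published archive.
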