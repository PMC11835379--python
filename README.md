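# dtpdyn

Multiscale dynamics of drug-tolerant persister (DTP) cells in cancer drug
treatment. Each cell carries a heritable epigenetic trait ("chance to
persist", `x ∈ (0,1)`) that is transmitted to daughters through a
dose-dependent Beta inheritance kernel, and a phenotype coordinate
(`y ∈ (0,1)`) that controls drug-induced apoptosis and adapts to drug
stress. The package implements three coupled views of the same model plus a
treatment optimizer and a synthetic calibration pipeline:

- **`dtpdyn.kernels`** — pure rate/kernel functions shared by every solver:
  dose schedules, the Beta inheritance density and its Hill-shaped
  conditional mean, trait-dependent proliferation, drug-gated apoptosis,
  and stress-adaptation drift.
- **`dtpdyn.population`** — finite-volume solver for the phenotype-
  structured population balance equation (upwind advection + zero-flux
  diffusion + death + nonlocal mitosis redistribution), with preheating to
  the drug-free stationary state and trajectory recording of relative
  tumor size and cell-type fractions (naive `y<0.5`; DTP `y>0.5, x>0.15`;
  resistant `y>0.5, x<0.15`).
- **`dtpdyn.singlecell`** — factorized single-cell density model
  `f(x,y,t) = h(y,t;x)·g(x,t)`: the trait marginal evolves under
  inheritance/selection (crowding-free), the conditional phenotype
  densities under advection-diffusion with relative-death reweighting.
  Includes fixed-trait survival curves.
- **`dtpdyn.agents`** — discrete-time stochastic simulation of individual
  cells (divide / die / rest with Euler–Maruyama phenotype updates),
  an independent check on the density solvers.
- **`dtpdyn.treatment`** — periodic dosing engine: stable-cycle detection,
  min–max schedule optimization over (therapeutic days, drug holidays)
  with the end-of-treatment feasibility constraint, and sweeps over the
  inverse epigenetic noise `eta0` and the selection strength.
- **`dtpdyn.calibration`** — synthetic clone-trait and tumor-volume
  datasets with seeded noise, bounded multi-start fitting of the
  epigenetic and cellular parameter groups, and a one-at-a-time
  sensitivity table.

Default parameter values are calibrated stand-ins chosen so the default
model reproduces the benchmark treatment kinetics (see `scripts/
acceptance.py`); every value can be overridden through a flat YAML config
(`eta0: 25.0`, `gamma1: 1.25`, `tau_off: 10`, ...; see
`dtpdyn.params.DEFAULT_CONFIG` for the full key list).

## Command line

```bash
simulate-population --dose 0.3 --t-end 60 --out traj.csv
simulate-singlecell --dose 0.9 --eta0 25 --t-end 60 --out probs.csv
simulate-agents --n0 5000 --seed 42 --dose 0.3 --t-end 20 --out agents.csv
optimize-schedule --tau-on 1:21 --tau-off 0:21 --out grid.csv
make-synth --seed 1 --out data/
fit --data data/ --which epigenetic --out fit.json
```

All commands accept `--config cfg.yaml` with flat key-value overrides.

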