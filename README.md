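# magsense

Simulation tool chain for nanoparticular magnetoresistive biosensors:

* **Magnetics** — stochastic Landau–Lifshitz–Gilbert spin dynamics of
  dipolar-coupled single-domain nanoparticles, WCA hard-sphere repulsion,
  overdamped translational dynamics, and the alternating hybrid SD/MD
  scheduler that models self-assembly in a liquid gel. Characteristic GMR
  curves are extracted from simulated magnetization loops via
  `GMR = A·(1 − (M/Ms)²)`. A rotating, oscillating, amplitude-damped
  demagnetization field protocol finds low-energy states of frustrated
  configurations more reliably than plain relaxation.
* **Biosensing** — a 2D flow-cell transport solver (plane Poiseuille flow,
  upwind advection, implicit diffusion on a wall-graded mesh) coupled
  through a Robin boundary to the 1:1 Langmuir surface reaction
  `dn/dt = ka·c·(1 − n/nA) − kd·n/nA`, producing sensorgrams; inference
  routines recover `kd` from the dissociation phase, `ka = kd/KD`, and
  `KD` from a one-site isotherm fit of peak coverages.

## CLI

All simulation subcommands take `--config <yaml> --out <dir> --seed <int>`:

```bash
magsense assemble  --config run.yaml --out out/   # hybrid SD/MD self-assembly
magsense relax     --config run.yaml --out out/   # T=0 moment relaxation
magsense demag     --config run.yaml --out out/   # demagnetization protocol
magsense gmr       --config run.yaml --out out/   # M(B) loop + GMR curve
magsense flowcell  --config run.yaml --out out/   # sensorgram simulation
magsense fit-kd    --input sensorgram.csv --na 2.56e-8 --kd-eq 21e-3
magsense fit-kd-equilibrium --input peaks.csv
```

A config file only needs the keys that differ from the defaults, e.g.

```yaml
ensemble: {n: 192, box: [350.0e-9, 350.0e-9], diameter: 20.0e-9}
schedule: {total_steps: 200000, sd_every: 10000}
injection: {c_in: 20.0e-3, ramp_up: 0.5, hold: 20.0, ramp_down: 0.5}
binding: {kd: 1.5e-8, KD: 21.0e-3, nA: 2.56e-8}
```

Outputs are plain text: extended-XYZ snapshots (`x y z mx my mz d`, SI),
CSV curves/sensorgrams written with 17 significant digits, and a
run-metadata JSON (config hash, seed, versions).

## Layout

```
src/magsense/
  ensemble.py       particle/ensemble types, generators, table import
  interactions.py   dipole–dipole + WCA energies, fields, forces
  spin_dynamics.py  stochastic LLG integrator, relaxation, demag, M(B)
  hybrid.py         overdamped MD and the alternating SD/MD scheduler
  gmr.py            magnetization -> GMR curve mapping
  flowcell.py       advection–diffusion–reaction channel solver
  binding.py        Langmuir rate law, isotherm, well-mixed sensorgrams
  inference.py      kd/ka/KD recovery from sensorgrams
  config.py, io.py, cli.py   run configs, writers, command line
```
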