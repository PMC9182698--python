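# spelearn

Uncertainty-guided reward learning with **scaled prediction errors** (SPE):
a learner that tracks both the mean `m` and the standard deviation `s` of a
reward signal and uses the scaled error `delta = (r - m) / s` as its teaching
signal, together with:

- Rescorla–Wagner and Kalman-filter baselines (including the steady-state
  Kalman gain and its high-noise approximation `nu / sigma`);
- the basal-ganglia formulation of the same rules, in which `(m, s)` are
  carried by direct/indirect pathway weights `G` and `N` with
  `m = (G - N)/2` and `lam * (s - 1) = (G + N)/2`;
- a continuous-time leaky-integrator model of the dopamine–thalamus feedback
  loop whose equilibrium computes the scaled prediction error;
- synthetic reward generators (drifting Gaussians, balanced Pavlovian
  schedules, discrete reward distributions) and simulation drivers that
  reproduce the value-tracking benchmark, the magnitude-invariance
  experiments, and the Kalman approximation curves.

## Library quick start

```python
import numpy as np
from spelearn.learners import SPEParams, run_spe
from spelearn.reward_sim import DriftingGaussianParams, generate_drifting_rewards

traj = generate_drifting_rewards(
    DriftingGaussianParams(nu=1.0, sigma=15.0, n_trials=10_000, seed=0)
)
trace = run_spe(SPEParams(alpha_m=1.0, alpha_s=0.1), traj.r)
print(np.mean((trace.m - traj.mu) ** 2))  # tracking error vs latent mean
```

The weight-space learner (`spelearn.basal_ganglia.run_pathway_learner`) in
`unconstrained` mode reproduces the `(m, s)` trajectories of `run_spe`
exactly; `constrained` mode clips weights at zero, which limits accurate
spread tracking to `s >= |m|/lam + 1`.

## Command line

```bash
spelearn --seed 1 --out-dir results benchmark      # RW grid vs SPE vs Kalman
spelearn --seed 1 --out-dir results tobler         # 50%-reward magnitude sweep
spelearn --seed 1 --out-dir results rothenhoefer   # discrete-distribution responses
spelearn --seed 1 --out-dir results circuit        # dopamine-thalamus ODE
spelearn --seed 1 --out-dir results kalman-curves  # gain / posterior-variance curves
```

Each subcommand writes `<name>.csv` (tidy results) and `<name>.json`
(parameter provenance). Defaults can be overridden with
`--config config.yaml`, using one top-level key per subcommand:

```yaml
benchmark:
  n_trials: 20000
  sigma_grid: [1.0, 5.0, 15.0]
```

Note the full benchmark default (100 noise levels x 12 learners x 1e5
trials) takes a few minutes; pass a smaller `n_trials`/`sigma_grid` via the
config for quick runs.

## Layout

| Module | Contents |
| --- | --- |
| `spelearn.learners` | SPE / RW / Kalman update rules, steady-state gain and variance, sequence runners |
| `spelearn.reward_sim` | drifting-Gaussian rewards, balanced Pavlovian schedules, discrete distributions |
| `spelearn.basal_ganglia` | weight encoding/decoding, plasticity nonlinearity, weight-space learner |
| `spelearn.circuit_dynamics` | leaky-integrator feedback loop, equilibrium analysis, settling time |
| `spelearn.experiments` | tracking benchmark, Pavlovian simulations, analytic response curves |
| `spelearn.cli` | `spelearn` command-line entry point |
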