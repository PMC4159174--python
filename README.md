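# senesim

Dynamical modelling of irradiation-induced cellular senescence.

After a single high dose of ionising radiation (20 Gy X-rays), human
fibroblasts enter a permanent cell-cycle arrest whose establishment unfolds
over about three weeks: a DNA-damage spike, persistent oxidative stress,
CDK-inhibitor (CDKN1A/CDKN1B) induction, an early burst of mTORC1-driven
mitochondrial biogenesis, and a progressive shift of the mitochondrial
population toward a dysfunctional, low-membrane-potential state that feeds
back into ROS production and DNA damage. `senesim` implements a mass-action
network model of this process — 23 species, 41 reactions, five modules
(DNA-damage response, oxidative stress, FoxO3a, insulin/IIS-mTOR,
mitochondria) — and the complete in-silico analysis campaign built on it.

The package is aimed at systems biologists who want to simulate the network,
reproduce the intervention predictions (ROS scavenging, mTOR inhibition,
catabolic over-activation), run local sensitivity and Lyapunov stability
analyses, and exercise the full chi-square calibration/identifiability
pipeline on synthetic data with the same structure as the in vitro time
courses.

## The model in brief

State variables `x` (arbitrary units) evolve by mass action,

    dx/dt = S v(x),   v_j(x) = k_j * prod_i x_i^(s_ij) * prod_m x_m,

where `S` is the stoichiometric matrix, reactants enter with their
stoichiometry and modifiers multiplicatively. Inputs are insulin and amino
acids (constant) and an irradiation impulse at t = 0 lasting 5 minutes.
Four phosphorylation cycles (Akt, mTORC1, AMPK, IKK-β) conserve their pool
totals, so the system is effectively 19-dimensional. The mitochondrial
population is split into "new" (made by biogenesis, high membrane potential
ψm) and "old" (made by CDKN1A-dependent deterioration of new mitochondria,
low ψm) pools, with separate mitophagy rate constants constrained as
`k36 < k35` (old cleared more slowly than new). Fourteen observables
(scale factor times a sum of species) connect the model to measured readouts,
e.g. `Mitochondrial-Mass = S * (mass_new + mass_old)`.

Quantities the analyses compute:

- **χ² score** — `Σ ((observed mean − simulated)/σ)²` with a 10% relative
  error model, plus a hinge penalty for the mitophagy constraint;
  **AIC** = χ² + 2·n_free.
- **Scaled sensitivities** — `s_ij(t) = (∂x_i/∂k_j)(k_j/x_i)` by central
  finite differences, normalised per matrix.
- **Lyapunov spectrum** — Wolf method on the conservation-reduced system:
  tangent vectors propagated with the analytic Jacobian, QR
  re-orthonormalisation, log stretch factors averaged after a transient;
  the sum of the exponents equals the average divergence (trace of the
  Jacobian along the trajectory).
- **Identifiability** — on the best 30% of a multistart fit ensemble, a
  parameter is non-identifiable when its related-parameter tuple has
  |correlation| > 0.9 and its coefficient of variation exceeds 0.25.

The rate constants shipped with `build_reference_network()` are this
package's own calibration of the published network description; see
`docs/methods.md` for what that does and does not reproduce.

## Worked example

```python
from senesim import (build_reference_network, simulate_deterministic,
                     SimulationSettings, PerturbationSpec, dose_response_scan)

model = build_reference_network()            # 23 species, 41 reactions
traj = simulate_deterministic(model)         # 21 days, grid 0.02 -> 1051 rows

mass = traj.observable("Mitochondrial-Mass")
psim = traj.observable("Mitochondrial-Membrane-Potential")
print(f"mass day 21 / day 0:  {mass[-1] / mass[0]:.2f}")
print(f"psim day 21 / day 0:  {psim[-1] / psim[0]:.2f}")

scan = dose_response_scan(model, PerturbationSpec("ROS", "dynamic-modulator"),
                          [0.0, 0.45, 0.9],
                          ["Mitochondrial-Membrane-Potential"], [12.0])
print(f"psim at day 12, control:            {scan.values[0, 0, 0]:.3f}")
print(f"psim at day 12, 90% ROS inhibition: {scan.values[2, 0, 0]:.3f}")
```

prints

```
mass day 21 / day 0:  1.77
psim day 21 / day 0:  0.21
psim at day 12, control:            0.322
psim at day 12, 90% ROS inhibition: 1.171
```

i.e. over three weeks the irradiated network gains almost 80% mitochondrial
mass while losing ~80% of its membrane potential, and sustained ROS
scavenging (a dynamic modulator calibrated so the day-1..21 average ROS level
is 10% of control) restores the day-12 potential beyond its basal value by
switching off the ROS-driven depolarisation of the new pool.

## The analysis campaign

Numbered drivers under `analysis/` run the individual studies and write their
tables to `results/`:

| script | what it does |
| --- | --- |
| `01_simulate_timecourses.py` | control vs irradiated time courses, internal mitochondrial states |
| `02_perturbation_scans.py` | ROS/mTOR inhibition and AMPK/FoxO3a/mitophagy activation scans, 2D grids |
| `03_sensitivity.py` | sensitivity matrices at days 1/10/20, time-averaged mitochondrial block, rate-factor sweeps |
| `04_stability.py` | Wolf-method Lyapunov spectrum and average divergence of the reduced system |
| `05_fit_identifiability.py` | synthetic data, multistart fitting, recovery errors, CC/CV identifiability |
| `06_stochastic.py` | Gillespie ensembles, stochastic noise growth of the stress species |

A thin `senesim` CLI exposes the same stages
(`senesim simulate`, `perturb`, `scan2d`, `sensitivity`, `lyapunov`, `fit`,
`identifiability`, `generate`, `export`, `recipe fig2a`, ...) with SBML
Level 2 Version 4 import/export.

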