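"""Stochastic simulation of the senescence network (Gillespie direct method).

Runs an ensemble in particle counts, checks that the ensemble mean tracks the
deterministic solution, and quantifies the late increase in signalling noise
for the stress-response species.
"""

import time
from pathlib import Path

import numpy as np
import pandas as pd

from senesim import SimulationSettings, build_reference_network, simulate_deterministic, simulate_stochastic

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

N_RUNS = 100
OMEGA = 1000.0


def main() -> None:
    model = build_reference_network()
    settings = SimulationSettings(duration=21.0, interval_size=0.1, seed=1,
                                  omega=OMEGA, max_internal_steps=100000)
    t0 = time.time()
    runs = simulate_stochastic(model, settings=settings, n_runs=N_RUNS)
    print(f"{N_RUNS} stochastic runs at system size {OMEGA:g} particles/a.u. "
          f"in {time.time() - t0:.1f} s.")

    det = simulate_deterministic(model, settings=SimulationSettings(duration=21.0,
                                                                    interval_size=0.1))
    mean = runs.ensemble_mean_amounts()
    rows = []
    obs_stack = np.stack([r.observables for r in runs.runs]) / OMEGA
    for j, name in enumerate(mean.observable_names):
        for d in (1.0, 10.0, 20.0):
            i = mean.at_time(d)
            mu = obs_stack[:, i, j].mean()
            sd = obs_stack[:, i, j].std(ddof=1)
            rows.append(dict(observable=name, day=d, ssa_mean=mu, ssa_sd=sd,
                             deterministic=det.observables[det.at_time(d), j],
                             cv=sd / mu if mu > 0 else np.nan))
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "stochastic_summary.tsv", sep="\t", index=False)

    dev = np.abs(df.ssa_mean - df.deterministic) / (df.ssa_sd / np.sqrt(N_RUNS))
    print(f"Ensemble mean vs ODE: max |z| over observables/days = {dev.max():.2f} "
          "standard errors.")

    for name in ("DNA-damage", "ROS"):
        sub = df[df.observable == name].set_index("day")
        print(f"{name}: coefficient of variation day 1 = {sub.loc[1.0, 'cv']:.3f}, "
              f"day 20 = {sub.loc[20.0, 'cv']:.3f} "
              f"({'increased' if sub.loc[20.0, 'cv'] > sub.loc[1.0, 'cv'] else 'decreased'} "
              "stochasticity late in senescence).")


if __name__ == "__main__":
    main()
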