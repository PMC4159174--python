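"""Simulate the calibrated senescence network: control versus 20 Gy irradiation.

Writes the full observable time courses and the internal mitochondrial states
(new/old mass and membrane potential) to results/, and prints the hallmark
changes over the 21-day course.
"""

from pathlib import Path

import numpy as np

from senesim import SimulationSettings, build_reference_network, simulate_deterministic

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    settings = SimulationSettings()  # duration 21, interval 0.02
    irradiated = simulate_deterministic(build_reference_network(), settings=settings)
    control = simulate_deterministic(
        build_reference_network(irradiation_amplitude=0.0), settings=settings
    )

    irradiated.to_frame().to_csv(OUT / "timecourse_irradiated.tsv", sep="\t", index=False)
    control.to_frame().to_csv(OUT / "timecourse_control.tsv", sep="\t", index=False)

    day = lambda tr, name, d: tr.observable(name)[tr.at_time(d)]
    print("Irradiation-induced senescence, day 0 -> day 21 (fold change):")
    for name in irradiated.observable_names:
        y = irradiated.observable(name)
        print(f"  {name:36s} {y[0]:8.4f} -> {y[-1]:8.4f}  ({y[-1] / max(y[0], 1e-12):5.2f}x)")
    print()
    print("Internal mitochondrial states at day 21 (a.u.):")
    for sid, label in (("X20", "new mass"), ("X21", "old mass"),
                       ("X22", "new membrane potential"), ("X23", "old membrane potential")):
        print(f"  {label:26s} {irradiated.state(sid)[-1]:8.4f}")
    dd = irradiated.observable("DNA-damage")
    print()
    print(f"DNA damage spikes to {dd.max():.3f} a.u. within the first day "
          f"(t = {irradiated.times[dd.argmax()]:.2f} d) and relaxes to "
          f"{day(irradiated, 'DNA-damage', 4.0):.3f} by day 4 before the "
          "ROS-driven late rise.")
    mt = irradiated.observable("mTOR-pS2448")
    print(f"mTOR-pS2448 peaks at day {irradiated.times[mt.argmax()]:.1f} "
          f"({mt.max():.3f} a.u.) and declines thereafter.")
    drift = np.abs(control.observables - control.observables[0]).max(axis=0)
    rel = drift / np.maximum(np.abs(control.observables[0]), 1e-12)
    print(f"Unirradiated control: max relative drift over 21 d = {rel.max():.3%} "
          "(basal state is stationary).")


if __name__ == "__main__":
    main()
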