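"""Lyapunov stability of the late-senescence state.

Computes the Wolf-method spectrum of the conservation-reduced (19-dimensional)
system together with the average divergence, and writes the Table-style
summary to results/.
"""

import time
from pathlib import Path

from senesim import (
    LyapunovSettings,
    build_reference_network,
    conservation_analysis,
    lyapunov_spectrum,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    model = build_reference_network()
    laws, reduced = conservation_analysis(model)
    print(f"{len(laws)} conserved pool totals -> {reduced} independent variables.")

    settings = LyapunovSettings(
        n_exponents=reduced,
        start_averaging_after=21.0,
        overall_time=50.0,
        orthonormalisation_interval=0.001,
    )
    t0 = time.time()
    res = lyapunov_spectrum(model, settings=settings)
    print(f"Wolf spectrum computed in {time.time() - t0:.1f} s "
          f"(orthonormalisation interval {settings.orthonormalisation_interval}).")

    with open(OUT / "lyapunov_spectrum.tsv", "w") as fh:
        for i, lam in enumerate(res.exponents, 1):
            fh.write(f"lambda_{i}\t{lam:.8g}\n")
        fh.write(f"Sum\t{res.sum:.8g}\n")
        fh.write(f"Avg divergence\t{res.average_divergence:.8g}\n")

    print("Exponents (sorted descending):")
    for i, lam in enumerate(res.exponents, 1):
        print(f"  lambda_{i:<2d} {lam:14.7g}")
    print(f"  Sum            {res.sum:14.7g}")
    print(f"  Avg divergence {res.average_divergence:14.7g}")
    rel = abs(res.sum - res.average_divergence) / abs(res.sum)
    print(f"Sum vs divergence agree to {rel:.2%}.")
    if res.all_negative:
        print("All exponents negative -> the late-senescence state is asymptotically "
              "Lyapunov stable.")
    else:
        n_pos = int((res.exponents >= 0).sum())
        print(f"{n_pos} exponent(s) non-negative: in this calibration the "
              "stress-accumulation mode is still creeping inside the averaging "
              "window, so the late state is not yet a Lyapunov-stable fixed point.")


if __name__ == "__main__":
    main()
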