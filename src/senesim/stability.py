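"""Lyapunov stability of the reaction network (Wolf method) and divergence.

The network carries conserved pool totals, so the Lyapunov spectrum is
computed for the conservation-reduced system: one species per conserved
moiety is eliminated and reconstructed algebraically from the pool total.
Tangent vectors are propagated with the analytic Jacobian of the reduced
system (symbolically derived; finite differences are too fragile for a
spectrum spanning several orders of magnitude) and re-orthonormalized by QR
factorisation at a fixed interval; exponents are the time-averaged log
stretch factors accumulated after a transient.

The average divergence is the time average of the trace of the reduced
Jacobian along the trajectory; for any trajectory sampling an ergodic
attractor it equals the sum of the Lyapunov exponents, which Table-style
reports show side by side as a consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .network import NetworkModel, conservation_analysis
from .simulate import _segments
from .symbolic import lambdified_system

__all__ = [
    "LyapunovSettings",
    "LyapunovResult",
    "ReducedSystem",
    "lyapunov_spectrum",
    "average_divergence",
]


@dataclass
class LyapunovSettings:
    """Wolf-method configuration (defaults follow the study's report)."""

    n_exponents: int = 19
    start_averaging_after: float = 21.0
    orthonormalisation_interval: float = 1e-4
    overall_time: float = 50.0
    rel_tol: float = 1e-6
    abs_tol: float = 1e-10
    max_internal_steps: int = 10000

    def __post_init__(self) -> None:
        if self.overall_time <= self.start_averaging_after:
            raise ValueError("overall_time must exceed start_averaging_after")
        if self.orthonormalisation_interval <= 0:
            raise ValueError("orthonormalisation interval must be positive")


@dataclass
class LyapunovResult:
    """Estimated spectrum, its sum, and the average divergence."""

    exponents: np.ndarray  # sorted descending, 1/time units
    sum: float
    average_divergence: float
    settings: LyapunovSettings

    @property
    def all_negative(self) -> bool:
        return bool(np.all(self.exponents < 0))


class ReducedSystem:
    """Conservation-reduced dynamics with analytic Jacobian.

    Keeps ``n - n_laws`` independent species; each eliminated species is
    reconstructed from its conserved total.  Exposes ``rhs(t, y, levels)``
    and ``jacobian(t, y, levels)`` in reduced coordinates.
    """

    def __init__(self, model: NetworkModel, params=None):
        self.model = model
        self.params = np.asarray(
            model.parameter_vector() if params is None else params, dtype=float
        )
        laws, self.dimension = conservation_analysis(model)
        n = model.n_species
        x0 = model.initial_state()
        elim, weights, totals = [], [], []
        for law in laws:
            idx = {model.species_index[sid]: w for sid, w in law.items()}
            # eliminate the highest-index species in the law (deterministic)
            e = max(idx)
            elim.append(e)
            weights.append(idx)
            totals.append(sum(w * x0[i] for i, w in idx.items()))
        if len(set(elim)) != len(elim):
            raise ValueError("conservation laws do not admit a disjoint elimination set")
        self.eliminated = elim
        self.kept = [i for i in range(n) if i not in set(elim)]
        self._laws = weights
        self._totals = totals
        self._f, self._jx, _ = lambdified_system(model)
        # d(x_elim)/d(x_kept) matrix
        kept_pos = {i: p for p, i in enumerate(self.kept)}
        D = np.zeros((len(elim), len(self.kept)))
        for r, (e, law) in enumerate(zip(elim, weights)):
            we = law[e]
            for i, w in law.items():
                if i != e and i in kept_pos:
                    D[r, kept_pos[i]] = -w / we
        self._D = D

    def initial_reduced_state(self) -> np.ndarray:
        return self.model.initial_state()[self.kept]

    def full_state(self, y: np.ndarray) -> np.ndarray:
        x = np.zeros(self.model.n_species)
        x[self.kept] = y
        for e, law, tot in zip(self.eliminated, self._laws, self._totals):
            rest = sum(w * x[i] for i, w in law.items() if i != e)
            x[e] = (tot - rest) / law[e]
        return x

    def rhs(self, t: float, y: np.ndarray, levels) -> np.ndarray:
        x = self.full_state(y)
        return self._f(x, self.params, levels)[self.kept]

    def jacobian(self, t: float, y: np.ndarray, levels) -> np.ndarray:
        x = self.full_state(y)
        J = self._jx(x, self.params, levels)
        Jkk = J[np.ix_(self.kept, self.kept)]
        Jke = J[np.ix_(self.kept, self.eliminated)]
        return Jkk + Jke @ self._D


def _input_levels_fn(model: NetworkModel, duration: float):
    segs = list(_segments(model, duration))

    def levels(t: float):
        for a, b, lv in segs:
            if a <= t < b:
                return lv
        return segs[-1][2]

    return levels, [a for a, _, _ in segs[1:]]


def lyapunov_spectrum(
    model: NetworkModel,
    params=None,
    settings: LyapunovSettings | None = None,
    initial_frame: np.ndarray | None = None,
) -> LyapunovResult:
    """Wolf-method Lyapunov spectrum of the conservation-reduced system.

    The base trajectory is integrated once per input segment with a dense
    LSODA solution; tangent vectors are then propagated across each
    orthonormalisation interval with the matrix exponential of the analytic
    Jacobian frozen at the interval midpoint (exact for locally constant
    Jacobians, second-order in the interval otherwise), followed by QR
    re-orthonormalisation.  Log stretch factors are averaged after
    ``start_averaging_after``; the divergence integrates the Jacobian trace
    over the same window.
    """
    from scipy.linalg import expm

    settings = settings or LyapunovSettings()
    red = ReducedSystem(model, params)
    d = red.dimension
    k = settings.n_exponents
    if k > d:
        raise ValueError(f"requested {k} exponents but reduced dimension is {d}")

    # dense base trajectory per piecewise-constant input segment
    segments = []
    y = red.initial_reduced_state()
    for a, b, levels in _segments(model, settings.overall_time):
        sol = solve_ivp(
            lambda t, yy: red.rhs(t, yy, levels), (a, b), y, method="LSODA",
            rtol=settings.rel_tol, atol=settings.abs_tol, dense_output=True,
        )
        if not sol.success:
            raise RuntimeError(f"base trajectory failed in [{a}, {b}]: {sol.message}")
        segments.append((a, b, levels, sol.sol))
        y = sol.y[:, -1]

    def state_at(t: float):
        for a, b, levels, interp in segments:
            if a <= t <= b + 1e-12:
                return interp(min(t, b)), levels
        raise ValueError(f"time {t} outside integrated range")

    if initial_frame is None:
        V = np.eye(d)[:, :k]
    else:
        V = np.asarray(initial_frame, dtype=float).copy()
        if V.shape != (d, k):
            raise ValueError(f"initial frame must be {d}x{k}")
    dt = settings.orthonormalisation_interval
    t0, t1 = 0.0, settings.overall_time
    t_avg = settings.start_averaging_after
    log_sums = np.zeros(k)
    averaged_time = 0.0
    div_integral = 0.0

    edges = sorted({a for a, *_ in segments} | {t_avg, t1})
    t = t0
    while t < t1 - 1e-12:
        t_next = min(t + dt, t1)
        for e in edges:
            if t + 1e-15 < e < t_next - 1e-15:
                t_next = e
                break
        h = t_next - t
        y_mid, levels = state_at(t + 0.5 * h)
        J = red.jacobian(t + 0.5 * h, y_mid, levels)
        V = expm(J * h) @ V
        V, R = np.linalg.qr(V)
        diag = np.abs(np.diag(R))
        sgn = np.sign(np.diag(R))
        sgn[sgn == 0] = 1.0
        V = V * sgn
        if t >= t_avg - 1e-12:
            log_sums += np.log(np.maximum(diag, 1e-300))
            averaged_time += h
            div_integral += np.trace(J) * h
        t = t_next

    exponents = np.sort(log_sums / averaged_time)[::-1]
    avg_div = div_integral / averaged_time
    return LyapunovResult(exponents, float(exponents.sum()), float(avg_div), settings)


def average_divergence(
    model: NetworkModel,
    params=None,
    window: tuple[float, float] = (21.0, 50.0),
    rel_tol: float = 1e-6,
    abs_tol: float = 1e-10,
    n_samples: int = 2000,
) -> float:
    """Time average of the reduced-Jacobian trace along the trajectory."""
    red = ReducedSystem(model, params)
    levels_fn, _ = _input_levels_fn(model, window[1])
    y0 = red.initial_reduced_state()
    out = np.zeros(n_samples + 1)
    times = np.linspace(window[0], window[1], n_samples + 1)
    y = y0
    t0 = 0.0
    filled = np.zeros(len(times), dtype=bool)
    for a, b, levels in _segments(model, window[1]):
        mask = (~filled) & (times > a + 1e-15) & (times <= b + 1e-15)
        seg_eval = times[mask]
        sol = solve_ivp(lambda tt, yy: red.rhs(tt, yy, levels), (a, b), y,
                        method="LSODA", t_eval=seg_eval if seg_eval.size else None,
                        rtol=rel_tol, atol=abs_tol)
        if not sol.success:
            raise RuntimeError(f"integration failed: {sol.message}")
        if seg_eval.size:
            for loc, idx in enumerate(np.nonzero(mask)[0]):
                out[idx] = np.trace(red.jacobian(times[idx], sol.y[:, loc], levels))
            filled[mask] = True
        y = sol.y[:, -1] if sol.y.size else y
    if times[0] == 0.0:
        out[0] = np.trace(red.jacobian(0.0, y0, levels_fn(0.0)))
        filled[0] = True
    return float(np.trapezoid(out, times) / (window[1] - window[0]))
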