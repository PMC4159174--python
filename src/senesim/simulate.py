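"""Deterministic (LSODA) and stochastic (Gillespie direct method) simulation.

Deterministic runs integrate the mass-action ODEs on a uniform reporting
grid, restarting the integrator at the irradiation pulse edges so the
discontinuity is not smeared.  Stochastic runs convert amounts (a.u.) to
particle counts with a system-size parameter ``omega`` (particles per a.u.),
rescale propensities accordingly, and sample exact trajectories with the
direct method.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .network import NetworkModel, PARAM_BOUNDS

__all__ = [
    "SimulationSettings",
    "Trajectory",
    "StochasticRunSet",
    "simulate_deterministic",
    "simulate_stochastic",
    "project_observables",
    "compile_rhs",
]


@dataclass
class SimulationSettings:
    """Solver configuration (defaults follow the study's reported settings)."""

    duration: float = 21.0
    interval_size: float = 0.02
    rel_tol: float = 1e-6
    abs_tol: float = 1e-12
    max_internal_steps: int = 10000
    seed: int = 1
    omega: float = 1000.0  # particles per a.u., stochastic only

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.interval_size <= 0:
            raise ValueError("duration and interval size must be positive")
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.omega < 1:
            raise ValueError("omega must be >= 1")

    def time_grid(self) -> np.ndarray:
        n = int(round(self.duration / self.interval_size))
        return np.linspace(0.0, n * self.interval_size, n + 1)


STOCHASTIC_DEFAULTS = dict(interval_size=0.01, max_internal_steps=100000)


@dataclass
class Trajectory:
    """Time-indexed states and observables of one simulation."""

    times: np.ndarray
    states: np.ndarray  # (n_times, n_species)
    observables: np.ndarray  # (n_times, n_observables)
    species_ids: list[str] = field(default_factory=list)
    observable_names: list[str] = field(default_factory=list)

    def state(self, species_id: str) -> np.ndarray:
        return self.states[:, self.species_ids.index(species_id)]

    def observable(self, name: str) -> np.ndarray:
        return self.observables[:, self.observable_names.index(name)]

    def at_time(self, t: float) -> int:
        """Index of the grid point closest to ``t``."""
        return int(np.argmin(np.abs(self.times - t)))

    def to_frame(self):
        """Long-format DataFrame (time, variable, value)."""
        import pandas as pd

        rows = []
        for j, sid in enumerate(self.species_ids):
            rows.append(pd.DataFrame({"time": self.times, "variable": sid, "value": self.states[:, j]}))
        for j, name in enumerate(self.observable_names):
            rows.append(
                pd.DataFrame({"time": self.times, "variable": name, "value": self.observables[:, j]})
            )
        return pd.concat(rows, ignore_index=True)


def trajectory_from_frame(df, species_ids: list[str], observable_names: list[str]) -> Trajectory:
    """Rebuild a Trajectory from the long-format table written by ``to_frame``."""
    times = np.sort(df["time"].unique())
    pivot = df.pivot_table(index="time", columns="variable", values="value")
    states = pivot.loc[times, species_ids].to_numpy()
    obs = pivot.loc[times, observable_names].to_numpy()
    return Trajectory(times, states, obs, list(species_ids), list(observable_names))


@dataclass
class StochasticRunSet:
    """Ensemble of stochastic runs in particle counts."""

    runs: list[Trajectory]
    omega: float
    seed: int

    def ensemble_mean_amounts(self) -> Trajectory:
        """Mean over runs, converted back from counts to amounts."""
        states = np.mean([r.states for r in self.runs], axis=0) / self.omega
        obs = np.mean([r.observables for r in self.runs], axis=0) / self.omega
        r0 = self.runs[0]
        return Trajectory(r0.times, states, obs, r0.species_ids, r0.observable_names)


def project_observables(traj_or_states, defs, model: NetworkModel | None = None) -> np.ndarray:
    """Observable matrix ``Y_i(t) = S_i * sum(component species amounts)``.

    Accepts a Trajectory (with ``model`` for the species index) or a raw
    (n_times, n_species) state matrix together with ``model``.
    """
    if isinstance(traj_or_states, Trajectory):
        states = traj_or_states.states
        index = {sid: i for i, sid in enumerate(traj_or_states.species_ids)}
    else:
        if model is None:
            raise ValueError("model required when passing a raw state matrix")
        states = np.asarray(traj_or_states)
        index = model.species_index
    out = np.empty((states.shape[0], len(defs)))
    for j, obs in enumerate(defs):
        for sid in obs.component_species:
            if sid not in index:
                raise KeyError(f"observable {obs.id} needs missing species {sid!r}")
        cols = [index[sid] for sid in obs.component_species]
        out[:, j] = obs.scaling_factor * states[:, cols].sum(axis=1)
    return out


# ---------------------------------------------------------------------------
# Compiled kinetics
# ---------------------------------------------------------------------------

_MAX_FACTORS = 4  # max reactant+modifier species factors per reaction


def _factor_tables(model: NetworkModel):
    """Per-reaction factor index tables into [state..., 1, input levels...].

    Returns (factor_idx (m, MAX), input_code (m,), n_species_factors (m,)).
    Index ``n_species`` points at a constant 1; inputs are applied separately
    because the irradiation level is piecewise constant.
    """
    n = model.n_species
    m = model.n_reactions
    fidx = np.full((m, _MAX_FACTORS), n, dtype=np.intp)  # default -> constant 1
    input_names = [i.name for i in model.inputs]
    icode = np.full(m, -1, dtype=np.intp)
    nsf = np.zeros(m, dtype=np.intp)
    for j, r in enumerate(model.reactions):
        slots = []
        for sid, sto in r.reactants.items():
            slots.extend([model.species_index[sid]] * sto)
        for mod in r.modifiers:
            if mod in model.species_index:
                slots.append(model.species_index[mod])
            else:
                icode[j] = input_names.index(mod)
        if len(slots) > _MAX_FACTORS:
            raise ValueError(f"reaction {r.id}: too many rate-law factors")
        nsf[j] = len(slots)
        fidx[j, : len(slots)] = slots
    return fidx, icode, nsf


def compile_rhs(model: NetworkModel):
    """Return ``rhs(t, x, params, input_levels)`` as a fast vectorised closure.

    ``input_levels`` is the tuple of current input values (assumed constant
    over the integration segment).
    """
    fidx, icode, _ = _factor_tables(model)
    S = model.stoichiometry
    n = model.n_species

    def rates(x, params, input_levels):
        ext = np.empty(n + 1)
        ext[:n] = x
        ext[n] = 1.0
        r = params * ext[fidx].prod(axis=1)
        for j in np.nonzero(icode >= 0)[0]:
            r[j] *= input_levels[icode[j]]
        return r

    def rhs(t, x, params, input_levels):
        return S @ rates(np.maximum(x, 0.0), params, input_levels)

    rhs.rates = rates
    return rhs


def _check_params(model: NetworkModel, params) -> np.ndarray:
    if params is None:
        params = model.parameter_vector()
    params = np.asarray(params, dtype=float)
    if params.shape != (model.n_reactions,):
        raise ValueError(f"expected {model.n_reactions} rate constants")
    if np.any(params < 0):
        raise ValueError("rate constants must be nonnegative")
    lo, hi = PARAM_BOUNDS
    active = params > 0
    if np.any(params[active] < lo) or np.any(params > hi):
        raise ValueError(f"rate constants must lie within [{lo}, {hi}] (or be 0)")
    return params


def _segments(model: NetworkModel, duration: float):
    """Integration segments with constant input levels (split at pulse edges)."""
    edges = {0.0, duration}
    for sig in model.inputs:
        if sig.kind == "pulse":
            for e in (sig.pulse_start, sig.pulse_start + sig.pulse_width):
                if 0.0 < e < duration:
                    edges.add(e)
    edges = sorted(edges)
    for a, b in zip(edges[:-1], edges[1:]):
        mid = 0.5 * (a + b)
        levels = tuple(sig.value(mid) for sig in model.inputs)
        yield a, b, levels


def simulate_deterministic(
    model: NetworkModel,
    params: np.ndarray | None = None,
    settings: SimulationSettings | None = None,
    t_eval: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the network ODEs with an LSODA-class adaptive solver.

    Reports on the uniform grid of ``settings`` (or on ``t_eval``); states
    are clipped at zero for reporting only.
    """
    settings = settings or SimulationSettings()
    params = _check_params(model, params)
    grid = settings.time_grid() if t_eval is None else np.asarray(t_eval, dtype=float)
    duration = max(settings.duration, float(grid[-1]))
    rhs = compile_rhs(model)

    x = model.initial_state().astype(float)
    out = np.empty((len(grid), model.n_species))
    filled = np.zeros(len(grid), dtype=bool)
    if grid[0] == 0.0:
        out[0] = x
        filled[0] = True

    for a, b, levels in _segments(model, duration):
        mask = (~filled) & (grid > a + 1e-15) & (grid <= b + 1e-15)
        seg_eval = grid[mask]
        sol = solve_ivp(
            rhs,
            (a, b),
            x,
            method="LSODA",
            t_eval=seg_eval if seg_eval.size else None,
            rtol=settings.rel_tol,
            atol=settings.abs_tol,
            args=(params, levels),
            max_step=np.inf,
        )
        if not sol.success:
            raise RuntimeError(f"integration failed in segment [{a}, {b}]: {sol.message}")
        if seg_eval.size:
            out[mask] = sol.y.T
            filled[mask] = True
        x = sol.y[:, -1] if sol.y.size else x
        x = np.asarray(x, dtype=float)

    if not filled.all():
        raise RuntimeError("reporting grid points outside integration range")
    states = np.clip(out, 0.0, None)
    obs = project_observables(states, model.observables, model)
    return Trajectory(
        grid,
        states,
        obs,
        [s.id for s in model.species],
        [o.name for o in model.observables],
    )


# ---------------------------------------------------------------------------
# Stochastic simulation (direct method)
# ---------------------------------------------------------------------------


def _ssa_kernel_py(counts, c_eff, fidx, nsf, stoich_cols, t0, t1, grid, out, seed):
    """Pure-python fallback of the direct-method kernel (see numba version)."""
    rng = np.random.RandomState(seed)
    t = t0
    m = len(c_eff)
    gi = 0
    while gi < len(grid) and grid[gi] < t0:
        gi += 1
    while t < t1:
        a = np.empty(m)
        for j in range(m):
            v = c_eff[j]
            for f in range(nsf[j]):
                v *= counts[fidx[j, f]]
            a[j] = v
        a0 = a.sum()
        if a0 <= 0.0:
            t = t1  # absorbing state: hold counts to the end of the segment
            break
        t += rng.exponential(1.0 / a0)
        while gi < len(grid) and grid[gi] <= min(t, t1):
            out[gi] = counts
            gi += 1
        if t >= t1:
            break
        r = rng.random_sample() * a0
        acc = 0.0
        j = 0
        for j in range(m):
            acc += a[j]
            if acc >= r:
                break
        counts += stoich_cols[j]
    while gi < len(grid) and grid[gi] <= t1:
        out[gi] = counts
        gi += 1
    return gi


try:  # pragma: no cover - exercised indirectly
    import numba

    @numba.njit(cache=True)
    def _ssa_kernel_nb(counts, c_eff, fidx, nsf, stoich_cols, t0, t1, grid, out, seed):
        np.random.seed(seed)
        t = t0
        m = len(c_eff)
        gi = 0
        while gi < len(grid) and grid[gi] < t0:
            gi += 1
        a = np.empty(m)
        while t < t1:
            for j in range(m):
                v = c_eff[j]
                for f in range(nsf[j]):
                    v *= counts[fidx[j, f]]
                a[j] = v
            a0 = a.sum()
            if a0 <= 0.0:
                break
            t += np.random.exponential(1.0 / a0)
            tcap = t if t < t1 else t1
            while gi < len(grid) and grid[gi] <= tcap:
                for i in range(counts.shape[0]):
                    out[gi, i] = counts[i]
                gi += 1
            if t >= t1:
                break
            r = np.random.random() * a0
            acc = 0.0
            j = 0
            for jj in range(m):
                acc += a[jj]
                j = jj
                if acc >= r:
                    break
            for i in range(counts.shape[0]):
                counts[i] += stoich_cols[j, i]
        while gi < len(grid) and grid[gi] <= t1:
            for i in range(counts.shape[0]):
                out[gi, i] = counts[i]
            gi += 1
        return gi

    _SSA_KERNEL = _ssa_kernel_nb
except Exception:  # pragma: no cover
    _SSA_KERNEL = _ssa_kernel_py


def simulate_stochastic(
    model: NetworkModel,
    params: np.ndarray | None = None,
    settings: SimulationSettings | None = None,
    n_runs: int = 1,
) -> StochasticRunSet:
    """Exact SSA sampling of the mass-action propensities.

    Initial amounts are multiplied by ``omega`` and rounded to the nearest
    integer; a propensity with ``s`` species factors is rescaled by
    ``omega**(1-s)`` so that densities converge to the ODE solution for
    large ``omega``.  Runs are reproducible: run ``r`` uses seed
    ``settings.seed + r`` for its own stream.
    """
    if settings is None:
        settings = SimulationSettings(**STOCHASTIC_DEFAULTS)
    params = _check_params(model, params)
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    omega = float(settings.omega)
    fidx, icode, nsf = _factor_tables(model)
    # factor table indexes [counts..., constant]: constant slot holds 1
    n = model.n_species
    stoich_cols = np.ascontiguousarray(model.stoichiometry.T.astype(np.int64))
    grid = settings.time_grid()
    base_scale = params * omega ** (1.0 - nsf)  # per-reaction c_j without inputs
    fidx64 = fidx.astype(np.int64)
    nsf64 = nsf.astype(np.int64)

    runs = []
    x0 = np.rint(model.initial_state() * omega).astype(np.int64)
    segs = list(_segments(model, settings.duration))
    for r in range(n_runs):
        counts = np.concatenate([x0, [1]]).astype(np.float64)  # last slot = constant 1
        out = np.empty((len(grid), n + 1))
        out[0] = counts
        for si, (a, b, levels) in enumerate(segs):
            c_eff = base_scale.copy()
            for j in np.nonzero(icode >= 0)[0]:
                c_eff[j] *= levels[icode[j]]
            seed = (settings.seed * 1000003 + r * 9176 + si) % (2**31 - 1)
            _SSA_KERNEL(counts, c_eff, fidx64, nsf64, stoich_cols_pad(stoich_cols), a, b, grid, out, seed)
        states = out[:, :n]
        obs = project_observables(states, model.observables, model)
        runs.append(
            Trajectory(
                grid,
                states,
                obs,
                [s.id for s in model.species],
                [o.name for o in model.observables],
            )
        )
    return StochasticRunSet(runs, omega, settings.seed)


def stoich_cols_pad(stoich_cols: np.ndarray) -> np.ndarray:
    """Pad stoichiometry columns with a zero entry for the constant slot."""
    m, n = stoich_cols.shape
    out = np.zeros((m, n + 1), dtype=np.int64)
    out[:, :n] = stoich_cols
    return out
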