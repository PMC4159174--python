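"""Scaled local sensitivity analysis of species to rate constants.

Sensitivities are computed by central finite differences with a relative
step ``delta`` on each rate constant: ``s_ij(t) = (dx_i/dk_j) * (k_j /
x_i)``.  A matrix is "normalized" by dividing all entries by the largest
absolute raw value (sign preserved), matching the convention of heat-map
style reporting; species whose amount falls below ``abs_floor`` report a
zero sensitivity there.

A forward variational-equation oracle (exact sensitivity ODEs driven by the
analytic Jacobians) is provided for cross-checking the finite differences on
small models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .network import NetworkModel
from .simulate import SimulationSettings, Trajectory, simulate_deterministic, _segments
from .symbolic import lambdified_system

__all__ = [
    "SensitivityMatrix",
    "local_sensitivities",
    "time_averaged_sensitivities",
    "rate_factor_timecourses",
    "variational_sensitivities",
]

DEFAULT_DELTA = 1e-3
ABS_FLOOR = 1e-9


@dataclass
class SensitivityMatrix:
    """Normalized scaled sensitivities (rows: species, columns: parameters)."""

    rows: list[str]
    columns: list[str]
    values: np.ndarray  # normalized to max|.| = 1
    raw_values: np.ndarray
    time_tag: str
    flagged: np.ndarray | None = None  # entries whose perturbed run failed

    def entry(self, species_id: str, param_id: str, raw: bool = False) -> float:
        m = self.raw_values if raw else self.values
        return float(m[self.rows.index(species_id), self.columns.index(param_id)])

    def to_frame(self, raw: bool = False):
        import pandas as pd

        return pd.DataFrame(self.raw_values if raw else self.values,
                            index=self.rows, columns=self.columns)


def _normalize(raw: np.ndarray) -> np.ndarray:
    peak = np.nanmax(np.abs(raw)) if raw.size else 0.0
    return raw / peak if peak > 0 else raw.copy()


def _scaled_fd(model, params, times, delta, settings):
    """Raw scaled sensitivities at each requested time: (n_times, n, m)."""
    params = np.asarray(params, dtype=float)
    times = np.asarray(times, dtype=float)
    base = simulate_deterministic(model, params, settings, t_eval=times)
    n, m = model.n_species, model.n_reactions
    raw = np.zeros((len(times), n, m))
    flagged = np.zeros((len(times), n, m), dtype=bool)
    for j in range(m):
        kj = params[j]
        if kj == 0.0:
            continue
        h = delta * kj
        up, dn = params.copy(), params.copy()
        up[j] += h
        dn[j] -= h
        try:
            y_up = simulate_deterministic(model, up, settings, t_eval=times).states
            y_dn = simulate_deterministic(model, dn, settings, t_eval=times).states
        except Exception:
            flagged[:, :, j] = True
            raw[:, :, j] = np.nan
            continue
        dxdk = (y_up - y_dn) / (2.0 * h)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = dxdk * kj / base.states
        s[np.abs(base.states) < ABS_FLOOR] = 0.0
        raw[:, :, j] = s
    return raw, flagged, base


def local_sensitivities(
    model: NetworkModel,
    params=None,
    times=(1.0, 10.0, 20.0),
    delta: float = DEFAULT_DELTA,
    settings: SimulationSettings | None = None,
) -> list[SensitivityMatrix]:
    """One normalized sensitivity matrix per requested time point."""
    if params is None:
        params = model.parameter_vector()
    settings = settings or SimulationSettings()
    raw, flagged, _ = _scaled_fd(model, params, times, delta, settings)
    rows = [s.id for s in model.species]
    cols = model.parameter_ids
    out = []
    for i, t in enumerate(np.atleast_1d(times)):
        out.append(
            SensitivityMatrix(rows, cols, _normalize(raw[i]), raw[i], f"day {t:g}", flagged[i])
        )
    return out


def time_averaged_sensitivities(
    model: NetworkModel,
    params=None,
    window: tuple[float, float] = (0.0, 21.0),
    delta: float = DEFAULT_DELTA,
    settings: SimulationSettings | None = None,
    grid_size: float | None = None,
) -> SensitivityMatrix:
    """Raw scaled sensitivities averaged over the uniform reporting grid."""
    if params is None:
        params = model.parameter_vector()
    settings = settings or SimulationSettings()
    step = grid_size or settings.interval_size
    n = int(round((window[1] - window[0]) / step))
    times = window[0] + step * np.arange(n + 1)
    raw, flagged, _ = _scaled_fd(model, params, times, delta, settings)
    mean_raw = np.nanmean(raw, axis=0)
    return SensitivityMatrix(
        [s.id for s in model.species],
        model.parameter_ids,
        _normalize(mean_raw),
        mean_raw,
        "averaged",
        flagged.any(axis=0),
    )


def rate_factor_timecourses(
    model: NetworkModel,
    params=None,
    param_id: str = "k33",
    factors=(0.5, 1.0, 1.5),
    settings: SimulationSettings | None = None,
) -> dict[float, Trajectory]:
    """One full simulation per multiplicative factor on one rate constant."""
    if params is None:
        params = model.parameter_vector()
    params = np.asarray(params, dtype=float)
    if np.any(np.asarray(factors) <= 0):
        raise ValueError("factors must be positive")
    settings = settings or SimulationSettings()
    j = model.reaction_index[param_id]
    out = {}
    for f in factors:
        p = params.copy()
        p[j] *= f
        out[float(f)] = simulate_deterministic(model, p, settings)
    return out


def variational_sensitivities(
    model: NetworkModel,
    params=None,
    times=(1.0,),
    rel_tol: float = 1e-8,
    abs_tol: float = 1e-10,
) -> np.ndarray:
    """Exact scaled sensitivities from the forward variational equations.

    Integrates ``dS/dt = J_x S + J_k`` alongside the state and returns the
    scaled sensitivities ``(n_times, n_species, n_params)``.  Independent
    oracle for the finite-difference path; O(n*(m+1)) state size, intended
    for small test models.
    """
    if params is None:
        params = model.parameter_vector()
    params = np.asarray(params, dtype=float)
    times = np.asarray(times, dtype=float)
    f_num, jx_num, jk_num = lambdified_system(model)
    n, m = model.n_species, model.n_reactions

    def rhs(t, z, levels):
        xv = z[:n]
        S = z[n:].reshape(n, m)
        fx = f_num(xv, params, levels)
        dS = jx_num(xv, params, levels) @ S + jk_num(xv, params, levels)
        return np.concatenate([fx, dS.ravel()])

    z = np.concatenate([model.initial_state(), np.zeros(n * m)])
    out = np.zeros((len(times), n, m))
    filled = np.zeros(len(times), dtype=bool)
    duration = float(np.max(times))
    if times.min() == 0.0:
        out[times == 0.0] = 0.0
        filled[times == 0.0] = True
    for a, b, levels in _segments(model, duration):
        mask = (~filled) & (times > a + 1e-15) & (times <= b + 1e-15)
        seg_eval = times[mask]
        sol = solve_ivp(rhs, (a, b), z, method="LSODA",
                        t_eval=seg_eval if seg_eval.size else None,
                        rtol=rel_tol, atol=abs_tol, args=(levels,))
        if not sol.success:
            raise RuntimeError(f"variational integration failed: {sol.message}")
        if seg_eval.size:
            for idx_local, idx in enumerate(np.nonzero(mask)[0]):
                zz = sol.y[:, idx_local]
                xv = zz[:n]
                S = zz[n:].reshape(n, m)
                with np.errstate(divide="ignore", invalid="ignore"):
                    scaled = S * params[None, :] / xv[:, None]
                scaled[np.abs(xv) < ABS_FLOOR] = 0.0
                out[idx] = scaled
            filled[mask] = True
        z = sol.y[:, -1] if sol.y.size else z
    return out
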