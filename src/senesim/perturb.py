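"""In-silico interventions: initial-amount scaling, calibrated dynamic
modulators, and 1D/2D dose-response scans.

Species without turnover (the conserved activation/inactivation pools of
mTORC1, Akt and AMPK) are perturbed by scaling the initial amounts of both
states.  Species with turnover (ROS, FoxO3a, Mitophagy) are perturbed
throughout the time course by a dummy modulator species feeding a
mass-action source (activator) or sink (inhibitor) on the target; the
modulator amount is calibrated by bisection so that the window-averaged
level of the target reaches a prescribed fraction of its control average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import NetworkModel, ReactionDef, SpeciesDef
from .simulate import SimulationSettings, Trajectory, simulate_deterministic

__all__ = [
    "PerturbationSpec",
    "ScanResult",
    "InvalidModeError",
    "CalibrationError",
    "resolve_target",
    "apply_initial_scaling",
    "add_modulator",
    "calibrate_modulator",
    "dose_response_scan",
    "double_perturbation_scan",
]

#: Conserved-pool targets (perturbed by initial scaling) by familiar name.
SCALING_TARGETS = {"mTORC1": "mTORC1", "Akt": "Akt", "AMPK": "AMPK"}

#: Turned-over targets (perturbed by a dynamic modulator): species id of the
#: activation readout used for calibration.
MODULATOR_TARGETS = {"ROS": "X14", "FoxO3a": "X8", "Mitophagy": "X19"}

MODULATOR_RATE_CONSTANT = 1.0  # fixed gauge; only the amount is calibrated


class InvalidModeError(ValueError):
    """Perturbation mode incompatible with the target's turnover."""


class CalibrationError(RuntimeError):
    """Modulator calibration could not reach the requested average ratio."""

    def __init__(self, message: str, achieved_ratio: float):
        super().__init__(message)
        self.achieved_ratio = achieved_ratio


@dataclass
class PerturbationSpec:
    """One intervention: which target, which mechanism, how strong.

    ``level`` is the fractional intervention strength: 0 is the control,
    positive levels inhibit (scale 1-level / average ratio 1-level) when
    ``direction`` is "inhibit" and over-activate (scale or ratio 1+level)
    when it is "activate".
    """

    target: str
    mode: str  # "initial-scaling" | "dynamic-modulator"
    level: float = 0.0
    direction: str = "inhibit"
    modulator_rate_constant: float = MODULATOR_RATE_CONSTANT
    modulator_amount: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("initial-scaling", "dynamic-modulator"):
            raise ValueError(f"unknown perturbation mode {self.mode!r}")
        if self.direction not in ("inhibit", "activate"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.mode == "initial-scaling" and self.target not in SCALING_TARGETS:
            raise InvalidModeError(
                f"{self.target!r} has turnover; initial scaling applies only to "
                f"{sorted(SCALING_TARGETS)} (use a dynamic modulator)"
            )
        if self.mode == "dynamic-modulator" and self.target not in MODULATOR_TARGETS:
            raise InvalidModeError(
                f"{self.target!r} has no turnover; dynamic modulators apply only to "
                f"{sorted(MODULATOR_TARGETS)} (scale the initial amounts instead)"
            )

    def scale_factor(self) -> float:
        return 1.0 - self.level if self.direction == "inhibit" else 1.0 + self.level


@dataclass
class ScanResult:
    """Readout values on a 1D or 2D grid of intervention levels."""

    levels: tuple[np.ndarray, ...]  # one array per scan axis
    axis_names: tuple[str, ...]
    readouts: list[str]
    days: list[float]
    values: np.ndarray  # shape (*grid, n_readouts, n_days)
    control: np.ndarray  # shape (n_readouts, n_days)


def resolve_target(model: NetworkModel, name: str) -> list[str]:
    """Species ids belonging to a named perturbation target."""
    if name in SCALING_TARGETS:
        pair = SCALING_TARGETS[name]
        sids = [s.id for s in model.species if s.conserved_pair_id == pair]
        if not sids:
            raise KeyError(f"model has no conserved pair {pair!r}")
        return sids
    if name in MODULATOR_TARGETS:
        return [MODULATOR_TARGETS[name]]
    # fall back: direct species id
    if name in model.species_index:
        return [name]
    raise KeyError(f"unknown perturbation target {name!r}")


def apply_initial_scaling(
    model: NetworkModel, targets: str | list[str], fraction: float, direction: str = "inhibit"
) -> NetworkModel:
    """Scale both activation states of each conserved-pool target.

    ``fraction`` is the intervention level (0 = control); amounts are scaled
    by ``1 - fraction`` (inhibition) or ``1 + fraction`` (over-activation).
    """
    if isinstance(targets, str):
        targets = [targets]
    for t in targets:
        if t not in SCALING_TARGETS:
            raise InvalidModeError(f"{t!r} has turnover; initial scaling not applicable")
    factor = 1.0 - fraction if direction == "inhibit" else 1.0 + fraction
    if factor < 0:
        raise ValueError("scaling would produce negative amounts")
    out = model.copy()
    sids = {sid for t in targets for sid in resolve_target(model, t)}
    for s in out.species:
        if s.id in sids:
            s.initial_amount *= factor
    return NetworkModel(
        out.species, out.reactions, out.inputs, out.observables, out.constraints,
        out.fixed_parameter_ids, out.name,
    )


def add_modulator(
    model: NetworkModel,
    target: str,
    amount: float,
    direction: str = "inhibit",
    rate_constant: float = MODULATOR_RATE_CONSTANT,
) -> NetworkModel:
    """Attach a dummy modulator species acting on a turned-over target.

    The modulator is a constant-amount species entering a mass-action sink
    (``target -> 0``, inhibitor) or source (``0 -> target``, activator) as a
    multiplicative modifier.
    """
    if target not in MODULATOR_TARGETS:
        raise InvalidModeError(f"{target!r} is not a dynamic-modulator target")
    sid = MODULATOR_TARGETS[target]
    out = model.copy()
    mod_id = f"MOD_{target}"
    out.species.append(SpeciesDef(mod_id, f"{target} modulator", float(amount), "oxidative-stress"))
    if direction == "inhibit":
        rxn = ReactionDef(f"kmod_{target}", {sid: 1}, {}, (mod_id,), rate_constant,
                          f"{target} modulator sink")
    else:
        rxn = ReactionDef(f"kmod_{target}", {}, {sid: 1}, (mod_id,), rate_constant,
                          f"{target} modulator source")
    out.reactions.append(rxn)
    return NetworkModel(
        out.species, out.reactions, out.inputs, out.observables, out.constraints,
        out.fixed_parameter_ids, out.name,
    )


def _window_average(traj: Trajectory, sid: str, window: tuple[float, float]) -> float:
    mask = (traj.times >= window[0]) & (traj.times <= window[1])
    return float(traj.state(sid)[mask].mean())


def calibrate_modulator(
    model: NetworkModel,
    target: str,
    desired_avg_ratio: float,
    window: tuple[float, float] = (1.0, 21.0),
    settings: SimulationSettings | None = None,
    tolerance: float = 0.01,
    max_amount: float = 1e6,
) -> float:
    """Modulator amount achieving the requested window-averaged target ratio.

    The achieved ratio ``mean(perturbed)/mean(control)`` is monotone in the
    modulator amount (asserted during the search); bisection stops when it is
    within ``tolerance`` (relative) of ``desired_avg_ratio``.
    """
    if desired_avg_ratio <= 0:
        raise ValueError("desired ratio must be positive")
    if abs(desired_avg_ratio - 1.0) < 1e-12:
        return 0.0
    settings = settings or SimulationSettings(interval_size=0.05)
    direction = "inhibit" if desired_avg_ratio < 1.0 else "activate"
    sid = MODULATOR_TARGETS[target]  # raises KeyError for unknown targets
    control = _window_average(simulate_deterministic(model, settings=settings), sid, window)

    def achieved(amount: float) -> float:
        pert = add_modulator(model, target, amount, direction)
        return _window_average(simulate_deterministic(pert, settings=settings), sid, window) / control

    sign = -1.0 if direction == "inhibit" else 1.0  # ratio decreases/increases with amount
    lo, r_lo = 0.0, 1.0
    hi = 1.0
    r_hi = achieved(hi)
    while sign * (r_hi - desired_avg_ratio) < 0:
        if hi >= max_amount:
            raise CalibrationError(
                f"ratio {desired_avg_ratio} unreachable within amount bounds "
                f"(achieved {r_hi:.4f} at amount {hi})",
                r_hi,
            )
        lo, r_lo = hi, r_hi
        hi *= 4.0
        r_hi = achieved(hi)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        r_mid = achieved(mid)
        if not (min(r_lo, r_hi) - 1e-9 <= r_mid <= max(r_lo, r_hi) + 1e-9):
            raise AssertionError("achieved ratio is not monotone in modulator amount")
        if abs(r_mid - desired_avg_ratio) <= tolerance * desired_avg_ratio:
            return mid
        if sign * (r_mid - desired_avg_ratio) < 0:
            lo, r_lo = mid, r_mid
        else:
            hi, r_hi = mid, r_mid
    raise CalibrationError("bisection did not converge", r_mid)


def _apply_spec(model: NetworkModel, spec: PerturbationSpec, level: float,
                settings: SimulationSettings | None = None,
                calibration_model: NetworkModel | None = None,
                amount: float | None = None) -> NetworkModel:
    """Model realising ``spec`` at the given level (0 = exact control copy).

    Modulator amounts are calibrated against ``calibration_model`` (the
    unperturbed control by default) unless ``amount`` is given.
    """
    if level == 0.0:
        return model.copy()
    if spec.mode == "initial-scaling":
        return apply_initial_scaling(model, spec.target, level, spec.direction)
    if amount is None:
        ratio = 1.0 - level if spec.direction == "inhibit" else 1.0 + level
        amount = calibrate_modulator(calibration_model or model, spec.target, ratio,
                                     settings=settings)
    return add_modulator(model, spec.target, amount, spec.direction, spec.modulator_rate_constant)


def _readout_matrix(traj: Trajectory, readouts: list[str], days: list[float]) -> np.ndarray:
    out = np.empty((len(readouts), len(days)))
    for i, r in enumerate(readouts):
        series = traj.observable(r) if r in traj.observable_names else traj.state(r)
        for j, d in enumerate(days):
            out[i, j] = series[traj.at_time(d)]
    return out


def dose_response_scan(
    model: NetworkModel,
    spec: PerturbationSpec,
    levels,
    readouts: list[str],
    days: list[float],
    settings: SimulationSettings | None = None,
) -> ScanResult:
    """One simulation per intervention level; readouts reported at ``days``.

    ``levels`` must be sorted ascending with the control (0) first.
    """
    levels = np.asarray(levels, dtype=float)
    if levels[0] != 0.0 or np.any(np.diff(levels) <= 0):
        raise ValueError("levels must start at 0 and increase")
    settings = settings or SimulationSettings(interval_size=0.05)
    values = np.empty((len(levels), len(readouts), len(days)))
    for i, lv in enumerate(levels):
        try:
            pert = _apply_spec(model, spec, float(lv), settings)
            traj = simulate_deterministic(pert, settings=settings)
        except Exception as exc:
            raise RuntimeError(f"scan failed at level {lv}: {exc}") from exc
        values[i] = _readout_matrix(traj, readouts, days)
    return ScanResult((levels,), (spec.target,), list(readouts), list(days), values, values[0].copy())


def double_perturbation_scan(
    model: NetworkModel,
    spec_a: PerturbationSpec,
    spec_b: PerturbationSpec,
    readouts: list[str],
    days: list[float],
    levels_a=None,
    levels_b=None,
    step_a: float | None = None,
    step_b: float | None = None,
    max_level_a: float = 0.9,
    max_level_b: float = 0.9,
    settings: SimulationSettings | None = None,
) -> ScanResult:
    """Full 2D grid over two interventions; grid point (0, 0) is the control."""
    if levels_a is None:
        levels_a = np.arange(0.0, max_level_a + 1e-9, step_a)
    if levels_b is None:
        levels_b = np.arange(0.0, max_level_b + 1e-9, step_b)
    levels_a = np.asarray(levels_a, dtype=float)
    levels_b = np.asarray(levels_b, dtype=float)
    settings = settings or SimulationSettings(interval_size=0.05)
    values = np.empty((len(levels_a), len(levels_b), len(readouts), len(days)))
    # modulator amounts are calibrated once per level against the control
    amounts_b: list[float | None] = []
    for b in levels_b:
        if spec_b.mode == "dynamic-modulator" and b > 0:
            ratio = 1.0 - b if spec_b.direction == "inhibit" else 1.0 + b
            amounts_b.append(calibrate_modulator(model, spec_b.target, ratio, settings=settings))
        else:
            amounts_b.append(None)
    models_a = [_apply_spec(model, spec_a, float(a), settings, calibration_model=model)
                for a in levels_a]
    for i, ma in enumerate(models_a):
        for j, b in enumerate(levels_b):
            try:
                mab = _apply_spec(ma, spec_b, float(b), settings, amount=amounts_b[j])
                traj = simulate_deterministic(mab, settings=settings)
            except Exception as exc:
                raise RuntimeError(f"scan failed at level ({levels_a[i]}, {b}): {exc}") from exc
            values[i, j] = _readout_matrix(traj, readouts, days)
    return ScanResult(
        (levels_a, levels_b),
        (spec_a.target, spec_b.target),
        list(readouts),
        list(days),
        values,
        values[0, 0].copy(),
    )
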