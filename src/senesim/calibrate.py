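"""Chi-square scoring, multistart bounded fitting, and CC/CV identifiability.

The objective is the weighted sum of squared residuals between observed
time-course means and simulated observables under a relative error model
(default 10% of the observed mean).  Fitting runs in log10 parameter space
with a trust-region least-squares solver inside the bounds [1e-6, 1e4];
multistart sequences restart from the current best fit randomised with a
configurable disturbance strength, the strategy used to explore the
parameter space while limiting non-convergent solutions.

Practical identifiability uses the proxy adopted throughout: on the best
fraction of all fits, a parameter is flagged non-identifiable when it
belongs to a tuple of related parameters with pairwise correlation
coefficient above 0.9 and its coefficient of variation exceeds 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .network import NetworkModel, PARAM_BOUNDS
from .simulate import SimulationSettings, simulate_deterministic

__all__ = [
    "Dataset",
    "ErrorModel",
    "FitConfig",
    "FitResult",
    "FitEnsemble",
    "IdentifiabilityReport",
    "chi_square",
    "aic",
    "multistart_fit",
    "fit_rounds",
    "identifiability_report",
    "read_dataset",
    "write_dataset",
]

DATASET_COLUMNS = ["time", "observable", "mean", "sd", "n"]


@dataclass
class Dataset:
    """Observable time-course records: (observable, time, mean, sd, n)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DATASET_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"dataset missing columns {missing}")
        if (self.records["sd"] < 0).any():
            raise ValueError("sd must be >= 0")
        if (self.records["n"] < 1).any():
            raise ValueError("replicate count must be >= 1")

    @property
    def n_points(self) -> int:
        return len(self.records)

    def times(self) -> np.ndarray:
        return np.unique(self.records["time"].to_numpy(dtype=float))

    def observables(self) -> list[str]:
        return sorted(self.records["observable"].unique())


def write_dataset(dataset: Dataset, path: str) -> None:
    """Write the tab-delimited layout (time, observable, mean, StdCol, n)."""
    df = dataset.records.loc[:, DATASET_COLUMNS].rename(columns={"sd": "StdCol"})
    df.to_csv(path, sep="\t", index=False)


def read_dataset(path: str) -> Dataset:
    df = pd.read_csv(path, sep="\t")
    if "StdCol" in df.columns:
        df = df.rename(columns={"StdCol": "sd"})
    return Dataset(df.loc[:, DATASET_COLUMNS])


@dataclass
class ErrorModel:
    """Relative measurement error: sigma = max(fraction * |mean|, floor)."""

    relative_fraction: float = 0.10
    floor: float = 1e-6

    def sigma(self, means: np.ndarray) -> np.ndarray:
        return np.maximum(self.relative_fraction * np.abs(means), self.floor)


def _observable_lookup(model: NetworkModel) -> dict[str, int]:
    table = {}
    for j, o in enumerate(model.observables):
        table[o.id] = j
        table[o.name] = j
    return table


def _residuals(
    model: NetworkModel,
    params: np.ndarray,
    dataset: Dataset,
    error_model: ErrorModel,
    settings: SimulationSettings,
    penalties: bool,
) -> np.ndarray:
    times = dataset.times()
    if times[0] > 0:
        times = np.concatenate([[0.0], times])
    traj = simulate_deterministic(model, params, settings, t_eval=times)
    lookup = _observable_lookup(model)
    t_index = {t: i for i, t in enumerate(traj.times)}
    rec = dataset.records
    try:
        cols = np.array([lookup[o] for o in rec["observable"]])
    except KeyError as exc:
        raise KeyError(f"dataset references unknown observable {exc.args[0]!r}") from exc
    rows = np.array([t_index[float(t)] for t in rec["time"]])
    sim = traj.observables[rows, cols]
    means = rec["mean"].to_numpy(dtype=float)
    res = (means - sim) / error_model.sigma(means)
    if penalties and model.constraints:
        pvec = {pid: params[model.reaction_index[pid]] for pid in model.parameter_ids}
        pens = []
        for c in model.constraints:
            small, large = c.expression
            pens.append(np.sqrt(c.penalty_strength) * max(0.0, pvec[small] - pvec[large]))
        res = np.concatenate([res, pens])
    return res


def chi_square(
    model: NetworkModel,
    params=None,
    dataset: Dataset | None = None,
    error_model: ErrorModel | None = None,
    settings: SimulationSettings | None = None,
    penalties: bool = True,
) -> float:
    """Weighted sum of squared residuals (plus constraint penalties)."""
    if dataset is None:
        raise ValueError("dataset is required")
    params = np.asarray(model.parameter_vector() if params is None else params, dtype=float)
    error_model = error_model or ErrorModel()
    settings = settings or SimulationSettings()
    res = _residuals(model, params, dataset, error_model, settings, penalties)
    return float(np.sum(res**2))


def aic(chi2: float, n_free: int) -> float:
    """Akaike information criterion as chi2 + 2 * (free parameters)."""
    return chi2 + 2.0 * n_free


@dataclass
class FitConfig:
    """Multistart protocol configuration."""

    n_sequences: int = 40
    fits_per_sequence: int = 500
    disturbance_strength: float = 0.4  # sd of the log10 start randomisation
    max_iterations: int = 150
    tol_fun: float = 1e-6
    tol_x: float = 1e-6
    seed: int = 1
    error_model: ErrorModel = field(default_factory=ErrorModel)
    settings: SimulationSettings = field(default_factory=SimulationSettings)
    penalties: bool = True


@dataclass
class FitResult:
    """One converged (or stopped) local fit."""

    parameters: dict[str, float]
    chi2: float
    aic: float
    n_points: int
    converged: bool
    sequence: int = 0
    fit_index: int = 0
    start_point: dict[str, float] = field(default_factory=dict)


@dataclass
class FitEnsemble:
    """All fits of a multistart run, with provenance."""

    fits: list[FitResult]
    free_ids: list[str]
    seed: int

    @property
    def best(self) -> FitResult:
        return min(self.fits, key=lambda f: f.chi2)

    def parameter_matrix(self) -> pd.DataFrame:
        rows = [{**f.parameters, "chi2": f.chi2, "sequence": f.sequence} for f in self.fits]
        return pd.DataFrame(rows)


def multistart_fit(
    model: NetworkModel,
    dataset: Dataset,
    free_ids: list[str] | None = None,
    config: FitConfig | None = None,
    start: dict[str, float] | None = None,
) -> FitEnsemble:
    """Multistart bounded trust-region fitting of the free rate constants.

    Every sequence starts from the current best fit, randomised in log10
    space with the configured disturbance strength; all local fits are
    retained for identifiability analysis.
    """
    config = config or FitConfig()
    if free_ids is None:
        free_ids = [pid for pid in model.parameter_ids if pid not in model.fixed_parameter_ids]
    unknown = [p for p in free_ids if p not in model.reaction_index]
    if unknown:
        raise KeyError(f"unknown free parameters {unknown}")
    rng = np.random.default_rng(config.seed)
    base = model.parameter_vector()
    idx = np.array([model.reaction_index[p] for p in free_ids])
    lo, hi = np.log10(PARAM_BOUNDS[0]), np.log10(PARAM_BOUNDS[1])

    start_vec = base.copy()
    if start:
        for pid, v in start.items():
            start_vec[model.reaction_index[pid]] = v
    current = np.log10(np.clip(start_vec[idx], 10**lo, 10**hi))

    def objective(logp: np.ndarray) -> np.ndarray:
        p = base.copy()
        p[idx] = 10**logp
        try:
            return _residuals(model, p, dataset, config.error_model, config.settings,
                              config.penalties)
        except Exception:
            return np.full(dataset.n_points + len(model.constraints), 1e6)

    fits: list[FitResult] = []
    failures = 0
    best_log = current.copy()
    best_chi2 = np.inf
    for seq in range(config.n_sequences):
        for i in range(config.fits_per_sequence):
            if seq == 0 and i == 0:
                x0 = current.copy()
            else:
                x0 = np.clip(best_log + rng.normal(0.0, config.disturbance_strength,
                                                   len(free_ids)), lo, hi)
            try:
                sol = least_squares(
                    objective, x0, bounds=(lo, hi), method="trf",
                    max_nfev=config.max_iterations, ftol=config.tol_fun,
                    xtol=config.tol_x, gtol=None,
                )
            except Exception:
                failures += 1
                continue
            chi2 = float(np.sum(sol.fun**2))
            pdict = {pid: float(10**v) for pid, v in zip(free_ids, sol.x)}
            fits.append(
                FitResult(
                    parameters=pdict,
                    chi2=chi2,
                    aic=aic(chi2, len(free_ids)),
                    n_points=dataset.n_points,
                    converged=bool(sol.status > 0),
                    sequence=seq,
                    fit_index=i,
                    start_point={pid: float(10**v) for pid, v in zip(free_ids, x0)},
                )
            )
            if chi2 < best_chi2:
                best_chi2, best_log = chi2, sol.x.copy()
    if not fits:
        raise RuntimeError(f"all {failures} fits failed; check model and dataset")
    return FitEnsemble(fits, list(free_ids), config.seed)


def fit_rounds(
    model: NetworkModel,
    dataset: Dataset,
    rounds: list[dict],
    config: FitConfig | None = None,
) -> list[tuple[FitEnsemble, "IdentifiabilityReport | None"]]:
    """Iterative fix-and-refit schedule driven by a round list.

    Each round is a dict with optional keys ``freeze`` (parameter ids fixed
    at the current best value from this round on) and ``config`` (overriding
    FitConfig).  Rounds fit all parameters not yet frozen and not globally
    fixed; after each round the best values are written into the working
    model and an identifiability report is attached (None when the ensemble
    is too small).
    """
    config = config or FitConfig()
    frozen: set[str] = set(model.fixed_parameter_ids)
    work = model.copy()
    out = []
    for rnd in rounds:
        frozen |= set(rnd.get("freeze", ()))
        free = [p for p in work.parameter_ids if p not in frozen]
        if not free:
            raise ValueError("no free parameters left to fit")
        ens = multistart_fit(work, dataset, free, rnd.get("config", config))
        best = ens.best
        work = work.with_parameters(best.parameters)
        try:
            report = identifiability_report(ens)
        except ValueError:
            report = None
        out.append((ens, report))
    return out


@dataclass
class IdentifiabilityReport:
    """Per-parameter CV, related-parameter tuples and identifiability flags."""

    cv: dict[str, float]
    tuples: list[tuple[str, ...]]
    max_abs_cc: dict[str, float]
    non_identifiable: dict[str, bool]
    correlations: pd.DataFrame
    n_selected: int

    def flagged(self) -> list[str]:
        return sorted(p for p, f in self.non_identifiable.items() if f)


def identifiability_report(
    ensemble: FitEnsemble,
    top_fraction: float = 0.30,
    cc_threshold: float = 0.9,
    cv_threshold: float = 0.25,
) -> IdentifiabilityReport:
    """CC/CV identifiability proxy on the best fraction of the ensemble.

    Deterministic given the ensemble: parameters are grouped into tuples by
    thresholding pairwise correlations of log10 values; a parameter is
    non-identifiable iff its tuple correlation exceeds ``cc_threshold`` and
    its coefficient of variation exceeds ``cv_threshold``.
    """
    if not ensemble.fits:
        raise ValueError("empty ensemble")
    fits = sorted(ensemble.fits, key=lambda f: f.chi2)
    n_sel = max(int(np.ceil(top_fraction * len(fits))), 1)
    if n_sel < 3:
        raise ValueError(f"only {n_sel} fits selected; need at least 3")
    sel = fits[:n_sel]
    P = pd.DataFrame([f.parameters for f in sel]).loc[:, ensemble.free_ids]
    cv = {}
    for pid in ensemble.free_ids:
        vals = P[pid].to_numpy()
        mean = vals.mean()
        cv[pid] = float(vals.std(ddof=1) / abs(mean)) if mean != 0 else np.inf
    logP = np.log10(np.clip(P.to_numpy(), 1e-300, None))
    with np.errstate(invalid="ignore"):
        C = np.corrcoef(logP.T)
    C = np.nan_to_num(np.atleast_2d(C), nan=0.0)
    corr = pd.DataFrame(C, index=ensemble.free_ids, columns=ensemble.free_ids)

    # tuples: connected components of the |CC| > threshold graph
    ids = ensemble.free_ids
    parent = {p: p for p in ids}

    def find(p):
        while parent[p] != p:
            parent[p] = parent[parent[p]]
            p = parent[p]
        return p

    max_cc = {p: 0.0 for p in ids}
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            c = abs(C[a, b])
            max_cc[ids[a]] = max(max_cc[ids[a]], c)
            max_cc[ids[b]] = max(max_cc[ids[b]], c)
            if c > cc_threshold:
                parent[find(ids[a])] = find(ids[b])
    groups: dict[str, list[str]] = {}
    for p in ids:
        groups.setdefault(find(p), []).append(p)
    tuples = [tuple(sorted(g)) for g in groups.values() if len(g) > 1]

    flags = {
        p: bool(max_cc[p] > cc_threshold and cv[p] > cv_threshold) for p in ids
    }
    return IdentifiabilityReport(cv, sorted(tuples), max_cc, flags, corr, n_sel)
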