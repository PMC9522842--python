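"""Per-patient nonlinear least-squares estimation.

Each patient is fitted independently: the six dimensionless model
parameters plus the unknown initial effector level x1 are chosen to
minimize the sum of squared residuals between the measured normalized
tumor burden and the simulated trajectory started at the first
measurement.  The initial tumor value y1 is taken from the data and is
never a decision variable.

The search is a multistart stochastic global optimization (differential
evolution over log10-transformed parameters, each run finished with a
local gradient polish), mirroring the scatter-search-plus-local-method
strategy customary for this problem class.  Results are deterministic
given the seed.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution, minimize

from .data import PatientRecord
from .model import (
    SEARCH_SOLVER,
    NondimParams,
    PARAM_NAMES,
    ScaleConstants,
    SolverConfig,
    integrate_y,
)

__all__ = ["FitConfig", "FitResult", "GoodnessMetrics", "objective", "fit_patient", "goodness"]

N_DECISION = 7  # six model parameters + x1


@dataclass(frozen=True)
class FitConfig:
    """Bounds, budgets and seeding for the per-patient fit.

    ``lower``/``upper`` bound the decision vector (sigma, rho, eta, mu,
    delta, alpha, x1); the defaults 1e-2 and 1e2 reflect the expectation
    that nondimensionalized values are of order one.  ``max_evals`` and
    ``max_time`` (seconds) are per-start budgets.  The default solver
    profile uses a reduced accuracy safety factor: estimation tolerates
    integration error well below the residual scale, and the search
    evaluates many stiff parameter regions where tight tolerances are
    costly.
    """

    lower: tuple[float, ...] = (1e-2,) * N_DECISION
    upper: tuple[float, ...] = (1e2,) * N_DECISION
    n_starts: int = 5
    max_evals: int = 100_000
    max_time: float = 100.0
    seed: int = 0
    solver: SolverConfig = SEARCH_SOLVER
    penalty: float = 1e12
    target_objective: float = 0.0  # stop multistart early at or below this SSR
    popsize: int = 15              # DE population multiplier

    def __post_init__(self) -> None:
        lo, up = np.asarray(self.lower), np.asarray(self.upper)
        if lo.shape != (N_DECISION,) or up.shape != (N_DECISION,):
            raise ValueError(f"bounds must have length {N_DECISION}")
        if np.any(lo <= 0) or np.any(lo >= up):
            raise ValueError("require 0 < lower < upper for every decision variable")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")

    @property
    def log_bounds(self) -> list[tuple[float, float]]:
        return [
            (np.log10(lo), np.log10(up))
            for lo, up in zip(self.lower, self.upper)
        ]

    @property
    def param_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Bounds restricted to the six model parameters."""
        return np.asarray(self.lower[:6]), np.asarray(self.upper[:6])


class GoodnessMetrics(NamedTuple):
    mae: float
    rmse: float
    r2: float | None


@dataclass
class FitResult:
    """Outcome of one per-patient fit.

    ``objective`` is the SSR on normalized y; ``predicted`` is the fitted
    trajectory evaluated at the record's tau grid (its first element equals
    y1 by construction).  ``success`` is False when every start diverged.
    """

    patient_id: str
    params: NondimParams | None
    x1: float | None
    objective: float
    predicted: np.ndarray | None
    metrics: GoodnessMetrics | None
    n_evals: int
    starts_used: int
    seed: int
    success: bool = True

    def theta(self) -> np.ndarray:
        if self.params is None:
            raise ValueError("failed fit has no parameters")
        return self.params.as_array()


def _ssr(
    theta: np.ndarray,
    x1: float,
    tau: np.ndarray,
    y_obs: np.ndarray,
    scales: ScaleConstants,
    solver: SolverConfig,
    penalty: float,
) -> float:
    out = integrate_y(theta, x1, y_obs[0], tau, scales, solver)
    if out is None:
        return penalty
    resid = out[:, 1] - y_obs
    return float(resid @ resid)


def objective(
    params: NondimParams,
    x1: float,
    record: PatientRecord,
    cfg: FitConfig = FitConfig(),
    scales: ScaleConstants = ScaleConstants(),
) -> float:
    """Sum of squared residuals on normalized y for one parameter point."""
    if not record.normalized:
        raise ValueError("record must be normalized before fitting")
    return _ssr(params.as_array(), x1, record.tau, record.y, scales, cfg.solver, cfg.penalty)


def goodness(y_obs: Sequence[float], y_pred: Sequence[float]) -> GoodnessMetrics:
    """MAE, RMSE and R^2 of predictions against observations.

    R^2 = 1 - SSR/SST may be negative; it is None (undefined) when the
    observations have zero variance.
    """
    obs = np.asarray(y_obs, dtype=float)
    pred = np.asarray(y_pred, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or len(obs) < 2:
        raise ValueError("need two equal-length 1-D arrays of length >= 2")
    resid = pred - obs
    mae = float(np.mean(np.abs(resid)))
    rmse = float(np.sqrt(np.mean(resid**2)))
    sst = float(np.sum((obs - obs.mean()) ** 2))
    r2 = None if sst == 0 else 1.0 - float(resid @ resid) / sst
    return GoodnessMetrics(mae=mae, rmse=rmse, r2=r2)


def _single_start(
    tau: np.ndarray,
    y_obs: np.ndarray,
    cfg: FitConfig,
    scales: ScaleConstants,
    rng: np.random.Generator,
) -> tuple[float, np.ndarray, int]:
    """One DE run in log10 space; returns (best SSR, best z, n_evals)."""
    state = {"n": 0, "best": np.inf, "t0": time.monotonic()}

    def func(z: np.ndarray) -> float:
        state["n"] += 1
        val = _ssr(10.0**z[:6], 10.0 ** z[6], tau, y_obs, scales, cfg.solver, cfg.penalty)
        if val < state["best"]:
            state["best"] = val
        return val

    def should_stop(*_args, **_kwargs) -> bool:
        return (
            state["best"] <= cfg.target_objective
            or state["n"] >= cfg.max_evals
            or time.monotonic() - state["t0"] > cfg.max_time
        )

    n_pop = cfg.popsize * N_DECISION
    # reserve part of the budget for local polishing of the best basins
    maxiter = max(2, int(0.8 * cfg.max_evals // n_pop))
    result = differential_evolution(
        func,
        bounds=cfg.log_bounds,
        maxiter=maxiter,
        popsize=cfg.popsize,
        init="sobol",
        mutation=(0.3, 1.0),
        recombination=0.8,
        tol=1e-8,
        seed=rng,
        polish=False,
        callback=should_stop,
    )
    best_val, best_z = float(result.fun), np.asarray(result.x)

    # polish the best population members; distinct members usually sit in
    # distinct basins of this multimodal landscape
    order = np.argsort(result.population_energies)
    starts_z = [result.population[i] for i in order[:6]]
    polished: list[np.ndarray] = [best_z]
    for z0 in starts_z:
        if state["best"] <= cfg.target_objective or should_stop():
            break
        if any(np.linalg.norm(z0 - zp) < 0.3 for zp in polished):
            continue
        loc = minimize(
            func,
            z0,
            method="L-BFGS-B",
            bounds=cfg.log_bounds,
            options={"maxfun": max(200, cfg.max_evals // 20)},
        )
        polished.append(np.asarray(loc.x))
        if loc.fun < best_val:
            best_val, best_z = float(loc.fun), np.asarray(loc.x)
    return best_val, best_z, state["n"]


def fit_patient(
    record: PatientRecord,
    cfg: FitConfig = FitConfig(),
    scales: ScaleConstants = ScaleConstants(),
) -> FitResult:
    """Fit one patient's trajectory; best of ``n_starts`` global searches.

    Requires a normalized record with at least three measurements.  The
    multistart seed schedule is prefix-stable: increasing ``n_starts``
    re-runs the same first starts and can only improve the best objective.
    """
    if not record.normalized:
        raise ValueError("record must be normalized before fitting")
    if len(record) < 3:
        raise ValueError("need at least three measurements to fit")

    tau, y_obs = record.tau, record.y
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_starts)

    best_val, best_z, total_evals, starts = np.inf, None, 0, 0
    for child in children:
        val, z, n_evals = _single_start(tau, y_obs, cfg, scales, np.random.default_rng(child))
        total_evals += n_evals
        starts += 1
        if val < best_val:
            best_val, best_z = val, z
        if best_val <= cfg.target_objective:
            break

    if best_z is None or best_val >= cfg.penalty:
        return FitResult(
            patient_id=record.patient_id,
            params=None,
            x1=None,
            objective=cfg.penalty,
            predicted=None,
            metrics=None,
            n_evals=total_evals,
            starts_used=starts,
            seed=cfg.seed,
            success=False,
        )

    theta = np.clip(10.0 ** best_z[:6], cfg.lower[:6], cfg.upper[:6])
    x1 = float(np.clip(10.0 ** best_z[6], cfg.lower[6], cfg.upper[6]))
    out = integrate_y(theta, x1, y_obs[0], tau, scales, cfg.solver)
    predicted = out[:, 1]
    predicted[0] = y_obs[0]
    resid = predicted - y_obs
    return FitResult(
        patient_id=record.patient_id,
        params=NondimParams.from_array(theta),
        x1=x1,
        objective=float(resid @ resid),
        predicted=predicted,
        metrics=goodness(y_obs, predicted),
        n_evals=total_evals,
        starts_used=starts,
        seed=cfg.seed,
    )


def fit_to_dict(fit: FitResult) -> dict:
    """JSON-serializable record of one fit."""
    d = {
        "patient_id": fit.patient_id,
        "objective": fit.objective,
        "x1": fit.x1,
        "n_evals": fit.n_evals,
        "starts_used": fit.starts_used,
        "seed": fit.seed,
        "success": fit.success,
    }
    if fit.params is not None:
        d.update({name: getattr(fit.params, name) for name in PARAM_NAMES})
    if fit.metrics is not None:
        d.update({"mae": fit.metrics.mae, "rmse": fit.metrics.rmse, "r2": fit.metrics.r2})
    return d


def fits_to_table(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Flat per-patient summary table of fit results."""
    return pd.DataFrame([fit_to_dict(f) for f in fits])


def save_fits_json(fits: Sequence[FitResult], path) -> None:
    with open(path, "w") as fh:
        json.dump([fit_to_dict(f) for f in fits], fh, indent=1)
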