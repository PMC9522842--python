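"""Global practical identifiability via feasible-set bounding boxes.

A parameter vector is epsilon-feasible for a fitted patient when its
predicted trajectory (with x1 fixed at the fitted value) stays within a
relative tolerance epsilon of the optimal fit's predictions at every
measurement time.  The smallest axis-aligned box containing this feasible
set is approximated by solving, for each of the six parameters, a
constrained search for its extremal feasible value.  A wide box edge means
many parameter values fit the data equally well (practically
non-identifiable); a narrow edge means the value is pinned down.  No
identifiability cutoff is imposed: box widths are reported and callers
judge qualitatively.

Every returned extremal point is re-verified by an independent feasibility
check; if the optimizer's point fails the check it is contracted toward
the fitted optimum (which is feasible by construction) until it passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import time
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution

from .data import PatientRecord
from .fitting import FitConfig, FitResult
from .model import SEARCH_SOLVER, NondimParams, PARAM_NAMES, ScaleConstants, SolverConfig, integrate_y

__all__ = [
    "IdentConfig",
    "ParameterBox",
    "is_feasible",
    "bound_parameter",
    "parameter_box",
    "range_frequency",
]


@dataclass(frozen=True)
class IdentConfig:
    """Settings for the feasible-set box computation.

    ``epsilon`` is the allowed relative deviation of predictions from the
    optimal fit (0.20 = 20%).  ``max_evals``/``max_time`` budget each of
    the 12 extremal searches.  ``constraint_tol`` is the absolute slack
    granted when re-verifying feasibility of returned points.
    """

    epsilon: float = 0.20
    constraint_tol: float = 1e-5
    max_evals: int = 5000
    max_time: float = 100.0
    seed: int = 0
    solver: SolverConfig = SEARCH_SOLVER
    popsize: int = 12

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


@dataclass
class ParameterBox:
    """Axis-aligned approximation of the epsilon-feasible parameter set.

    ``arg_min``/``arg_max`` hold the feasible parameter vectors realizing
    each edge; they can seed the search at a larger epsilon so that boxes
    nest by construction.
    """

    patient_id: str
    pmin: np.ndarray          # per-parameter lower edge
    pmax: np.ndarray          # per-parameter upper edge
    popt: np.ndarray          # the fitted optimum (always inside)
    epsilon: float
    arg_min: list | None = None   # 6 parameter vectors
    arg_max: list | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pmin = np.asarray(self.pmin, dtype=float)
        self.pmax = np.asarray(self.pmax, dtype=float)
        self.popt = np.asarray(self.popt, dtype=float)

    def widths(self) -> np.ndarray:
        return self.pmax - self.pmin

    def contains(self, theta: Sequence[float], tol: float = 0.0) -> bool:
        th = np.asarray(theta, dtype=float)
        return bool(np.all(th >= self.pmin - tol) and np.all(th <= self.pmax + tol))


def _deviation(
    theta: np.ndarray,
    fit: FitResult,
    record: PatientRecord,
    scales: ScaleConstants,
    solver: SolverConfig,
) -> float:
    """Worst normalized constraint violation margin of a parameter point.

    Returns max_i (|y_i - y_opt_i| - eps*y_opt_i) rescaled so feasibility
    is margin <= eps; infinity when the simulation diverges.
    """
    out = integrate_y(theta, fit.x1, record.y[0], record.tau, scales, solver)
    if out is None:
        return np.inf
    return float(np.max(np.abs(out[:, 1] - fit.predicted) / fit.predicted))


def is_feasible(
    params: NondimParams | np.ndarray,
    fit: FitResult,
    record: PatientRecord,
    eps: float,
    scales: ScaleConstants = ScaleConstants(),
    solver: SolverConfig = SEARCH_SOLVER,
    tol: float = 0.0,
) -> bool:
    """True iff predictions at ``params`` (x1 fixed at the fitted value)
    deviate from the optimal predictions by at most ``eps`` relative at
    every measurement time (with absolute slack ``tol``)."""
    theta = params.as_array() if isinstance(params, NondimParams) else np.asarray(params)
    out = integrate_y(theta, fit.x1, record.y[0], record.tau, scales, solver)
    if out is None:
        return False
    return bool(np.all(np.abs(out[:, 1] - fit.predicted) <= eps * fit.predicted + tol))


def _contract_to_feasible(
    z_cand: np.ndarray,
    z_opt: np.ndarray,
    fit: FitResult,
    record: PatientRecord,
    eps: float,
    scales: ScaleConstants,
    solver: SolverConfig,
    tol: float,
    n_bisect: int = 30,
) -> np.ndarray:
    """Contract a candidate toward the (feasible) optimum until feasible.

    Bisects along the log-space segment between candidate and optimum and
    returns the feasible point closest to the candidate."""
    if is_feasible(10.0**z_cand, fit, record, eps, scales, solver, tol):
        return z_cand
    lo, hi = 0.0, 1.0  # fraction of the way back toward z_opt
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        z_mid = (1 - mid) * z_cand + mid * z_opt
        if is_feasible(10.0**z_mid, fit, record, eps, scales, solver, tol):
            hi = mid
        else:
            lo = mid
    return (1 - hi) * z_cand + hi * z_opt


def bound_parameter(
    record: PatientRecord,
    fit: FitResult,
    k: int,
    direction: str,
    cfg: IdentConfig = IdentConfig(),
    fit_cfg: FitConfig = FitConfig(),
    scales: ScaleConstants = ScaleConstants(),
    free_indices: Sequence[int] | None = None,
    seed_points: Sequence[np.ndarray] = (),
) -> tuple[float, np.ndarray, bool]:
    """Extremal feasible value of parameter ``k`` (0-based) in one direction.

    Minimizes or maximizes the k-th parameter over the estimation bounds
    subject to the epsilon-deviation constraints, via a penalized global
    search in log10 space seeded with the fitted optimum.  ``free_indices``
    restricts which parameters may vary (others stay at the optimum); by
    default all six vary.  ``seed_points`` are extra candidate parameter
    vectors (e.g. extremal points found at a smaller epsilon) injected into
    the initial population and into the final comparison, so results can
    only improve on any feasible seed.  Returns ``(value, point, warned)``
    where ``point`` is a feasible parameter vector attaining ``value`` and
    ``warned`` flags a fallback to a contracted (conservative) point.
    """
    if direction not in ("min", "max"):
        raise ValueError("direction must be 'min' or 'max'")
    if not 0 <= k <= 5:
        raise ValueError("parameter index k must be in 0..5")
    free = list(range(6)) if free_indices is None else sorted(free_indices)
    if k not in free:
        raise ValueError("k must be among the free indices")

    z_opt = np.log10(fit.theta())
    lo6, up6 = fit_cfg.param_bounds
    zlo, zup = np.log10(lo6), np.log10(up6)
    sign = 1.0 if direction == "min" else -1.0
    eps, tol = cfg.epsilon, cfg.constraint_tol
    pos = free.index(k)
    # penalty scale: a full-range move in z_k is ~4 decades, so violations
    # must dominate by a large margin
    pen_w = 1e3 * float(np.max(zup - zlo))

    def expand(z_free: np.ndarray) -> np.ndarray:
        theta = z_opt.copy()
        theta[free] = z_free
        return theta

    state = {"n": 0, "t0": time.monotonic()}

    def func(z_free: np.ndarray) -> float:
        state["n"] += 1
        dev = _deviation(10.0 ** expand(z_free), fit, record, scales, cfg.solver)
        violation = max(0.0, dev - eps) if np.isfinite(dev) else 10.0
        return sign * z_free[pos] + pen_w * violation

    def should_stop(*_a, **_k) -> bool:
        return state["n"] >= cfg.max_evals or time.monotonic() - state["t0"] > cfg.max_time

    bounds = [(zlo[i], zup[i]) for i in free]
    b_lo = np.array([b[0] for b in bounds])
    b_up = np.array([b[1] for b in bounds])
    n_pop = max(cfg.popsize * len(free), 8)
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, k, 0 if direction == "min" else 1])
    )
    # seed the population with the incumbent optimum, any caller-provided
    # candidate points, and jittered copies of the optimum
    init = rng.uniform(b_lo, b_up, size=(n_pop, len(free)))
    init[0] = z_opt[free]
    z_seeds = [np.log10(np.asarray(sp, dtype=float)) for sp in seed_points]
    for i, zs in enumerate(z_seeds[: n_pop // 4]):
        init[1 + i] = np.clip(zs[free], b_lo, b_up)
    row0 = 1 + min(len(z_seeds), n_pop // 4)
    jitter = rng.normal(scale=0.3, size=(n_pop // 3, len(free)))
    init[row0 : row0 + len(jitter)] = np.clip(z_opt[free] + jitter, b_lo, b_up)
    result = differential_evolution(
        func,
        bounds=bounds,
        init=init,
        maxiter=max(2, int(cfg.max_evals // n_pop)),
        mutation=(0.3, 1.0),
        recombination=0.8,
        tol=1e-10,
        seed=rng,
        polish=False,
        callback=should_stop,
    )
    def push_along_k(z_start: np.ndarray) -> np.ndarray:
        """1-D outward bisection along coordinate k from a feasible point."""
        limit = zlo[k] if direction == "min" else zup[k]
        z_try = z_start.copy()
        z_try[k] = limit
        if is_feasible(10.0**z_try, fit, record, eps, scales, cfg.solver, tol):
            return z_try
        lo_t, hi_t = 0.0, 1.0
        for _ in range(25):
            mid = 0.5 * (lo_t + hi_t)
            z_try[k] = z_start[k] + mid * (limit - z_start[k])
            if is_feasible(10.0**z_try, fit, record, eps, scales, cfg.solver, tol):
                lo_t = mid
            else:
                hi_t = mid
        z_try[k] = z_start[k] + lo_t * (limit - z_start[k])
        return z_try

    z_cand = expand(np.asarray(result.x))
    z_ok = _contract_to_feasible(z_cand, z_opt, fit, record, eps, scales, cfg.solver, tol)
    warned = not np.allclose(z_ok, z_cand)

    # candidates: the pushed search result, the (feasible) optimum, and any
    # feasible caller seeds, each tightened by a 1-D outward push
    candidates = [push_along_k(z_ok), z_opt]
    for zs in z_seeds:
        if is_feasible(10.0**zs, fit, record, eps, scales, cfg.solver, tol):
            candidates.append(push_along_k(zs))
    values = [10.0 ** z[k] for z in candidates]
    best = int(np.argmin(values)) if direction == "min" else int(np.argmax(values))
    z_best = candidates[best]
    value = values[best]
    # the optimum itself is always feasible, so the edge never crosses it
    if direction == "min":
        value = min(value, fit.theta()[k])
    else:
        value = max(value, fit.theta()[k])
    return float(value), 10.0 ** z_best, warned


def parameter_box(
    record: PatientRecord,
    fit: FitResult,
    cfg: IdentConfig = IdentConfig(),
    fit_cfg: FitConfig = FitConfig(),
    scales: ScaleConstants = ScaleConstants(),
    seed_box: ParameterBox | None = None,
) -> ParameterBox:
    """Assemble the 12 extremal solves into a per-patient box.

    ``seed_box`` (typically computed at a smaller epsilon) contributes its
    extremal points as search seeds; since any point feasible at a smaller
    epsilon stays feasible at a larger one, the resulting boxes nest.
    """
    pmin = np.empty(6)
    pmax = np.empty(6)
    arg_min: list = [None] * 6
    arg_max: list = [None] * 6
    warnings_: list[str] = []
    for k in range(6):
        seeds_lo: list = []
        seeds_hi: list = []
        if seed_box is not None and seed_box.arg_min is not None:
            seeds_lo.append(seed_box.arg_min[k])
            seeds_hi.append(seed_box.arg_max[k])
        pmin[k], arg_min[k], w_lo = bound_parameter(
            record, fit, k, "min", cfg, fit_cfg, scales, seed_points=seeds_lo
        )
        pmax[k], arg_max[k], w_hi = bound_parameter(
            record, fit, k, "max", cfg, fit_cfg, scales, seed_points=seeds_hi
        )
        if w_lo or w_hi:
            warnings_.append(f"{PARAM_NAMES[k]}: optimizer point contracted to feasibility")
    return ParameterBox(
        patient_id=fit.patient_id,
        pmin=pmin,
        pmax=pmax,
        popt=fit.theta(),
        epsilon=cfg.epsilon,
        arg_min=arg_min,
        arg_max=arg_max,
        warnings=warnings_,
    )


def nested_boxes(
    record: PatientRecord,
    fit: FitResult,
    epsilons: Sequence[float],
    cfg: IdentConfig = IdentConfig(),
    fit_cfg: FitConfig = FitConfig(),
    scales: ScaleConstants = ScaleConstants(),
) -> dict[float, ParameterBox]:
    """Boxes for several deviation tolerances, nested by construction.

    Epsilons are processed in increasing order; each solve is seeded with
    the extremal points of the previous (tighter) box.
    """
    import dataclasses as _dc

    boxes: dict[float, ParameterBox] = {}
    prev: ParameterBox | None = None
    for eps in sorted(epsilons):
        eps_cfg = _dc.replace(cfg, epsilon=eps)
        prev = parameter_box(record, fit, eps_cfg, fit_cfg, scales, seed_box=prev)
        boxes[eps] = prev
    return boxes


def range_frequency(
    boxes: Sequence[ParameterBox],
    grids: Sequence[np.ndarray] | None = None,
    fit_cfg: FitConfig = FitConfig(),
    points_per_param: int = 200,
) -> pd.DataFrame:
    """Cohort-level frequency of each parameter value being inside a box.

    For each grid value v and parameter, returns the fraction of patients
    whose box satisfies pmin <= v <= pmax — the mean of box indicator
    functions, a histogram-like curve in [0, 1].  Default grids are
    logarithmic over the estimation bounds (they span four decades).
    """
    if not boxes:
        raise ValueError("need at least one box")
    if grids is None:
        lo6, up6 = fit_cfg.param_bounds
        grids = [
            np.logspace(np.log10(lo6[k]), np.log10(up6[k]), points_per_param)
            for k in range(6)
        ]
    rows = []
    for k, name in enumerate(PARAM_NAMES):
        grid = np.asarray(grids[k])
        inside = np.zeros(len(grid))
        for box in boxes:
            inside += (grid >= box.pmin[k]) & (grid <= box.pmax[k])
        freq = inside / len(boxes)
        rows.append(pd.DataFrame({"parameter": name, "grid_value": grid, "frequency": freq}))
    return pd.concat(rows, ignore_index=True)


def boxes_to_table(boxes: Sequence[ParameterBox]) -> pd.DataFrame:
    """Long-format CSV-ready table of box edges."""
    rows = []
    for box in boxes:
        for k, name in enumerate(PARAM_NAMES):
            rows.append(
                {
                    "patient_id": box.patient_id,
                    "parameter": name,
                    "pmin": box.pmin[k],
                    "popt": box.popt[k],
                    "pmax": box.pmax[k],
                    "epsilon": box.epsilon,
                }
            )
    return pd.DataFrame(rows)
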