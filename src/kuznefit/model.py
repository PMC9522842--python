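"""Simplified Kuznetsov tumor-immune dynamics.

The model describes the interaction between cytotoxic effector cells (EC:
CTL and NK cells) and tumor cells (TC).  Conjugate (bound EC-TC complex)
kinetics are eliminated with a quasi-steady-state assumption (QSSA),
``C ~= K*E*T`` with ``K = k1/(k2 + k3 - k_{-1})``, and the resulting
two-state system is nondimensionalized with cell-number scales ``E0`` and
``T0`` and a lumped time scale, giving

    dx/dtau = sigma + rho*x*y/(eta + y) - delta*x - mu*x*y
    dy/dtau = alpha*y - (E0/T0)*x*y

where ``x = E/E0`` and ``y = T/T0``.  The logistic crowding sink of the
original formulation is intentionally absent: growth limitation is carried
entirely by the immune interaction terms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.integrate import odeint, solve_ivp

__all__ = [
    "DimensionalParams",
    "ScaleConstants",
    "NondimParams",
    "StatePoint",
    "Trajectory",
    "SolverConfig",
    "DivergenceError",
    "rhs",
    "qssa_conjugates",
    "nondimensionalize",
    "simulate",
    "tumor_free_equilibrium",
]

PARAM_NAMES = ("sigma", "rho", "eta", "mu", "delta", "alpha")


class DivergenceError(RuntimeError):
    """Raised when an integration fails or the tumor state blows up.

    Callers performing optimization catch this and substitute a finite
    penalty objective.
    """


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class DimensionalParams:
    """Kinetic parameters of the dimensional EC/TC system.

    All rates are non-negative.  ``k2 + k3 > km1`` is required so the QSSA
    constant ``K = k1/(k2 + k3 - km1)`` is positive.
    """

    s: float       # EC influx rate, cells/day
    f: float       # stimulated-accumulation numerator, cells/day
    g: float       # saturation constant, cells
    h: float       # EC elimination rate, 1/day
    a: float       # max TC growth rate, 1/day
    k1: float      # conjugation rate, 1/(cells*day)
    km1: float     # dissociation rate, 1/day
    k2: float      # TC lethal-hit rate, 1/day
    k3: float      # EC inactivation rate, 1/day

    def __post_init__(self) -> None:
        for name in ("s", "f", "g", "h", "a", "k1", "km1", "k2", "k3"):
            v = getattr(self, name)
            _require_finite(name, v)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.k2 + self.k3 <= self.km1:
            raise ValueError(
                "require k2 + k3 > km1 for a positive QSSA constant; got "
                f"k2={self.k2}, k3={self.k3}, km1={self.km1}"
            )

    @property
    def K(self) -> float:
        """QSSA conjugate constant ``k1/(k2 + k3 - km1)``, 1/cells."""
        return self.k1 / (self.k2 + self.k3 - self.km1)


@dataclass(frozen=True)
class ScaleConstants:
    """Scales used for nondimensionalization and LD-to-cell conversion.

    ``time_scale`` is the lumped rate (1/day) mapping clinical time to
    dimensionless time, ``tau = time_scale * t_days``.  The default 0.01/day
    keeps typical trial durations (hundreds of days) at tau of order 1-10.
    """

    E0: float = 1e7                 # effector-cell scale, cells
    T0: float = 1e9                 # tumor-cell scale, cells
    cell_volume: float = 8e-6       # mm^3 per tumor cell
    packing_fraction: float = 0.75  # fraction of lesion volume that is TC
    time_scale: float = 0.01        # 1/day

    def __post_init__(self) -> None:
        for name in ("E0", "T0", "cell_volume", "packing_fraction", "time_scale"):
            v = getattr(self, name)
            _require_finite(name, v)
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if self.packing_fraction > 1:
            raise ValueError(
                f"packing_fraction must be <= 1, got {self.packing_fraction}"
            )

    @property
    def state_ratio(self) -> float:
        """E0/T0, the coupling factor in the tumor equation."""
        return self.E0 / self.T0


@dataclass(frozen=True)
class NondimParams:
    """The six dimensionless parameters (sigma, rho, eta, mu, delta, alpha).

    sigma: baseline effector influx; rho: stimulated effector recruitment;
    eta: recruitment half-saturation in y; mu: effector inactivation by
    tumor contact; delta: effector death/efflux; alpha: intrinsic tumor
    growth rate.
    """

    sigma: float
    rho: float
    eta: float
    mu: float
    delta: float
    alpha: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            _require_finite(name, v)
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "NondimParams":
        if len(values) != 6:
            raise ValueError(f"expected 6 parameter values, got {len(values)}")
        return cls(**dict(zip(PARAM_NAMES, map(float, values))))


class StatePoint(NamedTuple):
    """One point of a nondimensional trajectory: (tau, x, y)."""

    tau: float
    x: float
    y: float


@dataclass(frozen=True)
class Trajectory:
    """A simulated trajectory on a strictly increasing tau grid."""

    tau: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (len(tau) == len(x) == len(y)):
            raise ValueError("tau, x, y must have equal length")
        if len(tau) > 1 and not np.all(np.diff(tau) > 0):
            raise ValueError("tau must be strictly increasing")
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return len(self.tau)

    def points(self) -> list[StatePoint]:
        return [StatePoint(*p) for p in zip(self.tau, self.x, self.y)]


@dataclass(frozen=True)
class SolverConfig:
    """Integrator settings for :func:`simulate`.

    The defaults follow common practice for this model family: a
    stiff-capable variable-step, variable-order method with rtol 1e-3,
    atol 1e-6 and a maximum step of one tenth of the integration span.
    ``rtol``/``atol`` are treated as targets for the *delivered* accuracy
    of the returned samples: because a multistep method's tolerance only
    controls local error, the integrator internally runs at tolerances
    tightened by ``safety`` so that global error stays within the request
    on well-conditioned problems.  ``blowup`` caps the normalized tumor
    burden; states beyond it (or any non-finite state) signal divergence,
    which optimizers map to a penalty.
    """

    rtol: float = 1e-3
    atol: float = 1e-6
    max_step_frac: float = 0.1
    blowup: float = 1e3
    mxstep: int = 5000
    safety: float = 100.0


DEFAULT_SOLVER = SolverConfig()

# profile for optimization inner loops: estimation, feasibility searches and
# envelope solves tolerate integration error orders of magnitude below their
# residual/tolerance scales, and they evaluate many stiff parameter regions
# where the full safety factor is costly
SEARCH_SOLVER = SolverConfig(safety=10.0)


def rhs(
    params: NondimParams,
    scales: ScaleConstants,
    state: StatePoint | tuple[float, float, float],
) -> tuple[float, float]:
    """Right-hand side of the nondimensional model at one state point.

    Returns ``(dx/dtau, dy/dtau)``.
    """
    _, x, y = state
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValueError(f"non-finite state (x={x}, y={y})")
    eta_plus_y = params.eta + y
    if eta_plus_y <= 0:
        raise ValueError("require eta + y > 0")
    dx = params.sigma + params.rho * x * y / eta_plus_y - params.delta * x - params.mu * x * y
    dy = params.alpha * y - scales.state_ratio * x * y
    return dx, dy


def qssa_conjugates(E: float, T: float, dim: DimensionalParams) -> float:
    """Quasi-steady-state EC-TC conjugate count ``C = K*E*T`` (cells)."""
    if E < 0 or T < 0:
        raise ValueError("cell counts must be >= 0")
    return dim.K * E * T


def nondimensionalize(dim: DimensionalParams, scales: ScaleConstants) -> NondimParams:
    """Map dimensional kinetic parameters to the six dimensionless ones.

    sigma = s/(k2*K*E0*T0), rho = f/(k2*T0), eta = g/T0, mu = k3/k2,
    delta = h/(k2*K*T0), alpha = a/(k2*K*T0).
    """
    if dim.k2 == 0:
        raise ValueError("k2 must be > 0 to nondimensionalize")
    K = dim.K
    if K == 0:
        raise ValueError("QSSA constant K must be > 0 (k1 > 0 required)")
    k2K = dim.k2 * K
    return NondimParams(
        sigma=dim.s / (k2K * scales.E0 * scales.T0),
        rho=dim.f / (dim.k2 * scales.T0),
        eta=dim.g / scales.T0,
        mu=dim.k3 / dim.k2,
        delta=dim.h / (k2K * scales.T0),
        alpha=dim.a / (k2K * scales.T0),
    )


def _rhs_ode(state: np.ndarray, tau: float, sigma, rho, eta, mu, delta, alpha, r):
    x, y = state
    xy = x * y
    return (
        sigma + rho * xy / (eta + y) - delta * x - mu * xy,
        alpha * y - r * xy,
    )


def _jac_ode(state: np.ndarray, tau: float, sigma, rho, eta, mu, delta, alpha, r):
    x, y = state
    ey = eta + y
    return (
        (rho * y / ey - delta - mu * y, rho * x * eta / (ey * ey) - mu * x),
        (-r * y, alpha - r * x),
    )


def integrate_y(
    theta: np.ndarray,
    x1: float,
    y1: float,
    tau: np.ndarray,
    scales: ScaleConstants,
    solver: SolverConfig = DEFAULT_SOLVER,
) -> np.ndarray | None:
    """Fast integration returning states at ``tau`` or None on divergence.

    ``theta`` is the parameter vector in (sigma, rho, eta, mu, delta, alpha)
    order.  This is the inner loop of every optimization; it avoids the
    validation and object construction of :func:`simulate`.  Returns an
    array of shape (len(tau), 2) with columns (x, y).
    """
    if len(tau) == 1:
        return np.array([[x1, y1]], dtype=float)
    span = tau[-1] - tau[0]
    hmax = solver.max_step_frac * span if span > 0 else 0.0
    args = (*theta, scales.state_ratio)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out, info = odeint(
            _rhs_ode,
            (x1, y1),
            tau,
            args=args,
            Dfun=_jac_ode,
            rtol=solver.rtol / solver.safety,
            atol=solver.atol / solver.safety,
            hmax=hmax,
            mxstep=solver.mxstep,
            full_output=True,
        )
    if info["message"] != "Integration successful.":
        return None
    if not np.all(np.isfinite(out)):
        return None
    if np.max(np.abs(out[:, 1])) > solver.blowup or np.max(np.abs(out[:, 0])) > 1e6:
        return None
    return out


def simulate(
    params: NondimParams,
    scales: ScaleConstants,
    x1: float,
    y1: float,
    tau_grid: Sequence[float],
    solver: SolverConfig = DEFAULT_SOLVER,
) -> Trajectory:
    """Integrate the model from ``(x1, y1)`` at ``tau_grid[0]``.

    Returns the trajectory sampled exactly at ``tau_grid``.  Raises
    :class:`DivergenceError` if the integrator fails or the state exceeds
    the blow-up cap.
    """
    tau = np.asarray(tau_grid, dtype=float)
    if tau.ndim != 1 or len(tau) < 1:
        raise ValueError("tau_grid must be a non-empty 1-D sequence")
    if len(tau) > 1 and not np.all(np.diff(tau) > 0):
        raise ValueError("tau_grid must be strictly increasing")
    if x1 < 0 or y1 < 0:
        raise ValueError("initial state must be non-negative")
    out = integrate_y(params.as_array(), x1, y1, tau, scales, solver)
    if out is None:
        raise DivergenceError(
            f"integration failed or state exceeded blow-up cap {solver.blowup}"
        )
    return Trajectory(tau=tau, x=out[:, 0], y=out[:, 1])


def reference_simulate(
    params: NondimParams,
    scales: ScaleConstants,
    x1: float,
    y1: float,
    tau_grid: Sequence[float],
    rtol: float = 1e-9,
    atol: float = 1e-11,
) -> Trajectory:
    """Tight-tolerance reference integration (oracle for solver checks).

    Uses an independently implemented stiff scheme (scipy's BDF) at tight
    tolerance rather than the production multistep path.
    """
    tau = np.asarray(tau_grid, dtype=float)
    theta = params.as_array()

    def f(t, state):
        return _rhs_ode(state, t, *theta, scales.state_ratio)

    def jac(t, state):
        return np.array(_jac_ode(state, t, *theta, scales.state_ratio))

    sol = solve_ivp(
        f,
        (tau[0], tau[-1]),
        (x1, y1),
        t_eval=tau,
        method="BDF",
        jac=jac,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise DivergenceError(sol.message)
    return Trajectory(tau=tau, x=sol.y[0], y=sol.y[1])


def tumor_free_equilibrium(
    params: NondimParams, scales: ScaleConstants
) -> tuple[StatePoint, float]:
    """Tumor-free fixed point and the local tumor growth exponent.

    The fixed point is ``(x, y) = (sigma/delta, 0)``; a small tumor seeded
    there initially grows like ``exp((alpha - (E0/T0)*sigma/delta) * tau)``,
    so the sign of the returned exponent predicts escape vs. elimination.
    """
    if params.delta <= 0:
        raise ValueError("delta must be > 0")
    x_eq = params.sigma / params.delta
    exponent = params.alpha - scales.state_ratio * x_eq
    return StatePoint(tau=0.0, x=x_eq, y=0.0), exponent
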