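"""Dynamics, scale conversions and analytic reference points."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kuznefit.model import (
    DimensionalParams,
    DivergenceError,
    NondimParams,
    ScaleConstants,
    SolverConfig,
    StatePoint,
    Trajectory,
    nondimensionalize,
    qssa_conjugates,
    reference_simulate,
    rhs,
    simulate,
    tumor_free_equilibrium,
)

SCALES = ScaleConstants()

log_param = st.floats(min_value=-2.0, max_value=2.0).map(lambda z: 10.0**z)
params_strategy = st.builds(
    NondimParams,
    sigma=log_param, rho=log_param, eta=log_param,
    mu=log_param, delta=log_param, alpha=log_param,
)


def make_params(**kw) -> NondimParams:
    base = dict(sigma=1, rho=1, eta=1, mu=1, delta=1, alpha=1)
    base.update(kw)
    return NondimParams(**base)


class TestRhs:
    def test_hand_evaluated_point(self):
        # sigma + rho*1*1/(1+1) - delta - mu = -0.5; alpha - 0.01 = 0.99
        dx, dy = rhs(make_params(), SCALES, StatePoint(0.0, 1.0, 1.0))
        assert dx == pytest.approx(-0.5)
        assert dy == pytest.approx(0.99)

    @given(params=params_strategy)
    @settings(max_examples=50, deadline=None)
    def test_tumor_free_state_is_fixed_point(self, params):
        x_eq = params.sigma / params.delta
        dx, dy = rhs(params, SCALES, StatePoint(0.0, x_eq, 0.0))
        assert dx == pytest.approx(0.0, abs=1e-12 * max(1.0, x_eq))
        assert dy == 0.0

    @given(params=params_strategy, x=st.floats(0, 1e3))
    @settings(max_examples=50, deadline=None)
    def test_zero_tumor_axis_is_invariant(self, params, x):
        _, dy = rhs(params, SCALES, StatePoint(0.0, x, 0.0))
        assert dy == 0.0

    def test_nonfinite_state_rejected(self):
        with pytest.raises(ValueError):
            rhs(make_params(), SCALES, StatePoint(0.0, np.nan, 1.0))


class TestQssa:
    def test_conjugate_constant_formula(self):
        dim = DimensionalParams(s=1, f=1, g=1, h=1, a=1, k1=2, km1=2, k2=3, k3=1)
        # K = k1/(k2 + k3 - km1) = 2/2 = 1
        assert dim.K == pytest.approx(1.0)
        assert qssa_conjugates(5.0, 3.0, dim) == pytest.approx(15.0)

    @pytest.mark.parametrize("E,T", [(0.0, 7.0), (7.0, 0.0)])
    def test_no_conjugates_without_both_populations(self, E, T):
        dim = DimensionalParams(s=1, f=1, g=1, h=1, a=1, k1=2, km1=2, k2=3, k3=1)
        assert qssa_conjugates(E, T, dim) == 0.0

    def test_fast_dissociation_rejected(self):
        with pytest.raises(ValueError, match="k2"):
            DimensionalParams(s=1, f=1, g=1, h=1, a=1, k1=1, km1=5, k2=3, k3=1)


class TestNondimensionalize:
    def test_parameter_definitions(self):
        dim = DimensionalParams(s=1, f=4, g=SCALES.T0, h=2, a=3, k1=1, km1=0, k2=2, k3=3)
        K = dim.K  # 1/5
        nd = nondimensionalize(dim, SCALES)
        assert nd.mu == pytest.approx(3 / 2)
        assert nd.eta == pytest.approx(1.0)
        assert nd.rho == pytest.approx(4 / (2 * SCALES.T0))
        assert nd.sigma == pytest.approx(1 / (2 * K * SCALES.E0 * SCALES.T0))
        assert nd.delta == pytest.approx(2 / (2 * K * SCALES.T0))
        assert nd.alpha == pytest.approx(3 / (2 * K * SCALES.T0))

    def test_identity_case(self):
        scales = ScaleConstants(E0=1.0, T0=1.0)
        dim = DimensionalParams(s=1, f=1, g=1, h=1, a=1, k1=1, km1=0, k2=1, k3=1e-12)
        nd = nondimensionalize(dim, scales)
        # K = 1 up to the vanishing k3, so sigma = s = 1
        assert nd.sigma == pytest.approx(1.0, rel=1e-9)

    def test_zero_conjugation_rate_rejected(self):
        dim = DimensionalParams(s=1, f=1, g=1, h=1, a=1, k1=0, km1=0, k2=1, k3=1)
        with pytest.raises(ValueError):
            nondimensionalize(dim, SCALES)


class TestSimulate:
    def test_equilibrium_stays_constant(self):
        p = make_params(sigma=2.0, delta=0.5)
        tr = simulate(p, SCALES, x1=4.0, y1=0.0, tau_grid=np.linspace(0, 10, 21))
        assert np.all(np.abs(tr.y) <= 1e-6)
        assert np.all(np.abs(tr.x - 4.0) <= 1e-5)

    def test_output_grid_is_input_grid(self):
        tau = np.array([0.0, 0.3, 1.7, 2.0])
        tr = simulate(make_params(), SCALES, 1.0, 0.1, tau)
        assert np.array_equal(tr.tau, tau)

    def test_small_tumor_decays_below_threshold(self):
        # alpha < (E0/T0) * sigma/delta makes the tumor-free point attracting
        p = make_params(sigma=1.0, delta=0.005, alpha=0.5)  # 0.01*200 = 2 > 0.5
        tr = simulate(p, SCALES, x1=200.0, y1=1e-3, tau_grid=np.linspace(0, 1, 6))
        assert np.all(np.diff(tr.y) < 0)

    def test_blowup_signals_divergence(self):
        p = make_params(alpha=100.0, sigma=0.01, rho=0.01)
        with pytest.raises(DivergenceError):
            simulate(p, SCALES, x1=0.01, y1=1.0, tau_grid=np.linspace(0, 5, 10))

    def test_decreasing_grid_rejected(self):
        with pytest.raises(ValueError):
            simulate(make_params(), SCALES, 1.0, 1.0, [0.0, -1.0])

    @given(params=params_strategy)
    @settings(max_examples=25, deadline=None)
    def test_states_stay_nonnegative(self, params):
        try:
            tr = simulate(params, SCALES, x1=1.0, y1=0.05, tau_grid=np.linspace(0, 3, 8))
        except DivergenceError:
            return
        assert np.all(tr.x >= -1e-6)
        assert np.all(tr.y >= -1e-6)

    def test_default_solver_tracks_reference(self, rng):
        n_done = 0
        while n_done < 5:
            p = NondimParams.from_array(10 ** rng.uniform(-2, 2, 6))
            x1, y1 = 10 ** rng.uniform(-2, 2), 10 ** rng.uniform(-2, 0)
            tau = np.linspace(0, 4, 12)
            try:
                t_def = simulate(p, SCALES, x1, y1, tau)
                t_ref = reference_simulate(p, SCALES, x1, y1, tau)
            except DivergenceError:
                continue
            if np.abs(t_ref.y).max() > 1e3:
                continue
            w = np.abs(t_ref.y) + 1e-3
            assert np.max(np.abs(t_def.y - t_ref.y) / w) <= 1e-3
            n_done += 1


class TestTumorFreeEquilibrium:
    def test_effector_level_and_growth_exponent(self):
        state, exponent = tumor_free_equilibrium(make_params(), SCALES)
        assert state.x == pytest.approx(1.0)
        assert state.y == 0.0
        assert exponent == pytest.approx(0.99)

    def test_rhs_vanishes_at_equilibrium(self):
        p = make_params(sigma=3.0, delta=0.7, alpha=0.2)
        state, _ = tumor_free_equilibrium(p, SCALES)
        dx, dy = rhs(p, SCALES, state)
        assert dx == pytest.approx(0.0, abs=1e-12)
        assert dy == 0.0


def test_linear_limit_growth_rate():
    """Far below saturation (y << eta) with x pinned at sigma/delta, the
    tumor grows like exp((alpha - (E0/T0)*sigma/delta) * tau)."""
    p = make_params(sigma=1.0, delta=1.0, alpha=0.5, eta=10.0, rho=1.0, mu=1.0)
    exponent = 0.5 - 0.01 * 1.0
    y1 = 1e-4
    tau = np.linspace(0, 5, 26)
    tr = simulate(p, SCALES, x1=1.0, y1=y1, tau_grid=tau,
                  solver=SolverConfig(rtol=1e-8, atol=1e-12))
    window = tr.y < p.eta / 100
    expected = y1 * np.exp(exponent * tau[window])
    assert np.max(np.abs(tr.y[window] - expected) / expected) < 0.01


def test_trajectory_validates_monotone_grid():
    with pytest.raises(ValueError):
        Trajectory(tau=np.array([0.0, 0.0]), x=np.zeros(2), y=np.zeros(2))
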