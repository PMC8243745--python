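import numpy as np
import pytest

from limisim import (GridState, InitSpec, LatticeSpec, NumericalBlowupError,
                     SimulationParams, homogeneous_state, random_initial_state,
                     run_to_equilibrium, step)
from limisim.integrate import _raise_on_blowup, _residual

from oracles import homogeneous_fixed_points


def test_euler_arithmetic_from_empty_field():
    # all fields zero: only the Notch production term acts, N <- dt*beta_N
    params = SimulationParams(beta_N=100.0, beta_D=0.0, lattice=LatticeSpec(3, 3))
    state = homogeneous_state(0.0, 0.0, params)
    state.N[:] = 0.0
    out = step(state, params)
    np.testing.assert_allclose(out.N, 0.01)
    np.testing.assert_array_equal(out.D, 0.0)
    np.testing.assert_array_equal(out.R, 0.0)
    assert out.t == pytest.approx(params.dt)


def test_negative_excursion_is_clipped_to_zero():
    # huge Notch drives the cis term: Euler would push D far below zero
    params = SimulationParams(lattice=LatticeSpec(3, 3))
    state = homogeneous_state(0.5, 1000.0, params)
    out = step(state, params)
    assert np.all(out.D == 0.0)


def test_step_holds_pv_clamp(default_params):
    state = random_initial_state(InitSpec(seed=0, pv_cells=((10, 10),)),
                                 default_params)
    out = step(state, default_params)
    assert out.D[10, 10] == default_params.pv_delta


def test_homogeneous_fixed_point_is_stationary():
    params = SimulationParams(lattice=LatticeSpec(3, 3))
    D, N, R = min(homogeneous_fixed_points(params))
    state = homogeneous_state(D, N, params)
    state.R[:] = R
    out = step(state, params)
    np.testing.assert_allclose(out.D, D, rtol=1e-9, atol=1e-9)
    np.testing.assert_allclose(out.N, N, rtol=1e-9)
    np.testing.assert_allclose(out.R, R, rtol=1e-9)


def test_positivity_after_many_steps(rng, fast_params):
    state = GridState(D=rng.random((6, 6)), N=rng.random((6, 6)),
                      R=np.zeros((6, 6)), pv_mask=np.zeros((6, 6), dtype=bool))
    for _ in range(200):
        state = step(state, fast_params)
        assert (state.D.min() >= 0 and state.N.min() >= 0
                and state.R.min() >= 0)


def test_engines_agree(fast_params):
    state = random_initial_state(
        InitSpec(seed=9, pv_cells=((3, 3),)), fast_params)
    params = fast_params.with_(residual_tol=1e-12)  # force full step budget
    a = run_to_equilibrium(state, params, max_steps=500, engine="compiled")
    b = run_to_equilibrium(state, params, max_steps=500, engine="python")
    assert a.steps == b.steps == 500
    np.testing.assert_allclose(a.final_state.D, b.final_state.D, rtol=1e-8)
    np.testing.assert_allclose(a.final_state.N, b.final_state.N, rtol=1e-8)
    np.testing.assert_allclose(a.final_state.R, b.final_state.R, rtol=1e-8)


def test_max_steps_cap_reports_nonconvergence(default_params):
    state = random_initial_state(InitSpec(seed=0), default_params)
    res = run_to_equilibrium(state, default_params, max_steps=1)
    assert not res.converged and res.steps == 1
    assert res.final_residual >= default_params.residual_tol


def test_already_converged_state_returns_immediately():
    params = SimulationParams(beta_D=0.0, lattice=LatticeSpec(3, 3))
    state = homogeneous_state(0.0, params.beta_N / params.gamma, params)
    res = run_to_equilibrium(state, params)
    assert res.converged and res.steps == 0


@pytest.mark.parametrize("engine", ["compiled", "python"])
def test_delta_free_equilibrium_is_beta_N_over_gamma(engine):
    # beta_D=0 with D(0)=R(0)=0 decouples everything but dN = beta_N - gamma*N
    params = SimulationParams(beta_N=100.0, beta_D=0.0,
                              lattice=LatticeSpec(3, 3), dt=1e-3)
    state = homogeneous_state(0.0, 0.0, params)
    res = run_to_equilibrium(state, params, engine=engine)
    assert res.converged
    np.testing.assert_array_equal(res.final_state.D, 0.0)
    np.testing.assert_array_equal(res.final_state.R, 0.0)
    np.testing.assert_allclose(res.final_state.N, 100.0,
                               atol=params.residual_tol / params.gamma)


def test_converged_residual_reevaluates_below_tol(fast_params):
    state = random_initial_state(InitSpec(seed=2, pv_cells=((2, 2),)),
                                 fast_params)
    res = run_to_equilibrium(state, fast_params)
    assert res.converged
    # cross-check with the numpy-side residual, PV cells excluded
    assert _residual(res.final_state, fast_params) < fast_params.residual_tol
    assert res.final_state.t == pytest.approx(res.steps * fast_params.dt)


def test_residual_on_increments_option_is_dt_looser(fast_params):
    state = random_initial_state(InitSpec(seed=2, pv_cells=((2, 2),)),
                                 fast_params)
    strict = run_to_equilibrium(state, fast_params)
    loose = run_to_equilibrium(
        state, fast_params.with_(residual_on_increments=True))
    assert loose.converged
    assert loose.steps < strict.steps


def test_blowup_error_names_cell_and_field(small_params):
    state = homogeneous_state(1.0, 1.0, small_params)
    state.R[2, 4] = np.inf
    with pytest.raises(NumericalBlowupError, match=r"R at cell \(2, 4\)"):
        _raise_on_blowup(state)


def test_unknown_engine_rejected(fast_params):
    state = homogeneous_state(1.0, 1.0, fast_params)
    with pytest.raises(ValueError, match="engine"):
        run_to_equilibrium(state, fast_params, engine="rk4")
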