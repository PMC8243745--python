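import numpy as np
import pytest

from limisim import (GridState, LatticeSpec, SimulationParams,
                     classify_cholangiocytes, compute_diff, homogeneous_state)
from limisim.diffstat import pv_neighborhood

from oracles import loop_diff


def state_with_R(R, pv_cells, params):
    """State whose reporter field is given explicitly; D/N are irrelevant."""
    state = homogeneous_state(1.0, 1.0, params)
    state.R = np.asarray(R, dtype=float)
    for cell in pv_cells:
        state.pv_mask[cell] = True
        state.D[cell] = params.pv_delta
    return state


@pytest.fixture
def params5():
    return SimulationParams(lattice=LatticeSpec(5, 5))


def checkerboard_R(params5):
    """Included cells split 10/10 between 0 and 2 -> Ave=1, population SD=1."""
    pv = (2, 2)
    neighbors = [(1, 2), (2, 1), (2, 3), (3, 2)]
    included = [(i, j) for i in range(5) for j in range(5)
                if (i, j) != pv and (i, j) not in neighbors]
    R = np.zeros((5, 5))
    for cell in included[10:]:
        R[cell] = 2.0
    return R, pv, neighbors


def test_z_score_of_engineered_field(params5):
    R, pv, neighbors = checkerboard_R(params5)
    for cell in neighbors:
        R[cell] = 3.0
    report = compute_diff(state_with_R(R, [pv], params5), params5)
    assert report.ave == pytest.approx(1.0)
    assert report.sd == pytest.approx(1.0)
    np.testing.assert_allclose(report.neighbor_diffs, 2.0)
    assert report.mean_diff == pytest.approx(2.0)
    assert report.log2_mean_diff == pytest.approx(1.0)
    assert report.sentinel is None


def test_boundary_diff_of_two_is_not_a_cholangiocyte(params5):
    # the threshold is a strict inequality
    R, pv, neighbors = checkerboard_R(params5)
    for cell in neighbors:
        R[cell] = 3.0
    R[neighbors[0]] = 3.5
    report = compute_diff(state_with_R(R, [pv], params5), params5)
    calls = classify_cholangiocytes(report, params5)
    assert calls.tolist() == [True, False, False, False]
    np.testing.assert_array_equal(calls, report.cholangiocyte_calls)
    assert classify_cholangiocytes(report, params5.with_(diff_threshold=1.9)).all()


def test_negative_diffs_never_called(params5):
    R, pv, neighbors = checkerboard_R(params5)
    for cell in neighbors:
        R[cell] = 0.0  # diff = -1
    report = compute_diff(state_with_R(R, [pv], params5), params5)
    np.testing.assert_allclose(report.neighbor_diffs, -1.0)
    assert not report.cholangiocyte_calls.any()
    assert report.sentinel == "negative"
    assert np.isnan(report.log2_mean_diff)


def test_zero_sd_yields_infinity_sentinel(params5):
    R = np.ones((5, 5))
    R[1, 2] = 50.0
    report = compute_diff(state_with_R(R, [(2, 2)], params5), params5)
    assert report.sentinel == "infinity"
    assert report.sd == 0.0
    assert np.isnan(report.log2_mean_diff)
    assert np.isposinf(report.mean_diff)


def test_single_pv_on_default_lattice_has_395_included(default_params):
    state = homogeneous_state(1.0, 1.0, default_params)
    state.pv_mask[10, 10] = True
    state.D[10, 10] = default_params.pv_delta
    neighbors, included = pv_neighborhood(state, default_params)
    assert len(neighbors) == 4
    assert included.sum() == 395


def test_affine_invariance_of_diff(rng, small_params):
    R = rng.random((6, 6)) * 10
    base = compute_diff(state_with_R(R, [(3, 3)], small_params), small_params)
    for a, b in [(2.5, 0.0), (0.3, 7.0), (10.0, 0.9)]:
        scaled = compute_diff(state_with_R(a * R + b, [(3, 3)], small_params),
                              small_params)
        np.testing.assert_allclose(scaled.neighbor_diffs, base.neighbor_diffs,
                                   rtol=1e-10)


def test_matches_bruteforce_loop_on_random_field(rng, small_params):
    R = rng.random((6, 6)) * 5
    pv = [(1, 4)]
    report = compute_diff(state_with_R(R, pv, small_params), small_params)
    oracle = loop_diff(R, pv)
    assert report.ave == pytest.approx(oracle["ave"], rel=1e-12)
    assert report.sd == pytest.approx(oracle["sd"], rel=1e-12)
    assert list(report.neighbor_cells) == oracle["neighbors"]
    for cell, diff in zip(report.neighbor_cells, report.neighbor_diffs):
        assert diff == pytest.approx(oracle["diffs"][cell], rel=1e-12)


def test_multiple_pv_cells_use_union_neighborhood(small_params, rng):
    R = rng.random((6, 6))
    pv = [(2, 2), (2, 3)]  # adjacent PV cells exclude each other as neighbors
    state = state_with_R(R, pv, small_params)
    report = compute_diff(state, small_params)
    oracle = loop_diff(R, pv)
    assert list(report.neighbor_cells) == oracle["neighbors"]
    assert len(report.neighbor_cells) == 6
    assert (2, 2) not in report.neighbor_cells


def test_requires_pv_cell_and_enough_included_cells():
    params3 = SimulationParams(lattice=LatticeSpec(3, 3))
    state = homogeneous_state(1.0, 1.0, params3)
    with pytest.raises(ValueError, match="PV"):
        compute_diff(state, params3)
    # on 3x3, two diagonal PV cells leave < 2 included cells
    state.pv_mask[0, 0] = state.pv_mask[1, 1] = True
    state.D[state.pv_mask] = params3.pv_delta
    with pytest.raises(ValueError, match="included"):
        compute_diff(state, params3)
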