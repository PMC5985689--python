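"""Collicular map: geometry, mapping, connectivity, dynamics, outputs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sacsim import default_parameters
from sacsim.sc import (
    SCGeometry,
    SCMapState,
    activation,
    apply_inactivation,
    burst_layer,
    collicular_to_retinotopic,
    inactivation_mask,
    lateral_weight,
    lateral_weight_matrix,
    opn_projection_weights,
    bn_projection_weights,
    retinotopic_to_collicular,
    sc_outputs,
    sc_step,
)
from sacsim.cortex import cortical_drive


# --- retinotopic <-> collicular mapping --------------------------------

@pytest.mark.parametrize("D,expected", [
    (0.0, 0.0),
    (3.0, 1.4 * np.log(2.0)),       # 0.97041 mm
    (-3.0, -1.4 * np.log(2.0)),     # odd symmetry
])
def test_retinotopic_to_collicular_values(D, expected, params):
    assert retinotopic_to_collicular(D, params) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize("d,expected", [
    (0.0, 0.0),
    (1.4 * np.log(2.0), 3.0),
    (5.0, 3.0 * (np.exp(5.0 / 1.4) - 1.0)),  # map edge ~ 103.79 deg
])
def test_collicular_to_retinotopic_values(d, expected, params):
    assert collicular_to_retinotopic(d, params) == pytest.approx(expected, rel=1e-9)


def test_inverse_outside_map_rejected(params):
    with pytest.raises(ValueError):
        collicular_to_retinotopic(params.S + 0.1, params)


@given(D=st.floats(-100.0, 100.0))
@settings(max_examples=50, deadline=None)
def test_mapping_round_trip(D):
    p = default_parameters()
    d = retinotopic_to_collicular(D, p)
    if abs(d) <= p.S:
        assert collicular_to_retinotopic(d, p) == pytest.approx(D, abs=1e-9)


def test_geometry_spacing_and_midline(params, geometry):
    assert len(geometry.positions) == params.n_neurons
    assert geometry.spacing == pytest.approx(2 * params.S / (params.n_neurons - 1))
    assert geometry.spacing == pytest.approx(0.1)
    mid = geometry.midline_index
    assert geometry.positions[mid] == 0.0
    assert geometry.eccentricities[mid] == 0.0
    assert np.all(np.diff(geometry.positions) > 0)
    assert np.all(np.diff(geometry.eccentricities) > 0)
    assert np.all(np.sign(geometry.positions) == np.sign(geometry.eccentricities))


# --- lateral connectivity ----------------------------------------------

def test_lateral_weight_profile(params, geometry):
    mid = geometry.midline_index
    # zero distance -> A_w
    assert lateral_weight(mid, mid, geometry, params) == pytest.approx(1.0)
    # far apart -> -C
    assert lateral_weight(0, params.n_neurons - 1, geometry, params) == pytest.approx(
        -1.0, abs=1e-6
    )
    # at one excitation width: (A_w + C) e^{-1/2} - C
    j = mid + 5  # 0.5 mm away
    assert lateral_weight(mid, j, geometry, params) == pytest.approx(
        2 * np.exp(-0.5) - 1, abs=1e-12
    )


def test_weight_matrix_invariants(params, geometry):
    W = lateral_weight_matrix(geometry, params)
    assert np.allclose(W, W.T)
    assert np.allclose(np.diag(W), params.A_w)
    assert W.min() >= -params.C - 1e-12


# --- activation and burst layer ----------------------------------------

@pytest.mark.parametrize("u,expected", [
    (0.0, 250.0),                       # logistic midpoint F/2
    (10.0, 500.0 / (1 + np.exp(-1.0))), # ~365.53
    (1e6, 500.0),                       # saturation at F
])
def test_activation_values(u, expected, params):
    assert activation(u, params) == pytest.approx(expected, rel=1e-9)


def test_activation_monotone_and_bounded(params):
    u = np.linspace(-200, 200, 1001)
    a = activation(u, params)
    assert np.all(np.diff(a) > 0)
    assert np.all((a > 0) & (a < params.F))


def test_burst_layer_thresholding(params):
    thr = params.burst_threshold
    a = np.array([0.0, thr - 1e-9, thr, thr + 1.0, params.F])
    out = burst_layer(a, params)
    assert out[0] == 0.0
    assert out[1] == 0.0
    assert out[2] == thr          # boundary inclusive
    assert out[3] == thr + 1.0
    assert out[4] == params.F


# --- descending projection weights -------------------------------------

def test_projection_weight_shapes(params, geometry):
    w_opn = opn_projection_weights(geometry, params)
    mid = geometry.midline_index
    assert w_opn[mid] == pytest.approx(1.0)
    assert w_opn[0] == pytest.approx(0.0)
    assert w_opn[-1] == pytest.approx(0.0)
    w_bn = bn_projection_weights(geometry)
    assert w_bn[mid] == 0.0
    assert np.all(np.diff(w_bn[mid:]) > 0)   # grows with eccentricity


# --- sc_outputs ---------------------------------------------------------

def test_outputs_zero_burst(params, geometry):
    a = np.full(params.n_neurons, 10.0)   # below burst threshold
    out = sc_outputs(a, burst_layer(a, params), geometry, params)
    assert out.drive_bn_left == 0.0
    assert out.drive_bn_right == 0.0
    assert out.drive_opn > 0.0


def test_outputs_single_caudal_neuron(params, geometry):
    """A lone strong burst at +2 mm commands ~2 mm once it dominates."""
    a = np.full(params.n_neurons, 1.0)
    i = int(np.argmin(np.abs(geometry.positions - 2.0)))
    a[i] = params.F
    burst = np.zeros_like(a)
    burst[i] = 1e9   # dominates the buildup term in the denominator
    out = sc_outputs(a, burst, geometry, params)
    assert out.drive_bn_right == pytest.approx(2.0, rel=1e-4)
    assert out.drive_bn_left == 0.0


def test_outputs_symmetric_hill(params, geometry):
    mid = geometry.midline_index
    a = np.full(params.n_neurons, 1.0)
    a[mid - 5:mid + 6] = params.F
    out = sc_outputs(a, burst_layer(a, params), geometry, params)
    assert out.drive_bn_left == pytest.approx(out.drive_bn_right, rel=1e-12)


def test_normalization_insensitive_to_burst_scaling(params, geometry):
    """Scaling the burst layer changes the command by <5% (location code)."""
    a = np.full(params.n_neurons, 1.0)
    sl = slice(geometry.midline_index + 2, geometry.midline_index + 13)
    burst = np.zeros(params.n_neurons)
    burst[sl] = params.F
    a[sl] = params.F
    base = sc_outputs(a, burst, geometry, params).drive_bn_right
    scaled = sc_outputs(a, 3.0 * burst, geometry, params).drive_bn_right
    assert abs(scaled - base) / base < 0.05


def test_outputs_inactivation(params, geometry):
    a = np.full(params.n_neurons, 1.0)
    mid = geometry.midline_index
    a[mid - 6:mid + 7] = params.F
    burst = burst_layer(a, params)
    state = SCMapState(u=np.zeros_like(a), a=a, burst=burst, W=np.eye(len(a)))
    assert apply_inactivation(state, None, geometry, params) == sc_outputs(
        a, burst, geometry, params)
    none = inactivation_mask(geometry, None)
    assert not none.any()
    ctrl = sc_outputs(a, burst, geometry, params, inactive=none)
    # nulling (0, 1] mm removes the hill's right flank from the outputs
    mask = inactivation_mask(geometry, (0.0, 1.0))
    inact = sc_outputs(a, burst, geometry, params, inactive=mask)
    assert inact.drive_opn < ctrl.drive_opn
    assert inact.drive_bn_right < ctrl.drive_bn_right
    # whole-map inactivation silences every drive
    allmask = inactivation_mask(geometry, (-params.S, params.S))
    dead = sc_outputs(a, burst, geometry, params, inactive=allmask)
    assert dead.drive_opn == 0.0
    assert dead.drive_bn_left == 0.0 and dead.drive_bn_right == 0.0


# --- dynamics -----------------------------------------------------------

def test_uniform_state_steps_symmetrically(params, geometry):
    """One zero-input step preserves the translation-symmetric interior
    (the uniform state is an exact transient fixed pattern up to edge
    effects; over long runs it is pattern-forming and collapses)."""
    state = SCMapState.initial(geometry, params)
    zero = np.zeros(params.n_neurons)
    state = sc_step(state, zero, zero, 0.0, params.dt, geometry, params)
    interior = state.a[10:-10]
    assert interior.std() / interior.mean() < 1e-6
    # mirror symmetry holds exactly
    assert np.allclose(state.a, state.a[::-1], rtol=1e-10)


def test_hill_converges_under_constant_input(params, geometry):
    """Constant central drive yields a stable hill centred at 0 mm."""
    state = SCMapState.initial(geometry, params)
    zero = np.zeros(params.n_neurons)
    drive = cortical_drive(0.0, geometry, params).total
    for _ in range(500):
        state = sc_step(state, drive, zero, 0.0, params.dt, geometry, params)
    prev = state.a.copy()
    for _ in range(500):
        state = sc_step(state, drive, zero, 0.0, params.dt, geometry, params)
    assert np.max(np.abs(state.a - prev)) < 1e-6 * params.F * 500
    # converged and centred: flat-top plateau symmetric around the midline
    active = np.flatnonzero(state.a > params.F / 2)
    mid = geometry.midline_index
    assert active[0] + active[-1] == 2 * mid
    # last-step change is tiny
    nxt = sc_step(state, drive, zero, 0.0, params.dt, geometry, params)
    assert np.max(np.abs(nxt.a - state.a)) < 1e-6 * params.F


@pytest.mark.parametrize("favoured", [-2.0, 2.0])
def test_winner_take_all_between_two_inputs(params, geometry, favoured):
    """Two equal distant Gaussian drives, weak enough that the recurrent
    competition dominates: long-range inhibition leaves a single hill on
    the (slightly) seeded side."""
    pos = geometry.positions
    bump = lambda c: 1500.0 * np.exp(-((pos - c) ** 2) / (2 * 0.5**2))
    drive = bump(-2.0) + bump(2.0)
    state = SCMapState.initial(geometry, params)
    seed = np.zeros(params.n_neurons)
    seed[np.argmin(np.abs(pos - favoured))] = 1.0
    zero = np.zeros(params.n_neurons)
    state = sc_step(state, drive + seed, zero, 0.0, params.dt, geometry, params)
    for _ in range(999):
        state = sc_step(state, drive, zero, 0.0, params.dt, geometry, params)
    active = state.a > params.F / 2
    left = active[pos < -1.0].sum()
    right = active[pos > 1.0].sum()
    assert (left == 0) != (right == 0)   # exactly one side hosts the hill
    winner_side = right if favoured > 0 else left
    assert winner_side > 0


def test_step_scheme_substep_consistency(params, geometry):
    """One 1-ms step agrees with ten 0.1-ms substeps to 1e-3 relative."""
    state = SCMapState.initial(geometry, params)
    zero = np.zeros(params.n_neurons)
    drive = cortical_drive(1.0, geometry, params).total
    for _ in range(50):
        state = sc_step(state, drive, zero, 0.0, params.dt, geometry, params)
    coarse = sc_step(state, drive, zero, 0.0, params.dt, geometry, params)
    fine = state
    for _ in range(10):
        fine = sc_step(fine, drive, zero, 0.0, params.dt / 10, geometry, params)
    denom = np.maximum(np.abs(fine.a), 1.0)
    assert np.max(np.abs(coarse.a - fine.a) / denom) < 1e-3


def test_non_finite_state_raises(params, geometry):
    state = SCMapState.initial(geometry, params)
    state.u[0] = np.nan
    with pytest.raises(FloatingPointError):
        sc_step(state, np.zeros(params.n_neurons), np.zeros(params.n_neurons),
                0.0, params.dt, geometry, params)
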