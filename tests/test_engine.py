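"""Closed-loop engine: plant, delay, determinism, recording."""

import numpy as np
import pytest
import yaml

from sacsim import (
    EyeState,
    SimulationError,
    default_parameters,
    detect_saccades,
    make_target,
    plant_step,
    run_simulation,
)


# --- final common path / plant -----------------------------------------

def test_plant_idle_without_input(params):
    st = EyeState(eye_pos=1.5, integrator=1.5)
    for _ in range(100):
        st = plant_step(st, 0.0, 0.0, params.dt, params)
    assert st.eye_pos == pytest.approx(1.5, abs=1e-9)


def test_plant_symmetric_drive_cancels(params):
    st = EyeState()
    for _ in range(100):
        st = plant_step(st, 123.0, 123.0, params.dt, params)
    assert st.eye_pos == pytest.approx(0.0, abs=1e-9)


def test_plant_rectangular_pulse_displacement(params):
    """A 50-ms MLEBN pulse of rate R displaces the eye by
    velocity_gain * R * 0.05 deg (closed-form integral) within 1%."""
    R = 200.0
    st = EyeState()
    for _ in range(50):
        st = plant_step(st, 0.0, R, params.dt, params)
    for _ in range(600):   # settle
        st = plant_step(st, 0.0, 0.0, params.dt, params)
    expected = params.velocity_gain * R * 0.05
    assert st.eye_pos == pytest.approx(expected, rel=0.01)


# --- target descriptions ------------------------------------------------

def test_make_target_forms():
    assert make_target(1.5)(0.0) == 1.5
    step = make_target([(0.2, 2.0), (0.5, -1.0)])
    assert step(0.0) == 0.0
    assert step(0.3) == 2.0
    assert step(0.9) == -1.0
    fn = make_target(lambda t: 3 * t)
    assert fn(2.0) == 6.0


# --- closed loop --------------------------------------------------------

def test_noise_free_fixation_is_quiet(params):
    p = params.replace(noise_gain=0.0)
    res = run_simulation(p, target=0.0, duration=1.0, seed=0)
    assert detect_saccades(res.eye_pos, p.dt, p) == []
    assert np.max(np.abs(res.eye_pos)) < 0.01


def test_single_two_degree_saccade(params):
    p = params.replace(noise_gain=0.0)
    res = run_simulation(p, target=[(0.2, 2.0)], duration=1.0, seed=0)
    events = detect_saccades(res.eye_pos, p.dt, p)
    assert len(events) == 1
    ev = events[0]
    assert ev.direction == "right"
    assert ev.onset > 0.2
    assert abs(res.eye_pos[-1] - 2.0) / 2.0 < 0.10


def test_determinism_same_seed(params):
    a = run_simulation(params, target=0.0, duration=2.0, seed=42)
    b = run_simulation(params, target=0.0, duration=2.0, seed=42)
    for key in a.traces:
        assert np.array_equal(a.traces[key], b.traces[key]), key


def test_different_seeds_differ(params):
    a = run_simulation(params, target=0.0, duration=2.0, seed=1)
    b = run_simulation(params, target=0.0, duration=2.0, seed=2)
    assert not np.array_equal(a.traces["eye_pos"], b.traces["eye_pos"])


def test_visual_feedback_delay_in_error_signal(params):
    """The retinal error ignores the eye movement for one delay period."""
    p = params.replace(noise_gain=0.0)
    res = run_simulation(p, target=[(0.2, 2.0)], duration=0.8, seed=0)
    ev = detect_saccades(res.eye_pos, p.dt, p)[0]
    err = res.traces["target_error"]
    k_on = int(ev.onset / p.dt)
    delay_steps = int(round(p.visual_delay / p.dt))
    assert delay_steps == 50
    # error still reflects the pre-saccadic eye throughout the delay
    assert err[k_on + delay_steps - 2] == pytest.approx(2.0, abs=0.05)
    # and has incorporated the movement shortly after one delay + duration
    k_done = int(ev.offset / p.dt) + delay_steps + 5
    assert abs(err[k_done]) < 0.5


def test_dt_refinement_consistency(params):
    """Quartering the step changes the noise-free saccade amplitude <2%."""
    finals = {}
    for dt in (0.001, 0.00025):
        p = params.replace(noise_gain=0.0, dt=dt)
        res = run_simulation(p, target=[(0.2, 2.0)], duration=0.8, seed=0)
        finals[dt] = res.eye_pos[-1]
    assert abs(finals[0.001] - finals[0.00025]) / abs(finals[0.00025]) < 0.02


def test_closed_loop_bounded_and_recovering(params):
    """Default fixation stays bounded and the OPN returns after events."""
    res = run_simulation(params, target=0.0, duration=10.0, seed=3)
    assert np.max(np.abs(res.eye_pos)) < 5.0
    opn = res.traces["r_opn"]
    silent = opn < params.opn_silence_threshold
    # every silent episode ends well before the run does
    last_recovery = np.flatnonzero(~silent)[-1]
    assert last_recovery > len(opn) - 500


def test_too_short_duration_rejected(params):
    with pytest.raises(ValueError):
        run_simulation(params, duration=5 * params.dt)


def test_result_saving_round_trip(tmp_path, params):
    p = params.replace(noise_gain=0.0)
    res = run_simulation(p, target=0.0, duration=0.2, seed=5, record_maps=True)
    res.save(tmp_path)
    frame = res.to_frame()
    assert {"time", "eye_pos", "r_opn", "net_r"} <= set(frame.columns)
    assert (tmp_path / "traces.csv").exists()
    meta = yaml.safe_load((tmp_path / "metadata.yaml").read_text())
    assert meta["seed"] == 5
    assert meta["parameters"]["n_neurons"] == p.n_neurons
    maps = np.load(tmp_path / "maps.npz")
    assert maps["sc_activation"].shape == (len(frame), p.n_neurons)


def test_inactivation_region_validated(params):
    with pytest.raises(ValueError):
        run_simulation(params, duration=0.1, inactivation=(-10.0, 1.0))
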