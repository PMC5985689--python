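"""Closed-loop fixed-step simulation engine.

Wires the collicular map, cortical drives, noise field, brainstem
trigger, cerebellar stop circuit and the oculomotor plant into one
system integrated at a fixed 1-ms step (third-order Bogacki-Shampine by
default).  Discrete elements -- the visual delay buffer, the per-step
noise draw, the noise reset at saccade onset and the cerebellar
integrator reset at saccade end -- are updated once per step; the
remaining continuous states are advanced jointly.

The motor pathway is a pulse-slide-step final common path: the net
medium-lead burst drive is scaled to an eye-velocity command, a neural
integrator accumulates it into the step, and the pulse (with a
low-passed slide component) compensates the first-order eye plant so
that the eye tracks the integrator without post-saccadic drift.

The collicular motor commands, which the map emits as centre-of-mass
positions in mm, are converted back to retinal degrees through the
exact inverse of the logarithmic magnification before they reach the
brainstem and cerebellum; this undoes the map's logarithmic compression
so that one set of downstream gains yields accurate saccades across
amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import brainstem as bs
from .cortex import fef_eccentricity_gain
from .noise import NoiseField
from .numerics import rk3_step, euler_step
from .params import ModelParameters
from .sc import (
    SCGeometry,
    inactivation_mask,
    lateral_weight_matrix,
    bn_projection_weights,
    opn_projection_weights,
    retinotopic_to_collicular,
    rostral_profile,
)

__all__ = ["EyeState", "SimulationResult", "SimulationError",
           "plant_step", "run_simulation", "make_target"]

SCALAR_TRACES = (
    "eye_pos", "eye_vel", "target", "target_error",
    "r_opn", "r_llibn_l", "r_llibn_r", "r_mlebn_l", "r_mlebn_r",
    "r_mlibn_l", "r_mlibn_r",
    "drive_opn", "drive_bn_l", "drive_bn_r", "cmd_l", "cmd_r",
    "net_l", "net_r",
    "early_l", "early_r", "late_l", "late_r",
)


class SimulationError(RuntimeError):
    """Numerical failure during a run, naming the first bad signal/step."""


@dataclass
class EyeState:
    """Plant state: neural integrator, slide filter and eye position."""

    integrator: float = 0.0   # step command, deg
    slide: float = 0.0        # low-passed pulse, deg/s
    eye_pos: float = 0.0      # deg
    eye_vel: float = 0.0      # deg/s
    delay_buffer: np.ndarray | None = None


def plant_step(
    state: EyeState, mlebn_l: float, mlebn_r: float, dt: float,
    params: ModelParameters,
) -> EyeState:
    """Advance the final common path and plant one step.

    The velocity command is ``velocity_gain * (mlebn_r - mlebn_l)``; the
    motoneuron signal combines step (integrator), pulse and slide so the
    first-order plant (time constant ``tau_plant``) is compensated.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    v = params.velocity_gain * (mlebn_r - mlebn_l)
    sf = params.slide_fraction

    def deriv(y: np.ndarray) -> np.ndarray:
        integ, slide, eye = y
        m = integ + params.tau_plant * ((1.0 - sf) * v + sf * slide)
        return np.array([v, (v - slide) / params.tau_slide,
                         (m - eye) / params.tau_plant])

    stepper = rk3_step if params.integrator == "rk3" else euler_step
    integ, slide, eye = stepper(
        deriv, np.array([state.integrator, state.slide, state.eye_pos]), dt
    )
    m = integ + params.tau_plant * ((1.0 - sf) * v + sf * slide)
    return EyeState(integrator=integ, slide=slide, eye_pos=eye,
                    eye_vel=(m - eye) / params.tau_plant,
                    delay_buffer=state.delay_buffer)


@dataclass
class SimulationResult:
    """Time-indexed traces of every signal plus run metadata.

    ``traces`` holds one column per scalar signal (see
    ``SCALAR_TRACES``); the per-neuron maps (buildup activation, burst
    layer, noise input) are recorded only when the run was asked to.
    Metadata (parameters, seed, condition) is sufficient to re-run the
    simulation bit-identically.
    """

    time: np.ndarray
    traces: dict[str, np.ndarray]
    params: ModelParameters
    seed: int
    condition: str = "default"
    sc_activation: np.ndarray | None = None   # (n_steps, n_neurons)
    sc_burst: np.ndarray | None = None
    noise_input: np.ndarray | None = None

    @property
    def dt(self) -> float:
        return self.params.dt

    @property
    def eye_pos(self) -> np.ndarray:
        return self.traces["eye_pos"]

    @property
    def eye_vel(self) -> np.ndarray:
        return self.traces["eye_vel"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, **self.traces})

    def save(self, outdir: str | Path) -> None:
        """Write scalar traces (CSV), metadata (YAML) and, if recorded,
        the map traces (NPZ sidecar)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(outdir / "traces.csv", index=False)
        meta = {
            "seed": int(self.seed),
            "condition": self.condition,
            "parameters": self.params.to_dict(),
        }
        (outdir / "metadata.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
        if self.sc_activation is not None:
            np.savez_compressed(
                outdir / "maps.npz",
                sc_activation=self.sc_activation,
                sc_burst=self.sc_burst,
                noise_input=self.noise_input,
            )


def make_target(target: float | Callable[[float], float] | Sequence[tuple[float, float]]
                ) -> Callable[[float], float]:
    """Normalize a target description to a function of time (s -> deg).

    Accepts a constant, a callable, or a sequence of (time, value) steps
    interpreted as a right-continuous staircase starting at 0 deg.
    """
    if callable(target):
        return target
    if np.isscalar(target):
        value = float(target)
        return lambda t: value
    steps = sorted((float(t), float(v)) for t, v in target)

    def staircase(t: float) -> float:
        out = 0.0
        for t_k, v_k in steps:
            if t >= t_k:
                out = v_k
            else:
                break
        return out

    return staircase


def run_simulation(
    params: ModelParameters,
    target: float | Callable[[float], float] | Sequence[tuple[float, float]] = 0.0,
    duration: float = 1.0,
    seed: int = 0,
    condition: str = "default",
    inactivation: tuple[float, float] | None = None,
    record_maps: bool = False,
) -> SimulationResult:
    """Run the closed loop for ``duration`` seconds.

    Parameters
    ----------
    params
        Full model parameter set.
    target
        Desired gaze location over time, deg (constant, callable, or
        (time, value) step schedule).
    duration
        Simulated time, s (at least 10 steps).
    seed
        Seed for the noise stream; recorded in the result.
    inactivation
        Optional (lo, hi] interval of collicular positions (mm) whose
        output is nulled, emulating focal inactivation.
    record_maps
        Also record the per-neuron activation/burst/noise maps
        (memory-heavy for long runs).
    """
    dt = params.dt
    if duration < 10 * dt:
        raise ValueError("duration must be at least 10 steps")
    n_steps = int(round(duration / dt))
    n = params.n_neurons

    geometry = SCGeometry.from_params(params)
    W = lateral_weight_matrix(geometry, params)
    w_opn = opn_projection_weights(geometry, params)
    w_bn = bn_projection_weights(geometry)
    rostral = rostral_profile(geometry, params)
    inactive = inactivation_mask(geometry, inactivation)
    any_inactive = bool(inactive.any())
    pos = geometry.positions
    left_side = pos < 0
    right_side = pos > 0
    w_bn_l = np.where(left_side, w_bn, 0.0)
    w_bn_r = np.where(right_side, w_bn, 0.0)

    target_fn = make_target(target)
    rng = np.random.default_rng(seed)
    noise = NoiseField(params, geometry, rng)

    # --- state vector layout -------------------------------------------
    # [u (n) | brainstem x (7) | cerebellar stages (4) | integ, slide, eye]
    i_bs = n
    i_cb = n + 7
    i_pl = n + 11
    y = np.zeros(n + 14)
    y[i_bs + bs.OPN] = params.opn_bias
    eye0 = 0.0
    y[i_pl + 2] = eye0
    y[i_pl + 0] = eye0

    # local bindings for speed inside the derivative
    F, beta_u, thr = params.F, params.beta_u, params.burst_threshold
    tau_SC, tau_BN = params.tau_SC, params.tau_BN
    A_, B_, S_ = params.A, params.B, params.S
    bf = params.buildup_fraction
    F1, F2 = params.F1, params.F2
    T1, T2, eg = params.T_cblm1, params.T_cblm2, params.efference_gain
    vg, sf = params.velocity_gain, params.slide_fraction
    tau_p, tau_s = params.tau_plant, params.tau_slide
    choke_gain, reset_gain = params.choke_gain, params.rostral_reset_gain
    crossed = params.crossed_choke
    cross_w = params.bn_cross_inhibition
    k_opn = params.k_opn
    stepper = rk3_step if params.integrator == "rk3" else euler_step

    def descending_drives(a: np.ndarray, burst: np.ndarray):
        if any_inactive:
            a = np.where(inactive, 0.0, a)
            burst = np.where(inactive, 0.0, burst)
        drive_opn = max(float(w_opn @ a), 0.0)
        denom = float(burst.sum()) + bf * float(a.sum())
        if denom <= 0.0:
            return drive_opn, 0.0, 0.0
        return (drive_opn,
                float(w_bn_l @ burst) / denom,
                float(w_bn_r @ burst) / denom)

    def to_degrees(d_mm: float) -> float:
        return A_ * np.expm1(min(d_mm, S_) / B_)

    held_cortex = np.zeros(n)
    held_noise = np.zeros(n)

    def deriv(yv: np.ndarray) -> np.ndarray:
        u = yv[:n]
        xb = yv[i_bs:i_bs + 7]
        e1l, e2l, e1r, e2r = yv[i_cb:i_cb + 4]
        integ, slide, eye = yv[i_pl:i_pl + 3]

        a = F / (1.0 + np.exp(np.clip(-beta_u * u, -700.0, 700.0)))
        burst = np.where(a >= thr, a, 0.0)
        drive_opn, d_l, d_r = descending_drives(a, burst)
        c_l, c_r = to_degrees(d_l), to_degrees(d_r)
        # crossed rostral inhibition: a hill centred at the rostral pole
        # yields zero net command to both sides
        net_l = max(c_l - cross_w * c_r, 0.0)
        net_r = max(c_r - cross_w * c_l, 0.0)

        late_l = max(F1 * e2l - F2 * net_l, 0.0)
        late_r = max(F1 * e2r - F2 * net_r, 0.0)
        ch_l, ch_r = choke_gain * late_l, choke_gain * late_r
        if crossed:
            ch_l, ch_r = ch_r, ch_l
        reset_drive = reset_gain * (late_l + late_r)

        rates = bs.brainstem_rates(xb, params)
        bs_inp = bs.brainstem_inputs(rates, net_l, net_r, drive_opn,
                                     ch_l, ch_r, params)

        dy = np.empty_like(yv)
        dy[:n] = (W @ a + held_cortex + held_noise + reset_drive * rostral - u) / tau_SC
        dy[i_bs:i_bs + 7] = (bs_inp - xb) / tau_BN
        r_ml, r_mr = rates[bs.MLEBN_L], rates[bs.MLEBN_R]
        dy[i_cb + 0] = (eg * r_ml - e1l) / T1
        dy[i_cb + 1] = (e1l - e2l) / T2
        dy[i_cb + 2] = (eg * r_mr - e1r) / T1
        dy[i_cb + 3] = (e1r - e2r) / T2
        v = vg * (r_mr - r_ml)
        m = integ + tau_p * ((1.0 - sf) * v + sf * slide)
        dy[i_pl + 0] = v
        dy[i_pl + 1] = (v - slide) / tau_s
        dy[i_pl + 2] = (m - eye) / tau_p
        return dy

    # --- recording ------------------------------------------------------
    time = np.arange(n_steps) * dt
    scal = np.empty((n_steps, len(SCALAR_TRACES)))
    map_a = np.empty((n_steps, n)) if record_maps else None
    map_b = np.empty((n_steps, n)) if record_maps else None
    map_n = np.empty((n_steps, n)) if record_maps else None

    delay_steps = int(round(params.visual_delay / dt))
    ring = np.full(delay_steps, eye0)

    in_saccade = False
    for k in range(n_steps):
        t = k * dt
        eye_delayed = ring[k % delay_steps]
        tgt = target_fn(t)
        err = tgt - eye_delayed
        d_t = retinotopic_to_collicular(err, params)
        delta = pos - d_t
        held_cortex[:] = (
            fef_eccentricity_gain(err, params)
            * np.exp(-(delta * delta) / (2.0 * params.sigma_FEF**2))
            - params.bg_depth
            * (1.0 - np.exp(-(delta * delta) / (2.0 * params.sigma_BG**2)))
        )
        held_noise[:] = noise.step(dt)

        y = stepper(deriv, y, dt)
        if not np.all(np.isfinite(y)):
            bad = int(np.flatnonzero(~np.isfinite(y))[0])
            raise SimulationError(
                f"non-finite state component {bad} at step {k} (t={t:.3f}s)"
            )

        # derived signals at the new state
        u = y[:n]
        a = F / (1.0 + np.exp(np.clip(-beta_u * u, -700.0, 700.0)))
        burst = np.where(a >= thr, a, 0.0)
        drive_opn, d_l, d_r = descending_drives(a, burst)
        c_l, c_r = to_degrees(d_l), to_degrees(d_r)
        net_l = max(c_l - cross_w * c_r, 0.0)
        net_r = max(c_r - cross_w * c_l, 0.0)
        rates = bs.brainstem_rates(y[i_bs:i_bs + 7], params)
        e2l, e2r = y[i_cb + 1], y[i_cb + 3]
        late_l = max(F1 * e2l - F2 * net_l, 0.0)
        late_r = max(F1 * e2r - F2 * net_r, 0.0)
        early_l = max(params.F3 * net_l - params.F4 * e2l, 0.0)
        early_r = max(params.F3 * net_r - params.F4 * e2r, 0.0)
        integ, slide, eye = y[i_pl:i_pl + 3]
        v = vg * (rates[bs.MLEBN_R] - rates[bs.MLEBN_L])
        m = integ + tau_p * ((1.0 - sf) * v + sf * slide)
        eye_vel = (m - eye) / tau_p

        scal[k] = (
            eye, eye_vel, tgt, err,
            rates[bs.OPN], rates[bs.LLIBN_L], rates[bs.LLIBN_R],
            rates[bs.MLEBN_L], rates[bs.MLEBN_R],
            rates[bs.MLIBN_L], rates[bs.MLIBN_R],
            drive_opn, d_l, d_r, c_l, c_r, net_l, net_r,
            early_l, early_r, late_l, late_r,
        )
        if record_maps:
            map_a[k] = a
            map_b[k] = burst
            map_n[k] = held_noise

        # discrete event logic: saccade onset resets the noise pattern;
        # the cerebellar displacement estimate empties through its own
        # leak after the movement (no discrete reset needed)
        opn_now = rates[bs.OPN]
        if not in_saccade and opn_now < params.opn_silence_threshold:
            in_saccade = True
            noise.reset()
        elif in_saccade and opn_now >= params.opn_silence_threshold:
            in_saccade = False

        ring[k % delay_steps] = eye

    traces = {name: scal[:, j].copy() for j, name in enumerate(SCALAR_TRACES)}
    return SimulationResult(
        time=time, traces=traces, params=params, seed=seed, condition=condition,
        sc_activation=map_a, sc_burst=map_b, noise_input=map_n,
    )
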