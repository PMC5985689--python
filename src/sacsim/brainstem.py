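"""Brainstem reticular formation: the OPN / burst-neuron trigger.

One omnipause neuron (OPN) and three burst neurons per side -- long-lead
inhibitory (LLIBN), medium-lead excitatory (MLEBN) and medium-lead
inhibitory (MLIBN) -- form a mutually inhibitory network.  The OPN
inhibits all six BNs; the IBNs inhibit the OPN and the three
contralateral BNs.  The OPN<->LLIBN double inhibition is a net positive
feedback loop, so the network behaves as a Schmitt trigger: distinct
drive thresholds switch it between the fixation state (OPN firing, BNs
silent) and the saccade state (OPN silent, one side's BNs firing).

Every neuron is a leaky integrator (time constant ``tau_BN``) with the
saturating exponential rate function ``B(x) = B_m (1 - exp(-(x-e0)/b))``,
rectified at zero so rates are never negative.  Weight names follow the
convention ``w_X_Y`` = strength of the projection from X to Y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParameters
from .numerics import integrate_step

__all__ = [
    "OPN", "LLIBN_L", "LLIBN_R", "MLEBN_L", "MLEBN_R", "MLIBN_L", "MLIBN_R",
    "NEURON_NAMES",
    "BrainstemState",
    "bn_rate",
    "opn_rate",
    "brainstem_rates",
    "brainstem_inputs",
    "brainstem_step",
    "trigger_hysteresis_curve",
    "TriggerDiagnosticError",
]

# state-vector indices
OPN, LLIBN_L, LLIBN_R, MLEBN_L, MLEBN_R, MLIBN_L, MLIBN_R = range(7)
NEURON_NAMES = ("opn", "llibn_l", "llibn_r", "mlebn_l", "mlebn_r",
                "mlibn_l", "mlibn_r")


class TriggerDiagnosticError(RuntimeError):
    """The quasi-static ramp produced no state switch within range."""


def bn_rate(x, params: ModelParameters):
    """Rectified exponential rate of a burst neuron (spikes/s)."""
    x = np.asarray(x, dtype=float)
    z = np.clip(-(x - params.e0) / params.b, -700.0, 700.0)
    r = np.maximum(0.0, params.B_m * -np.expm1(z))
    return float(r) if r.ndim == 0 else r


def opn_rate(x, params: ModelParameters):
    """OPN rate: same functional form, its own saturation rate."""
    x = np.asarray(x, dtype=float)
    z = np.clip(-(x - params.e0) / params.b, -700.0, 700.0)
    r = np.maximum(0.0, params.opn_max_rate * -np.expm1(z))
    return float(r) if r.ndim == 0 else r


def brainstem_rates(x: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Firing rates of all seven neurons from their integrator states."""
    r = bn_rate(x, params)
    r[OPN] = opn_rate(x[OPN], params)
    return r


@dataclass
class BrainstemState:
    """Integrator states of the seven-neuron network."""

    x: np.ndarray  # shape (7,), order given by the index constants

    @classmethod
    def initial(cls, params: ModelParameters) -> "BrainstemState":
        # Start in the fixation state: OPN charged to its tonic bias,
        # all burst neurons at rest, so no movement occurs at t = 0.
        x = np.zeros(7)
        x[OPN] = params.opn_bias
        return cls(x=x)

    def rates(self, params: ModelParameters) -> np.ndarray:
        return brainstem_rates(self.x, params)


def brainstem_inputs(
    rates: np.ndarray,
    drive_bn_left: float,
    drive_bn_right: float,
    drive_opn: float,
    choke_left: float,
    choke_right: float,
    params: ModelParameters,
) -> np.ndarray:
    """Net synaptic input to each neuron given the current rates.

    The collicular motor commands enter the BNs of their own side --
    with gain ``k_llibn`` at the long-lead IBNs (trigger sensitivity)
    and ``k_bn`` at the medium-lead neurons (movement drive); the
    rostrally weighted collicular drive excites the OPN with gain
    ``k_opn`` on top of its tonic bias.  The cerebellar choke is
    subtractive inhibition on the medium-lead neurons.
    """
    inp = np.empty(7)
    r = rates
    ibn_l = r[LLIBN_L] + r[MLIBN_L]  # inhibitory rates originating on the left
    ibn_r = r[LLIBN_R] + r[MLIBN_R]
    inp[OPN] = (
        params.opn_bias
        + params.k_opn * drive_opn
        - params.w_LLIBN_OPN * (r[LLIBN_L] + r[LLIBN_R])
        - params.w_MLIBN_OPN * (r[MLIBN_L] + r[MLIBN_R])
    )
    drive_l = params.k_bn * drive_bn_left
    drive_r = params.k_bn * drive_bn_right
    trig_l = params.k_llibn * drive_bn_left
    trig_r = params.k_llibn * drive_bn_right
    opn_to_ll = params.w_OPN_LLIBN * r[OPN]
    opn_to_bn = params.w_OPN_BN * r[OPN]
    cross = params.W_IBN_BN
    inp[LLIBN_L] = trig_l - opn_to_ll - cross * ibn_r
    inp[LLIBN_R] = trig_r - opn_to_ll - cross * ibn_l
    inp[MLEBN_L] = drive_l - opn_to_bn - cross * ibn_r - choke_left
    inp[MLEBN_R] = drive_r - opn_to_bn - cross * ibn_l - choke_right
    inp[MLIBN_L] = drive_l - opn_to_bn - cross * ibn_r - choke_left
    inp[MLIBN_R] = drive_r - opn_to_bn - cross * ibn_l - choke_right
    return inp


def brainstem_step(
    state: BrainstemState,
    drive_bn_left: float,
    drive_bn_right: float,
    drive_opn: float,
    choke_left: float,
    choke_right: float,
    dt: float,
    params: ModelParameters,
) -> BrainstemState:
    """Advance the network one step with drives frozen over the step."""
    if min(drive_bn_left, drive_bn_right, drive_opn) < 0:
        raise ValueError("collicular drives must be non-negative")

    def deriv(x: np.ndarray) -> np.ndarray:
        inp = brainstem_inputs(
            brainstem_rates(x, params),
            drive_bn_left, drive_bn_right, drive_opn,
            choke_left, choke_right, params,
        )
        return (inp - x) / params.tau_BN

    x = integrate_step(deriv, state.x, dt, params.integrator)
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite brainstem state after step")
    return BrainstemState(x=x)


def trigger_hysteresis_curve(
    params: ModelParameters,
    drive_max: float = 2.0,
    ramp_rate: float = 0.1,
    llibn_switch_rate: float = 10.0,
    dt: float | None = None,
) -> tuple[float, float]:
    """Measure the trigger's switching thresholds under quasi-static ramps.

    The rightward motor command is ramped slowly from 0 to ``drive_max``
    and back while the OPN receives only its tonic bias.  The state
    switch is normally read from the OPN: silencing (rate below
    ``opn_silence_threshold``) gives the up-threshold, recovery the
    down-threshold.  When the network has no inhibitory path capable of
    ever silencing the OPN (e.g. the LLIBN->OPN weight is zeroed to
    break the positive feedback loop), the switch is read instead from
    the LLIBN rate crossing ``llibn_switch_rate`` spikes/s, so the
    collapse of hysteresis remains measurable.  Returns
    ``(up_threshold, down_threshold)`` in motor-command units.

    Raises :class:`TriggerDiagnosticError` if no switch occurs in range.
    """
    dt = params.dt if dt is None else dt
    max_inhibition = (params.w_LLIBN_OPN + params.w_MLIBN_OPN) * params.B_m
    use_opn = max_inhibition > params.opn_bias

    def switched(state: BrainstemState) -> bool:
        r = state.rates(params)
        if use_opn:
            return r[OPN] < params.opn_silence_threshold
        return r[LLIBN_R] >= llibn_switch_rate

    state = BrainstemState.initial(params)
    for _ in range(int(0.05 / dt)):  # settle at zero drive
        state = brainstem_step(state, 0.0, 0.0, 0.0, 0.0, 0.0, dt, params)

    n = int(np.ceil(drive_max / (ramp_rate * dt)))
    up_threshold = None
    down_threshold = None
    for k in range(n):  # ramp up
        drive = (k + 1) * ramp_rate * dt
        state = brainstem_step(state, 0.0, drive, 0.0, 0.0, 0.0, dt, params)
        if switched(state):
            up_threshold = drive
            break
    if up_threshold is None:
        raise TriggerDiagnosticError(
            f"no fixation->saccade switch for drives up to {drive_max}"
        )
    for k in range(n):  # ramp down from where the switch occurred
        drive = max(0.0, up_threshold - (k + 1) * ramp_rate * dt)
        state = brainstem_step(state, 0.0, drive, 0.0, 0.0, 0.0, dt, params)
        if not switched(state):
            down_threshold = drive
            break
        if drive == 0.0:
            break
    if down_threshold is None:
        raise TriggerDiagnosticError("no saccade->fixation switch down to zero drive")
    return up_threshold, down_threshold
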