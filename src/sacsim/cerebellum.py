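"""Cerebellar (fastigial) stop circuit.

For each movement direction the circuit integrates an efference copy of
the corresponding MLEBN rate -- a running estimate of the displacement
of the ongoing saccade -- through a second-order system: two cascaded
leaky stages with time constants ``T_cblm1`` and ``T_cblm2``.  Over the
duration of a saccade (comparable to the time constants) the cascade
behaves as an integrator; afterwards it leaks back to zero, so each
saccade's displacement is effectively integrated afresh.  Two rectified
bursts are formed per direction from this estimate ``e`` and the
collicular command ``c``:

    late  = max(F1 * e - F2 * c, 0)
    early = max(F3 * c - F4 * e, 0)

The late burst switches on when the integrated efference copy surpasses
the command, i.e. when the eye approaches the target; it is turned into
a "choke" -- strong subtractive inhibition of the medium-lead burst
neurons driving the movement -- and, summed over both directions, into
a drive that excites the rostral map and inhibits the caudal map,
snapping the collicular hill back to centre at saccade end.  Because
the estimate decays over tens of milliseconds after the burst neurons
stop, the choke and the rostral reset outlast the movement, giving the
system a refractory period that covers the visual feedback delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParameters
from .numerics import integrate_step

__all__ = ["CerebellumState", "cerebellar_bursts", "choke_signal",
           "rostral_reset_drive", "cerebellum_step"]


@dataclass
class CerebellumState:
    """Per-direction integrator stages and cached bursts."""

    e1_l: float = 0.0  # smoothing stage, leftward channel
    e2_l: float = 0.0  # integrated efference copy, leftward channel
    e1_r: float = 0.0
    e2_r: float = 0.0
    c_l: float = 0.0   # collicular command, deg
    c_r: float = 0.0
    early_l: float = 0.0
    early_r: float = 0.0
    late_l: float = 0.0
    late_r: float = 0.0

    @property
    def stages(self) -> np.ndarray:
        return np.array([self.e1_l, self.e2_l, self.e1_r, self.e2_r])

    def reset_integrator(self) -> None:
        """Zero the displacement estimate (the closed loop relies on the
        cascade's own leak instead)."""
        self.e1_l = self.e2_l = self.e1_r = self.e2_r = 0.0
        self.late_l = self.late_r = 0.0


def cerebellar_bursts(
    e2_l: float, e2_r: float, c_l: float, c_r: float, params: ModelParameters
) -> tuple[float, float, float, float]:
    """Rectified (early_l, early_r, late_l, late_r) for the two movement
    channels."""
    late_l = max(params.F1 * e2_l - params.F2 * c_l, 0.0)
    late_r = max(params.F1 * e2_r - params.F2 * c_r, 0.0)
    early_l = max(params.F3 * c_l - params.F4 * e2_l, 0.0)
    early_r = max(params.F3 * c_r - params.F4 * e2_r, 0.0)
    return early_l, early_r, late_l, late_r


def choke_signal(state: CerebellumState, params: ModelParameters) -> tuple[float, float]:
    """Inhibition delivered to the (left, right) medium-lead BNs.

    By default each channel's late burst chokes the burst neurons
    driving that channel's movement; ``crossed_choke`` swaps the sides
    for strict anatomical crossing (behaviourally equivalent in this
    collapsed one-dimensional map, kept for sensitivity analyses).
    """
    ch_l = params.choke_gain * state.late_l
    ch_r = params.choke_gain * state.late_r
    if params.crossed_choke:
        ch_l, ch_r = ch_r, ch_l
    return ch_l, ch_r


def rostral_reset_drive(state: CerebellumState, params: ModelParameters) -> float:
    """Scaled sum of the two late bursts, routed to the collicular map as
    rostral excitation / caudal inhibition."""
    return params.rostral_reset_gain * (state.late_l + state.late_r)


def cerebellum_step(
    state: CerebellumState,
    mlebn_l: float,
    mlebn_r: float,
    c_l: float,
    c_r: float,
    dt: float,
    params: ModelParameters,
) -> CerebellumState:
    """Advance the stop circuit one step with inputs frozen over the step."""
    if min(mlebn_l, mlebn_r) < 0:
        raise ValueError("efference-copy rates must be non-negative")

    g = params.efference_gain

    def deriv(y: np.ndarray) -> np.ndarray:
        e1l, e2l, e1r, e2r = y
        return np.array([
            (g * mlebn_l - e1l) / params.T_cblm1,
            (e1l - e2l) / params.T_cblm2,
            (g * mlebn_r - e1r) / params.T_cblm1,
            (e1r - e2r) / params.T_cblm2,
        ])

    e1l, e2l, e1r, e2r = integrate_step(deriv, state.stages, dt, params.integrator)
    new = CerebellumState(e1_l=e1l, e2_l=e2l, e1_r=e1r, e2_r=e2r, c_l=c_l, c_r=c_r)
    new.early_l, new.early_r, new.late_l, new.late_r = cerebellar_bursts(
        e2l, e2r, c_l, c_r, params
    )
    return new
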