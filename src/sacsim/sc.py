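"""One-dimensional superior colliculus map.

The two colliculi are collapsed into a single signed one-dimensional
structure of ``n_neurons`` leaky-integrator neurons spanning
[-S, +S] mm, rightward eccentricities at positive coordinates and the
shared rostral pole (0 deg) at the map centre.  The map combines
cortical drive, noise and a cerebellar reset drive through a
Mexican-hat lateral connectivity, producing a single self-sustaining
hill of activity.  A thresholded burst layer on top of the buildup
layer supplies the weighted, normalized motor command to the brainstem
burst neurons, while the whole buildup layer (weighted toward the
rostral pole) drives the omnipause neuron.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParameters
from .numerics import integrate_step

__all__ = [
    "SCGeometry",
    "SCMapState",
    "SCOutputs",
    "retinotopic_to_collicular",
    "collicular_to_retinotopic",
    "lateral_weight",
    "lateral_weight_matrix",
    "activation",
    "burst_layer",
    "opn_projection_weights",
    "bn_projection_weights",
    "rostral_profile",
    "inactivation_mask",
    "apply_inactivation",
    "sc_outputs",
    "sc_inputs",
    "sc_step",
]


def retinotopic_to_collicular(D, params: ModelParameters):
    """Map signed eccentricity (deg) to signed collicular position (mm).

    The one-sided logarithmic magnification ``d = B * ln((D + A)/A)`` is
    extended to both directions by odd symmetry.
    """
    D = np.asarray(D, dtype=float)
    d = np.sign(D) * params.B * np.log1p(np.abs(D) / params.A)
    return float(d) if d.ndim == 0 else d


def collicular_to_retinotopic(d, params: ModelParameters):
    """Exact inverse map, mm -> deg; positions must lie within the map."""
    d = np.asarray(d, dtype=float)
    if np.any(np.abs(d) > params.S + 1e-12):
        raise ValueError(f"collicular position outside the map [-S, S]: {d}")
    D = np.sign(d) * params.A * np.expm1(np.abs(d) / params.B)
    return float(D) if D.ndim == 0 else D


@dataclass(frozen=True)
class SCGeometry:
    """Neuron coordinates of the map."""

    positions: np.ndarray      # signed collicular coordinate, mm
    eccentricities: np.ndarray  # signed retinotopic coordinate, deg

    @classmethod
    def from_params(cls, params: ModelParameters) -> "SCGeometry":
        pos = np.linspace(-params.S, params.S, params.n_neurons)
        # exact zero at the midline neuron
        pos[params.n_neurons // 2] = 0.0
        return cls(positions=pos, eccentricities=collicular_to_retinotopic(pos, params))

    @property
    def midline_index(self) -> int:
        return len(self.positions) // 2

    @property
    def spacing(self) -> float:
        return float(self.positions[1] - self.positions[0])


def lateral_weight(i: int, j: int, geometry: SCGeometry, params: ModelParameters) -> float:
    """Mexican-hat connection strength between neurons ``i`` and ``j``."""
    dist = abs(geometry.positions[i] - geometry.positions[j])
    return float(
        (params.A_w + params.C) * np.exp(-(dist**2) / (2 * params.sigma_SC**2))
        - params.C
    )


def lateral_weight_matrix(geometry: SCGeometry, params: ModelParameters) -> np.ndarray:
    """Full symmetric lateral weight matrix (short-range excitation,
    long-range inhibition)."""
    d = geometry.positions[:, None] - geometry.positions[None, :]
    return (params.A_w + params.C) * np.exp(-(d**2) / (2 * params.sigma_SC**2)) - params.C


def activation(u, params: ModelParameters):
    """Logistic buildup activation ``a(u) = F / (1 + exp(-beta_u * u))``."""
    u = np.asarray(u, dtype=float)
    a = params.F / (1.0 + np.exp(np.clip(-params.beta_u * u, -700.0, 700.0)))
    return float(a) if a.ndim == 0 else a


def burst_layer(a, params: ModelParameters):
    """Thresholded copy of the buildup layer (same threshold map-wide).

    The boundary is inclusive: a neuron exactly at threshold bursts.
    """
    a = np.asarray(a, dtype=float)
    out = np.where(a >= params.burst_threshold, a, 0.0)
    return float(out) if out.ndim == 0 else out


def opn_projection_weights(geometry: SCGeometry, params: ModelParameters) -> np.ndarray:
    """Buildup -> OPN weights, maximal (1) at the rostral pole, 0 at +-S."""
    return 1.0 - np.abs(geometry.positions) / params.S


def bn_projection_weights(geometry: SCGeometry) -> np.ndarray:
    """Burst -> BN weights: distance from the rostral pole, mm."""
    return np.abs(geometry.positions)


def rostral_profile(geometry: SCGeometry, params: ModelParameters) -> np.ndarray:
    """Spatial profile of the cerebellar reset drive.

    +1 for neurons within ``rostral_extent`` of the map centre (rostral
    excitation), -1 elsewhere (caudal inhibition of equal magnitude).
    """
    return np.where(np.abs(geometry.positions) <= params.rostral_extent, 1.0, -1.0)


def inactivation_mask(
    geometry: SCGeometry, interval: tuple[float, float] | None
) -> np.ndarray:
    """Boolean mask of neurons whose *output* is nulled.

    ``interval`` is an open/closed (lo, hi] range of signed collicular
    positions in mm; ``None`` or an empty range inactivates nothing.
    """
    n = len(geometry.positions)
    mask = np.zeros(n, dtype=bool)
    if interval is None:
        return mask
    lo, hi = interval
    if not (-geometry.positions[-1] - 1e-9 <= lo <= geometry.positions[-1] + 1e-9):
        raise ValueError(f"inactivation bound {lo} outside the map")
    mask[(geometry.positions > lo) & (geometry.positions <= hi)] = True
    return mask


@dataclass
class SCMapState:
    """Integrator states and derived layers of the map."""

    u: np.ndarray       # integrator states
    a: np.ndarray       # buildup activations, spikes/s
    burst: np.ndarray   # burst-layer outputs, spikes/s
    W: np.ndarray       # lateral weight matrix

    @classmethod
    def initial(cls, geometry: SCGeometry, params: ModelParameters) -> "SCMapState":
        u = np.zeros(len(geometry.positions))
        a = activation(u, params)
        return cls(u=u, a=a, burst=burst_layer(a, params),
                   W=lateral_weight_matrix(geometry, params))


@dataclass(frozen=True)
class SCOutputs:
    """Scalar drives leaving the map."""

    drive_opn: float       # weighted buildup sum to the OPN
    drive_bn_left: float   # normalized centre-of-activity command, mm
    drive_bn_right: float  # normalized centre-of-activity command, mm


def sc_outputs(
    a: np.ndarray,
    burst: np.ndarray,
    geometry: SCGeometry,
    params: ModelParameters,
    inactive: np.ndarray | None = None,
) -> SCOutputs:
    """Compute the three descending drives.

    The OPN drive is the rostrally weighted sum over the whole buildup
    layer.  Each BN drive is the distance-weighted sum over its side of
    the burst layer, divided by the total burst activity of the whole
    map plus a small fraction of the total buildup activity, so the
    command encodes the *location* rather than the amount of activity.
    Inactivated neurons are removed from the outputs only; the map
    dynamics are untouched.
    """
    if inactive is not None and inactive.any():
        a = np.where(inactive, 0.0, a)
        burst = np.where(inactive, 0.0, burst)
    pos = geometry.positions
    drive_opn = float(np.dot(opn_projection_weights(geometry, params), a))
    denom = float(burst.sum() + params.buildup_fraction * a.sum())
    if denom <= 0.0:
        return SCOutputs(drive_opn=max(drive_opn, 0.0), drive_bn_left=0.0,
                         drive_bn_right=0.0)
    w = bn_projection_weights(geometry)
    right = float(np.dot(w[pos > 0], burst[pos > 0]) / denom)
    left = float(np.dot(w[pos < 0], burst[pos < 0]) / denom)
    return SCOutputs(drive_opn=max(drive_opn, 0.0),
                     drive_bn_left=left, drive_bn_right=right)


def apply_inactivation(
    state: "SCMapState",
    region: tuple[float, float] | None,
    geometry: SCGeometry,
    params: ModelParameters,
) -> SCOutputs:
    """Descending drives with the output of a focal region nulled.

    ``region`` is a (lo, hi] interval of signed collicular positions in
    mm (an empty or ``None`` region is a no-op).  Only the outputs are
    silenced; the map dynamics are untouched.
    """
    mask = inactivation_mask(geometry, region)
    return sc_outputs(state.a, state.burst, geometry, params, inactive=mask)


def sc_inputs(
    a: np.ndarray,
    W: np.ndarray,
    cortical_input: np.ndarray,
    noise: np.ndarray,
    cblm_rostral_drive: float,
    rostral: np.ndarray,
) -> np.ndarray:
    """Total per-neuron input: lateral recurrence + cortex + noise +
    cerebellar reset drive."""
    return W @ a + cortical_input + noise + cblm_rostral_drive * rostral


def sc_step(
    state: SCMapState,
    cortical_input: np.ndarray,
    noise: np.ndarray,
    cblm_rostral_drive: float,
    dt: float,
    geometry: SCGeometry,
    params: ModelParameters,
) -> SCMapState:
    """Advance the map one step with all inputs frozen over the step.

    The closed-loop engine integrates the map jointly with the rest of
    the system; this standalone step uses the same integration scheme
    and is intended for isolated-map studies and tests.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rostral = rostral_profile(geometry, params)

    def deriv(u: np.ndarray) -> np.ndarray:
        a = activation(u, params)
        total = sc_inputs(a, state.W, cortical_input, noise, cblm_rostral_drive, rostral)
        return (total - u) / params.tau_SC

    u = integrate_step(deriv, state.u, dt, params.integrator)
    if not np.all(np.isfinite(u)):
        raise FloatingPointError("non-finite collicular state after step")
    a = activation(u, params)
    return SCMapState(u=u, a=a, burst=burst_layer(a, params), W=state.W)
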