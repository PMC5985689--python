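"""Model parameters: published constants plus engine/plant constants.

The model is specified by a flat set of named constants.  The published
constants (brainstem rate function, collicular map geometry and
connectivity, cortical drive widths, noise correlation constants,
brainstem synaptic weights, cerebellar gains) carry the values of the
source model.  Everything the published description leaves open --
input gains between stages, the oculomotor plant, the noise amplitude,
detection thresholds -- is a first-class, documented parameter here, so
that experiment presets are pure parameter edits.

Units follow the field conventions: firing rates in spikes/s, collicular
distances in mm, eccentricities in degrees, times in seconds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "ModelParameters",
    "ParameterError",
    "ConfigError",
    "default_parameters",
    "load_config",
    "save_config",
]


class ParameterError(ValueError):
    """A parameter value violates a model invariant."""


class ConfigError(ValueError):
    """A configuration file could not be interpreted."""


@dataclass
class ModelParameters:
    # --- Brainstem burst neurons and omnipause neuron -------------------
    #: leaky-integrator time constant of every brainstem neuron, s
    tau_BN: float = 0.001
    #: curvature of the exponential rate function, input units
    b: float = 8.0
    #: maximum burst-neuron firing rate, spikes/s
    B_m: float = 800.0
    #: offset of the rate function (fixed at 0 in the source model)
    e0: float = 0.0
    #: OPN saturation rate, spikes/s.  Kept separate from B_m so that
    #: lowering the burst-neuron gain (the PSP manipulation) does not
    #: also weaken the omnipause neuron; defaults to the same value.
    opn_max_rate: float = 800.0
    #: tonic drive to the OPN, spikes/s
    opn_bias: float = 50.0
    #: synaptic weight OPN -> long-lead inhibitory burst neurons (weak)
    w_OPN_LLIBN: float = 0.0015
    #: synaptic weight OPN -> medium-lead burst neurons (strong)
    w_OPN_BN: float = 0.2
    #: synaptic weight LLIBN -> OPN (strong; closes the trigger loop)
    w_LLIBN_OPN: float = 10.0
    #: crossed inhibition from contralateral IBNs onto each burst neuron
    W_IBN_BN: float = 0.1
    #: optional MLIBN -> OPN weight (anatomically suggested, absent from
    #: the published weight table; disabled by default)
    w_MLIBN_OPN: float = 0.0
    #: gain applied to the collicular OPN drive before it reaches the OPN
    k_opn: float = 0.009
    #: gain applied to the collicular motor command (deg) at the
    #: medium-lead BNs (sets eye speed per degree of command)
    k_bn: float = 1.0
    #: gain of the command at the long-lead IBNs (sets the trigger
    #: sensitivity: smaller commands can silence the OPN as this grows)
    k_llibn: float = 5.5
    #: weight of the inhibition each side's BNs receive from the opposite
    #: side's command, so a hill centred at the rostral pole yields zero
    #: net drive to both sides
    bn_cross_inhibition: float = 1.0

    # --- Superior colliculus map ----------------------------------------
    #: maximum buildup activation, spikes/s
    F: float = 500.0
    #: retinal magnification offset, deg
    A: float = 3.0
    #: collicular map scale, mm
    B: float = 1.4
    #: maximum lateral excitation
    A_w: float = 1.0
    #: maximum lateral inhibition
    C: float = 1.0
    #: width of the lateral-excitation Gaussian, mm
    sigma_SC: float = 0.5
    #: collicular time constant, s
    tau_SC: float = 0.005
    #: half-length of the map, mm (map spans [-S, S])
    S: float = 5.0
    #: slope of the logistic activation
    beta_u: float = 0.1
    #: number of map neurons (odd, so one neuron sits at 0 mm)
    n_neurons: int = 101
    #: burst-layer threshold, spikes/s.  Sits above the fixation buildup
    #: plateau but below saccade-related peaks (0.6 * F by default).
    burst_threshold: float = 300.0
    #: fraction of buildup activity added to the burst normalization
    #: denominator for stability
    buildup_fraction: float = 0.05

    # --- Cortical inputs (FEF drive, BG disinhibition) ------------------
    #: width of the FEF excitatory Gaussian, mm
    sigma_FEF: float = 0.5
    #: width of the BG inhibitory surround, mm
    sigma_BG: float = 1.0
    #: FEF drive at zero retinal error (fixation is still driven)
    fef_base: float = 2000.0
    #: additional FEF drive at large eccentricity
    fef_gain: float = 10000.0
    #: eccentricity scale of the saturating FEF gain, deg
    fef_ecc_scale: float = 2.0
    #: depth of the BG surround inhibition
    bg_depth: float = 15000.0

    # --- Noise field -----------------------------------------------------
    #: temporal correlation constant of the noise, s
    tau_noise: float = 0.02
    #: spatial correlation width of the noise, mm
    sigma_noise: float = 0.2
    #: stationary standard deviation of the noise input to each map
    #: neuron, input units.  The published description gives the noise
    #: correlation constants but no amplitude; this default is calibrated
    #: so the default fixation simulation produces 1-2 microsaccades/s.
    noise_gain: float = 850.0

    # --- Cerebellum (fastigial stop circuit) -----------------------------
    #: first cerebellar integrator constant, s
    T_cblm1: float = 0.02
    #: second cerebellar integrator constant, s
    T_cblm2: float = 0.02
    #: late-burst gain on the integrated efference copy
    F1: float = 0.1
    #: late-burst gain on the collicular command
    F2: float = 0.03
    #: early-burst gain on the collicular command
    F3: float = 1.0
    #: early-burst gain on the integrated efference copy
    F4: float = 0.13
    #: gain on the MLEBN efference copy entering the cerebellar integrator
    efference_gain: float = 0.013
    #: gain turning the late burst into the brainstem choke
    choke_gain: float = 20000.0
    #: if True, the late burst chokes the anatomically crossed side
    #: instead of the side driving the ongoing movement
    crossed_choke: bool = False
    #: gain turning the summed late bursts into the rostral reset drive
    rostral_reset_gain: float = 1000000.0
    #: half-width of the rostral zone excited by the reset drive, mm
    rostral_extent: float = 0.5

    # --- Engine, plant, detection ----------------------------------------
    #: integration step, s
    dt: float = 0.001
    #: visual feedback delay, s
    visual_delay: float = 0.050
    #: integration scheme: "rk3" (fixed-step Bogacki-Shampine) or "euler"
    integrator: str = "rk3"
    #: deg/s of eye velocity per spike/s of net MLEBN drive
    velocity_gain: float = 0.62
    #: eye-plant time constant, s
    tau_plant: float = 0.15
    #: slide (pulse low-pass) time constant, s
    tau_slide: float = 0.05
    #: fraction of the pulse routed through the slide filter
    slide_fraction: float = 0.1
    #: OPN rate below which the engine flags "saccade in progress", spikes/s
    opn_silence_threshold: float = 1.0
    #: saccade detection: velocity threshold, deg/s
    vel_threshold: float = 5.0
    #: saccade detection: minimum event duration, s
    min_duration: float = 0.003
    #: saccade detection: events closer than this are merged, s
    merge_interval: float = 0.010

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Raise :class:`ParameterError` on any invariant violation."""
        positive = [
            "tau_BN", "b", "B_m", "opn_max_rate", "F", "A", "B",
            "sigma_SC", "tau_SC", "S", "sigma_FEF", "sigma_BG",
            "tau_noise", "sigma_noise", "T_cblm1", "T_cblm2",
            "dt", "tau_plant", "tau_slide", "velocity_gain",
            "burst_threshold", "vel_threshold",
        ]
        for name in positive:
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and v > 0):
                raise ParameterError(f"{name} must be strictly positive, got {v!r}")
        nonnegative = [
            "e0", "opn_bias", "w_OPN_LLIBN", "w_OPN_BN", "w_LLIBN_OPN",
            "W_IBN_BN", "w_MLIBN_OPN", "k_opn", "k_bn", "k_llibn", "A_w", "C",
            "beta_u", "buildup_fraction", "fef_base", "fef_gain",
            "fef_ecc_scale", "bg_depth", "noise_gain", "F1", "F2", "F3",
            "F4", "bn_cross_inhibition", "efference_gain", "choke_gain",
            "rostral_reset_gain",
            "rostral_extent", "visual_delay", "slide_fraction",
            "opn_silence_threshold", "min_duration", "merge_interval",
        ]
        for name in nonnegative:
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and v >= 0):
                raise ParameterError(f"{name} must be non-negative, got {v!r}")
        if self.n_neurons < 3 or self.n_neurons % 2 == 0:
            raise ParameterError(
                f"n_neurons must be odd and >= 3 so one neuron sits at 0 mm, "
                f"got {self.n_neurons}"
            )
        if not self.burst_threshold < self.F:
            raise ParameterError("burst_threshold must lie below F")
        if self.integrator not in ("rk3", "euler"):
            raise ParameterError(f"unknown integrator {self.integrator!r}")
        if self.visual_delay < self.dt:
            raise ParameterError("visual_delay must be at least one step")

    def replace(self, **overrides: Any) -> "ModelParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        unknown = set(overrides) - {f.name for f in fields(self)}
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def default_parameters() -> ModelParameters:
    """Return the default parameter set (published constants + engine defaults)."""
    return ModelParameters()


def load_config(path: str | Path) -> ModelParameters:
    """Load parameters from a flat YAML mapping.

    Missing keys fall back to defaults; unknown keys are rejected with a
    :class:`ConfigError` naming the offending key(s).  An empty file
    yields the defaults.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} must contain a flat key/value mapping")
    valid = {f.name for f in fields(ModelParameters)}
    unknown = set(raw) - valid
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
    try:
        return ModelParameters(**raw)
    except ParameterError:
        raise
    except TypeError as exc:
        raise ConfigError(f"bad configuration value: {exc}") from exc


def save_config(params: ModelParameters, path: str | Path) -> None:
    """Write the full parameter set as a flat YAML mapping."""
    Path(path).write_text(
        yaml.safe_dump(params.to_dict(), sort_keys=False, default_flow_style=False)
    )
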