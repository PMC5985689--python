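"""Named experiment presets and condition batteries.

Each preset bundles a target trajectory, a duration and a set of
parameter overrides expressed as deltas from the defaults, so a
condition differs from the healthy model only in the listed overrides.
The disease conditions follow the modeling hypotheses for parkinsonian
intrusions: Parkinson's disease as increased collicular noise alone,
progressive supranuclear palsy as increased noise plus a reduced
burst-neuron gain (``B_m``), and spinocerebellar ataxia as a weakened
cerebellar stop signal.  Focal rostral inactivation nulls the output of
the map neurons just caudal to the midline on one side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

import pandas as pd

from .analysis import detect_saccades, summarize_fixation
from .engine import SimulationResult, run_simulation
from .params import ModelParameters, default_parameters

__all__ = [
    "ExperimentPreset", "PresetError", "PRESET_NAMES", "preset",
    "run_preset", "run_preset_battery", "parameter_sweep_grid",
    # condition scaling factors
    "PD_NOISE_FACTOR", "PSP_NOISE_FACTOR", "PSP_BN_GAIN", "SCA_STOP_FACTOR",
    "INACTIVATION_REGION",
]

#: noise multiplier modeling basal-ganglia impairment in PD
PD_NOISE_FACTOR = 2.0
#: noise multiplier for PSP
PSP_NOISE_FACTOR = 4.0
#: reduced burst-neuron saturation rate for PSP, spikes/s
PSP_BN_GAIN = 300.0
#: multiplier on the cerebellar late-burst gain (F1) modeling the
#: weakened stop signal in spinocerebellar ataxia
SCA_STOP_FACTOR = 0.5
#: default rostral inactivation region (lo, hi], mm, right side
INACTIVATION_REGION = (0.4, 1.0)


class PresetError(KeyError):
    """Unknown preset name."""


@dataclass(frozen=True)
class ExperimentPreset:
    name: str
    overrides: dict[str, Any]
    target: Any                       # constant, callable or step schedule
    duration: float                   # s
    inactivation: tuple[float, float] | None = None
    n_seeds: int = 5

    def parameters(self, base: ModelParameters | None = None) -> ModelParameters:
        base = base or default_parameters()
        return base.replace(**self.overrides)


def _builtin_presets() -> dict[str, ExperimentPreset]:
    d = default_parameters()
    return {
        "single_saccade_2deg": ExperimentPreset(
            name="single_saccade_2deg",
            overrides={"noise_gain": 0.0},
            target=[(0.2, 2.0)],
            duration=1.0,
            n_seeds=1,
        ),
        "fixation_default": ExperimentPreset(
            name="fixation_default",
            overrides={},
            target=0.0,
            duration=100.0,
        ),
        "sc_inactivation": ExperimentPreset(
            name="sc_inactivation",
            overrides={},
            target=0.0,
            duration=100.0,
            inactivation=INACTIVATION_REGION,
        ),
        "pd": ExperimentPreset(
            name="pd",
            overrides={"noise_gain": PD_NOISE_FACTOR * d.noise_gain},
            target=0.0,
            duration=100.0,
        ),
        "psp": ExperimentPreset(
            name="psp",
            overrides={
                "noise_gain": PSP_NOISE_FACTOR * d.noise_gain,
                "B_m": PSP_BN_GAIN,
            },
            target=0.0,
            duration=100.0,
        ),
        "sca": ExperimentPreset(
            name="sca",
            overrides={"F1": SCA_STOP_FACTOR * d.F1},
            target=0.0,
            duration=5.0,
        ),
    }


PRESET_NAMES = tuple(_builtin_presets())


def preset(name: str) -> ExperimentPreset:
    """Return a built-in preset by name; raise listing valid names."""
    table = _builtin_presets()
    try:
        return table[name]
    except KeyError:
        raise PresetError(
            f"unknown preset {name!r}; valid names: {sorted(table)}"
        ) from None


def run_preset(
    p: ExperimentPreset | str,
    seed: int = 0,
    duration: float | None = None,
    base: ModelParameters | None = None,
    record_maps: bool = False,
) -> SimulationResult:
    """Run one preset with one seed (optionally overriding the duration)."""
    if isinstance(p, str):
        p = preset(p)
    return run_simulation(
        p.parameters(base),
        target=p.target,
        duration=duration if duration is not None else p.duration,
        seed=seed,
        condition=p.name,
        inactivation=p.inactivation,
        record_maps=record_maps,
    )


def _stats_row(result: SimulationResult) -> dict[str, float]:
    events = detect_saccades(result.eye_pos, result.dt, result.params)
    stats = summarize_fixation(events, result.eye_pos, result.time[-1] + result.dt)
    return {
        "rate": stats.rate,
        "median_magnitude": stats.magnitude_quantiles["median"],
        "median_isi": stats.isi_quantiles["median"],
        "main_sequence_slope": stats.main_sequence_slope,
        "mean_eye_position": stats.mean_eye_position,
        "swj_count": float(stats.swj_count),
        "oscillation_count": float(stats.oscillation_count),
        "n_events": float(stats.n_events),
    }


def run_preset_battery(
    presets: Sequence[ExperimentPreset | str],
    seeds: Sequence[int],
    duration: float | None = None,
    base: ModelParameters | None = None,
) -> pd.DataFrame:
    """Fixation statistics per (preset, seed), plus per-preset median rows.

    Median rows carry ``seed == -1``.  Failures propagate with the
    preset name and seed attached.
    """
    if len(seeds) == 0:
        raise ValueError("at least one seed is required")
    rows = []
    for p in presets:
        p = preset(p) if isinstance(p, str) else p
        for seed in seeds:
            try:
                result = run_preset(p, seed=seed, duration=duration, base=base)
            except Exception as exc:
                raise RuntimeError(
                    f"simulation failed for preset {p.name!r}, seed {seed}"
                ) from exc
            rows.append({"preset": p.name, "seed": seed, **_stats_row(result)})
    frame = pd.DataFrame(rows)
    medians = (
        frame.drop(columns="seed")
        .groupby("preset", sort=False)
        .median(numeric_only=True)
        .reset_index()
    )
    medians.insert(1, "seed", -1)
    return pd.concat([frame, medians], ignore_index=True)


def parameter_sweep_grid(
    noise_gains: Sequence[float],
    bn_gains: Sequence[float],
    seeds: Sequence[int],
    duration: float = 30.0,
    base: ModelParameters | None = None,
) -> pd.DataFrame:
    """Noise x burst-neuron-gain grid of fixation statistics.

    Reproduces the qualitative pattern of the disease continuum: rate
    grows with noise, velocity (main-sequence slope) falls with the
    burst-neuron gain.  Returns one median-across-seeds row per
    (noise_gain, B_m) cell.
    """
    base = base or default_parameters()
    rows = []
    for bm in bn_gains:
        for ng in noise_gains:
            cell = []
            for seed in seeds:
                result = run_simulation(
                    base.replace(noise_gain=ng, B_m=bm),
                    target=0.0, duration=duration, seed=seed,
                    condition=f"sweep_ng{ng:g}_bm{bm:g}",
                )
                cell.append(_stats_row(result))
            med = pd.DataFrame(cell).median(numeric_only=True).to_dict()
            rows.append({"noise_gain": ng, "B_m": bm, **med})
    return pd.DataFrame(rows)
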