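"""Saccade detection and fixation statistics.

A velocity-threshold detector extracts saccadic events from simulated
eye-position traces: samples where the smoothed speed exceeds a
threshold for a minimum duration form an event, and events separated by
less than a merge interval are fused.  Summary statistics cover the
quantities usually reported for fixational eye movements: rate,
magnitude and inter-saccadic-interval quantiles, the main-sequence
slope (peak velocity against magnitude, fitted through the origin),
mean eye position, square-wave-jerk pairs and macrosaccadic-oscillation
runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .params import ModelParameters, default_parameters

__all__ = [
    "SaccadeEvent",
    "FixationStatistics",
    "saccadic_velocity",
    "detect_saccades",
    "summarize_fixation",
    "detect_swj",
    "detect_oscillations",
    "events_to_frame",
]


@dataclass(frozen=True)
class SaccadeEvent:
    onset: float          # s
    offset: float         # s
    amplitude: float      # deg, signed displacement
    peak_velocity: float  # deg/s
    direction: str        # "left" | "right"

    @property
    def magnitude(self) -> float:
        return abs(self.amplitude)

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def saccadic_velocity(pos: np.ndarray, dt: float) -> np.ndarray:
    """Eye velocity by a 5-sample quadratic Savitzky-Golay derivative."""
    pos = np.asarray(pos, dtype=float)
    if len(pos) < 5:
        return np.gradient(pos, dt) if len(pos) > 1 else np.zeros_like(pos)
    return savgol_filter(pos, window_length=5, polyorder=2, deriv=1, delta=dt)


def detect_saccades(
    pos: np.ndarray,
    dt: float,
    params: ModelParameters | None = None,
) -> list[SaccadeEvent]:
    """Detect saccades in a uniformly sampled position trace (deg).

    An event is a run of samples with ``|velocity| > vel_threshold``
    lasting at least ``min_duration``; dual-threshold refinement then
    extends each event's boundaries outward while the speed stays above
    one fifth of the threshold, so the slow tail of the movement is
    attributed to the event.  Events closer than ``merge_interval`` are
    merged.  Amplitude is the position change between event onset and
    offset.  Detection is invariant to constant position offsets.  A
    trace shorter than the minimum duration yields an empty list.
    """
    params = params or default_parameters()
    pos = np.asarray(pos, dtype=float)
    min_samples = max(int(round(params.min_duration / dt)), 1)
    if len(pos) <= min_samples:
        return []
    vel = saccadic_velocity(pos, dt)
    above = np.abs(vel) > params.vel_threshold
    if not above.any():
        return []
    low = np.abs(vel) > 0.2 * params.vel_threshold

    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)  # exclusive
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(pos))
    # extend boundaries outward through the low-speed skirt of the event
    for i, (s, e) in enumerate(zip(starts, ends)):
        while s > 0 and low[s - 1]:
            s -= 1
        while e < len(pos) and low[e]:
            e += 1
        starts[i], ends[i] = s, min(e, len(pos))

    # merge events separated by short gaps
    merged: list[list[int]] = []
    gap = int(round(params.merge_interval / dt))
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    events = []
    for s, e in merged:
        if e - s < min_samples:
            continue
        amplitude = float(pos[min(e, len(pos) - 1)] - pos[s])
        peak = float(np.max(np.abs(vel[s:e])))
        events.append(SaccadeEvent(
            onset=s * dt,
            offset=e * dt,
            amplitude=amplitude,
            peak_velocity=peak,
            direction="right" if amplitude >= 0 else "left",
        ))
    return events


def main_sequence_slope(events: list[SaccadeEvent]) -> float:
    """Least-squares slope through the origin of peak velocity vs magnitude
    ((deg/s)/deg); NaN with fewer than two events."""
    if len(events) < 2:
        return float("nan")
    m = np.array([ev.magnitude for ev in events])
    v = np.array([ev.peak_velocity for ev in events])
    denom = float(np.dot(m, m))
    return float(np.dot(v, m) / denom) if denom > 0 else float("nan")


@dataclass(frozen=True)
class FixationStatistics:
    n_events: int
    duration: float
    rate: float                      # events/s
    magnitude_quantiles: dict[str, float]   # deg; NaN-valued if no events
    isi_quantiles: dict[str, float]         # s; NaN-valued if < 2 events
    main_sequence_slope: float       # (deg/s)/deg; NaN if < 2 events
    mean_eye_position: float         # deg
    swj_count: int
    oscillation_count: int


def _quantiles(values: np.ndarray) -> dict[str, float]:
    keys = {"q25": 0.25, "median": 0.5, "q75": 0.75}
    if len(values) == 0:
        return {k: float("nan") for k in keys}
    return {k: float(np.quantile(values, q)) for k, q in keys.items()}


def summarize_fixation(
    events: list[SaccadeEvent],
    pos: np.ndarray,
    duration: float,
) -> FixationStatistics:
    """Summary statistics of a fixation run."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    mags = np.array([ev.magnitude for ev in events])
    onsets = np.array([ev.onset for ev in events])
    isis = np.diff(onsets) if len(onsets) >= 2 else np.array([])
    return FixationStatistics(
        n_events=len(events),
        duration=float(duration),
        rate=len(events) / duration,
        magnitude_quantiles=_quantiles(mags),
        isi_quantiles=_quantiles(isis),
        main_sequence_slope=main_sequence_slope(events),
        mean_eye_position=float(np.mean(pos)),
        swj_count=detect_swj(events)[0],
        oscillation_count=detect_oscillations(events),
    )


def detect_swj(
    events: list[SaccadeEvent],
    max_isi: float = 0.5,
    ratio_band: tuple[float, float] = (0.5, 2.0),
) -> tuple[int, list[tuple[int, int]]]:
    """Count square-wave-jerk pairs among time-ordered events.

    A pair (i, i+1) qualifies when the directions are opposite, the
    inter-saccadic interval is at most ``max_isi`` and the magnitude
    ratio lies within ``ratio_band`` (conventional clinical criteria).
    """
    pairs = []
    for i in range(len(events) - 1):
        a, b = events[i], events[i + 1]
        if a.direction == b.direction:
            continue
        if b.onset - a.onset > max_isi:
            continue
        if a.magnitude == 0 or b.magnitude == 0:
            continue
        ratio = b.magnitude / a.magnitude
        if ratio_band[0] <= ratio <= ratio_band[1]:
            pairs.append((i, i + 1))
    return len(pairs), pairs


def detect_oscillations(
    events: list[SaccadeEvent],
    max_isi: float = 0.5,
    min_run: int = 3,
    min_magnitude: float = 0.5,
) -> int:
    """Count macrosaccadic-oscillation runs among time-ordered events.

    A run of at least ``min_run`` consecutive direction-alternating
    events, each of magnitude at least ``min_magnitude`` (macrosaccadic:
    ordinary fixational microsaccades do not qualify) and each within
    ``max_isi`` of its predecessor, counts as one oscillation; a longer
    alternation is still a single run.
    """
    count = 0
    run = 1 if events and events[0].magnitude >= min_magnitude else 0
    for i in range(1, len(events)):
        qualifies = (
            events[i].magnitude >= min_magnitude
            and events[i - 1].magnitude >= min_magnitude
            and events[i].direction != events[i - 1].direction
            and events[i].onset - events[i - 1].onset <= max_isi
        )
        if qualifies:
            run = max(run, 1) + 1
        else:
            if run >= min_run:
                count += 1
            run = 1 if events[i].magnitude >= min_magnitude else 0
    if run >= min_run:
        count += 1
    return count


def events_to_frame(events: list[SaccadeEvent]) -> pd.DataFrame:
    """One row per detected event."""
    return pd.DataFrame([
        {
            "onset": ev.onset, "offset": ev.offset, "duration": ev.duration,
            "amplitude": ev.amplitude, "magnitude": ev.magnitude,
            "peak_velocity": ev.peak_velocity, "direction": ev.direction,
        }
        for ev in events
    ])
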