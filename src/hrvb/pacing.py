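"""Paced-breathing protocol generation, adaptive guidance, and monitoring.

A pacer protocol is either a stepped grid (descending frequencies held for
a fixed duration each), a sliding sweep (frequency ramped linearly in time),
or a fixed rate.  The waveform generator integrates breathing phase so that
guidance displays, the simulator, and breath-window bookkeeping all share
one clock.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import BoundaryWarning, ProtocolWarning

__all__ = [
    "PacerProtocol",
    "PacerTrace",
    "PacerState",
    "AlertEvent",
    "build_stepped_protocol",
    "build_sliding_protocol",
    "build_fixed_protocol",
    "pacer_waveform",
    "breath_starts",
    "adaptive_adjust",
    "detect_deviation",
    "adherence_check",
]

#: admissible guided breathing frequencies, breaths/min
FREQ_BOUNDS = (4.0, 8.5)

#: adaptive fine-tuning increment, breaths/min
ADJUST_STEP = 0.25


@dataclass(frozen=True)
class PacerProtocol:
    kind: str  # stepped | sliding | fixed
    frequencies: tuple = ()  # stepped grid, breaths/min (descending)
    step_duration: float = 180.0  # s per stepped frequency
    start_bpm: float = 0.0  # sliding sweep start
    end_bpm: float = 0.0  # sliding sweep end
    duration: float = 0.0  # sliding/fixed total duration, s
    fixed_bpm: float = 0.0
    inhale_fraction: float = 0.4

    def __post_init__(self):
        if not 0 < self.inhale_fraction < 1:
            raise ValueError("inhale_fraction must lie in (0, 1)")
        for f in self._all_freqs():
            if not FREQ_BOUNDS[0] <= f <= FREQ_BOUNDS[1]:
                raise ValueError(f"frequency {f} outside {FREQ_BOUNDS} breaths/min")
        if self.total_duration <= 0:
            raise ValueError("protocol duration must be positive")

    def _all_freqs(self):
        if self.kind == "stepped":
            return self.frequencies
        if self.kind == "sliding":
            return (self.start_bpm, self.end_bpm)
        return (self.fixed_bpm,)

    @property
    def total_duration(self) -> float:
        if self.kind == "stepped":
            return self.step_duration * len(self.frequencies)
        return self.duration

    @property
    def freq_bounds(self) -> tuple[float, float]:
        fs = self._all_freqs()
        return (min(fs), max(fs))


@dataclass(frozen=True)
class PacerTrace:
    """Sampled pacer output on a closed grid t[0]=0 .. t[-1]=duration."""

    t: np.ndarray  # s
    phase: np.ndarray  # radians, non-decreasing, phase[0] = 0
    freq: np.ndarray  # breaths/min target at each sample
    fs: float


@dataclass
class PacerState:
    t: float  # s
    target_freq: float  # breaths/min
    resp_phase: float = 0.0  # radians


@dataclass(frozen=True)
class AlertEvent:
    time: float | None  # s within session; None for session_missed
    type: str  # frequency_deviation | depth_deviation | session_missed
    detail: str
    magnitude: float


def build_stepped_protocol(
    grid_hi: float = 8.0,
    grid_lo: float = 4.5,
    step: float = 0.5,
    step_duration: float = 180.0,
) -> PacerProtocol:
    """Descending frequency grid, inclusive of both ends when reachable.

    With the defaults this is the 8 -> 4.5 breaths/min ladder in 0.5
    decrements, 3 min per rung (8 rungs, 1440 s).
    """
    if grid_hi < grid_lo:
        raise ValueError("grid_hi must not be below grid_lo")
    if step <= 0 or step_duration <= 0:
        raise ValueError("step and step_duration must be positive")
    n = int(np.floor((grid_hi - grid_lo) / step + 1e-9)) + 1
    freqs = tuple(round(grid_hi - k * step, 10) for k in range(n))
    if abs(freqs[-1] - grid_lo) > 1e-9:
        warnings.warn(
            f"grid_lo {grid_lo} not reachable from {grid_hi} in steps of {step}; "
            f"grid ends at {freqs[-1]}",
            ProtocolWarning,
        )
    return PacerProtocol(kind="stepped", frequencies=freqs, step_duration=step_duration)


def build_sliding_protocol(
    start_bpm: float, end_bpm: float, duration: float
) -> PacerProtocol:
    return PacerProtocol(
        kind="sliding", start_bpm=start_bpm, end_bpm=end_bpm, duration=duration
    )


def build_fixed_protocol(bpm: float, duration: float) -> PacerProtocol:
    return PacerProtocol(kind="fixed", fixed_bpm=bpm, duration=duration)


def _freq_of_t(protocol: PacerProtocol, t: np.ndarray) -> np.ndarray:
    if protocol.kind == "stepped":
        idx = np.minimum(
            (t / protocol.step_duration).astype(int), len(protocol.frequencies) - 1
        )
        return np.asarray(protocol.frequencies, dtype=float)[idx]
    if protocol.kind == "sliding":
        frac = np.clip(t / protocol.duration, 0.0, 1.0)
        return protocol.start_bpm + (protocol.end_bpm - protocol.start_bpm) * frac
    return np.full(t.shape, float(protocol.fixed_bpm))


def pacer_waveform(protocol: PacerProtocol, fs: float = 8.0) -> PacerTrace:
    """Integrate breathing phase dphi/dt = 2*pi*freq(t)/60 over the protocol.

    The grid is closed (both 0 and the total duration are samples) so that
    cumulative phase at step boundaries is exact: a 180 s step at 6
    breaths/min advances the phase by exactly 18 cycles.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    total = protocol.total_duration
    n = int(round(total * fs))
    t = np.arange(n + 1) / fs
    freq = _freq_of_t(protocol, t)
    dphi = 2.0 * np.pi * freq[:-1] / 60.0 / fs
    phase = np.concatenate(([0.0], np.cumsum(dphi)))
    return PacerTrace(t=t, phase=phase, freq=freq, fs=fs)


def breath_starts(trace: PacerTrace) -> np.ndarray:
    """Times at which the pacer phase crosses multiples of 2*pi."""
    n_cycles = int(np.floor(trace.phase[-1] / (2.0 * np.pi) + 1e-9))
    targets = 2.0 * np.pi * np.arange(n_cycles + 1)
    return np.interp(targets, trace.phase, trace.t)


def adaptive_adjust(
    state: PacerState,
    recent_amps,
    resting_freq: float = 12.0,
    bounds: tuple[float, float] = FREQ_BOUNDS,
    breaths_since_adjust: int = 3,
) -> float:
    """Fine-tune the guiding frequency on sustained amplitude decline.

    When the last three per-breath amplitudes are strictly decreasing, the
    target moves by 0.25 breaths/min toward the resting rate, clamped to
    the protocol bounds; at most one adjustment fires per 3 breaths.
    """
    amps = np.asarray(recent_amps, dtype=float)
    if amps.size < 3:
        raise ValueError("need at least 3 recent amplitudes")
    if breaths_since_adjust < 3:
        return state.target_freq
    last3 = amps[-3:]
    if not (last3[0] > last3[1] > last3[2]):
        return state.target_freq
    direction = np.sign(resting_freq - state.target_freq)
    if direction == 0:
        return state.target_freq
    new = state.target_freq + direction * ADJUST_STEP
    clamped = float(np.clip(new, bounds[0], bounds[1]))
    if clamped != new:
        warnings.warn(
            f"adaptive target clamped to protocol bound {clamped}", BoundaryWarning
        )
    return clamped


def _runs(mask: np.ndarray):
    """Yield (start, stop) index pairs of maximal True runs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    for a, b in zip(idx[::2], idx[1::2]):
        yield int(a), int(b)


def detect_deviation(
    breath_times,
    measured_freqs,
    measured_depths,
    target_freqs,
    baseline_depth: float,
    freq_tol: float = 1.0,
    depth_fraction: float = 0.5,
    run_length: int = 3,
) -> list[AlertEvent]:
    """Raise alerts only for *repeated* deviations.

    A frequency alert fires when the measured rate is off target by more
    than ``freq_tol`` breaths/min on at least ``run_length`` consecutive
    breaths; a depth alert when breathing depth drops below
    ``depth_fraction`` of baseline for the same run length.  One event is
    emitted per maximal run, stamped at the breath on which the run first
    qualifies (its ``run_length``-th breath).
    """
    if baseline_depth <= 0:
        raise ValueError("baseline_depth must be positive")
    times = np.asarray(breath_times, dtype=float)
    mf = np.asarray(measured_freqs, dtype=float)
    md = np.asarray(measured_depths, dtype=float)
    tf = np.asarray(target_freqs, dtype=float)
    if not (times.size == mf.size == md.size == tf.size):
        raise ValueError("per-breath arrays must share a length")
    events: list[AlertEvent] = []
    freq_dev = np.abs(mf - tf) > freq_tol
    for a, b in _runs(freq_dev):
        if b - a >= run_length:
            events.append(
                AlertEvent(
                    time=float(times[a + run_length - 1]),
                    type="frequency_deviation",
                    detail=f"{b - a} consecutive breaths off target",
                    magnitude=float(np.mean(np.abs(mf[a:b] - tf[a:b]))),
                )
            )
    depth_dev = md < depth_fraction * baseline_depth
    for a, b in _runs(depth_dev):
        if b - a >= run_length:
            events.append(
                AlertEvent(
                    time=float(times[a + run_length - 1]),
                    type="depth_deviation",
                    detail=f"{b - a} consecutive shallow breaths",
                    magnitude=float(np.mean(md[a:b]) / baseline_depth),
                )
            )
    events.sort(key=lambda e: e.time)
    return events


@dataclass(frozen=True)
class WeeklyCompliance:
    week: str  # ISO "YYYY-Www"
    sessions: int  # sessions meeting the duration floor
    compliant: bool


def adherence_check(
    session_log,
    min_sessions_per_week: int = 4,
    min_duration_s: float = 900.0,
) -> tuple[list[WeeklyCompliance], list[AlertEvent]]:
    """Weekly training-dose compliance: >= 4 sessions of >= 15 min each.

    ``session_log`` holds ``(date, duration_s)`` pairs; dates may be
    :class:`datetime.date` or ISO strings.  Non-compliant weeks raise a
    ``session_missed`` alert.
    """
    buckets: dict[str, int] = {}
    for date, duration in session_log:
        if isinstance(date, str):
            date = _dt.date.fromisoformat(date)
        iso = date.isocalendar()
        week = f"{iso[0]}-W{iso[1]:02d}"
        buckets.setdefault(week, 0)
        if duration >= min_duration_s:
            buckets[week] += 1
    report, alerts = [], []
    for week in sorted(buckets):
        count = buckets[week]
        ok = count >= min_sessions_per_week
        report.append(WeeklyCompliance(week=week, sessions=count, compliant=ok))
        if not ok:
            alerts.append(
                AlertEvent(
                    time=None,
                    type="session_missed",
                    detail=f"week {week}: {count} qualifying sessions "
                    f"(need {min_sessions_per_week})",
                    magnitude=float(min_sessions_per_week - count),
                )
            )
    return report, alerts
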