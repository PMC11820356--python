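"""Resonance-frequency determination.

Four estimators are provided:

- ``stepped_and_ranked``: rank every trialled breathing frequency under
  three HRV metrics (mean peak-trough amplitude, LF/(LF+HF) coherence
  ratio, phase-locking value), intersect the per-metric top-3 sets, and
  break ties by amplitude.
- ``time_domain_only_rf``: amplitude ranking alone.
- ``sliding_assess``: per-breath amplitude along a continuous frequency
  sweep, smoothed, reported to 0.01 breaths/min.
- ``hybrid_rf``: stepped decision first, then a sliding sweep restricted to
  +/- 0.5 breaths/min around it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    BoundaryWarning,
    DegenerateSweepWarning,
    SeriesQualityError,
    TrialExclusionWarning,
)
from .metrics import breath_amplitudes, phase_synchrony, spectral_metrics
from .signals import HRCurve, RRSeries, instantaneous_hr

__all__ = [
    "STEPPED_GRID",
    "FrequencyTrial",
    "RankTable",
    "RFDecision",
    "SlidingResult",
    "evaluate_trials",
    "stepped_and_ranked",
    "time_domain_only_rf",
    "sliding_assess",
    "hybrid_rf",
    "trials_from_metric_values",
]

#: default stepped assessment grid, breaths/min (descending)
STEPPED_GRID = tuple(round(8.0 - 0.5 * k, 10) for k in range(8))

#: minimum usable trial segment, s
MIN_TRIAL_S = 120.0

METRICS = ("mean_amp", "lf_ratio", "plv")


@dataclass(frozen=True)
class FrequencyTrial:
    """One paced segment at one breathing frequency with its three scores."""

    freq: float  # breaths/min
    rr_segment: RRSeries | None
    mean_amp: float  # beats/min
    lf_ratio: float
    plv: float

    def __post_init__(self):
        if not 4.0 <= self.freq <= 8.5:
            raise ValueError("trial frequency outside [4.0, 8.5] breaths/min")
        for name in METRICS:
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"trial metric {name} is not finite")

    def metric(self, name: str) -> float:
        return getattr(self, name)


@dataclass(frozen=True)
class RankTable:
    """Competition ranks of trial frequencies under each metric.

    ``ranks[metric]`` maps frequency -> rank (1 = best, ties share the
    better rank); ``top3[metric]`` is the set of frequencies ranked <= 3.
    """

    ranks: dict
    top3: dict

    def ordering(self, metric: str) -> list[float]:
        return sorted(self.ranks[metric], key=lambda f: (self.ranks[metric][f], f))

    def rank_sum(self, freq: float) -> int:
        return sum(self.ranks[m][freq] for m in METRICS)


@dataclass(frozen=True)
class RFDecision:
    rf: float  # breaths/min
    candidates: frozenset
    rule_used: str  # intersection_unique | amplitude_tiebreak |
    #                 majority_tiebreak | fallback_ranksum | amplitude_only
    evidence: RankTable | None = None


@dataclass(frozen=True)
class SlidingResult:
    rf: float  # breaths/min, 0.01 resolution
    breath_freqs: np.ndarray
    amplitudes: np.ndarray
    smoothed: np.ndarray
    at_boundary: bool = False


def _competition_ranks(values: dict) -> dict:
    """Descending competition ranking; exact ties share the better rank."""
    ordered = sorted(values.items(), key=lambda kv: -kv[1])
    ranks, seen = {}, 0
    prev_val, prev_rank = None, 0
    for freq, val in ordered:
        seen += 1
        rank = prev_rank if val == prev_val else seen
        ranks[freq] = rank
        prev_val, prev_rank = val, rank
    return ranks


def rank_trials(trials) -> RankTable:
    ranks, top3 = {}, {}
    for m in METRICS:
        r = _competition_ranks({t.freq: t.metric(m) for t in trials})
        ranks[m] = r
        top3[m] = frozenset(f for f, rk in r.items() if rk <= 3)
    return RankTable(ranks=ranks, top3=top3)


def evaluate_trials(
    session,
    fs_out: float = 4.0,
    min_duration: float = MIN_TRIAL_S,
    settle_breaths: int = 2,
):
    """Score each ``(freq, rr_segment[, resp_phase])`` trial.

    ``resp_phase``, when omitted or ``None``, is synthesised from the pacing
    frequency on the HR-curve grid; breath-cycle windows always come from
    the pacer schedule.  The first ``settle_breaths`` cycles of every
    segment are discarded so that the carried-over oscillation from the
    previous pacing frequency does not contaminate the amplitude score.
    Segments shorter than ``min_duration`` are excluded with a warning.
    Duplicate frequencies are an error; at least three distinct frequencies
    are required.
    """
    freqs = [item[0] for item in session]
    if len(set(freqs)) != len(freqs):
        raise ValueError("duplicate trial frequencies in session")
    if len(freqs) < 3:
        raise ValueError("need at least 3 distinct trial frequencies")
    trials = []
    for item in session:
        freq, rr = item[0], item[1]
        resp_phase = item[2] if len(item) > 2 else None
        if rr.duration < min_duration:
            warnings.warn(
                f"trial at {freq} breaths/min spans only {rr.duration:.0f} s "
                f"(< {min_duration:.0f} s): excluded",
                TrialExclusionWarning,
            )
            continue
        hr = instantaneous_hr(rr, fs_out=fs_out)
        period = 60.0 / freq
        bounds = np.arange(hr.t[0], hr.t[-1] + period, period)[settle_breaths:]
        # settle region is cut from every metric, not just the amplitudes
        keep = hr.t >= bounds[0]
        hr = HRCurve(t=hr.t[keep], hr=hr.hr[keep], fs_out=hr.fs_out)
        amp = breath_amplitudes(hr, bounds).mean_amp
        spec = spectral_metrics(hr)
        if resp_phase is None:
            resp_phase = 2.0 * np.pi * (freq / 60.0) * (hr.t - hr.t[0])
        else:
            resp_phase = np.interp(hr.t, resp_phase[0], resp_phase[1])
        sync = phase_synchrony(hr, resp_phase, pacing_freq=freq / 60.0)
        trials.append(
            FrequencyTrial(
                freq=freq,
                rr_segment=rr,
                mean_amp=amp,
                lf_ratio=spec.lf_ratio,
                plv=sync.plv,
            )
        )
    return trials


def _best_by_amplitude(trials, among) -> float:
    pool = [t for t in trials if t.freq in among]
    best = max(pool, key=lambda t: (t.mean_amp, -t.freq))
    return best.freq


def stepped_and_ranked(trials, tiebreak: str = "amplitude") -> RFDecision:
    """Select RF from ranked frequency trials.

    The per-metric top-3 frequency sets are intersected.  A unique member
    is the RF; among several, the one with the largest mean amplitude wins
    (``tiebreak="majority"`` instead prefers the candidate holding the most
    first ranks, falling back to amplitude).  An empty intersection falls
    back to the frequency minimising the sum of its three ranks.
    """
    if tiebreak not in ("amplitude", "majority"):
        raise ValueError(f"unknown tiebreak {tiebreak!r}")
    trials = list(trials)
    if len(trials) < 3:
        raise SeriesQualityError("stepped selection needs at least 3 valid trials")
    table = rank_trials(trials)
    candidates = frozenset.intersection(*(table.top3[m] for m in METRICS))
    if len(candidates) == 1:
        (rf,) = candidates
        return RFDecision(rf, candidates, "intersection_unique", table)
    if len(candidates) > 1:
        if tiebreak == "majority":
            firsts = {
                f: sum(table.ranks[m][f] == 1 for m in METRICS) for f in candidates
            }
            top = max(firsts.values())
            leaders = [f for f, c in firsts.items() if c == top]
            rf = leaders[0] if len(leaders) == 1 else _best_by_amplitude(trials, leaders)
            return RFDecision(rf, candidates, "majority_tiebreak", table)
        rf = _best_by_amplitude(trials, candidates)
        return RFDecision(rf, candidates, "amplitude_tiebreak", table)
    sums = {t.freq: table.rank_sum(t.freq) for t in trials}
    best_sum = min(sums.values())
    leaders = frozenset(f for f, s in sums.items() if s == best_sum)
    rf = _best_by_amplitude(trials, leaders) if len(leaders) > 1 else next(iter(leaders))
    return RFDecision(rf, frozenset(), "fallback_ranksum", table)


def time_domain_only_rf(trials) -> RFDecision:
    """RF by amplitude ranking alone; rank-1 ties go to the lower frequency."""
    trials = list(trials)
    if not trials:
        raise SeriesQualityError("no valid trials")
    best_amp = max(t.mean_amp for t in trials)
    rf = min(t.freq for t in trials if t.mean_amp == best_amp)
    return RFDecision(rf, frozenset({rf}), "amplitude_only", rank_trials(trials))


def sliding_assess(
    rr: RRSeries,
    breath_freqs,
    breath_starts=None,
    min_breaths: int = 10,
    min_span: float = 1.5,
    smooth_window: int = 3,
    edge_margin: float = 0.02,
    fs_out: float = 4.0,
) -> SlidingResult:
    """RF from a one-breath-per-frequency sweep.

    Per-breath peak-trough HR amplitudes are smoothed with a centred
    3-breath moving average; the maximising breath's frequency is the RF,
    reported to two decimals.  Interior maxima within ``edge_margin`` of
    the global maximum are preferred over sweep endpoints.
    """
    freqs = np.asarray(breath_freqs, dtype=float)
    if freqs.size < min_breaths:
        raise SeriesQualityError(
            f"sweep too short: {freqs.size} breaths (< {min_breaths})"
        )
    if np.ptp(freqs) < min_span:
        raise SeriesQualityError(
            f"sweep too narrow: spans {np.ptp(freqs):.2f} breaths/min (< {min_span})"
        )
    if breath_starts is None:
        durs = 60.0 / freqs
        breath_starts = rr.beat_times[0] + np.concatenate(([0.0], np.cumsum(durs)))
    starts = np.asarray(breath_starts, dtype=float)
    if starts.size == freqs.size:  # starts only: close the last window
        starts = np.concatenate((starts, [starts[-1] + 60.0 / freqs[-1]]))
    if starts.size != freqs.size + 1:
        raise ValueError("breath_starts must bound every annotated breath")
    hr = instantaneous_hr(rr, fs_out=fs_out)
    amps = np.full(freqs.size, np.nan)
    for k in range(freqs.size):
        m = (hr.t >= starts[k]) & (hr.t < starts[k + 1])
        if m.sum() >= 2:
            amps[k] = np.max(hr.hr[m]) - np.min(hr.hr[m])
    valid = np.flatnonzero(~np.isnan(amps))
    if valid.size < min_breaths:
        raise SeriesQualityError("too few breaths overlap the recorded HR curve")
    f_v, a_v = freqs[valid], amps[valid]
    half = smooth_window // 2
    smoothed = np.array(
        [np.mean(a_v[max(0, k - half) : k + half + 1]) for k in range(a_v.size)]
    )
    if np.ptp(smoothed) < 1e-12:
        warnings.warn(
            "all per-breath amplitudes equal; returning lowest frequency",
            DegenerateSweepWarning,
        )
        k = int(np.argmin(f_v))
        return SlidingResult(round(float(f_v[k]), 2), f_v, a_v, smoothed, False)
    peak = float(np.max(smoothed))
    interior = np.arange(1, smoothed.size - 1)
    near = interior[smoothed[interior] >= (1.0 - edge_margin) * peak]
    if near.size:
        k = int(near[np.argmax(smoothed[near])])
        boundary = False
    else:
        k = int(np.argmax(smoothed))
        boundary = True
        warnings.warn(
            f"sweep amplitude maximal at endpoint ({f_v[k]:.2f} breaths/min)",
            BoundaryWarning,
        )
    return SlidingResult(round(float(f_v[k]), 2), f_v, a_v, smoothed, boundary)


def hybrid_rf(stepped: RFDecision, sweep_fn, half_range: float = 0.5) -> float:
    """Refine a stepped decision with a sliding sweep over +/- 0.5 breaths/min.

    ``sweep_fn(lo, hi)`` must produce ``(rr, breath_freqs)`` or
    ``(rr, breath_freqs, breath_starts)`` covering [lo, hi].  The sliding
    result is clamped to that range.
    """
    lo, hi = stepped.rf - half_range, stepped.rf + half_range
    produced = sweep_fn(lo, hi)
    rr, freqs = produced[0], produced[1]
    starts = produced[2] if len(produced) > 2 else None
    res = sliding_assess(
        rr, freqs, breath_starts=starts, min_span=0.9 * (hi - lo)
    )
    rf = res.rf
    if rf < lo or rf > hi:
        warnings.warn(
            f"sliding result {rf:.2f} clamped to [{lo:.2f}, {hi:.2f}]",
            BoundaryWarning,
        )
        rf = float(np.clip(rf, lo, hi))
    return round(rf, 2)


def trials_from_metric_values(values: dict) -> list[FrequencyTrial]:
    """Build metric-only trials from ``{metric: {freq: value}}`` tables.

    Convenience for replaying recorded rank tables (no RR segments).
    """
    freqs = sorted({f for per in values.values() for f in per})
    return [
        FrequencyTrial(
            freq=f,
            rr_segment=None,
            mean_amp=values["mean_amp"][f],
            lf_ratio=values["lf_ratio"][f],
            plv=values["plv"][f],
        )
        for f in freqs
    ]
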