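"""Physiological trace I/O and RR-interval conditioning.

The central substrate is :class:`RRSeries`: beat times in seconds from
session start and beat-to-beat intervals in milliseconds, with a
per-interval quality flag.  Everything downstream (time-domain metrics,
spectra, breath amplitudes) consumes this type, either directly or through
the evenly resampled :class:`HRCurve`.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, find_peaks, sosfiltfilt

from .errors import FlatSignalWarning, ParseError, SeriesQualityError

__all__ = [
    "ECGRecord",
    "RRSeries",
    "HRCurve",
    "read_rr_csv",
    "write_rr_csv",
    "detect_r_peaks",
    "clean_rr",
    "instantaneous_hr",
]

FLAG_OK = "ok"
FLAG_ARTIFACT = "artifact"
FLAG_INTERPOLATED = "interpolated"

#: absolute physiological bounds on a plausible RR interval, ms
RR_BOUNDS_MS = (300.0, 2000.0)
#: maximal relative jump from the previous accepted interval
RR_MAX_REL_STEP = 0.20


@dataclass(frozen=True)
class ECGRecord:
    """Single-lead ECG trace: amplitudes in mV at a fixed sampling rate."""

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.size < 2:
            raise ValueError("ECG record needs at least 2 samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class RRSeries:
    """Beat times (s) with the intervals (ms) between consecutive beats.

    ``intervals[k]`` spans ``beat_times[k] .. beat_times[k+1]``, so there is
    always one interval fewer than there are beats.
    """

    beat_times: np.ndarray
    intervals: np.ndarray
    quality_flags: np.ndarray = field(default=None)  # type: ignore[assignment]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.quality_flags is None:
            self.quality_flags = np.full(self.intervals.size, FLAG_OK, dtype=object)
        else:
            self.quality_flags = np.asarray(self.quality_flags, dtype=object)
        if self.intervals.size != self.beat_times.size - 1:
            raise ValueError("need exactly len(beat_times) - 1 intervals")
        if self.quality_flags.size != self.intervals.size:
            raise ValueError("one quality flag per interval required")
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if np.any(self.intervals <= 0):
            raise ValueError("intervals must be positive")

    @classmethod
    def from_beat_times(cls, beat_times, **kwargs) -> "RRSeries":
        beat_times = np.asarray(beat_times, dtype=float)
        intervals = np.diff(beat_times) * 1000.0
        return cls(beat_times, intervals, **kwargs)

    @classmethod
    def from_intervals(cls, intervals_ms, t0: float = 0.0, **kwargs) -> "RRSeries":
        intervals_ms = np.asarray(intervals_ms, dtype=float)
        beat_times = t0 + np.concatenate(([0.0], np.cumsum(intervals_ms) / 1000.0))
        return cls(beat_times, intervals_ms, **kwargs)

    def __len__(self) -> int:
        return self.intervals.size

    @property
    def duration(self) -> float:
        return float(self.beat_times[-1] - self.beat_times[0])

    @property
    def accepted(self) -> np.ndarray:
        """Boolean mask of intervals usable for metrics (not artifacts)."""
        return self.quality_flags != FLAG_ARTIFACT

    def slice_time(self, t0: float, t1: float) -> "RRSeries":
        """Beats within the half-open window [t0, t1)."""
        keep = (self.beat_times >= t0) & (self.beat_times < t1)
        idx = np.flatnonzero(keep)
        if idx.size < 2:
            raise SeriesQualityError("window contains fewer than 2 beats")
        lo, hi = idx[0], idx[-1]
        return RRSeries(
            self.beat_times[lo : hi + 1],
            self.intervals[lo:hi],
            self.quality_flags[lo:hi],
            dict(self.meta),
        )

    def copy(self) -> "RRSeries":
        return RRSeries(
            self.beat_times.copy(),
            self.intervals.copy(),
            self.quality_flags.copy(),
            dict(self.meta),
        )


@dataclass(frozen=True)
class HRCurve:
    """Instantaneous heart rate (beats/min) on a uniform time grid."""

    t: np.ndarray
    hr: np.ndarray
    fs_out: float

    def __post_init__(self):
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "hr", np.asarray(self.hr, dtype=float))
        if self.fs_out <= 0:
            raise ValueError("fs_out must be positive")
        if self.t.size != self.hr.size:
            raise ValueError("t and hr must have equal length")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if not np.allclose(dt, 1.0 / self.fs_out, rtol=0, atol=1e-9):
                raise ValueError("time grid must be uniform at 1/fs_out")
        if np.any(self.hr <= 0):
            raise ValueError("heart rate must be positive everywhere")


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def _parse_meta(lines) -> dict:
    meta = {}
    for ln in lines:
        body = ln.lstrip("#").strip()
        if "=" in body:
            k, v = body.split("=", 1)
            meta[k.strip()] = v.strip()
    return meta


def read_rr_csv(path) -> RRSeries:
    """Read a two-column RR CSV (``time_s,rr_ms``; one row per interval).

    The time column holds the onset beat of each interval; the final beat
    time is reconstructed from the last row.  ``#``-prefixed lines carry
    ``key=value`` metadata.  Column consistency is enforced to 1 ms.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = fh.readlines()
    comments = [ln for ln in raw if ln.startswith("#")]
    body = [ln for ln in raw if ln.strip() and not ln.startswith("#")]
    if body and not body[0].split(",")[0].strip().replace(".", "", 1).replace(
        "-", "", 1
    ).isdigit():
        body = body[1:]  # header row
    if not body:
        raise ParseError(f"{path}: no data rows")
    try:
        arr = np.loadtxt(io.StringIO("".join(body)), delimiter=",", ndmin=2)
    except ValueError as exc:
        raise ParseError(f"{path}: malformed CSV ({exc})") from exc
    if arr.shape[1] != 2:
        raise ParseError(f"{path}: expected 2 columns, got {arr.shape[1]}")
    times, rr = arr[:, 0], arr[:, 1]
    if np.any(np.diff(times) <= 0):
        raise ParseError(f"{path}: beat times must be strictly increasing")
    if np.any(rr <= 0):
        raise ParseError(f"{path}: intervals must be positive")
    implied = np.diff(times) * 1000.0
    if implied.size and np.max(np.abs(implied - rr[:-1])) > 1.0:
        raise ParseError(f"{path}: time and interval columns disagree by > 1 ms")
    beat_times = np.concatenate((times, [times[-1] + rr[-1] / 1000.0]))
    return RRSeries(beat_times, rr, meta=_parse_meta(comments))


def write_rr_csv(path, rr: RRSeries, meta: dict | None = None) -> None:
    """Write an :class:`RRSeries` in the layout read by :func:`read_rr_csv`."""
    meta = {**rr.meta, **(meta or {})}
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        fh.write("time_s,rr_ms\n")
        for t, x in zip(rr.beat_times[:-1], rr.intervals):
            fh.write(f"{t:.6f},{x:.3f}\n")


def read_ecg_csv(path) -> ECGRecord:
    """Read a ``sample,mV`` CSV whose header carries ``# fs=<Hz>``."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = fh.readlines()
    meta = _parse_meta([ln for ln in raw if ln.startswith("#")])
    if "fs" not in meta:
        raise ParseError(f"{path}: missing '# fs=<Hz>' header")
    body = [ln for ln in raw if ln.strip() and not ln.startswith("#")]
    if body and body[0].lstrip().startswith("sample"):
        body = body[1:]
    arr = np.loadtxt(io.StringIO("".join(body)), delimiter=",", ndmin=2)
    return ECGRecord(arr[:, 1], fs=float(meta["fs"]), t0=float(meta.get("t0", 0.0)))


# ---------------------------------------------------------------------------
# R-peak detection
# ---------------------------------------------------------------------------

def detect_r_peaks(ecg: ECGRecord, refractory_s: float = 0.25) -> np.ndarray:
    """Locate R-peak times with a derivative/energy detector.

    Pipeline: band-pass (5 Hz to min(20, 0.45*fs) Hz, zero-phase), squaring,
    150 ms moving-window integration, adaptive threshold, then refinement of
    each candidate to the local raw-amplitude maximum.  A 250 ms refractory
    spacing is enforced throughout.
    """
    if ecg.fs < 100:
        raise ValueError("R-peak detection requires fs >= 100 Hz")
    x = ecg.samples - np.median(ecg.samples)
    if np.ptp(x) < 1e-12:
        warnings.warn("flat ECG signal: no beats detected", FlatSignalWarning)
        return np.array([])
    hi = min(20.0, 0.45 * ecg.fs)
    sos = butter(2, [5.0, hi], btype="bandpass", fs=ecg.fs, output="sos")
    filt = sosfiltfilt(sos, x)
    energy = filt**2
    win = max(1, int(round(0.15 * ecg.fs)))
    integ = np.convolve(energy, np.ones(win) / win, mode="same")
    thresh = 0.25 * np.percentile(integ, 99.5)
    dist = max(1, int(round(refractory_s * ecg.fs)))
    cand, _ = find_peaks(integ, height=thresh, distance=dist)
    if cand.size == 0:
        warnings.warn("no QRS energy above threshold", FlatSignalWarning)
        return np.array([])
    # snap each candidate to the nearest raw-|amplitude| maximum
    half = max(1, int(round(0.10 * ecg.fs)))
    peaks = []
    for c in cand:
        lo, hi_i = max(0, c - half), min(x.size, c + half + 1)
        peaks.append(lo + int(np.argmax(np.abs(x[lo:hi_i]))))
    peaks = np.unique(peaks)
    keep = [peaks[0]]
    for p in peaks[1:]:
        if p - keep[-1] >= dist:
            keep.append(p)
    return ecg.t0 + np.asarray(keep, dtype=float) / ecg.fs


# ---------------------------------------------------------------------------
# Artifact handling
# ---------------------------------------------------------------------------

def _artifact_mask(intervals: np.ndarray) -> np.ndarray:
    lo, hi = RR_BOUNDS_MS
    bad = np.zeros(intervals.size, dtype=bool)
    last_ok = None
    for k, x in enumerate(intervals):
        if not (lo <= x <= hi):
            bad[k] = True
        elif last_ok is not None and abs(x - last_ok) > RR_MAX_REL_STEP * last_ok:
            bad[k] = True
        else:
            last_ok = x
    return bad


def clean_rr(rr: RRSeries, policy: str = "flag") -> RRSeries:
    """Flag, interpolate over, or drop implausible intervals.

    An interval is an artifact when it leaves [300, 2000] ms or differs by
    more than 20% from the previous accepted interval.  ``policy`` chooses
    what happens next:

    - ``flag``: mark and keep (downstream metrics skip artifacts)
    - ``interpolate``: replace values linearly over beat time, rebuild beats
    - ``drop``: remove the offending intervals, rebuild beats

    Raises :class:`SeriesQualityError` when over half the series is marked.
    """
    if policy not in ("flag", "interpolate", "drop"):
        raise ValueError(f"unknown policy {policy!r}")
    bad = _artifact_mask(rr.intervals)
    if rr.intervals.size and bad.sum() > 0.5 * rr.intervals.size:
        raise SeriesQualityError(
            f"{bad.sum()}/{rr.intervals.size} intervals are artifacts; series unusable"
        )
    if policy == "flag":
        flags = np.where(bad, FLAG_ARTIFACT, rr.quality_flags)
        # never downgrade a previously interpolated interval
        flags = np.where(
            rr.quality_flags == FLAG_INTERPOLATED, FLAG_INTERPOLATED, flags
        )
        return RRSeries(rr.beat_times.copy(), rr.intervals.copy(), flags, dict(rr.meta))
    if policy == "drop":
        kept = rr.intervals[~bad]
        if kept.size == 0:
            raise SeriesQualityError("no intervals survive drop policy")
        return RRSeries.from_intervals(kept, t0=rr.beat_times[0], meta=dict(rr.meta))
    # interpolate: values re-drawn linearly over the onset-time axis
    vals = rr.intervals.copy()
    onsets = rr.beat_times[:-1]
    good = ~bad
    if not np.any(good):
        raise SeriesQualityError("no accepted intervals to interpolate from")
    vals[bad] = np.interp(onsets[bad], onsets[good], rr.intervals[good])
    flags = np.where(bad, FLAG_INTERPOLATED, FLAG_OK)
    flags = np.where(
        (~bad) & (rr.quality_flags == FLAG_INTERPOLATED), FLAG_INTERPOLATED, flags
    )
    out = RRSeries.from_intervals(vals, t0=rr.beat_times[0], meta=dict(rr.meta))
    out.quality_flags = flags.astype(object)
    return out


# ---------------------------------------------------------------------------
# Instantaneous heart rate
# ---------------------------------------------------------------------------

def instantaneous_hr(rr: RRSeries, fs_out: float = 4.0) -> HRCurve:
    """Resample 60000/RR onto a uniform grid.

    Rate samples are anchored at interval midpoints and cubic-interpolated
    (linear when fewer than four midpoints are available); artifact-flagged
    intervals are excluded.  The grid is clipped to the span of the anchor
    points so no extrapolation occurs.
    """
    if fs_out <= 0:
        raise ValueError("fs_out must be positive")
    if rr.beat_times.size < 4:
        raise SeriesQualityError("instantaneous HR needs at least 4 beats")
    mask = rr.accepted
    mids = (rr.beat_times[:-1] + rr.beat_times[1:])[mask] / 2.0
    hr_pts = 60000.0 / rr.intervals[mask]
    if mids.size < 2:
        raise SeriesQualityError("too few accepted intervals for an HR curve")
    t = np.arange(mids[0], mids[-1], 1.0 / fs_out)
    if t.size < 2:
        raise SeriesQualityError("series too short for the requested grid")
    if mids.size >= 4:
        hr = CubicSpline(mids, hr_pts)(t)
    else:
        hr = np.interp(t, mids, hr_pts)
    hr = np.maximum(hr, 1e-6)  # guard against overshoot through zero
    return HRCurve(t=t, hr=hr, fs_out=fs_out)
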