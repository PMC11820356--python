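"""HRV metrics: time-domain statistics, LF/HF spectral balance,
per-breath peak-trough amplitudes, and cardiorespiratory phase locking.

These are the quantities that score each paced-breathing frequency during
resonance-frequency selection and that populate training reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, hilbert, periodogram, sosfiltfilt, welch

from .errors import SeriesQualityError, SpectralFallbackWarning
from .signals import HRCurve, RRSeries, instantaneous_hr

__all__ = [
    "HRVTimeDomain",
    "SpectralResult",
    "BreathAmplitudes",
    "PhaseSynchrony",
    "time_domain_metrics",
    "spectral_metrics",
    "breath_amplitudes",
    "phase_synchrony",
    "training_effect_report",
    "LF_BAND",
    "HF_BAND",
]

#: low- and high-frequency HRV bands, Hz (half-open)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

#: Welch segment length, s
_SEGMENT_S = 120.0


@dataclass(frozen=True)
class HRVTimeDomain:
    sdnn: float  # ms
    rmssd: float  # ms
    pnn50: float  # percent, 0-100

    def as_dict(self) -> dict:
        return {"sdnn": self.sdnn, "rmssd": self.rmssd, "pnn50": self.pnn50}


@dataclass(frozen=True)
class SpectralResult:
    freqs: np.ndarray  # Hz
    psd: np.ndarray  # ms^2/Hz
    lf_power: float  # ms^2
    hf_power: float  # ms^2
    lf_ratio: float  # LF/(LF+HF), dimensionless


@dataclass(frozen=True)
class BreathAmplitudes:
    per_cycle: np.ndarray  # beats/min, one value per breath cycle
    mean_amp: float  # beats/min


@dataclass(frozen=True)
class PhaseSynchrony:
    plv: float  # in [0, 1]
    mean_phase_lag: float  # radians, (-pi, pi]


def time_domain_metrics(rr: RRSeries) -> HRVTimeDomain:
    """SDNN, RMSSD and pNN50 over the accepted (non-artifact) intervals.

    SDNN uses the sample (n-1) standard deviation; pNN50 counts successive
    differences strictly above 50 ms.
    """
    x = rr.intervals[rr.accepted]
    if x.size < 2:
        raise SeriesQualityError("SDNN requires at least 2 accepted intervals")
    if x.size < 3:
        raise SeriesQualityError("RMSSD/pNN50 require at least 3 accepted intervals")
    d = np.diff(x)
    return HRVTimeDomain(
        sdnn=float(np.std(x, ddof=1)),
        rmssd=float(np.sqrt(np.mean(d**2))),
        pnn50=float(100.0 * np.mean(np.abs(d) > 50.0)),
    )


def _band_power(freqs: np.ndarray, psd: np.ndarray, band) -> float:
    mask = (freqs >= band[0]) & (freqs < band[1])
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[mask], freqs[mask]))


def spectral_metrics(hr_or_rr: HRCurve | RRSeries, fs_out: float = 4.0) -> SpectralResult:
    """LF/HF power balance of the uniformly resampled RR tachogram.

    The input may be an :class:`HRCurve` (converted back to RR in ms) or an
    :class:`RRSeries` (resampled internally).  The mean-removed tachogram is
    fed to a Welch estimator (120 s Hann segments, 50% overlap, linear
    detrend); records shorter than two segments fall back to a
    single-segment periodogram with a warning.
    """
    if isinstance(hr_or_rr, RRSeries):
        curve = instantaneous_hr(hr_or_rr, fs_out=fs_out)
    else:
        curve = hr_or_rr
    fs = curve.fs_out
    x = 60000.0 / curve.hr  # tachogram, ms
    x = x - np.mean(x)
    duration = curve.t[-1] - curve.t[0]
    nperseg = int(round(_SEGMENT_S * fs))
    if duration < 2 * _SEGMENT_S:
        warnings.warn(
            f"record {duration:.0f} s < {2 * _SEGMENT_S:.0f} s: "
            "single-segment periodogram used",
            SpectralFallbackWarning,
        )
        freqs, psd = periodogram(x, fs=fs, window="hann", detrend="linear")
    else:
        freqs, psd = welch(
            x,
            fs=fs,
            window="hann",
            nperseg=min(nperseg, x.size),
            noverlap=min(nperseg, x.size) // 2,
            detrend="linear",
        )
    lf = _band_power(freqs, psd, LF_BAND)
    hf = _band_power(freqs, psd, HF_BAND)
    total = lf + hf
    ratio = lf / total if total > 0 else float("nan")
    return SpectralResult(freqs=freqs, psd=psd, lf_power=lf, hf_power=hf, lf_ratio=ratio)


def breath_amplitudes(hr: HRCurve, cycle_bounds) -> BreathAmplitudes:
    """Peak-trough HR amplitude per breath cycle.

    ``cycle_bounds`` are breath start times; cycle ``k`` is the half-open
    window ``[bounds[k], bounds[k+1])``.  Cycles not fully contained in the
    curve span are skipped.
    """
    bounds = np.asarray(cycle_bounds, dtype=float)
    if bounds.size < 2:
        raise ValueError("need at least two cycle bounds (one cycle)")
    amps = []
    t_end = hr.t[-1] + 1.0 / hr.fs_out
    for a, b in zip(bounds[:-1], bounds[1:]):
        if a < hr.t[0] - 1e-9 or b > t_end + 1e-9:
            continue
        m = (hr.t >= a) & (hr.t < b)
        if m.sum() < 2:
            continue
        seg = hr.hr[m]
        amps.append(float(np.max(seg) - np.min(seg)))
    if not amps:
        raise SeriesQualityError("no complete breath cycle inside the HR curve span")
    amps = np.asarray(amps)
    return BreathAmplitudes(per_cycle=amps, mean_amp=float(np.mean(amps)))


def phase_synchrony(
    hr: HRCurve, resp_phase: np.ndarray, pacing_freq: float, half_band: float = 0.03
) -> PhaseSynchrony:
    """Phase-locking value between heart rate and respiration.

    The HR curve is band-passed around ``pacing_freq`` (Hz) with a
    zero-phase 4th-order Butterworth (two passes of order 2), its analytic
    phase extracted by Hilbert transform, and the circular mean of the
    phase difference to ``resp_phase`` (radians, same grid) taken.
    """
    resp_phase = np.asarray(resp_phase, dtype=float)
    if resp_phase.shape != hr.t.shape:
        raise ValueError("respiration phase must share the HR curve grid")
    if not (0.05 <= pacing_freq <= 0.17):
        raise ValueError("pacing frequency outside the paced-breathing range")
    lo = max(pacing_freq - half_band, 1e-3)
    hi = min(pacing_freq + half_band, 0.49 * hr.fs_out)
    sos = butter(2, [lo, hi], btype="bandpass", fs=hr.fs_out, output="sos")
    filt = sosfiltfilt(sos, hr.hr - np.mean(hr.hr))
    phi_hr = np.angle(hilbert(filt))
    vec = np.mean(np.exp(1j * (phi_hr - resp_phase)))
    return PhaseSynchrony(plv=float(np.abs(vec)), mean_phase_lag=float(np.angle(vec)))


def training_effect_report(
    pre: RRSeries, during: RRSeries, post: RRSeries
) -> tuple[dict[str, HRVTimeDomain], dict[str, float | None]]:
    """Per-phase time-domain metrics plus the during/pre ratio per metric.

    Each phase must span at least 60 s.  Ratios with a zero pre-phase value
    are reported as ``None`` (undefined), never as infinity.
    """
    phases = {"pre": pre, "during": during, "post": post}
    for name, rr in phases.items():
        if rr.duration < 60.0:
            raise SeriesQualityError(f"{name} phase shorter than 60 s")
    report = {name: time_domain_metrics(rr) for name, rr in phases.items()}
    ratios: dict[str, float | None] = {}
    pre_m = report["pre"].as_dict()
    dur_m = report["during"].as_dict()
    for key in ("sdnn", "rmssd", "pnn50"):
        ratios[key] = dur_m[key] / pre_m[key] if pre_m[key] != 0 else None
    return report, ratios
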