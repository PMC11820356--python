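"""Seeded cardiorespiratory simulator with ground-truth resonance.

Respiratory sinus arrhythmia is modelled as a second-order resonator driven
by the pacer: the RR-interval modulation amplitude at pacing frequency f is
``a_rsa * gain(f)`` where the gain peaks near the subject's true resonance
frequency.  Beats are generated by forward interval stepping, so every
session comes with an exact truth record for parameter-recovery tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ClippingWarning
from .pacing import PacerProtocol, PacerTrace, pacer_waveform
from .signals import RR_BOUNDS_MS, RRSeries

__all__ = [
    "SubjectProfile",
    "SimSession",
    "resonance_gain",
    "simulate_session",
    "simulate_cohort",
]


@dataclass(frozen=True)
class SubjectProfile:
    """Simulator ground truth for one subject."""

    rf_true: float  # resonance frequency, breaths/min
    rr0: float = 900.0  # baseline interval, ms
    a_rsa: float = 40.0  # peak RSA interval modulation, ms
    zeta: float = 0.15  # resonance damping ratio
    a_hf: float = 10.0  # unpaced high-frequency modulation, ms
    f_hf: float = 0.25  # Hz
    a_lf: float = 0.0  # low-frequency wander SD, ms (0.04-0.15 Hz band)
    resp_drift: float = 0.4  # deterministic slow breathing drift amplitude, rad
    phase_jitter: float = 0.0  # stochastic breathing-phase jitter SD, radians
    sigma_rr: float = 0.0  # additive white interval noise, ms
    seed: int = 0

    def __post_init__(self):
        if not 4.0 <= self.rf_true <= 8.0:
            raise ValueError("rf_true must lie in [4.0, 8.0] breaths/min")
        if not 600.0 <= self.rr0 <= 1200.0:
            raise ValueError("rr0 must lie in [600, 1200] ms")
        if not 0.0 < self.zeta < 1.0:
            raise ValueError("zeta must lie in (0, 1)")
        if min(self.a_rsa, self.a_hf, self.a_lf, self.sigma_rr) < 0:
            raise ValueError("modulation amplitudes must be non-negative")
        if self.resp_drift < 0 or self.phase_jitter < 0:
            raise ValueError("phase perturbation amplitudes must be non-negative")


@dataclass
class SimSession:
    rr: RRSeries
    resp_t: np.ndarray  # s
    resp_phase: np.ndarray  # radians, shared grid with resp_t
    trace: PacerTrace
    protocol: PacerProtocol
    truth: SubjectProfile
    clipped: bool = False


def resonance_gain(f: float | np.ndarray, profile: SubjectProfile):
    """Second-order resonator amplitude gain and phase at pacing rate ``f``.

    With r = f/rf_true: gain = 1/sqrt((1-r^2)^2 + (2*zeta*r)^2) and
    phase = -atan2(2*zeta*r, 1-r^2).  gain -> 1 as f -> 0 and equals
    1/(2*zeta) at r = 1.
    """
    r = np.asarray(f, dtype=float) / profile.rf_true
    if np.any(r <= 0):
        raise ValueError("pacing frequency must be positive")
    one_minus = 1.0 - r**2
    damp = 2.0 * profile.zeta * r
    gain = 1.0 / np.sqrt(one_minus**2 + damp**2)
    phase = -np.arctan2(damp, one_minus)
    if np.isscalar(f) or np.asarray(f).ndim == 0:
        return float(gain), float(phase)
    return gain, phase


#: lead-in discarded before t=0 so the resonator starts in steady state, s
_LEADIN_S = 60.0

#: correlation time of the breathing-phase jitter process, s
_JITTER_TAU_S = 3.0

#: period of the deterministic slow breathing drift, s
_DRIFT_PERIOD_S = 60.0


def _ou_process(rng, n: int, fs: float, sd: float, tau: float) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck samples (mean 0, SD ``sd``)."""
    from scipy.signal import lfilter

    a = np.exp(-1.0 / (fs * tau))
    innov = sd * np.sqrt(1.0 - a * a) * rng.standard_normal(n)
    innov[0] = sd * rng.standard_normal()
    return lfilter([1.0], [1.0, -a], innov)


def _rsa_response(profile: SubjectProfile, trace: PacerTrace, rng) -> np.ndarray:
    """RSA interval modulation (ms): second-order resonator driven by breathing.

    The drive is sin(pacer phase + jitter + pi); the resonator is the unit
    static-gain system w0^2/(s^2 + 2*zeta*w0*s + w0^2), so the clean
    steady-state response at pacing rate f is exactly
    ``gain(f)*sin(phase(f) + ...)`` from :func:`resonance_gain`.  A lead-in
    at the starting frequency is simulated and discarded so each session
    begins in steady state.
    """
    from scipy.signal import lsim

    fs = trace.fs
    n_lead = int(round(_LEADIN_S * fs))
    f0 = trace.freq[0]
    t_lead = (np.arange(n_lead) - n_lead) / fs
    phase_lead = trace.phase[0] + 2.0 * np.pi * f0 / 60.0 * t_lead
    phase = np.concatenate((phase_lead, trace.phase))
    t_full = np.concatenate((t_lead, trace.t))
    if profile.resp_drift > 0:
        # slow drift around the pacer: its sidebands survive the measurement
        # band-pass but are stripped by the resonator near resonance
        phase = phase + profile.resp_drift * np.sin(
            2.0 * np.pi * t_full / _DRIFT_PERIOD_S
        )
    if profile.phase_jitter > 0:
        phase = phase + _ou_process(
            rng, phase.size, fs, profile.phase_jitter, _JITTER_TAU_S
        )
    drive = np.sin(phase + np.pi)
    w0 = 2.0 * np.pi * profile.rf_true / 60.0
    system = ([w0**2], [1.0, 2.0 * profile.zeta * w0, w0**2])
    t_all = np.arange(phase.size) / fs
    _, y, _ = lsim(system, drive, t_all)
    return profile.a_rsa * y[n_lead:]


def _interval_function(profile: SubjectProfile, trace: PacerTrace, rng) -> np.ndarray:
    """RR(t) in ms sampled on the pacer grid."""
    rsa = _rsa_response(profile, trace, rng)
    hf = profile.a_hf * np.sin(2.0 * np.pi * profile.f_hf * trace.t)
    out = profile.rr0 + rsa + hf
    if profile.a_lf > 0:
        # seeded low-frequency wander: band-limited unit-SD noise, scaled
        from scipy.signal import butter, sosfiltfilt

        white = rng.standard_normal(trace.t.size)
        sos = butter(2, [0.04, 0.15], btype="bandpass", fs=trace.fs, output="sos")
        wander = sosfiltfilt(sos, white)
        sd = np.std(wander)
        if sd > 0:
            out = out + profile.a_lf * wander / sd
    return out


def simulate_session(
    profile: SubjectProfile, protocol: PacerProtocol, fs: float = 8.0
) -> SimSession:
    """Generate beat times under a pacer protocol.

    Beat stepping reads the continuous interval function at each beat onset:
    ``t[k+1] = t[k] + RR(t[k])/1000`` with per-beat white noise ``sigma_rr``.
    Intervals are clipped to the physiological bounds; a clipped session is
    flagged and warned about.
    """
    trace = pacer_waveform(protocol, fs=fs)
    max_gain, _ = resonance_gain(profile.rf_true, profile)
    if profile.rr0 - profile.a_rsa * max_gain - profile.a_hf <= 0:
        raise ValueError("profile implies non-positive RR intervals")
    rng = np.random.default_rng(profile.seed)
    rr_det = _interval_function(profile, trace, rng=rng)
    total = protocol.total_duration
    t, beats, intervals = 0.0, [0.0], []
    clipped = False
    while t < total:
        rr_ms = float(np.interp(t, trace.t, rr_det))
        if profile.sigma_rr > 0:
            rr_ms += profile.sigma_rr * rng.standard_normal()
        lo, hi = RR_BOUNDS_MS
        if rr_ms < lo or rr_ms > hi:
            clipped = True
            rr_ms = float(np.clip(rr_ms, lo, hi))
        t += rr_ms / 1000.0
        beats.append(t)
        intervals.append(rr_ms)
    if clipped:
        warnings.warn("simulated intervals hit the clip bounds", ClippingWarning)
    rr = RRSeries(
        np.asarray(beats),
        np.asarray(intervals),
        meta={"rf_true": profile.rf_true, "seed": profile.seed},
    )
    return SimSession(
        rr=rr,
        resp_t=trace.t,
        resp_phase=trace.phase,
        trace=trace,
        protocol=protocol,
        truth=profile,
        clipped=clipped,
    )


#: cohort sampling defaults: field -> (low, high) of a uniform draw
DEFAULT_COHORT_RANGES = {
    "rf_true": (4.5, 6.5),
    "rr0": (750.0, 1050.0),
    "a_rsa": (25.0, 45.0),
    "zeta": (0.10, 0.18),
    "a_lf": (10.0, 20.0),
    "phase_jitter": (0.2, 0.5),
}


def simulate_cohort(
    n: int,
    master_seed: int,
    ranges: dict | None = None,
    protocol: PacerProtocol | None = None,
    **fixed,
) -> list:
    """Draw ``n`` subject profiles (and optionally simulate each session).

    Per-subject seeds derive deterministically from ``master_seed``.
    ``ranges`` overrides the uniform sampling bounds per profile field;
    keyword arguments pin fields to constants.  Returns a list of profiles,
    or of ``(profile, SimSession)`` pairs when a protocol is given.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(master_seed)
    bounds = {**DEFAULT_COHORT_RANGES, **(ranges or {})}
    for key in fixed:
        bounds.pop(key, None)
    out = []
    for _ in range(n):
        draws = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in bounds.items()}
        draws.update(fixed)
        profile = SubjectProfile(seed=int(rng.integers(2**31)), **draws)
        if protocol is None:
            out.append(profile)
        else:
            out.append((profile, simulate_session(profile, protocol)))
    return out
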