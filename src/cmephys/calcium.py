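"""Ca2+-transient feature extraction and caffeine-response analysis.

Per transient: amplitude ``r_amp`` (peak minus the pre-upstroke local-minimum
baseline, in ratio units), the maximal rates of rise and decay (from the
shared local-polynomial-smoothed derivative; decay reported as a positive
magnitude), and the area above baseline.  An ensemble average of 20
consecutive transients is computed beat-aligned, and features are recomputed
on the average.  Optional monoexponential fits of the rise and decay
segments recover the underlying time constants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from ._smooth import smoothed_derivative
from .core import Modality, VoltageTrace

__all__ = ["CaTransient", "CaTransientFeatures", "extract_ca_transients",
           "CaffeineResponse", "analyze_caffeine"]

ENSEMBLE_N = 20          # transients averaged for the ensemble waveform
ONSET_FRAC = 0.05        # onset / 95%-return level as a fraction of amplitude
MEASURABLE_FRAC = 0.25   # "first measurable transient" amplitude threshold


@dataclass(frozen=True)
class CaTransient:
    peak_time_s: float
    peak_index: int
    baseline: float
    r_amp: float
    rise_max: float       # units/s
    decay_max: float      # units/s, positive magnitude
    area: float           # ratio-units * s above baseline
    onset_index: int
    end_index: int


@dataclass
class CaTransientFeatures:
    transients: list[CaTransient]
    rate_hz: float
    ensemble: CaTransient | None = None
    tau_rise_s: np.ndarray | None = None
    tau_decay_s: np.ndarray | None = None

    @property
    def n_transients(self) -> int:
        return len(self.transients)

    @property
    def r_amp(self) -> np.ndarray:
        return np.array([t.r_amp for t in self.transients])

    @property
    def dca_rise_max(self) -> np.ndarray:
        return np.array([t.rise_max for t in self.transients])

    @property
    def dca_decay_max(self) -> np.ndarray:
        return np.array([t.decay_max for t in self.transients])

    @property
    def peak_times_s(self) -> np.ndarray:
        return np.array([t.peak_time_s for t in self.transients])


def _measure_transient(s: np.ndarray, rate_hz: float, t0_s: float,
                       lo: int, peak: int, hi: int) -> CaTransient:
    """Features of one transient occupying ``s[lo:hi]`` with peak at ``peak``."""
    baseline = float(np.min(s[lo:peak + 1]))
    base_idx = lo + int(np.argmin(s[lo:peak + 1]))
    amp = float(s[peak]) - baseline
    level = baseline + ONSET_FRAC * amp
    pre = s[base_idx:peak + 1]
    above = np.flatnonzero(pre > level)
    onset = base_idx + (int(above[0]) - 1 if above.size and above[0] > 0 else 0)
    post = s[peak:hi]
    back = np.flatnonzero(post <= level)
    end = peak + (int(back[0]) if back.size else len(post) - 1)

    d = smoothed_derivative(s[max(0, onset - 2):end + 3], rate_hz)
    k0 = max(0, onset - 2)
    rise = float(np.max(d[:peak - k0 + 1])) if peak > k0 else 0.0
    decay = float(np.max(-d[peak - k0:])) if end > peak else 0.0
    area = float(np.trapezoid(s[onset:end + 1] - baseline, dx=1.0 / rate_hz))
    return CaTransient(t0_s + peak / rate_hz, peak, baseline, amp,
                       rise, decay, area, onset, end)


def extract_ca_transients(trace: VoltageTrace,
                          prominence_frac: float = 0.3,
                          min_distance_s: float = 0.2,
                          fit_time_constants: bool = False) -> CaTransientFeatures:
    """Segment and measure Ca2+ transients in a fluorescence-ratio trace."""
    if trace.modality is not Modality.CA:
        raise ValueError("extract_ca_transients requires a ca trace")
    s = trace.samples
    fs = trace.rate_hz
    robust_range = float(np.percentile(s, 99.5) - np.percentile(s, 0.5))
    noise_scale = 1.4826 * float(np.median(np.abs(np.diff(s)))) if s.size > 1 else 0.0
    if robust_range <= 0 or robust_range < 6.0 * noise_scale:
        return CaTransientFeatures([], fs)  # flat / featureless trace
    peaks, _ = find_peaks(s, prominence=prominence_frac * robust_range,
                          distance=max(1, int(min_distance_s * fs)))
    if peaks.size == 0:
        return CaTransientFeatures([], fs)

    transients: list[CaTransient] = []
    for j, p in enumerate(peaks):
        lo = int(peaks[j - 1]) if j > 0 else 0
        hi = int(peaks[j + 1]) if j + 1 < peaks.size else s.size
        transients.append(_measure_transient(s, fs, trace.t0_s, lo, int(p), hi))

    feats = CaTransientFeatures(transients, fs)
    if len(transients) >= ENSEMBLE_N + 1:
        feats.ensemble = _ensemble_average(s, fs, trace.t0_s, peaks[:ENSEMBLE_N])
    else:
        warnings.warn(
            f"only {len(transients)} transients; ensemble average of {ENSEMBLE_N} "
            "consecutive signals not computed", stacklevel=2)
    if fit_time_constants:
        feats.tau_rise_s, feats.tau_decay_s = _fit_taus(s, fs, transients)
    return feats


def _ensemble_average(s: np.ndarray, fs: float, t0_s: float,
                      peaks: np.ndarray) -> CaTransient:
    """Beat-aligned mean of the given transients, re-measured."""
    ibi = int(np.median(np.diff(peaks)))
    pre = ibi // 3
    post = ibi - pre
    segs = [s[p - pre:p + post] for p in peaks
            if p - pre >= 0 and p + post <= s.size]
    avg = np.mean(np.asarray(segs), axis=0)
    peak = int(np.argmax(avg))
    return _measure_transient(avg, fs, t0_s, 0, peak, avg.size)


def _fit_taus(s: np.ndarray, fs: float,
              transients: list[CaTransient]) -> tuple[np.ndarray, np.ndarray]:
    """Monoexponential fits: rise A(1-exp(-t/tau)) and decay c exp(-t/tau)+d."""
    taur, taud = [], []
    for tr in transients:
        t_rise = np.arange(tr.peak_index - tr.onset_index + 1) / fs
        y_rise = s[tr.onset_index:tr.peak_index + 1] - tr.baseline
        t_dec = np.arange(tr.end_index - tr.peak_index + 1) / fs
        y_dec = s[tr.peak_index:tr.end_index + 1] - tr.baseline
        # rise: log-linear regression on the unsaturated segment of
        # 1 - y/amplitude (robust where a free-asymptote fit is ill-posed)
        keep = (y_rise > 0.1 * tr.r_amp) & (y_rise < 0.85 * tr.r_amp)
        if np.count_nonzero(keep) >= 3:
            z = np.log(1.0 - y_rise[keep] / tr.r_amp)
            slope = np.polyfit(t_rise[keep], z, 1)[0]
            taur.append(-1.0 / slope if slope < 0 else np.nan)
        else:
            taur.append(np.nan)
        try:
            pd_, _ = curve_fit(lambda t, c, tau, d: c * np.exp(-t / tau) + d,
                               t_dec, y_dec, p0=(tr.r_amp, max(t_dec[-1] / 3, 1e-3), 0.0),
                               maxfev=2000)
            taud.append(pd_[1])
        except Exception:
            taud.append(np.nan)
    return np.asarray(taur), np.asarray(taud)


@dataclass
class CaffeineResponse:
    """Quantified caffeine (RyR-opener) response."""

    recovery_time_s: float       # caffeine peak to first measurable transient (NaN if none)
    amp_change_pct: float        # % change of caffeine amplitude vs mean pre amplitude
    area_fold_change: float      # caffeine transient area / mean pre-transient area
    caffeine_peak_time_s: float = field(default=float("nan"))


def analyze_caffeine(trace: VoltageTrace,
                     caffeine_time_s: float,
                     measurable_frac: float = MEASURABLE_FRAC) -> CaffeineResponse:
    """Quantify the response to a caffeine bolus at ``caffeine_time_s``.

    The caffeine transient is the largest-amplitude transient after the
    bolus; recovery time runs from its peak to the first subsequent transient
    whose amplitude reaches ``measurable_frac`` of the mean pre-caffeine
    amplitude.  Areas are trapezoidal, above each transient's own baseline,
    from onset to 95% return.
    """
    if not trace.t0_s < caffeine_time_s < trace.t_end_s:
        raise ValueError("caffeine_time_s outside the trace")
    feats = extract_ca_transients(trace)
    pre = [t for t in feats.transients if t.peak_time_s < caffeine_time_s]
    post = [t for t in feats.transients if t.peak_time_s >= caffeine_time_s]
    if len(pre) < 3:
        raise ValueError("need at least 3 pre-caffeine transients")
    if not post:
        raise ValueError("no transient found after the caffeine bolus")
    caf = max(post, key=lambda t: t.r_amp)
    mean_pre_amp = float(np.mean([t.r_amp for t in pre]))
    mean_pre_area = float(np.mean([t.area for t in pre]))
    amp_change = 100.0 * (caf.r_amp - mean_pre_amp) / mean_pre_amp
    fold = caf.area / mean_pre_area

    resumed = [t for t in post
               if t.peak_time_s > caf.peak_time_s
               and t.r_amp >= measurable_frac * mean_pre_amp]
    if resumed:
        recovery = resumed[0].peak_time_s - caf.peak_time_s
    else:
        warnings.warn("no measurable post-caffeine transient; recovery time missing",
                      stacklevel=2)
        recovery = float("nan")
    return CaffeineResponse(recovery, amp_change, fold, caf.peak_time_s)
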