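"""Beat location: AP peaks, MEA spikes, ECG R-waves -> :class:`BeatSeries`."""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from ._smooth import highpass_rc
from .core import BeatSeries, Modality, VoltageTrace

__all__ = ["detect_ap_beats", "detect_mea_spikes", "detect_r_peaks"]


def detect_ap_beats(trace: VoltageTrace,
                    threshold_mv: float = 0.0,
                    refractory_s: float = 0.2) -> BeatSeries:
    """Locate action potentials in an intracellular trace.

    A beat is the local maximum following each upward crossing of
    ``threshold_mv`` (default 0 mV — the overshoot crossing); successive
    beats are separated by at least ``refractory_s``.  A trace with no
    crossings yields an empty series.
    """
    _require(trace, Modality.AP)
    v = trace.samples
    above = v >= threshold_mv
    rises = np.flatnonzero(~above[:-1] & above[1:]) + 1
    falls = np.flatnonzero(above[:-1] & ~above[1:]) + 1
    times: list[float] = []
    last = -np.inf
    for r in rises:
        f_candidates = falls[falls > r]
        f = int(f_candidates[0]) if f_candidates.size else v.size
        peak = r + int(np.argmax(v[r:f]))
        t = trace.t0_s + peak / trace.rate_hz
        if t - last >= refractory_s:
            times.append(t)
            last = t
    return BeatSeries(np.asarray(times), Modality.AP)


def detect_mea_spikes(trace: VoltageTrace,
                      k_mad: float = 5.0,
                      refractory_s: float = 0.1) -> BeatSeries:
    """Locate extracellular spikes by a robust amplitude threshold.

    The signal is detrended with a 1 Hz first-difference high-pass, the noise
    scale estimated as 1.4826 x median absolute deviation, and a spike placed
    at the absolute extremum of each run where ``|signal|`` exceeds
    ``k_mad`` x noise.  Polarity-invariant by construction.
    """
    _require(trace, Modality.MEA)
    if trace.duration_s < 1.0:
        raise ValueError("MEA trace shorter than 1 s")
    x = highpass_rc(trace.samples, trace.rate_hz, corner_hz=1.0)
    noise = 1.4826 * float(np.median(np.abs(x - np.median(x))))
    if noise <= 0:
        return BeatSeries(np.asarray([]), Modality.MEA)
    thr = k_mad * noise
    idx = np.flatnonzero(np.abs(x) > thr)
    times: list[float] = []
    if idx.size:
        splits = np.flatnonzero(np.diff(idx) > 1) + 1
        last = -np.inf
        for run in np.split(idx, splits):
            peak = run[int(np.argmax(np.abs(x[run])))]
            t = trace.t0_s + peak / trace.rate_hz
            if t - last >= refractory_s:
                times.append(t)
                last = t
    return BeatSeries(np.asarray(times), Modality.MEA)


def detect_r_peaks(trace: VoltageTrace,
                   refractory_s: float = 0.04) -> BeatSeries:
    """R-wave detection: band-pass, differentiate, square, integrate, then an
    adaptive threshold (a Pan-Tompkins-style chain sized for rat rates)."""
    _require(trace, Modality.ECG)
    fs = trace.rate_hz
    if fs < 100:
        raise ValueError("ECG sampling rate below 100 Hz: insufficient bandwidth")
    nyq = fs / 2.0
    b, a = butter(2, [min(10.0 / nyq, 0.8), min(45.0 / nyq, 0.95)], btype="band")
    band = filtfilt(b, a, trace.samples)
    energy = np.gradient(band) ** 2
    win = max(3, int(round(0.03 * fs)))
    integ = np.convolve(energy, np.ones(win) / win, mode="same")
    peak_level = float(np.percentile(integ, 99.5))
    if peak_level <= 0 or np.max(integ) < 10 * (float(np.median(integ)) + 1e-30):
        return BeatSeries(np.asarray([]), Modality.ECG)  # flat / featureless trace
    thr = 0.2 * peak_level
    locs, _ = find_peaks(integ, height=thr, distance=max(1, int(refractory_s * fs)))
    # refine each detection to the extremum of the band-passed ECG nearby
    half = int(round(0.04 * fs))
    times: list[float] = []
    for p in locs:
        lo, hi = max(0, p - half), min(band.size, p + half + 1)
        peak = lo + int(np.argmax(np.abs(band[lo:hi])))
        t = trace.t0_s + peak / fs
        if not times or t - times[-1] >= refractory_s:
            times.append(t)
    return BeatSeries(np.asarray(times), Modality.ECG)


def _require(trace: VoltageTrace, modality: Modality) -> None:
    if trace.modality is not modality:
        raise ValueError(f"expected a {modality.value} trace, got {trace.modality.value}")
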