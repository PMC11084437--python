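"""Shared local-polynomial smoothing and derivative estimation.

A single Savitzky-Golay configuration (5-point window, order 2) is used for
every derivative in the package (AP upstroke velocity, Ca2+ rise/decay rates)
so generator calibration and measurement agree on what "the derivative" means.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter

DERIV_WINDOW = 5
DERIV_ORDER = 2


def smoothed_derivative(samples: np.ndarray, rate_hz: float,
                        window: int = DERIV_WINDOW, order: int = DERIV_ORDER) -> np.ndarray:
    """First derivative (units per second) of a local-polynomial fit."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < window:
        # fall back to plain differences on very short segments
        return np.gradient(samples) * rate_hz
    return savgol_filter(samples, window, order, deriv=1, delta=1.0 / rate_hz)


def smooth(samples: np.ndarray, window: int = DERIV_WINDOW, order: int = DERIV_ORDER) -> np.ndarray:
    samples = np.asarray(samples, dtype=float)
    if samples.size < window:
        return samples.copy()
    return savgol_filter(samples, window, order)


def lowpass(samples: np.ndarray, rate_hz: float, corner_hz: float) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth low-pass (for event detection)."""
    from scipy.signal import butter, filtfilt

    wn = min(corner_hz / (rate_hz / 2.0), 0.99)
    b, a = butter(2, wn, btype="low")
    return filtfilt(b, a, np.asarray(samples, dtype=float))


def highpass_rc(samples: np.ndarray, rate_hz: float, corner_hz: float = 1.0) -> np.ndarray:
    """First-difference-based single-pole RC high-pass.

    Removes baseline wander (field-potential drift) without the ringing of a
    sharp filter; corner frequency in Hz.
    """
    from scipy.signal import lfilter

    x = np.asarray(samples, dtype=float)
    dt = 1.0 / rate_hz
    alpha = 1.0 / (1.0 + 2.0 * np.pi * corner_hz * dt)
    # y[i] = alpha * y[i-1] + alpha * (x[i] - x[i-1])
    y = lfilter([alpha, -alpha], [1.0, -alpha], x - x[0])
    return y
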