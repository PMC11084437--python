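"""Per-beat action-potential characteristics and pacing-protocol windows.

Per beat: MDP (maximal diastolic potential), peak, APA (peak - MDP),
dV/dt_max (maximal upstroke velocity from a local-polynomial-smoothed
derivative), and APD90 — the duration from activation (time of dV/dt_max)
until the falling phase first crosses ``peak - 0.9 * APA``.  Referencing
APD90 to activation rather than to the peak is the package's convention and
is recorded in the output metadata.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._smooth import smoothed_derivative
from .core import BeatSeries, Modality, VoltageTrace

__all__ = ["APFeatures", "compute_ap_features", "paced_epochs", "PacingProtocol", "Epoch"]

log = logging.getLogger(__name__)

UPSTROKE_WINDOW_S = 0.05  # dV/dt_max search window ending at the peak


@dataclass
class APFeatures:
    """Per-beat AP feature vectors plus the recording-level summary."""

    beat_times_s: np.ndarray
    mdp_mv: np.ndarray
    peak_mv: np.ndarray
    apa_mv: np.ndarray
    dvdt_max_vps: np.ndarray
    activation_times_s: np.ndarray
    apd90_ms: np.ndarray          # NaN where 90% repolarization was not reached
    beat_rate_bpm: float
    meta: dict = field(default_factory=lambda: {"apd90_reference": "activation"})

    def summary(self) -> dict[str, tuple[float, float]]:
        """(mean, sample SD) for each feature over beats with valid values."""
        out = {}
        for name in ("mdp_mv", "peak_mv", "apa_mv", "dvdt_max_vps", "apd90_ms"):
            v = getattr(self, name)
            v = v[np.isfinite(v)]
            out[name] = (float(np.mean(v)), float(np.std(v, ddof=1)) if v.size > 1 else float("nan"))
        return out


def compute_ap_features(trace: VoltageTrace, beats: BeatSeries) -> APFeatures:
    """Measure AP characteristics for each beat of an intracellular trace."""
    if trace.modality is not Modality.AP:
        raise ValueError("compute_ap_features requires an intracellular (ap) trace")
    if beats.n_beats < 2:
        raise ValueError("need at least 2 beats")
    fs = trace.rate_hz
    v = trace.samples
    peak_idx = np.array([trace.index_of(t) for t in beats.beat_times_s])

    n = beats.n_beats
    mdp = np.empty(n)
    peak = np.empty(n)
    dvdt = np.empty(n)
    act_t = np.empty(n)
    apd90 = np.full(n, np.nan)

    prev_bound = 0  # start of the current beat's diastolic search window
    for k in range(n):
        p = peak_idx[k]
        peak[k] = v[p]
        lo = max(0, p - int(round(UPSTROKE_WINDOW_S * fs)))
        seg = v[lo:p + 1]
        d = smoothed_derivative(seg, fs)
        act = lo + int(np.argmax(d))
        dvdt[k] = float(np.max(d)) / 1000.0  # mV/s -> V/s
        act_t[k] = trace.t0_s + act / fs

        # MDP: minimum over [previous APD90 crossing (or trace start), upstroke)
        mdp_lo = prev_bound
        mdp_hi = max(mdp_lo + 1, act)
        mdp[k] = float(np.min(v[mdp_lo:mdp_hi]))

        apa_k = peak[k] - mdp[k]
        level = peak[k] - 0.9 * apa_k
        nxt = peak_idx[k + 1] - int(round(UPSTROKE_WINDOW_S * fs)) if k + 1 < n else v.size
        fall = v[p:max(p + 1, nxt)]
        below = np.flatnonzero(fall <= level)
        if below.size:
            cross = p + int(below[0])
            apd90[k] = (cross - act) / fs * 1000.0
            prev_bound = cross
        else:
            msg = f"beat {k}: repolarization never reached the 90% level before the next beat"
            log.warning(msg)
            warnings.warn(msg, stacklevel=2)
            prev_bound = p + 1

    apa = peak - mdp
    ibis = beats.ibis_s
    rate_bpm = 60.0 * ibis.size / float(np.sum(ibis))
    return APFeatures(beats.beat_times_s.copy(), mdp, peak, apa, dvdt, act_t, apd90, rate_bpm)


# ---------------------------------------------------------------------------
# pacing protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PacingProtocol:
    """Pulse-train protocol: trains of fixed pulse count at increasing rates,
    separated by a fixed pause."""

    pulses_per_train: int = 20
    rates_hz: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0)
    pause_s: float = 20.0


@dataclass(frozen=True)
class Epoch:
    """A labeled half-open window ``[t_start_s, t_end_s)``."""

    label: str            # "train" or "pause"
    rate_hz: float
    t_start_s: float
    t_end_s: float


def paced_epochs(stim_times: Sequence[float],
                 protocol: PacingProtocol = PacingProtocol()) -> list[Epoch]:
    """Split a stimulus-time list into per-train and post-train pause windows.

    The stimulus list must contain exactly ``pulses_per_train`` pulses per
    train, trains ordered as in ``protocol.rates_hz``, with inter-pulse
    intervals matching each train's rate (10% tolerance).
    """
    stim = np.asarray(stim_times, dtype=float)
    if stim.size == 0:
        return []
    expected = protocol.pulses_per_train * len(protocol.rates_hz)
    if stim.size != expected:
        raise ValueError(f"expected {expected} stimuli "
                         f"({protocol.pulses_per_train} x {len(protocol.rates_hz)} trains), "
                         f"got {stim.size}")
    epochs: list[Epoch] = []
    k = 0
    for r in protocol.rates_hz:
        train = stim[k:k + protocol.pulses_per_train]
        k += protocol.pulses_per_train
        period = 1.0 / r
        gaps = np.diff(train)
        if np.any(np.abs(gaps - period) > 0.1 * period):
            raise ValueError(f"train at {r} Hz has inter-pulse intervals "
                             "inconsistent with its rate")
        t_end = float(train[-1]) + period
        epochs.append(Epoch("train", r, float(train[0]), t_end))
        epochs.append(Epoch("pause", r, t_end, t_end + protocol.pause_s))
    return epochs
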