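"""Subthreshold event detection and classification, cohort arrhythmia
metrics, pacing-response scoring, and whole-heart VA episode quantification.

Event taxonomy (diastolic, subthreshold):

* **DAD** — follows a normally timed action potential; a single oscillation
  or a damped run (non-increasing amplitudes after the first);
* **OPP** — a run of >= 3 oscillations with strictly increasing amplitudes
  that terminates in an action potential;
* **failed beat** — a deflection standing where a beat was expected, so the
  enclosing inter-beat interval is abnormally long.

The classification thresholds (2 mV minimum amplitude, 0.5 x APA ceiling,
+/-25% expected-time window, 1.5 x median IBI for failed beats) are declared
conventions of this package: the source morphology descriptions are
qualitative, and each threshold is a configurable argument.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

from .apfeatures import Epoch, compute_ap_features
from .core import ArrhythmiaEvent, BeatSeries, CohortTable, EventKind, VoltageTrace

__all__ = [
    "Candidate",
    "detect_subthreshold_events",
    "classify_events",
    "ArrhythmiaSummary",
    "summarize_arrhythmia",
    "percent_arrhythmogenic",
    "score_pacing_response",
    "VAReport",
    "detect_va_episodes",
]

log = logging.getLogger(__name__)

ARRHYTHMOGENIC_MIN_EVENTS = 3   # >= 3 events/cell defines an arrhythmogenic cell
SUSTAINED_VA_S = 30.0           # an episode lasting more than this is sustained


@dataclass(frozen=True)
class Candidate:
    """A diastolic subthreshold deflection candidate."""

    time_s: float
    amplitude_mv: float
    diastole_index: int  # candidate lies between beats i and i+1 (-1: before beat 0)


def detect_subthreshold_events(trace: VoltageTrace,
                               beats: BeatSeries,
                               min_amp_mv: float = 2.0,
                               max_amp_frac_apa: float = 0.5) -> list[Candidate]:
    """Find diastolic local maxima with prominence in
    ``[min_amp_mv, max_amp_frac_apa * median APA]``, excluding each beat's
    upstroke and repolarization windows."""
    if beats.n_beats < 2:
        raise ValueError("need >= 2 beats to define diastolic intervals")
    feats = compute_ap_features(trace, beats)
    apa_med = float(np.median(feats.apa_mv))
    max_amp = max_amp_frac_apa * apa_med

    fs = trace.rate_hz
    win = int(round(0.015 * fs)) // 2 * 2 + 1  # ~15 ms local-polynomial smoother
    v = savgol_filter(trace.samples, win, 2) if trace.samples.size > win >= 5 else trace.samples

    # diastolic windows: end of one beat's repolarization to the next upstroke
    margin = 0.02
    repol_end = np.where(np.isfinite(feats.apd90_ms),
                         feats.activation_times_s + feats.apd90_ms / 1000.0,
                         feats.beat_times_s + 0.5 * float(np.median(beats.ibis_s)))
    windows: list[tuple[int, float, float]] = [(-1, trace.t0_s, feats.activation_times_s[0] - margin)]
    for i in range(beats.n_beats):
        lo = repol_end[i] + margin
        hi = feats.activation_times_s[i + 1] - margin if i + 1 < beats.n_beats else trace.t_end_s
        windows.append((i, lo, hi))

    out: list[Candidate] = []
    for idx, lo, hi in windows:
        a = trace.index_of(lo)
        b = trace.index_of(hi)
        if b - a < 5:
            continue
        seg = v[a:b]
        peaks, props = find_peaks(seg, prominence=min_amp_mv)
        for p, prom in zip(peaks, props["prominences"]):
            if prom > max_amp:
                continue
            out.append(Candidate(trace.t0_s + (a + p) / fs, float(prom), idx))
    return sorted(out, key=lambda c: c.time_s)


def classify_events(candidates: list[Candidate],
                    beats: BeatSeries,
                    timing_tol_frac: float = 0.25,
                    failed_ibi_factor: float = 1.5,
                    median_window: int = 10) -> list[ArrhythmiaEvent]:
    """Apply the ordered classification rules to diastolic candidate runs.

    Per diastole: (1) OPP if >= 3 strictly increasing amplitudes ending in a
    beat; (2) failed beat if the enclosing IBI exceeds ``failed_ibi_factor`` x
    the running median IBI and a candidate lies within ``timing_tol_frac`` of
    the expected beat time; (3) DAD for remaining single/damped runs after a
    normally timed beat.  Unclassifiable runs are kept with kind ``unknown``.
    """
    t = beats.beat_times_s
    runs: dict[int, list[Candidate]] = {}
    for c in sorted(candidates, key=lambda x: x.time_s):
        runs.setdefault(c.diastole_index, []).append(c)

    events: list[ArrhythmiaEvent] = []
    all_ibis = beats.ibis_s
    for i, run in sorted(runs.items()):
        times = [c.time_s for c in run]
        amps = [c.amplitude_mv for c in run]
        t_start = times[0] - 0.01
        t_end = times[-1] + 0.01
        ibis_before = all_ibis[max(0, i - median_window):max(0, i)]
        med_ibi = float(np.median(ibis_before)) if ibis_before.size else \
            (float(np.median(all_ibis)) if all_ibis.size else np.nan)

        followed_by_beat = 0 <= i + 1 < beats.n_beats or i == -1
        increasing = len(amps) >= 3 and all(b > a for a, b in zip(amps, amps[1:]))
        if increasing and followed_by_beat:
            events.append(ArrhythmiaEvent(EventKind.OPP, t_start, t_end, tuple(amps)))
            continue

        interior = 0 <= i < beats.n_beats - 1
        if interior and np.isfinite(med_ibi):
            enclosing = t[i + 1] - t[i]
            expected = t[i] + med_ibi
            near = any(abs(tt - expected) <= timing_tol_frac * med_ibi for tt in times)
            if enclosing > failed_ibi_factor * med_ibi and near:
                events.append(ArrhythmiaEvent(EventKind.FAILED_BEAT, t_start, t_end, tuple(amps)))
                continue

        non_increasing_after_first = all(b <= a for a, b in zip(amps[1:], amps[2:]))
        if i >= 0 and non_increasing_after_first:
            events.append(ArrhythmiaEvent(EventKind.DAD, t_start, t_end, tuple(amps)))
            continue

        msg = f"unclassifiable candidate run at t={times[0]:.3f}s (n={len(run)})"
        log.warning(msg)
        warnings.warn(msg, stacklevel=2)
        events.append(ArrhythmiaEvent(EventKind.UNKNOWN, t_start, t_end, tuple(amps)))
    return events


@dataclass
class ArrhythmiaSummary:
    """Recording-level arrhythmia metrics."""

    events: list[ArrhythmiaEvent]
    duration_s: float
    n_events: int = field(init=False)
    occurrence_per_min: float = field(init=False)
    is_arrhythmogenic: bool = field(init=False)
    counts_by_kind: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.n_events = len(self.events)
        self.occurrence_per_min = self.n_events / (self.duration_s / 60.0)
        self.is_arrhythmogenic = self.n_events >= ARRHYTHMOGENIC_MIN_EVENTS
        self.counts_by_kind = {k.value: 0 for k in EventKind}
        for e in self.events:
            self.counts_by_kind[e.kind.value] += 1


def summarize_arrhythmia(events: list[ArrhythmiaEvent], duration_s: float) -> ArrhythmiaSummary:
    """Event count, events/minute occurrence, and the >= 3 events/cell rule."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    return ArrhythmiaSummary(list(events), duration_s)


def percent_arrhythmogenic(cohort: CohortTable) -> pd.DataFrame:
    """Per-group percentage of arrhythmogenic cells (with group n)."""
    if "is_arrhythmogenic" not in cohort.data.columns:
        raise ValueError("cohort rows need an 'is_arrhythmogenic' column")
    rows = []
    for g in cohort.groups:
        sub = cohort.data[cohort.data["group"] == g]
        if len(sub) == 0:
            warnings.warn(f"group {g!r} is empty; percentage reported missing", stacklevel=2)
            rows.append({"group": g, "n": 0, "percent_arrhythmogenic": np.nan})
            continue
        pct = 100.0 * float(sub["is_arrhythmogenic"].sum()) / len(sub)
        rows.append({"group": g, "n": len(sub), "percent_arrhythmogenic": pct})
    return pd.DataFrame(rows)


def score_pacing_response(trace: VoltageTrace,
                          beats: BeatSeries,
                          epochs: list[Epoch],
                          cessation_factor: float = 2.0) -> dict[float, bool]:
    """Flag each pacing rate whose post-train pause shows an arrhythmia.

    A rate is flagged if a classified event occurs inside its pause window or
    firing ceases (no beat for more than ``cessation_factor`` x the median
    pre-pacing IBI) during the pause.
    """
    spans = sorted((e.t_start_s, e.t_end_s) for e in epochs)
    for (s0, e0), (s1, _) in zip(spans, spans[1:]):
        if s1 < e0 - 1e-9:
            raise ValueError("overlapping epochs")
    pauses = [e for e in epochs if e.label == "pause"]
    first_train = min((e.t_start_s for e in epochs if e.label == "train"), default=np.inf)
    pre = beats.ibis_s[beats.beat_times_s[1:] <= first_train]
    med_pre = float(np.median(pre)) if pre.size else float(np.median(beats.ibis_s))

    candidates = detect_subthreshold_events(trace, beats)
    events = classify_events(candidates, beats)
    flags: dict[float, bool] = {}
    for p in pauses:
        hit = any(p.t_start_s <= e.t_start_s < p.t_end_s for e in events)
        inside = beats.beat_times_s[(beats.beat_times_s >= p.t_start_s)
                                    & (beats.beat_times_s < p.t_end_s)]
        marks = np.concatenate([[p.t_start_s], inside, [p.t_end_s]])
        max_gap = float(np.max(np.diff(marks)))
        flags[p.rate_hz] = bool(hit or max_gap > cessation_factor * med_pre)
    return flags


@dataclass
class VAReport:
    """Ventricular-arrhythmia episodes over a whole-heart recording."""

    episodes: list[tuple[float, float]]
    recording_duration_s: float
    any_sustained_va: bool = field(init=False)
    fractional_duration_pct: float = field(init=False)

    def __post_init__(self) -> None:
        self.any_sustained_va = any(t1 - t0 > SUSTAINED_VA_S for t0, t1 in self.episodes)
        total = sum(t1 - t0 for t0, t1 in self.episodes)
        self.fractional_duration_pct = 100.0 * total / self.recording_duration_s


def detect_va_episodes(beats: BeatSeries,
                       baseline_window_s: float = 60.0,
                       rate_factor: float = 1.5,
                       min_gap_s: float = 2.0,
                       recording_duration_s: float | None = None) -> VAReport:
    """Detect abrupt fast-rate (VA) episodes from a beat series.

    Baseline RR is the median RR over the initial ``baseline_window_s``; any
    RR below ``baseline / rate_factor`` is a VA interval.  Consecutive VA
    intervals form episodes; episodes closer than ``min_gap_s`` are merged.
    An episode lasting more than 30 s is sustained.
    """
    t = beats.beat_times_s
    duration = recording_duration_s if recording_duration_s is not None else float(t[-1])
    if t.size < 2 or t[-1] - t[0] < 60.0:
        raise ValueError("need at least 60 s of beats")
    if baseline_window_s > duration:
        raise ValueError("baseline window longer than the recording")
    rr = beats.ibis_s
    rr_t0 = t[:-1]
    base = rr[rr_t0 <= t[0] + baseline_window_s]
    baseline_rr = float(np.median(base))
    is_va = rr < baseline_rr / rate_factor

    episodes: list[tuple[float, float]] = []
    i = 0
    while i < is_va.size:
        if is_va[i]:
            j = i
            while j + 1 < is_va.size and is_va[j + 1]:
                j += 1
            # the onset lies somewhere in the RR interval preceding the first
            # fast beat; its midpoint is the unbiased estimate
            start = float(0.5 * (t[i - 1] + t[i])) if i > 0 else float(t[i])
            episodes.append((start, float(t[j + 1])))
            i = j + 1
        i += 1
    merged: list[tuple[float, float]] = []
    for ep in episodes:
        if merged and ep[0] - merged[-1][1] < min_gap_s:
            merged[-1] = (merged[-1][0], ep[1])
        else:
            merged.append(ep)
    return VAReport(merged, duration)
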