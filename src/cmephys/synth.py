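"""Synthetic recordings with ground-truth labels for every input modality.

These generators stand in for the study's recordings: spontaneous action
potential trains with injected DADs / oscillatory pre-potentials / failed
beats, unimodal and alternation-biased bimodal inter-beat-interval processes,
extracellular (MEA) electrograms, rat-heart beat sequences with ventricular
arrhythmia episodes, Ca2+ transient traces with an optional caffeine bolus,
and two-channel cell images with a prescribed nucleus/cytoplasm density
ratio.  Every injected feature is recorded in a :class:`GroundTruth` so the
analysis stages can be scored against known labels.

All generators are deterministic for a fixed seed (single
``numpy.random.default_rng`` stream per call).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from ._smooth import lowpass, smoothed_derivative
from .core import BeatSeries, EventKind, Modality, VoltageTrace

__all__ = [
    "GroundTruth",
    "APWaveform",
    "EventSpec",
    "gen_ap_train",
    "gen_paced_recording",
    "gen_ibi_series",
    "gen_mea_trace",
    "VAEpisodeSpec",
    "gen_ecg_beats",
    "render_ecg_trace",
    "CaffeineSpec",
    "gen_ca_trace",
    "ca_analytic_rates",
    "CellGeometry",
    "gen_cell_image",
    "NC_PRESETS",
]

# N/C density-ratio presets emulating the study conditions
NC_PRESETS: dict[str, float] = {
    "control": 1.30,
    "-AA": 0.25,
    "-AA+YWF": 2.66,
    "-AA+LMB": 2.36,
}


@dataclass
class GroundTruth:
    """Labels recorded by a generator for downstream scoring."""

    beat_times_s: np.ndarray | None = None
    injected_events: list[tuple[str, float, dict]] = field(default_factory=list)
    ibi_process: dict | None = None
    image_truth: dict | None = None
    va_episodes: list[tuple[float, float]] = field(default_factory=list)
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# action potential trains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class APWaveform:
    """Phenomenological AP shape: linear upstroke, brief plateau, exponential
    repolarization calibrated so the measured APD90 equals ``apd90_ms``."""

    mdp_mv: float = -75.0
    peak_mv: float = 30.0
    apd90_ms: float = 300.0
    upstroke_vps: float = 100.0
    plateau_ms: float = 2.0

    @property
    def apa_mv(self) -> float:
        return self.peak_mv - self.mdp_mv


@dataclass(frozen=True)
class EventSpec:
    """Injection request: ``kind`` at (relative to) scheduled beat ``beat_index``.

    * ``DAD``: damped oscillation run in the diastole *after* the beat;
    * ``OPP``: growing oscillation run ending in the beat's upstroke;
    * ``failed_beat``: the beat is omitted and replaced by a subthreshold bump.
    """

    kind: EventKind
    beat_index: int
    amplitude_mv: float | None = None
    n_oscillations: int | None = None


def _activation_index(samples: np.ndarray, rate_hz: float, peak_idx: int,
                      window_s: float = 0.05) -> int:
    """Sample of maximal smoothed dV/dt in the window ending at the peak."""
    lo = max(0, peak_idx - int(round(window_s * rate_hz)))
    seg = samples[lo:peak_idx + 1]
    d = smoothed_derivative(seg, rate_hz)
    return lo + int(np.argmax(d))


def _ap_template(wf: APWaveform, rate_hz: float) -> dict:
    """Build one AP kernel on the sample grid and calibrate its decay constant.

    The repolarization time constant is solved so that the 90%-repolarization
    crossing, measured from the activation time the feature stage will itself
    report (max smoothed dV/dt), lands exactly at ``apd90_ms``.
    """
    dt = 1.0 / rate_hz
    n_plateau = max(1, int(round(wf.plateau_ms / 1000.0 / dt)))
    lead = 10  # diastolic samples ahead of the upstroke, for the derivative fit

    # upstroke with an exact per-sample increment so its slope is exactly
    # upstroke_vps (a shorter first step absorbs any remainder)
    inc = wf.upstroke_vps * 1000.0 * dt  # mV per sample
    n_full = int(math.floor(wf.apa_mv / inc))
    if n_full >= 2:
        up = wf.peak_mv - inc * np.arange(n_full, -1, -1)
        if up[0] > wf.mdp_mv + 1e-9:
            up = np.concatenate([[wf.mdp_mv], up])
    else:  # upstroke too fast for the grid: 2 intervals, slope undersampled
        up = np.linspace(wf.mdp_mv, wf.peak_mv, 3)
    head = np.concatenate([np.full(lead, wf.mdp_mv), up, np.full(n_plateau - 1, wf.peak_mv)])
    peak_idx = lead + up.size - 1  # last ramp sample is the first at peak value
    act_idx = _activation_index(head, rate_hz, peak_idx)

    apd90_s = wf.apd90_ms / 1000.0
    t_cross = act_idx * dt + apd90_s           # target crossing (continuous time)
    t_decay0 = (peak_idx + n_plateau - 1) * dt  # decay start
    if t_cross <= t_decay0 + dt:
        raise ValueError("apd90_ms too short for the requested upstroke/plateau")
    tau = (t_cross - t_decay0) / math.log(10.0)

    # decay until within 0.5% of MDP, then clamp so diastole (and MDP) is exact
    n_decay = int(math.ceil(tau * math.log(200.0) / dt))
    t_rel = np.arange(1, n_decay + 1) * dt
    decay = wf.mdp_mv + wf.apa_mv * np.exp(-t_rel / tau)
    decay[decay < wf.mdp_mv + 0.005 * wf.apa_mv] = wf.mdp_mv
    kernel = np.concatenate([head, decay])
    return {
        "kernel": kernel,
        "lead": lead,
        "peak_offset": peak_idx,          # samples from kernel start to peak
        "act_offset": act_idx,
        "repol_offset": peak_idx + n_plateau - 1 + int(round((t_cross - t_decay0) / dt)),
        "tau_s": tau,
    }


def _raised_cosine_run(peak_amps: Sequence[float], period_s: float,
                       rate_hz: float) -> np.ndarray:
    """Adjacent raised-cosine bumps, one per oscillation, peak at each center."""
    n_per = max(4, int(round(period_s * rate_hz)))
    t = np.arange(n_per) / n_per
    bump = 0.5 * (1.0 - np.cos(2.0 * np.pi * t))
    return np.concatenate([a * bump for a in peak_amps])


def gen_ap_train(rate_bpm: float = 60.0,
                 duration_s: float = 60.0,
                 waveform: APWaveform = APWaveform(),
                 events: Sequence[EventSpec] = (),
                 noise_sd_mv: float = 0.5,
                 seed: int = 0,
                 rate_hz: float = 10_000.0,
                 ibi_cv: float = 0.0) -> tuple[VoltageTrace, GroundTruth]:
    """Spontaneous AP train with optional injected arrhythmogenic events.

    Returns the trace and a :class:`GroundTruth` whose ``beat_times_s`` are
    the AP peak times actually present (failed beats omitted) and whose
    ``injected_events`` hold one ``(kind, time, params)`` entry per request.
    """
    if rate_bpm <= 0:
        raise ValueError("rate_bpm must be positive")
    ibi_s = 60.0 / rate_bpm
    if waveform.apd90_ms >= 60_000.0 / rate_bpm:
        raise ValueError("apd90_ms must be shorter than the beat interval")
    rng = np.random.default_rng(seed)
    dt = 1.0 / rate_hz
    n = int(round(duration_s * rate_hz))

    tpl = _ap_template(waveform, rate_hz)
    kernel = tpl["kernel"]
    lead, peak_off = tpl["lead"], tpl["peak_offset"]

    # scheduled upstroke onsets (the sample after the diastolic lead)
    onsets: list[float] = []
    t = ibi_s / 2.0
    while t + dt * (peak_off - lead) < duration_s - dt:
        onsets.append(t)
        step = ibi_s * (1.0 + ibi_cv * float(rng.standard_normal())) if ibi_cv > 0 else ibi_s
        t += max(step, 0.25 * ibi_s)
    n_sched = len(onsets)

    by_index: dict[int, EventSpec] = {}
    for ev in events:
        if not 0 <= ev.beat_index < n_sched:
            raise ValueError(f"event beat_index {ev.beat_index} outside schedule (0..{n_sched - 1})")
        if ev.beat_index in by_index:
            raise ValueError(f"multiple events at beat {ev.beat_index}")
        by_index[ev.beat_index] = ev

    failed = {i for i, ev in by_index.items() if ev.kind is EventKind.FAILED_BEAT}

    samples = np.full(n, waveform.mdp_mv)
    beat_times: list[float] = []
    for i, onset in enumerate(onsets):
        if i in failed:
            continue
        i0 = int(round(onset * rate_hz)) - lead
        seg = kernel[max(0, -i0):min(len(kernel), n - i0)]
        samples[max(i0, 0):max(i0, 0) + len(seg)] = seg
        beat_times.append((i0 + peak_off) * dt)

    truth = GroundTruth(beat_times_s=np.asarray(beat_times))
    apd90_s = waveform.apd90_ms / 1000.0
    osc_period = 0.12

    for i, ev in sorted(by_index.items()):
        if ev.kind is EventKind.FAILED_BEAT:
            amp = ev.amplitude_mv if ev.amplitude_mv is not None else float(rng.uniform(5.0, 15.0))
            width = 0.16
            center = onsets[i] + dt * (peak_off - lead)
            run = _raised_cosine_run([amp], width, rate_hz)
            start_t = center - width / 2.0
            peaks_t = [center]
            amps = [amp]
        elif ev.kind is EventKind.DAD:
            n_osc = ev.n_oscillations if ev.n_oscillations is not None else int(rng.integers(1, 4))
            a0 = ev.amplitude_mv if ev.amplitude_mv is not None else float(rng.uniform(5.0, 15.0))
            amps = [a0 * 0.55 ** j for j in range(n_osc)]
            start_t = onsets[i] + apd90_s + 0.10
            run = _raised_cosine_run(amps, osc_period, rate_hz)
            peaks_t = [start_t + (j + 0.5) * osc_period for j in range(n_osc)]
        elif ev.kind is EventKind.OPP:
            n_osc = ev.n_oscillations if ev.n_oscillations is not None else int(rng.integers(3, 7))
            if n_osc < 3:
                raise ValueError("OPP run needs >= 3 oscillations")
            a_last = ev.amplitude_mv if ev.amplitude_mv is not None else float(rng.uniform(8.0, 15.0))
            amps = [a_last / 1.3 ** (n_osc - 1 - j) for j in range(n_osc)]
            # compress the oscillation period if the run would not fit the diastole
            prev_end = onsets[i - 1] + apd90_s + 0.04 if i > 0 else 0.0
            avail = onsets[i] - 0.02 - prev_end
            period = min(osc_period, avail / n_osc)
            if period < 0.05:
                raise ValueError(f"OPP run of {n_osc} oscillations does not fit "
                                 f"the diastole before beat {i}")
            start_t = onsets[i] - 0.02 - n_osc * period
            run = _raised_cosine_run(amps, period, rate_hz)
            peaks_t = [start_t + (j + 0.5) * period for j in range(n_osc)]
        else:
            raise ValueError(f"cannot inject event kind {ev.kind}")

        end_t = start_t + len(run) * dt
        _check_diastolic(start_t, end_t, i, onsets, apd90_s, ev.kind)
        i0 = int(round(start_t * rate_hz))
        if i0 < 0 or i0 + len(run) > n:
            raise ValueError(f"event at beat {i} falls outside the trace")
        samples[i0:i0 + len(run)] += run
        truth.injected_events.append(
            (ev.kind.value, peaks_t[0],
             {"peak_times_s": peaks_t, "amplitudes_mv": amps, "beat_index": i}))

    if noise_sd_mv > 0:
        samples = samples + _bandlimited_noise(rng, n, rate_hz, noise_sd_mv, corner_hz=1000.0)

    trace = VoltageTrace(samples, rate_hz, Modality.AP, units="mV",
                         meta={"generator": "gen_ap_train", "seed": seed})
    truth.extra.update(tau_repol_s=tpl["tau_s"], waveform=waveform, ibi_s=ibi_s,
                       scheduled_onsets_s=onsets)
    return trace, truth


def _check_diastolic(start_t: float, end_t: float, i: int, onsets: list[float],
                     apd90_s: float, kind: EventKind) -> None:
    """Reject injections that collide with an AP or its refractory margin."""
    margin = 0.02
    if kind is EventKind.FAILED_BEAT:
        lo = onsets[i - 1] + apd90_s + margin if i > 0 else 0.0
        hi = onsets[i + 1] - margin if i + 1 < len(onsets) else end_t + 1.0
    elif kind is EventKind.DAD:
        lo = onsets[i] + apd90_s + margin
        hi = onsets[i + 1] - margin if i + 1 < len(onsets) else end_t + 1.0
    else:  # OPP: run must fit after the previous repolarization
        lo = onsets[i - 1] + apd90_s + margin if i > 0 else 0.0
        hi = onsets[i] - 0.001
    if start_t < lo or end_t > hi:
        raise ValueError(
            f"{kind.value} at beat {i} collides with the AP/refractory window "
            f"([{start_t:.3f}, {end_t:.3f}) not within [{lo:.3f}, {hi:.3f}))")


def _bandlimited_noise(rng: np.random.Generator, n: int, rate_hz: float,
                       sd: float, corner_hz: float) -> np.ndarray:
    white = rng.standard_normal(n)
    if corner_hz < rate_hz / 2.0:
        white = lowpass(white, rate_hz, corner_hz)
    s = np.std(white)
    return white * (sd / s) if s > 0 else white


# ---------------------------------------------------------------------------
# paced recordings (pulse-train protocol)
# ---------------------------------------------------------------------------

def gen_paced_recording(rates_hz: Sequence[float] = (0.5, 1.0, 1.5, 2.0),
                        pulses_per_train: int = 20,
                        pause_s: float = 20.0,
                        pre_s: float = 20.0,
                        spont_rate_hz: float = 1.0,
                        waveform: APWaveform = APWaveform(apd90_ms=250.0),
                        pause_events: dict[float, str] | None = None,
                        noise_sd_mv: float = 0.5,
                        seed: int = 0,
                        rate_hz: float = 10_000.0) -> tuple[VoltageTrace, np.ndarray, GroundTruth]:
    """Recording under the pulse-train pacing protocol.

    ``pause_events`` maps a train rate to ``"dad"`` (a DAD injected in that
    rate's post-train pause) or ``"cessation"`` (spontaneous firing suppressed
    for most of that pause).  Returns (trace, stimulus_times, truth).
    """
    pause_events = dict(pause_events or {})
    unknown = set(pause_events) - set(rates_hz)
    if unknown:
        raise ValueError(f"pause_events at rates not in the protocol: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    dt = 1.0 / rate_hz

    onsets: list[float] = []
    stim_times: list[float] = []
    dad_requests: list[tuple[float, float]] = []  # (time, rate flagged)
    t = 1.0
    spont_ibi = 1.0 / spont_rate_hz
    while t < pre_s:
        onsets.append(t)
        t += spont_ibi
    for r in rates_hz:
        period = 1.0 / r
        for _ in range(pulses_per_train):
            stim_times.append(t)
            onsets.append(t)
            t += period
        pause_start = t
        mode = pause_events.get(r)
        if mode == "dad":
            dad_requests.append((pause_start + 2.3, r))  # mid-diastole of the pause
        if mode == "cessation":
            t = pause_start + pause_s - 2.0
            onsets.append(t)
            t += spont_ibi
        else:
            t += 0.8 * spont_ibi  # first spontaneous escape beat
            while t < pause_start + pause_s - 0.4:  # margin before the next train
                onsets.append(t)
                t += spont_ibi
        t = pause_start + pause_s

    duration = t + 1.0
    n = int(round(duration * rate_hz))
    tpl = _ap_template(waveform, rate_hz)
    kernel, lead, peak_off = tpl["kernel"], tpl["lead"], tpl["peak_offset"]

    samples = np.full(n, waveform.mdp_mv)
    beat_times = []
    for onset in onsets:
        i0 = int(round(onset * rate_hz)) - lead
        seg = kernel[max(0, -i0):min(len(kernel), n - i0)]
        samples[max(i0, 0):max(i0, 0) + len(seg)] = seg
        beat_times.append((i0 + peak_off) * dt)

    truth = GroundTruth(beat_times_s=np.asarray(sorted(beat_times)))
    for t_dad, r in dad_requests:
        amp = float(rng.uniform(8.0, 14.0))
        run = _raised_cosine_run([amp], 0.12, rate_hz)
        i0 = int(round((t_dad - 0.06) * rate_hz))
        samples[i0:i0 + len(run)] += run
        truth.injected_events.append((EventKind.DAD.value, t_dad,
                                      {"pause_rate_hz": r, "amplitudes_mv": [amp]}))
    truth.extra["pause_events"] = pause_events
    truth.extra["protocol"] = {"rates_hz": list(rates_hz),
                               "pulses_per_train": pulses_per_train, "pause_s": pause_s}

    if noise_sd_mv > 0:
        samples = samples + _bandlimited_noise(rng, n, rate_hz, noise_sd_mv, 1000.0)
    trace = VoltageTrace(samples, rate_hz, Modality.AP, units="mV")
    return trace, np.asarray(stim_times), truth


# ---------------------------------------------------------------------------
# inter-beat-interval processes
# ---------------------------------------------------------------------------

def gen_ibi_series(mode: str,
                   modes_s: float | Sequence[float],
                   sd_s: float,
                   n: int,
                   seed: int = 0,
                   switch_prob: float = 0.5,
                   source_modality: Modality = Modality.AP,
                   t0_s: float = 0.0) -> BeatSeries:
    """IBI process: i.i.d. truncated-normal (``unimodal``) or an
    alternation-biased two-state process (``bimodal``).

    ``n`` is the number of IBIs (the series has ``n + 1`` beats).  In the
    bimodal process the generating state switches with probability
    ``switch_prob`` per beat, so consecutive IBIs hop between two clouds with
    minimal overlap.
    """
    if sd_s <= 0:
        raise ValueError("sd_s must be positive")
    if n < 3:
        raise ValueError("need n >= 3 IBIs")
    rng = np.random.default_rng(seed)
    if mode == "unimodal":
        m = float(np.atleast_1d(modes_s)[0])
        ibis = _truncnorm(rng, m, sd_s, n)
        process = {"mode": "unimodal", "modes_s": [m], "sd_s": sd_s}
    elif mode == "bimodal":
        mv = [float(x) for x in np.atleast_1d(modes_s)]
        if len(mv) != 2 or mv[0] == mv[1]:
            raise ValueError("bimodal mode requires two distinct mode values")
        state = int(rng.integers(0, 2))
        states = np.empty(n, dtype=int)
        for k in range(n):
            states[k] = state
            if rng.random() < switch_prob:
                state = 1 - state
        ibis = _truncnorm(rng, 0.0, sd_s, n) + np.asarray(mv)[states]
        process = {"mode": "bimodal", "modes_s": mv, "sd_s": sd_s,
                   "switch_prob": switch_prob, "states": states}
    else:
        raise ValueError(f"unknown mode {mode!r}")
    beats = t0_s + np.concatenate([[0.0], np.cumsum(ibis)])
    series = BeatSeries(beats, source_modality)
    series.__dict__["ibi_process"] = process  # attach ground truth descriptor
    return series


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal draws truncated to +/- 4 SD (and strictly positive shifts)."""
    x = rng.standard_normal(n)
    x = np.clip(x, -4.0, 4.0)
    return mean + sd * x


# ---------------------------------------------------------------------------
# MEA electrograms
# ---------------------------------------------------------------------------

def gen_mea_trace(n_spikes: int = 120,
                  spike_rate_hz: float = 1.0,
                  beat_times: np.ndarray | None = None,
                  ibi_cv: float = 0.03,
                  amp_uv: float = 200.0,
                  noise_sd_uv: float = 5.0,
                  wander_uv: float = 20.0,
                  rate_hz: float = 1000.0,
                  seed: int = 0) -> tuple[VoltageTrace, GroundTruth]:
    """Extracellular electrogram: a biphasic spike template on beat times,
    band-limited Gaussian noise, and slow field-potential baseline wander."""
    rng = np.random.default_rng(seed)
    if beat_times is None:
        ibi = 1.0 / spike_rate_hz
        ibis = np.maximum(ibi * (1.0 + ibi_cv * rng.standard_normal(n_spikes)), 0.2 * ibi)
        beat_times = 0.5 + np.concatenate([[0.0], np.cumsum(ibis[:-1])])
    beat_times = np.asarray(beat_times, dtype=float)
    t_start = beat_times[0] - 0.5  # pre-roll so no spike is clipped at the edge
    n = int(round((beat_times[-1] + 1.0 - t_start) * rate_hz))
    dt = 1.0 / rate_hz

    # biphasic kernel: dominant negative deflection (extremum at the beat
    # time) preceded by a smaller positive lobe
    sigma = 0.0012
    tk = (np.arange(-8 * sigma, 8 * sigma, dt))
    kernel = (-np.exp(-tk ** 2 / (2 * sigma ** 2))
              + 0.45 * np.exp(-(tk + 2.5 * sigma) ** 2 / (2 * sigma ** 2)))
    kernel *= amp_uv / np.max(np.abs(kernel))
    center = int(np.argmax(np.abs(kernel)))

    samples = np.zeros(n)
    for bt in beat_times:
        i0 = int(round((bt - t_start) * rate_hz)) - center
        seg = kernel[max(0, -i0):min(len(kernel), n - i0)]
        samples[max(i0, 0):max(i0, 0) + len(seg)] += seg

    tgrid = np.arange(n) * dt
    samples += wander_uv * np.sin(2 * np.pi * 0.2 * tgrid + rng.uniform(0, 2 * np.pi))
    if noise_sd_uv > 0:
        samples += _bandlimited_noise(rng, n, rate_hz, noise_sd_uv, corner_hz=rate_hz / 3.0)

    trace = VoltageTrace(samples, rate_hz, Modality.MEA, units="uV", t0_s=t_start)
    truth = GroundTruth(beat_times_s=beat_times)
    return trace, truth


# ---------------------------------------------------------------------------
# whole-heart beat sequences and ECG
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VAEpisodeSpec:
    """A ventricular-arrhythmia episode: fast, irregular beating."""

    t_start_s: float
    duration_s: float
    rate_factor: float = 2.5
    ibi_cv: float = 0.2


def gen_ecg_beats(duration_s: float,
                  sinus_rate_hz: float = 5.0,
                  ibi_cv: float = 0.03,
                  va_episodes: Sequence[VAEpisodeSpec] = (),
                  seed: int = 0) -> tuple[BeatSeries, GroundTruth]:
    """Rat-range sinus beat times with optional injected VA episodes."""
    rng = np.random.default_rng(seed)
    for ep in va_episodes:
        if ep.t_start_s < 0 or ep.t_start_s + ep.duration_s > duration_s:
            raise ValueError(f"VA episode [{ep.t_start_s}, {ep.t_start_s + ep.duration_s}) "
                             "outside the recording")
    sinus_ibi = 1.0 / sinus_rate_hz
    times: list[float] = []
    t = sinus_ibi
    while t < duration_s:
        times.append(t)
        ep = next((e for e in va_episodes
                   if e.t_start_s <= t < e.t_start_s + e.duration_s), None)
        if ep is not None:
            ibi = sinus_ibi / ep.rate_factor
            t += max(ibi * (1.0 + ep.ibi_cv * float(rng.standard_normal())), 0.25 * ibi)
        else:
            t += max(sinus_ibi * (1.0 + ibi_cv * float(rng.standard_normal())), 0.25 * sinus_ibi)
    beats = BeatSeries(np.asarray(times), Modality.ECG)
    truth = GroundTruth(beat_times_s=beats.beat_times_s,
                        va_episodes=[(e.t_start_s, e.t_start_s + e.duration_s)
                                     for e in va_episodes],
                        extra={"duration_s": duration_s, "sinus_rate_hz": sinus_rate_hz})
    return beats, truth


def render_ecg_trace(beats: BeatSeries,
                     rate_hz: float = 500.0,
                     qrs_amp_uv: float = 1000.0,
                     qrs_width_s: float = 0.008,
                     noise_sd_uv: float = 20.0,
                     wander_uv: float = 100.0,
                     duration_s: float | None = None,
                     seed: int = 0) -> VoltageTrace:
    """Synthesize an ECG waveform from beat times (Ricker QRS kernel)."""
    rng = np.random.default_rng(seed)
    duration = duration_s if duration_s is not None else beats.beat_times_s[-1] + 1.0
    n = int(round(duration * rate_hz))
    dt = 1.0 / rate_hz
    a = qrs_width_s
    tk = np.arange(-4 * a, 4 * a, dt)
    kernel = qrs_amp_uv * (1.0 - (tk / a) ** 2) * np.exp(-tk ** 2 / (2 * a ** 2))
    center = int(np.argmax(kernel))
    samples = np.zeros(n)
    for bt in beats.beat_times_s:
        i0 = int(round(bt * rate_hz)) - center
        seg = kernel[max(0, -i0):min(len(kernel), n - i0)]
        samples[max(i0, 0):max(i0, 0) + len(seg)] += seg
    tgrid = np.arange(n) * dt
    samples += wander_uv * np.sin(2 * np.pi * 0.3 * tgrid + rng.uniform(0, 2 * np.pi))
    if noise_sd_uv > 0:
        samples += _bandlimited_noise(rng, n, rate_hz, noise_sd_uv, corner_hz=rate_hz / 3.0)
    return VoltageTrace(samples, rate_hz, Modality.ECG, units="uV")


# ---------------------------------------------------------------------------
# Ca2+ transients
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CaffeineSpec:
    """Caffeine bolus: one large transient, a quiescent gap, then resumption.

    ``gap_s`` is the time from the caffeine-transient *peak* to the first
    resumed transient *peak*.
    """

    time_s: float
    f_caf: float = 2.0
    gap_s: float = 8.0
    tau_decay_factor: float = 3.0


def _ca_kernel(amp: float, tau_rise_s: float, tau_decay_s: float,
               total_s: float, rate_hz: float) -> tuple[np.ndarray, int]:
    """One transient on the grid: normalized exponential rise to exactly
    ``amp`` at the (grid-aligned) peak, exponential decay to exactly zero at
    the end of its allotted interval.  Returns (kernel, peak index)."""
    dt = 1.0 / rate_hz
    tp = tau_rise_s * math.log(100.0)
    ip = max(2, int(round(tp / dt)))  # samples from onset to peak
    ntot = int(round(total_s / dt))
    if ntot <= ip + 2:
        raise ValueError("transient interval too short for the rise time")
    t_rise = np.arange(ip + 1) * dt
    rise = amp * (1.0 - np.exp(-t_rise / tau_rise_s)) / (1.0 - np.exp(-(ip * dt) / tau_rise_s))
    t_dec = np.arange(1, ntot - ip) * dt
    span = (ntot - ip - 1) * dt
    e_end = math.exp(-span / tau_decay_s)
    decay = amp * (np.exp(-t_dec / tau_decay_s) - e_end) / (1.0 - e_end)
    return np.concatenate([rise, decay]), ip


def ca_analytic_rates(amp: float, tau_rise_s: float, tau_decay_s: float,
                      interval_s: float, rate_hz: float = 100.0) -> tuple[float, float]:
    """Closed-form maximal rise and decay rates of the generated transient.

    Rise: d/dt of the normalized rise at onset; decay: magnitude of d/dt of
    the end-anchored decay at the peak.  Both in ratio-units per second.
    """
    dt = 1.0 / rate_hz
    ip = max(2, int(round(tau_rise_s * math.log(100.0) / dt)))
    ntot = int(round(interval_s / dt))
    rise_max = amp / (tau_rise_s * (1.0 - math.exp(-(ip * dt) / tau_rise_s)))
    span = (ntot - ip - 1) * dt
    e_end = math.exp(-span / tau_decay_s)
    decay_max = amp / (tau_decay_s * (1.0 - e_end))
    return rise_max, decay_max


def gen_ca_trace(n_transients: int = 30,
                 ibi_s: float = 1.0,
                 baseline: float = 1.0,
                 amp: float = 0.8,
                 tau_rise_s: float = 0.05,
                 tau_decay_s: float = 0.2,
                 noise_frac: float = 0.02,
                 rate_hz: float = 100.0,
                 caffeine: CaffeineSpec | None = None,
                 seed: int = 0) -> tuple[VoltageTrace, GroundTruth]:
    """Fluorescence-ratio Ca2+ transient train, optionally with a caffeine
    bolus (abrupt large transient, quiescent gap, then resumed transients)."""
    rng = np.random.default_rng(seed)
    dt = 1.0 / rate_hz
    onsets = [0.5 + k * ibi_s for k in range(n_transients)]
    kernel, ip = _ca_kernel(amp, tau_rise_s, tau_decay_s, ibi_s, rate_hz)

    events: list[tuple[float, float, float, float, float]] = []  # onset, amp, taur, taud, interval
    truth = GroundTruth()
    if caffeine is None:
        for on in onsets:
            events.append((on, amp, tau_rise_s, tau_decay_s, ibi_s))
    else:
        if not 0 < caffeine.time_s < onsets[-1]:
            raise ValueError("caffeine_time_s must fall inside the transient train")
        pre = [on for on in onsets if on + ip * dt < caffeine.time_s]
        if len(pre) < 3:
            raise ValueError("need >= 3 pre-caffeine transients")
        for on in pre:
            events.append((on, amp, tau_rise_s, tau_decay_s, ibi_s))
        caf_amp = caffeine.f_caf * amp
        caf_taud = tau_decay_s * caffeine.tau_decay_factor
        caf_on = max(caffeine.time_s, pre[-1] + ibi_s)
        tp_caf = max(2, int(round(tau_rise_s * math.log(100.0) / dt))) * dt
        caf_peak = caf_on + tp_caf
        caf_interval = caffeine.gap_s  # decays over the gap
        events.append((caf_on, caf_amp, tau_rise_s, caf_taud, caf_interval))
        resume_peak = caf_peak + caffeine.gap_s
        resume_on = resume_peak - tp_caf
        k = 0
        on = resume_on
        while k < max(6, n_transients - len(pre)):
            events.append((on, amp, tau_rise_s, tau_decay_s, ibi_s))
            on += ibi_s
            k += 1
        truth.extra.update(caffeine_onset_s=caf_on, caffeine_peak_s=caf_peak,
                           caffeine_amp=caf_amp, resume_peak_s=resume_peak,
                           gap_s=caffeine.gap_s, f_caf=caffeine.f_caf)

    duration = events[-1][0] + events[-1][4] + 1.0
    n = int(round(duration * rate_hz))
    samples = np.full(n, baseline)
    peak_times = []
    for on, a, taur, taud, interval in events:
        kern, ipk = (kernel, ip) if (a == amp and taud == tau_decay_s and interval == ibi_s) \
            else _ca_kernel(a, taur, taud, interval, rate_hz)
        i0 = int(round(on * rate_hz))
        seg = kern[:min(len(kern), n - i0)]
        samples[i0:i0 + len(seg)] += seg
        peak_times.append((i0 + ipk) * dt)

    if noise_frac > 0:
        samples += _bandlimited_noise(rng, n, rate_hz, noise_frac * baseline,
                                      corner_hz=rate_hz / 3.0)
    trace = VoltageTrace(samples, rate_hz, Modality.CA, units="ratio")
    truth.beat_times_s = np.asarray(peak_times)
    truth.extra.update(amp=amp, baseline=baseline, tau_rise_s=tau_rise_s,
                       tau_decay_s=tau_decay_s, ibi_s=ibi_s)
    return trace, truth


# ---------------------------------------------------------------------------
# cell images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellGeometry:
    """One elliptical cell with a circular nucleus, on a square tile."""

    shape: tuple[int, int] = (192, 192)
    cell_axes: tuple[float, float] = (80.0, 55.0)
    nucleus_radius: float = 26.0
    nucleus_offset: tuple[float, float] = (6.0, -4.0)


def gen_cell_image(nc_ratio: float,
                   geometry: CellGeometry = CellGeometry(),
                   mean_intensity: float = 100.0,
                   nuclear_stain_intensity: float = 400.0,
                   noise_model: str = "gaussian",
                   noise_frac: float = 0.05,
                   seed: int = 0):
    """Two-channel cell image with a prescribed nucleus/cytoplasm density ratio.

    The signal channel has expected per-pixel intensity ``mean_intensity`` on
    the cytoplasm and ``nc_ratio * mean_intensity`` on the nucleus; the
    nuclear channel is nonzero only on the nucleus.  Returns
    ``(CellImagePair, GroundTruth)`` with exact masks in the truth.
    """
    from .imaging import CellImagePair

    if nc_ratio <= 0:
        raise ValueError("nc_ratio must be positive")
    rng = np.random.default_rng(seed)
    h, w = geometry.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    a, b = geometry.cell_axes
    cell = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    ny, nx = cy + geometry.nucleus_offset[1], cx + geometry.nucleus_offset[0]
    nucleus = (xx - nx) ** 2 + (yy - ny) ** 2 <= geometry.nucleus_radius ** 2

    # nucleus must sit strictly inside the cell (a 2-px margin)
    r = geometry.nucleus_radius + 2.0
    margin = ((nx - cx) / (a - 2.0)) ** 2 + ((ny - cy) / (b - 2.0)) ** 2
    if r >= min(a, b) or margin + (r / min(a, b)) ** 2 > 1.0:
        raise ValueError("nucleus not strictly inside the cell")

    rho_c = mean_intensity
    rho_n = nc_ratio * rho_c
    signal = np.zeros((h, w))
    signal[cell] = rho_c
    signal[nucleus] = rho_n
    nuclear = np.zeros((h, w))
    nuclear[nucleus] = nuclear_stain_intensity

    if noise_model == "gaussian":
        if noise_frac > 0:
            signal = signal + rng.normal(0.0, noise_frac * rho_c, size=(h, w))
            nuclear = nuclear + rng.normal(0.0, noise_frac * nuclear_stain_intensity, size=(h, w))
    elif noise_model == "poisson":
        signal = rng.poisson(np.maximum(signal, 0.0)).astype(float)
        nuclear = rng.poisson(np.maximum(nuclear, 0.0)).astype(float)
    else:
        raise ValueError(f"unknown noise model {noise_model!r}")

    pair = CellImagePair(nuclear=nuclear, signal=signal)
    truth = GroundTruth(image_truth={
        "nc_ratio": nc_ratio, "rho_n": rho_n, "rho_c": rho_c,
        "nucleus_mask": nucleus, "cell_mask": cell,
        "cytoplasm_mask": cell & ~nucleus,
    })
    return pair, truth
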