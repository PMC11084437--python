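"""Synthetic-validation suite: end-to-end recovery benchmarks.

Every function generates fresh synthetic data (seeded), runs the analysis
stages on it, and measures agreement with the generator's ground truth or
with an independent oracle.  These are the quantitative checks behind the
package's stated guarantees; they are recomputed at run time, never cached.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .apfeatures import compute_ap_features
from .arrhythmia import (classify_events, detect_subthreshold_events,
                         detect_va_episodes, summarize_arrhythmia)
from .beats import detect_ap_beats, detect_mea_spikes, detect_r_peaks
from .brv import compute_brv, detect_bimodality, poincare_cloud_count
from .calcium import extract_ca_transients
from .core import BeatSeries, EventKind
from .stats import compare_groups
from .synth import (APWaveform, EventSpec, NC_PRESETS, VAEpisodeSpec,
                    ca_analytic_rates, gen_ap_train, gen_ca_trace,
                    gen_cell_image, gen_ecg_beats, gen_ibi_series,
                    gen_mea_trace, render_ecg_trace)

__all__ = [
    "brv_oracle_benchmark",
    "closed_form_benchmark",
    "detection_benchmark",
    "recovery_benchmark",
    "definitional_rules_benchmark",
    "directional_benchmark",
    "calibration_benchmark",
]


def _child_seeds(seed: int, n: int, tag: str) -> list[int]:
    import zlib

    ss = np.random.SeedSequence([seed, zlib.crc32(tag.encode())])
    return [int(s) % (2 ** 31 - 1) for s in ss.generate_state(n)]


# ---------------------------------------------------------------------------

def brv_oracle_benchmark(n_series: int = 100, seed: int = 0) -> dict[str, float]:
    """SD1/SD2/CV vs explicit variance-sum oracles on random IBI series."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    identity_worst = 0.0
    for _ in range(n_series):
        n = int(rng.integers(4, 300))
        ibis = rng.uniform(0.3, 2.0, n)
        beats = BeatSeries(np.concatenate([[0.0], np.cumsum(ibis)]))
        m = compute_brv(beats)

        mean = sum(ibis) / n
        var = sum((x - mean) ** 2 for x in ibis) / (n - 1)
        d = [ibis[i + 1] - ibis[i] for i in range(n - 1)]
        dm = sum(d) / len(d)
        var_d = sum((x - dm) ** 2 for x in d) / (len(d) - 1)
        sd1 = math.sqrt(0.5 * var_d)
        sd2 = math.sqrt(max(2.0 * var - 0.5 * var_d, 0.0))
        cv = 100.0 * math.sqrt(var) / mean

        for got, want in ((m.sd1_s, sd1), (m.sd2_s, sd2), (m.cv_pct, cv)):
            if want > 0:
                worst = max(worst, abs(got - want) / want)
        if m.sd2_s > 0:
            identity_worst = max(
                identity_worst,
                abs(m.sd1_s ** 2 + m.sd2_s ** 2 - 2.0 * var) / (2.0 * var))
    return {"max_rel_err": worst, "identity_max_rel_err": identity_worst,
            "n_series": n_series}


def closed_form_benchmark(seed: int = 0) -> dict[str, float]:
    """Noise-free features vs the generator's construction parameters."""
    wf = APWaveform(mdp_mv=-75.0, peak_mv=30.0, apd90_ms=300.0, upstroke_vps=100.0)
    trace, _ = gen_ap_train(60.0, 20.0, waveform=wf, noise_sd_mv=0.0, seed=seed)
    f = compute_ap_features(trace, detect_ap_beats(trace))
    out = {
        "mdp_abs_err_mv": float(np.max(np.abs(f.mdp_mv - wf.mdp_mv))),
        "peak_abs_err_mv": float(np.max(np.abs(f.peak_mv - wf.peak_mv))),
        "apa_abs_err_mv": float(np.max(np.abs(f.apa_mv - wf.apa_mv))),
        "apd90_abs_err_ms": float(np.max(np.abs(f.apd90_ms - wf.apd90_ms))),
        "dvdt_rel_err_pct": float(100.0 * np.max(
            np.abs(f.dvdt_max_vps - wf.upstroke_vps) / wf.upstroke_vps)),
    }
    # Ca2+: clean 1 kHz trace so the derivative window resolves the corners
    amp, taur, taud, ibi = 0.8, 0.05, 0.2, 1.0
    ca, _ = gen_ca_trace(n_transients=25, ibi_s=ibi, amp=amp, tau_rise_s=taur,
                         tau_decay_s=taud, noise_frac=0.0, rate_hz=1000.0, seed=seed)
    feats = extract_ca_transients(ca)
    rise, decay = ca_analytic_rates(amp, taur, taud, ibi, rate_hz=1000.0)
    out.update({
        "ca_amp_abs_err": float(np.max(np.abs(feats.r_amp - amp))),
        "ca_rise_rel_err_pct": float(100.0 * abs(np.mean(feats.dca_rise_max) - rise) / rise),
        "ca_decay_rel_err_pct": float(100.0 * abs(np.mean(feats.dca_decay_max) - decay) / decay),
    })
    return out


def _match_counts(true_t: np.ndarray, det_t: np.ndarray, tol: float) -> tuple[int, int]:
    """(matched detections, detections) under one-to-one nearest matching."""
    used = np.zeros(true_t.size, dtype=bool)
    matched = 0
    for t in det_t:
        i = int(np.argmin(np.abs(true_t - t))) if true_t.size else -1
        if i >= 0 and not used[i] and abs(true_t[i] - t) <= tol:
            used[i] = True
            matched += 1
    return matched, det_t.size


def detection_benchmark(n_seeds: int = 20, seed: int = 0) -> dict[str, float]:
    """Beat/spike/R recall+precision, event-kind accuracy, VA recovery."""
    kinds = [EventKind.DAD, EventKind.OPP, EventKind.FAILED_BEAT]
    ap_tp = ap_det = ap_true = 0
    mea_tp = mea_det = mea_true = 0
    ecg_tp = ecg_det = ecg_true = 0
    ev_correct = ev_total = 0
    va_boundary_rr = []
    va_frac_err = []

    for k, s in enumerate(_child_seeds(seed, n_seeds, "detection")):
        rng = np.random.default_rng(s)
        # --- intracellular train with injected events, default noise
        slots = np.sort(rng.choice(np.arange(2, 36, 4), size=5, replace=False))
        events = [EventSpec(kinds[(k + j) % 3], int(b)) for j, b in enumerate(slots)]
        trace, truth = gen_ap_train(60.0, 40.0, events=events, seed=s)
        beats = detect_ap_beats(trace)
        m, d = _match_counts(truth.beat_times_s, beats.beat_times_s, 0.05)
        ap_tp += m
        ap_det += d
        ap_true += truth.beat_times_s.size
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cands = detect_subthreshold_events(trace, beats)
            classified = classify_events(cands, beats)
        for kind_true, t_true, _ in truth.injected_events:
            ev_total += 1
            hits = [e for e in classified
                    if e.t_start_s - 0.3 <= t_true <= e.t_end_s + 0.3]
            if hits and hits[0].kind.value == kind_true:
                ev_correct += 1

        # --- MEA
        mtrace, mtruth = gen_mea_trace(n_spikes=120, seed=s)
        spikes = detect_mea_spikes(mtrace)
        m, d = _match_counts(mtruth.beat_times_s, spikes.beat_times_s, 0.02)
        mea_tp += m
        mea_det += d
        mea_true += mtruth.beat_times_s.size

        # --- ECG
        ebeats, etruth = gen_ecg_beats(120.0, seed=s)
        etrace = render_ecg_trace(ebeats, seed=s + 1)
        rdet = detect_r_peaks(etrace)
        m, d = _match_counts(etruth.beat_times_s, rdet.beat_times_s, 0.01)
        ecg_tp += m
        ecg_det += d
        ecg_true += etruth.beat_times_s.size

        # --- whole-heart VA
        t0 = float(rng.uniform(600.0, 3600.0))
        dur = float(rng.uniform(60.0, 400.0))
        hbeats, htruth = gen_ecg_beats(5400.0, va_episodes=[VAEpisodeSpec(t0, dur)],
                                       seed=s + 2)
        rep = detect_va_episodes(hbeats, recording_duration_s=5400.0)
        med_rr = float(np.median(hbeats.ibis_s))
        if rep.episodes:
            (d0, d1) = max(rep.episodes, key=lambda e: e[1] - e[0])
            va_boundary_rr.append(max(abs(d0 - t0), abs(d1 - (t0 + dur))) / med_rr)
        else:
            va_boundary_rr.append(float("inf"))
        true_frac = 100.0 * dur / 5400.0
        va_frac_err.append(abs(rep.fractional_duration_pct - true_frac))

    return {
        "ap_recall": ap_tp / ap_true, "ap_precision": ap_tp / ap_det,
        "mea_recall": mea_tp / mea_true, "mea_precision": mea_tp / mea_det,
        "ecg_recall": ecg_tp / ecg_true, "ecg_precision": ecg_tp / ecg_det,
        "event_kind_accuracy": ev_correct / ev_total,
        "va_boundary_err_median_rr": float(np.max(va_boundary_rr)),
        "va_fractional_err_pct_points": float(np.max(va_frac_err)),
        "n_seeds": n_seeds,
    }


def recovery_benchmark(n_seeds: int = 20, seed: int = 0) -> dict[str, float]:
    """N/C-preset and IBI-mode parameter recovery; bimodality specificity."""
    from .imaging import measure_nc_ratio, segment_cell

    nc_err = 0.0
    for preset, s0 in zip(NC_PRESETS.values(), _child_seeds(seed, 4, "nc")):
        vals = []
        for s in _child_seeds(s0, 5, "cells"):
            pair, _ = gen_cell_image(preset, noise_frac=0.05, seed=s)
            masks = segment_cell(pair, nuc_threshold=100.0, cell_threshold=30.0)
            vals.append(measure_nc_ratio(pair, masks).nc_ratio)
        nc_err = max(nc_err, abs(float(np.mean(vals)) - preset) / preset)

    mode_err = 0.0
    missed_bimodal = 0
    false_bimodal = 0
    for s in _child_seeds(seed, n_seeds, "modes"):
        series = gen_ibi_series("bimodal", (0.8, 1.6), 0.03, 400, seed=s)
        bimodal, modes = detect_bimodality(series)
        if not bimodal:
            missed_bimodal += 1
        else:
            mode_err = max(mode_err, abs(modes[0] - 0.8) / 0.8,
                           abs(modes[1] - 1.6) / 1.6)
        uni = gen_ibi_series("unimodal", 0.9, 0.03, 400, seed=s + 1)
        if detect_bimodality(uni)[0]:
            false_bimodal += 1

    return {"nc_max_rel_err_pct": 100.0 * nc_err,
            "ibi_mode_max_rel_err_pct": 100.0 * mode_err,
            "bimodal_missed": missed_bimodal,
            "bimodal_false_positives": false_bimodal,
            "n_seeds": n_seeds}


def definitional_rules_benchmark() -> dict[str, float]:
    """Exact outputs of the counting rules on constructed inputs."""
    from .core import ArrhythmiaEvent

    ev = lambda k: ArrhythmiaEvent(EventKind.DAD, float(k), k + 0.1, (5.0,))
    s6 = summarize_arrhythmia([ev(k) for k in range(6)], 180.0)
    s2 = summarize_arrhythmia([ev(k) for k in range(2)], 60.0)
    s3 = summarize_arrhythmia([ev(k) for k in range(3)], 60.0)

    n_fast = int(math.ceil(31.0 / 0.08))  # > 30 s of fast beating
    rr = np.concatenate([np.full(400, 0.2), np.full(n_fast, 0.08), np.full(400, 0.2)])
    beats = BeatSeries(np.concatenate([[0.0], np.cumsum(rr)]))
    rep_long = detect_va_episodes(beats, recording_duration_s=float(beats.beat_times_s[-1]))
    rr_short = np.concatenate([np.full(400, 0.2), np.full(int(20 / 0.08), 0.08),
                               np.full(400, 0.2)])
    beats_short = BeatSeries(np.concatenate([[0.0], np.cumsum(rr_short)]))
    rep_short = detect_va_episodes(beats_short,
                                   recording_duration_s=float(beats_short.beat_times_s[-1]))
    return {
        "occurrence_6_events_180s_per_min": s6.occurrence_per_min,
        "six_events_is_arrhythmogenic": float(s6.is_arrhythmogenic),
        "two_events_is_arrhythmogenic": float(s2.is_arrhythmogenic),
        "three_events_is_arrhythmogenic": float(s3.is_arrhythmogenic),
        "va_31s_sustained": float(rep_long.any_sustained_va),
        "va_20s_sustained": float(rep_short.any_sustained_va),
        "va_20s_detected": float(len(rep_short.episodes) >= 1),
    }


def directional_benchmark(n_seeds: int = 20, seed: int = 0) -> dict[str, float]:
    """Figure-level directional claims, required to hold on every seed."""
    ok_brv = ok_ca = ok_heart = 0
    for s in _child_seeds(seed, n_seeds, "directional"):
        uni = gen_ibi_series("unimodal", 1.0, 0.025, 300, seed=s)
        bim = gen_ibi_series("bimodal", (0.8, 1.6), 0.03, 300, seed=s + 1)
        mu, mb = compute_brv(uni), compute_brv(bim)
        if (mb.cv_pct > mu.cv_pct and mb.sd2_s > mu.sd2_s and mb.bimodal
                and not mu.bimodal and poincare_cloud_count(bim) > 1
                and poincare_cloud_count(uni) == 1):
            ok_brv += 1

        ctrl, _ = gen_ca_trace(n_transients=22, amp=0.8, tau_rise_s=0.05,
                               tau_decay_s=0.2, seed=s)
        slow, _ = gen_ca_trace(n_transients=22, amp=0.5, tau_rise_s=0.08,
                               tau_decay_s=0.35, seed=s + 1)
        fc, fs_ = extract_ca_transients(ctrl), extract_ca_transients(slow)
        if (np.mean(fs_.r_amp) < np.mean(fc.r_amp)
                and np.mean(fs_.dca_rise_max) < np.mean(fc.dca_rise_max)
                and np.mean(fs_.dca_decay_max) < np.mean(fc.dca_decay_max)):
            ok_ca += 1

        aa, _ = gen_ecg_beats(5400.0, va_episodes=[VAEpisodeSpec(1200.0, 60.0)],
                              seed=s + 2)
        ywf, _ = gen_ecg_beats(5400.0, va_episodes=[VAEpisodeSpec(900.0, 150.0),
                                                    VAEpisodeSpec(3000.0, 180.0)],
                               seed=s + 3)
        f_aa = detect_va_episodes(aa, recording_duration_s=5400.0).fractional_duration_pct
        f_ywf = detect_va_episodes(ywf, recording_duration_s=5400.0).fractional_duration_pct
        if f_ywf > f_aa:
            ok_heart += 1

    return {"brv_direction_ok": ok_brv, "calcium_direction_ok": ok_ca,
            "heart_direction_ok": ok_heart, "n_seeds": n_seeds}


def calibration_benchmark(n_sims: int = 5000, n_per_group: int = 30,
                          seed: int = 0) -> dict[str, float]:
    """Empirical type-I error of the comparison tree under the global null."""
    import pandas as pd

    from .core import CohortTable

    rng = np.random.default_rng(seed)
    groups = ("a", "b", "c")
    labels = np.repeat(groups, n_per_group)
    rejections = 0
    for _ in range(n_sims):
        df = pd.DataFrame({"group": labels,
                           "x": rng.normal(0.0, 1.0, 3 * n_per_group)})
        c = compare_groups(CohortTable(df, groups), "x", post_hoc=False)
        rejections += c.p_value < 0.05
    return {"type1_error_rate": rejections / n_sims, "n_sims": n_sims}
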