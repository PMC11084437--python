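"""Subthreshold event taxonomy, cohort metrics, pacing response, VA episodes."""

import numpy as np
import pandas as pd
import pytest

from cmephys.apfeatures import paced_epochs
from cmephys.arrhythmia import (classify_events, detect_subthreshold_events,
                                detect_va_episodes, percent_arrhythmogenic,
                                score_pacing_response, summarize_arrhythmia)
from cmephys.beats import detect_ap_beats
from cmephys.core import ArrhythmiaEvent, BeatSeries, CohortTable, EventKind
from cmephys.synth import (EventSpec, VAEpisodeSpec, gen_ap_train, gen_ecg_beats,
                           gen_paced_recording)


def _detect(trace):
    beats = detect_ap_beats(trace)
    return beats, detect_subthreshold_events(trace, beats)


class TestDetection:
    def test_regular_train_has_no_candidates(self, clean_ap_train):
        trace, _ = clean_ap_train
        _, cands = _detect(trace)
        assert cands == []

    def test_single_dad_candidate_at_injected_time(self):
        ev = EventSpec(EventKind.DAD, 5, amplitude_mv=10.0, n_oscillations=1)
        trace, truth = gen_ap_train(60, 20, events=[ev], noise_sd_mv=0.0, seed=1)
        _, cands = _detect(trace)
        assert len(cands) == 1
        (_, t_true, _), = truth.injected_events
        assert abs(cands[0].time_s - t_true) < 0.005
        # prominence is measured against the enclosing diastole, which still
        # carries the repolarization tail, so it reads slightly low
        assert cands[0].amplitude_mv == pytest.approx(10.0, rel=0.2)

    def test_opp_run_gives_grouped_candidates(self):
        ev = EventSpec(EventKind.OPP, 10, n_oscillations=4)
        trace, _ = gen_ap_train(60, 20, events=[ev], noise_sd_mv=0.0, seed=2)
        _, cands = _detect(trace)
        assert len(cands) == 4
        assert len({c.diastole_index for c in cands}) == 1

    def test_needs_two_beats(self):
        trace, _ = gen_ap_train(60, 20, noise_sd_mv=0.0, seed=1)
        with pytest.raises(ValueError, match="2 beats"):
            detect_subthreshold_events(trace, BeatSeries(np.array([1.0])))


class TestClassification:
    @pytest.mark.parametrize("spec,expected", [
        (EventSpec(EventKind.DAD, 5, n_oscillations=2), EventKind.DAD),
        (EventSpec(EventKind.FAILED_BEAT, 7), EventKind.FAILED_BEAT),
        (EventSpec(EventKind.OPP, 9, n_oscillations=4), EventKind.OPP),
    ])
    def test_injected_kind_recovered(self, spec, expected):
        trace, _ = gen_ap_train(60, 20, events=[spec], noise_sd_mv=0.0, seed=3)
        beats, cands = _detect(trace)
        events = classify_events(cands, beats)
        assert [e.kind for e in events] == [expected]

    def test_failed_beat_doubles_enclosing_ibi(self):
        trace, _ = gen_ap_train(60, 30, events=[EventSpec(EventKind.FAILED_BEAT, 10)],
                                noise_sd_mv=0.0, seed=4)
        beats, cands = _detect(trace)
        (event,) = classify_events(cands, beats)
        assert event.kind is EventKind.FAILED_BEAT
        k = np.searchsorted(beats.beat_times_s, event.t_start_s)
        enclosing = beats.beat_times_s[k] - beats.beat_times_s[k - 1]
        assert enclosing == pytest.approx(2.0, abs=0.01)

    def test_classification_exhaustive_never_drops(self):
        events = [EventSpec(EventKind.DAD, 4), EventSpec(EventKind.OPP, 8),
                  EventSpec(EventKind.FAILED_BEAT, 12), EventSpec(EventKind.DAD, 16)]
        trace, truth = gen_ap_train(60, 25, events=events, noise_sd_mv=0.0, seed=5)
        beats, cands = _detect(trace)
        classified = classify_events(cands, beats)
        # every candidate run appears exactly once; kinds match truth order
        assert [e.kind.value for e in classified] == [k for k, _, _ in truth.injected_events]


class TestSummary:
    def test_zero_events(self):
        s = summarize_arrhythmia([], 60.0)
        assert s.occurrence_per_min == 0.0 and not s.is_arrhythmogenic

    def test_occurrence_arithmetic(self):
        evs = [ArrhythmiaEvent(EventKind.DAD, float(k), k + 0.1, (5.0,)) for k in range(6)]
        s = summarize_arrhythmia(evs, 180.0)
        assert s.occurrence_per_min == pytest.approx(2.0)
        assert s.is_arrhythmogenic

    def test_two_events_below_rule(self):
        evs = [ArrhythmiaEvent(EventKind.DAD, float(k), k + 0.1, (5.0,)) for k in range(2)]
        assert not summarize_arrhythmia(evs, 37.0).is_arrhythmogenic

    def test_occurrence_inverse_in_duration(self):
        evs = [ArrhythmiaEvent(EventKind.DAD, float(k), k + 0.1, (5.0,)) for k in range(4)]
        a = summarize_arrhythmia(evs, 60.0).occurrence_per_min
        b = summarize_arrhythmia(evs, 120.0).occurrence_per_min
        assert a == pytest.approx(2.0 * b)

    def test_negative_duration_is_error(self):
        with pytest.raises(ValueError):
            summarize_arrhythmia([], -1.0)


class TestPercentArrhythmogenic:
    @pytest.mark.parametrize("flags,expected", [
        ([True] * 3 + [False] * 5, 37.5),
        ([False] * 6, 0.0),
        ([True] * 26 + [False] * 11, 70.3),  # 26/37, to 1 decimal place
    ])
    def test_percentages(self, flags, expected):
        df = pd.DataFrame({"group": "g", "is_arrhythmogenic": flags})
        out = percent_arrhythmogenic(CohortTable(df, ("g",)))
        assert round(float(out["percent_arrhythmogenic"][0]), 1) == expected
        assert int(out["n"][0]) == len(flags)

    def test_empty_group_missing_with_warning(self):
        df = pd.DataFrame({"group": ["a"], "is_arrhythmogenic": [True]})
        with pytest.warns(UserWarning, match="empty"):
            out = percent_arrhythmogenic(CohortTable(df, ("a", "b")))
        assert np.isnan(out.set_index("group").loc["b", "percent_arrhythmogenic"])


class TestPacingResponse:
    def _run(self, pause_events):
        trace, stim, _ = gen_paced_recording(pause_events=pause_events,
                                             rate_hz=5000.0, seed=11)
        beats = detect_ap_beats(trace)
        return score_pacing_response(trace, beats, paced_epochs(stim))

    def test_quiet_pauses_not_flagged(self):
        assert self._run({}) == {0.5: False, 1.0: False, 1.5: False, 2.0: False}

    def test_dad_in_pause_flags_that_rate_only(self):
        assert self._run({1.5: "dad"}) == {0.5: False, 1.0: False, 1.5: True, 2.0: False}

    def test_cessation_flags_that_rate(self):
        flags = self._run({2.0: "cessation"})
        assert flags[2.0] and not any(flags[r] for r in (0.5, 1.0, 1.5))

    def test_overlapping_epochs_rejected(self):
        trace, stim, _ = gen_paced_recording(rate_hz=5000.0, seed=11)
        beats = detect_ap_beats(trace)
        epochs = paced_epochs(stim)
        bad = epochs + [epochs[0]]
        with pytest.raises(ValueError, match="overlap"):
            score_pacing_response(trace, beats, bad)


class TestVAEpisodes:
    def test_pure_sinus_has_no_episodes(self):
        beats, _ = gen_ecg_beats(90 * 60.0, seed=1)
        rep = detect_va_episodes(beats, recording_duration_s=90 * 60.0)
        assert rep.episodes == [] and rep.fractional_duration_pct == 0.0

    def test_injected_six_minute_episode(self):
        beats, truth = gen_ecg_beats(90 * 60.0,
                                     va_episodes=[VAEpisodeSpec(1200.0, 360.0)], seed=2)
        rep = detect_va_episodes(beats, recording_duration_s=90 * 60.0)
        assert len(rep.episodes) == 1
        assert rep.any_sustained_va
        med_rr = float(np.median(beats.ibis_s))
        (t0, t1), = rep.episodes
        assert abs(t0 - 1200.0) <= 2 * med_rr and abs(t1 - 1560.0) <= 2 * med_rr
        assert rep.fractional_duration_pct == pytest.approx(100 * 360 / 5400.0, abs=0.1)

    def test_short_episode_detected_but_not_sustained(self):
        beats, _ = gen_ecg_beats(10 * 60.0,
                                 va_episodes=[VAEpisodeSpec(300.0, 20.0)], seed=3)
        rep = detect_va_episodes(beats, recording_duration_s=600.0)
        assert len(rep.episodes) == 1
        assert not rep.any_sustained_va

    def test_baseline_window_longer_than_recording_is_error(self):
        beats, _ = gen_ecg_beats(120.0, seed=4)
        with pytest.raises(ValueError, match="baseline"):
            detect_va_episodes(beats, baseline_window_s=500.0, recording_duration_s=120.0)
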