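"""Generator determinism, label completeness, and closed-form waveform checks."""

import numpy as np
import pytest

from cmephys.apfeatures import compute_ap_features
from cmephys.beats import detect_ap_beats
from cmephys.core import EventKind, Modality
from cmephys.synth import (APWaveform, CaffeineSpec, EventSpec, NC_PRESETS,
                           VAEpisodeSpec, gen_ap_train, gen_ca_trace,
                           gen_cell_image, gen_ecg_beats, gen_ibi_series,
                           gen_mea_trace)


class TestAPTrain:
    def test_beat_count_and_empty_truth(self, clean_ap_train):
        trace, truth = clean_ap_train
        assert truth.beat_times_s.size == 60
        assert truth.injected_events == []
        assert trace.rate_hz == 10_000.0 and trace.modality is Modality.AP

    def test_failed_beat_bookkeeping(self):
        _, truth = gen_ap_train(60, 60, events=[EventSpec(EventKind.FAILED_BEAT, 5)],
                                noise_sd_mv=0.0, seed=1)
        assert truth.beat_times_s.size == 59
        kinds = [k for k, _, _ in truth.injected_events]
        assert kinds == ["failed_beat"]

    def test_apd90_matches_request_on_clean_trace(self):
        wf = APWaveform(apd90_ms=300.0)
        trace, _ = gen_ap_train(60, 10, waveform=wf, noise_sd_mv=0.0, seed=1)
        f = compute_ap_features(trace, detect_ap_beats(trace))
        assert np.all(np.abs(f.apd90_ms - 300.0) <= 1000.0 / trace.rate_hz)

    def test_apd90_too_long_for_rate_is_error(self):
        with pytest.raises(ValueError, match="apd90"):
            gen_ap_train(120, 10, waveform=APWaveform(apd90_ms=600.0))

    def test_colliding_event_is_error(self):
        # a DAD cannot fit between a 550 ms APD and the next beat at 100 BPM
        wf = APWaveform(apd90_ms=550.0)
        with pytest.raises(ValueError, match="collides"):
            gen_ap_train(100, 10, waveform=wf,
                         events=[EventSpec(EventKind.DAD, 3, n_oscillations=3)],
                         noise_sd_mv=0.0, seed=1)

    def test_determinism(self):
        a, _ = gen_ap_train(60, 5, seed=7)
        b, _ = gen_ap_train(60, 5, seed=7)
        assert np.array_equal(a.samples, b.samples)

    def test_label_completeness(self):
        events = [EventSpec(EventKind.DAD, 3), EventSpec(EventKind.OPP, 8),
                  EventSpec(EventKind.FAILED_BEAT, 12)]
        _, truth = gen_ap_train(60, 20, events=events, seed=4)
        assert sorted(k for k, _, _ in truth.injected_events) == \
            ["DAD", "OPP", "failed_beat"]


class TestIBISeries:
    def test_unimodal_mean_recovery(self):
        s = gen_ibi_series("unimodal", 0.6, 0.02, 500, seed=3)
        assert np.mean(s.ibis_s) == pytest.approx(0.6, abs=0.01)  # ~3 SE

    def test_bimodal_modes_present(self):
        s = gen_ibi_series("bimodal", (0.8, 1.6), 0.03, 400, seed=7)
        ibis = s.ibis_s
        lo, hi = ibis[ibis < 1.2], ibis[ibis >= 1.2]
        assert np.mean(lo) == pytest.approx(0.8, rel=0.05)
        assert np.mean(hi) == pytest.approx(1.6, rel=0.05)

    def test_degenerate_sd_limit(self):
        s = gen_ibi_series("unimodal", 0.5, 1e-12, 3, seed=0)
        assert np.allclose(s.ibis_s, 0.5)

    @pytest.mark.parametrize("kwargs", [
        dict(mode="unimodal", modes_s=0.6, sd_s=0.0, n=10),
        dict(mode="bimodal", modes_s=(0.8, 0.8), sd_s=0.01, n=10),
        dict(mode="unimodal", modes_s=0.6, sd_s=0.01, n=2),
    ])
    def test_invalid_args(self, kwargs):
        with pytest.raises(ValueError):
            gen_ibi_series(seed=0, **kwargs)

    def test_alternation_bias(self):
        # switch probability 1.0 -> strict alternation between the two modes
        s = gen_ibi_series("bimodal", (0.8, 1.6), 0.01, 200, seed=5, switch_prob=1.0)
        states = (s.ibis_s > 1.2).astype(int)
        assert np.all(np.abs(np.diff(states)) == 1)


class TestOtherModalities:
    def test_ecg_va_episode_duration(self):
        _, truth = gen_ecg_beats(90 * 60.0, va_episodes=[VAEpisodeSpec(1000.0, 360.0)],
                                 seed=1)
        assert sum(t1 - t0 for t0, t1 in truth.va_episodes) == pytest.approx(360.0)

    def test_ecg_episode_outside_recording_is_error(self):
        with pytest.raises(ValueError, match="outside"):
            gen_ecg_beats(100.0, va_episodes=[VAEpisodeSpec(80.0, 40.0)], seed=1)

    def test_caffeine_amplitude_factor(self):
        spec = CaffeineSpec(time_s=12.0, f_caf=2.0)
        _, truth = gen_ca_trace(amp=0.8, caffeine=spec, noise_frac=0.0, seed=1)
        assert truth.extra["caffeine_amp"] == pytest.approx(1.6)

    def test_mea_determinism_and_truth(self):
        t1, tr1 = gen_mea_trace(n_spikes=30, seed=5)
        t2, tr2 = gen_mea_trace(n_spikes=30, seed=5)
        assert np.array_equal(t1.samples, t2.samples)
        assert tr1.beat_times_s.size == 30


class TestCellImage:
    def test_noise_free_ratio_exact(self):
        pair, truth = gen_cell_image(1.0, noise_frac=0.0, seed=0)
        it = truth.image_truth
        nuc, cyt = it["nucleus_mask"], it["cytoplasm_mask"]
        dn = pair.signal[nuc].sum() / nuc.sum()
        dc = pair.signal[cyt].sum() / cyt.sum()
        assert dn / dc == pytest.approx(1.0)

    def test_preset_metadata(self):
        assert NC_PRESETS["control"] == 1.30
        pair, truth = gen_cell_image(NC_PRESETS["control"], noise_frac=0.0, seed=0)
        assert truth.image_truth["nc_ratio"] == 1.30

    def test_nucleus_outside_cell_is_error(self):
        from cmephys.synth import CellGeometry

        with pytest.raises(ValueError, match="nucleus"):
            gen_cell_image(1.0, geometry=CellGeometry(nucleus_offset=(70.0, 0.0)), seed=0)

    def test_invalid_ratio(self):
        with pytest.raises(ValueError):
            gen_cell_image(-1.0, seed=0)
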