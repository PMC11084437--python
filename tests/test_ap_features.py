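"""Action-potential feature measurement: constructed cases and invariances."""

import numpy as np
import pytest

from cmephys.apfeatures import (PacingProtocol, compute_ap_features,
                                paced_epochs)
from cmephys.beats import detect_ap_beats
from cmephys.core import BeatSeries, Modality, VoltageTrace
from cmephys.synth import APWaveform, gen_ap_train


def _square_ap_trace(n_beats=3, mdp=-80.0, peak=40.0, hold_s=0.2, ibi=1.0, fs=10_000.0):
    """Idealized square APs: instant rise, hold at peak, instant return."""
    n = int(n_beats * ibi * fs)
    v = np.full(n, mdp)
    for k in range(n_beats):
        i0 = int((0.3 + k * ibi) * fs)
        v[i0:i0 + int(hold_s * fs)] = peak
    return VoltageTrace(v, fs, Modality.AP)


class TestComputeAPFeatures:
    def test_amplitude_arithmetic(self):
        trace = _square_ap_trace()
        f = compute_ap_features(trace, detect_ap_beats(trace))
        assert np.allclose(f.mdp_mv, -80.0)
        assert np.allclose(f.peak_mv, 40.0)
        assert np.allclose(f.apa_mv, 120.0)

    def test_square_ap_apd90(self):
        trace = _square_ap_trace(hold_s=0.2)
        f = compute_ap_features(trace, detect_ap_beats(trace))
        # instant return: the 90% crossing is the fall edge, 200 ms after rise
        assert np.all(np.abs(f.apd90_ms - 200.0) <= 2 * 1000.0 / trace.rate_hz)

    def test_dvdt_max_matches_constructed_slope(self):
        wf = APWaveform(upstroke_vps=100.0)
        trace, _ = gen_ap_train(60, 10, waveform=wf, noise_sd_mv=0.0, seed=1)
        f = compute_ap_features(trace, detect_ap_beats(trace))
        assert np.all(np.abs(f.dvdt_max_vps - 100.0) <= 2.0)

    def test_beat_rate_from_ibis(self, clean_ap_train, clean_ap_beats):
        trace, _ = clean_ap_train
        f = compute_ap_features(trace, clean_ap_beats)
        ibis = clean_ap_beats.ibis_s
        assert f.beat_rate_bpm == pytest.approx(60.0 * ibis.size / ibis.sum())

    def test_translation_invariance(self):
        trace, _ = gen_ap_train(60, 6, noise_sd_mv=0.0, seed=2)
        shifted = VoltageTrace(trace.samples, trace.rate_hz, Modality.AP, t0_s=10.0)
        f0 = compute_ap_features(trace, detect_ap_beats(trace))
        f1 = compute_ap_features(shifted, detect_ap_beats(shifted))
        assert np.allclose(f1.beat_times_s - f0.beat_times_s, 10.0)
        for name in ("mdp_mv", "peak_mv", "apa_mv", "dvdt_max_vps", "apd90_ms"):
            assert np.allclose(getattr(f0, name), getattr(f1, name), equal_nan=True)

    def test_apd90_scales_with_repolarization_stretch(self):
        out = {}
        for apd in (200.0, 400.0):
            trace, _ = gen_ap_train(60, 8, waveform=APWaveform(apd90_ms=apd),
                                    noise_sd_mv=0.0, seed=3)
            f = compute_ap_features(trace, detect_ap_beats(trace))
            out[apd] = np.nanmean(f.apd90_ms)
        dt_ms = 0.1
        assert out[400.0] == pytest.approx(2.0 * out[200.0], abs=2 * dt_ms)

    def test_unreached_repolarization_flagged_missing(self):
        # hold longer than the beat interval margin: last-90% never crossed
        trace = _square_ap_trace(n_beats=2, hold_s=0.9, ibi=1.0)
        beats = detect_ap_beats(trace)
        with pytest.warns(UserWarning, match="90%"):
            f = compute_ap_features(trace, beats)
        assert np.isnan(f.apd90_ms[-1])

    def test_needs_two_beats(self):
        trace = _square_ap_trace(n_beats=1)
        with pytest.raises(ValueError, match="2 beats"):
            compute_ap_features(trace, BeatSeries(np.array([0.35]), Modality.AP))


class TestPacedEpochs:
    @staticmethod
    def _stims():
        t, out = 0.0, []
        for r in (0.5, 1.0, 1.5, 2.0):
            for _ in range(20):
                out.append(t)
                t += 1.0 / r
            t += 20.0 - 1.0 / r  # 20 s pause after the train's last interval
        return out

    def test_canonical_protocol_windows(self):
        epochs = paced_epochs(self._stims())
        assert len(epochs) == 8
        trains = [e for e in epochs if e.label == "train"]
        pauses = [e for e in epochs if e.label == "pause"]
        assert [e.rate_hz for e in trains] == [0.5, 1.0, 1.5, 2.0]
        assert trains[0].t_start_s == 0.0
        assert trains[0].t_end_s == pytest.approx(40.0)   # 20 pulses at 0.5 Hz
        assert pauses[0].t_end_s == pytest.approx(60.0)
        for tr, pa in zip(trains, pauses):
            assert pa.t_start_s == pytest.approx(tr.t_end_s)
            assert pa.t_end_s - pa.t_start_s == pytest.approx(20.0)

    def test_empty_stimulus_list(self):
        assert paced_epochs([]) == []

    def test_wrong_pulse_count_is_error(self):
        with pytest.raises(ValueError, match="80"):
            paced_epochs(self._stims()[:-1])

    def test_wrong_intervals_is_error(self):
        stims = self._stims()
        stims[5] += 0.5  # corrupt one interval in the 0.5 Hz train
        with pytest.raises(ValueError, match="inconsistent"):
            paced_epochs(stims)
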