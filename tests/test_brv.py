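"""Poincaré SD1/SD2 against a brute-force oracle, and bimodality detection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmephys.brv import compute_brv, detect_bimodality, poincare_cloud_count
from cmephys.core import BeatSeries
from cmephys.synth import gen_ibi_series


def sd1_sd2_bruteforce(ibis):
    """Independent oracle: explicit variance sums with plain Python loops."""
    n = len(ibis)
    mean = sum(ibis) / n
    var = sum((x - mean) ** 2 for x in ibis) / (n - 1)
    d = [ibis[i + 1] - ibis[i] for i in range(n - 1)]
    dmean = sum(d) / len(d)
    var_d = sum((x - dmean) ** 2 for x in d) / (len(d) - 1)
    sd1_sq = 0.5 * var_d
    sd2_sq = max(2.0 * var - sd1_sq, 0.0)
    return math.sqrt(sd1_sq), math.sqrt(sd2_sq), 100.0 * math.sqrt(var) / mean


def _beats_from_ibis(ibis):
    return BeatSeries(np.concatenate([[0.0], np.cumsum(ibis)]))


class TestOracle:
    def test_matches_bruteforce_on_random_series(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 200))
            ibis = rng.uniform(0.3, 2.0, n)
            m = compute_brv(_beats_from_ibis(ibis))
            sd1, sd2, cv = sd1_sd2_bruteforce(list(ibis))
            assert m.sd1_s == pytest.approx(sd1, rel=1e-12)
            assert m.sd2_s == pytest.approx(sd2, rel=1e-12)
            assert m.cv_pct == pytest.approx(cv, rel=1e-12)
            # identity: sd1^2 + sd2^2 = 2 Var(IBI), unless the floor at
            # sd2 = 0 engaged (strongly anti-correlated short series)
            if m.sd2_s > 0:
                assert m.sd1_s ** 2 + m.sd2_s ** 2 == \
                    pytest.approx(2.0 * np.var(ibis, ddof=1), rel=1e-12)
            else:
                assert m.sd1_s ** 2 >= 2.0 * np.var(ibis, ddof=1)

    def test_sd1_equals_rotated_coordinate_sd(self, rng):
        # geometric route: SD1 is the sample SD of the anti-identity projection
        ibis = rng.uniform(0.5, 1.5, 300)
        m = compute_brv(_beats_from_ibis(ibis))
        v = (ibis[1:] - ibis[:-1]) / np.sqrt(2.0)
        assert m.sd1_s == pytest.approx(float(np.std(v, ddof=1)), rel=1e-12)


class TestClosedForms:
    def test_constant_ibis(self):
        m = compute_brv(_beats_from_ibis(np.full(50, 1.0)))
        assert m.cv_pct == 0.0 and m.sd1_s == 0.0 and m.sd2_s == 0.0
        assert not m.bimodal

    def test_perfect_alternation(self):
        ibis = np.tile([0.5, 0.7], 100)
        m = compute_brv(_beats_from_ibis(ibis))
        # SD1 = |delta| / sqrt(2) = 0.2 / sqrt(2)
        assert m.sd1_s == pytest.approx(0.2 / np.sqrt(2.0), rel=0.01)
        assert m.sd2_s < 0.01
        assert m.cv_pct == pytest.approx(100.0 * np.std(ibis, ddof=1) / 0.6, rel=1e-12)
        assert m.cv_pct == pytest.approx(16.7, abs=0.1)

    def test_iid_series_sd1_equals_sd2(self, rng):
        ibis = np.random.default_rng(9).normal(0.6, 0.05, 1000)
        m = compute_brv(_beats_from_ibis(ibis))
        assert m.sd1_s == pytest.approx(0.05, rel=0.10)
        assert m.sd2_s == pytest.approx(0.05, rel=0.10)

    def test_too_few_beats_is_error(self):
        with pytest.raises(ValueError, match="4 beats"):
            compute_brv(BeatSeries(np.array([0.0, 1.0, 2.0])))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.floats(0.5, 3.0))
def test_time_rescaling_property(seed, c):
    """Scaling all IBIs by c scales mean/SD1/SD2 by c; CV is invariant."""
    r = np.random.default_rng(seed)
    ibis = r.uniform(0.4, 1.6, 60)
    m0 = compute_brv(_beats_from_ibis(ibis))
    m1 = compute_brv(_beats_from_ibis(c * ibis))
    assert m1.mean_ibi_s == pytest.approx(c * m0.mean_ibi_s, rel=1e-9)
    assert m1.sd1_s == pytest.approx(c * m0.sd1_s, rel=1e-9)
    assert m1.sd2_s == pytest.approx(c * m0.sd2_s, rel=1e-9)
    assert m1.cv_pct == pytest.approx(m0.cv_pct, rel=1e-9)


class TestBimodality:
    def test_bimodal_process_recovered(self):
        s = gen_ibi_series("bimodal", (0.8, 1.6), 0.03, 400, seed=7)
        bimodal, modes = detect_bimodality(s)
        assert bimodal
        assert modes[0] == pytest.approx(0.8, rel=0.05)
        assert modes[1] == pytest.approx(1.6, rel=0.05)

    def test_unimodal_not_flagged(self):
        s = gen_ibi_series("unimodal", 0.6, 0.02, 400, seed=11)
        bimodal, modes = detect_bimodality(s)
        assert not bimodal
        assert modes[0] == pytest.approx(0.6, rel=0.02)

    def test_constant_ibis_not_bimodal(self):
        bimodal, _ = detect_bimodality(_beats_from_ibis(np.full(100, 0.8)))
        assert not bimodal

    def test_needs_30_ibis(self):
        with pytest.raises(ValueError, match="30"):
            detect_bimodality(_beats_from_ibis(np.full(10, 1.0)))


class TestPoincareClouds:
    def test_constant_series_one_cloud(self):
        assert poincare_cloud_count(_beats_from_ibis(np.full(100, 1.0) +
                                                     np.random.default_rng(0).normal(0, 1e-4, 100))) == 1

    def test_strict_alternation_two_clouds(self):
        # alternation visits only (a,b) and (b,a)
        s = gen_ibi_series("bimodal", (0.8, 1.6), 0.02, 300, seed=5, switch_prob=1.0)
        assert poincare_cloud_count(s) == 2

    def test_half_switching_four_clouds(self):
        s = gen_ibi_series("bimodal", (0.8, 1.6), 0.02, 600, seed=13, switch_prob=0.5)
        assert poincare_cloud_count(s) == 4
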