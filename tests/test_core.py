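"""Domain containers and trace/cohort I/O round trips."""

import numpy as np
import pandas as pd
import pytest

from cmephys.core import (ArrhythmiaEvent, BeatSeries, CohortTable, EventKind,
                          Modality, VoltageTrace, read_results, read_trace,
                          write_results, write_trace)


class TestVoltageTrace:
    def test_invariants(self):
        t = VoltageTrace(np.zeros(10) - 70.0, 10_000.0, Modality.AP)
        assert t.duration_s == pytest.approx(0.001)
        assert t.times()[3] == pytest.approx(3 / 10_000.0)

    @pytest.mark.parametrize("kwargs,match", [
        (dict(samples=np.zeros(10), rate_hz=0.0, modality="ap"), "rate_hz"),
        (dict(samples=np.zeros(1), rate_hz=1.0, modality="ap"), "length"),
        (dict(samples=np.array([0.0, np.nan, 1.0]), rate_hz=1.0, modality="ap"), "index 1"),
    ])
    def test_rejects_invalid(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            VoltageTrace(**kwargs)


class TestBeatSeries:
    def test_ibis_are_differences(self):
        b = BeatSeries(np.array([0.0, 1.0, 2.5]))
        assert np.allclose(b.ibis_s, [1.0, 1.5])

    def test_rejects_non_monotone(self):
        with pytest.raises(ValueError, match="index 1"):
            BeatSeries(np.array([0.0, 2.0, 1.0]))


class TestArrhythmiaEvent:
    def test_opp_requires_increasing_run(self):
        ArrhythmiaEvent(EventKind.OPP, 0.0, 1.0, (1.0, 2.0, 3.0))
        with pytest.raises(ValueError):
            ArrhythmiaEvent(EventKind.OPP, 0.0, 1.0, (1.0, 2.0))
        with pytest.raises(ValueError):
            ArrhythmiaEvent(EventKind.OPP, 0.0, 1.0, (3.0, 2.0, 1.0))

    def test_dad_damped_after_first(self):
        ArrhythmiaEvent(EventKind.DAD, 0.0, 1.0, (5.0,))
        ArrhythmiaEvent(EventKind.DAD, 0.0, 1.0, (2.0, 8.0, 4.0, 2.0))
        with pytest.raises(ValueError):
            ArrhythmiaEvent(EventKind.DAD, 0.0, 1.0, (2.0, 4.0, 8.0))


@pytest.mark.parametrize("fmt,suffix", [("csv", ".csv"), ("tsv", ".tsv"), ("hdf5", ".h5")])
def test_trace_roundtrip_bit_identical(tmp_path, fmt, suffix):
    rng = np.random.default_rng(0)
    trace = VoltageTrace(rng.normal(-70, 5, 1000), 10_000.0, Modality.AP, t0_s=1.25)
    path = tmp_path / f"trace{suffix}"
    write_trace(trace, path, fmt)
    back = read_trace(path, fmt)
    assert np.array_equal(back.samples, trace.samples)
    assert back.rate_hz == trace.rate_hz
    assert back.modality is trace.modality
    assert back.t0_s == trace.t0_s


def test_read_trace_2col_csv(tmp_path):
    path = tmp_path / "t.csv"
    rows = "\n".join(f"{i / 10_000.0},{-70.0 + i % 3}" for i in range(1000))
    path.write_text("# rate_hz=10000\n# units=mV\n# modality=ap\ntime_s,value\n" + rows + "\n")
    t = read_trace(path)
    assert t.rate_hz == 10_000.0 and t.n == 1000


def test_read_trace_missing_rate_is_error(tmp_path):
    path = tmp_path / "t.csv"
    path.write_text("# units=mV\ntime_s,value\n0.0,1.0\n1.0,2.0\n")
    with pytest.raises(ValueError, match="rate_hz"):
        read_trace(path)


def test_read_trace_nan_row_names_index(tmp_path):
    path = tmp_path / "t.csv"
    path.write_text("# rate_hz=100\ntime_s,value\n0.0,1.0\n0.01,nan\n0.02,2.0\n")
    with pytest.raises(ValueError, match="index 1"):
        read_trace(path)


class TestCohortResults:
    def test_summary_mean_and_sample_sd(self, tmp_path):
        table = CohortTable(pd.DataFrame({"group": ["a"] * 3, "x": [1.0, 2.0, 3.0]}), ("a",))
        path = tmp_path / "out.csv"
        write_results(table, path)
        text = path.read_text()
        assert "x: 2 +/- 1" in text  # mean 2.0, sample SD 1.0

    def test_data_block_roundtrip(self, tmp_path):
        df = pd.DataFrame({"group": ["a", "a", "b"], "x": [1.0, 2.0, 3.0]})
        table = CohortTable(df, ("a", "b"))
        path = tmp_path / "out.csv"
        write_results(table, path)
        back = read_results(path, ("a", "b"))
        pd.testing.assert_frame_equal(back.data, df)

    def test_declared_empty_group_is_error(self, tmp_path):
        table = CohortTable(pd.DataFrame({"group": ["a"], "x": [1.0]}), ("a", "b"))
        with pytest.raises(ValueError, match="'b'"):
            write_results(table, tmp_path / "out.csv")

    def test_empty_table_is_error(self, tmp_path):
        table = CohortTable(pd.DataFrame({"group": [], "x": []}), ())
        with pytest.raises(ValueError, match="empty"):
            write_results(table, tmp_path / "out.csv")

    def test_undeclared_group_rejected(self):
        with pytest.raises(ValueError, match="undeclared"):
            CohortTable(pd.DataFrame({"group": ["z"], "x": [1.0]}), ("a",))
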