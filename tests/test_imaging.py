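"""Segmentation exactness, density-ratio arithmetic, and recovery under noise."""

import numpy as np
import pytest

from cmephys.imaging import (CellImagePair, cohort_nc_summary, measure_nc_ratio,
                             segment_cell)
from cmephys.synth import NC_PRESETS, gen_cell_image


class TestSegmentation:
    def test_noise_free_masks_exact(self):
        pair, truth = gen_cell_image(1.3, noise_frac=0.0, seed=0)
        masks = segment_cell(pair, nuc_threshold=100.0, cell_threshold=30.0)
        it = truth.image_truth
        assert np.array_equal(masks.nucleus, it["nucleus_mask"])
        assert np.array_equal(masks.cell, it["cell_mask"])
        assert np.array_equal(masks.cytoplasm, it["cytoplasm_mask"])

    def test_nucleus_area_within_2pct_under_noise(self):
        pair, truth = gen_cell_image(1.3, noise_frac=0.05, seed=7)
        masks = segment_cell(pair, nuc_threshold=100.0, cell_threshold=30.0)
        true_area = truth.image_truth["nucleus_mask"].sum()
        assert abs(int(masks.nucleus.sum()) - true_area) / true_area < 0.02

    def test_all_zero_image_is_error(self):
        pair = CellImagePair(np.zeros((64, 64)), np.zeros((64, 64)))
        with pytest.raises(ValueError, match="empty"):
            segment_cell(pair, 10.0, 10.0)

    def test_unregistered_channels_rejected(self):
        with pytest.raises(ValueError, match="registered"):
            CellImagePair(np.zeros((64, 64)), np.zeros((32, 32)))


class TestDensityRatio:
    def _measure(self, nc, noise=0.0, seed=0, noise_model="gaussian"):
        pair, _ = gen_cell_image(nc, noise_frac=noise, seed=seed, noise_model=noise_model)
        masks = segment_cell(pair, nuc_threshold=100.0, cell_threshold=30.0)
        return measure_nc_ratio(pair, masks)

    def test_uniform_intensity_gives_ratio_one(self):
        assert self._measure(1.0).nc_ratio == pytest.approx(1.0)

    def test_double_nuclear_intensity_gives_two(self):
        assert self._measure(2.0).nc_ratio == pytest.approx(2.0)

    def test_low_ratio_recovered_under_noise(self):
        m = self._measure(0.25, noise=0.05, seed=11)
        assert m.nc_ratio == pytest.approx(0.25, rel=0.05)

    def test_poisson_noise_recovery(self):
        m = self._measure(1.3, noise_model="poisson", seed=3)
        assert m.nc_ratio == pytest.approx(1.3, rel=0.05)

    def test_scale_invariance_of_ratio(self):
        pair, _ = gen_cell_image(1.3, noise_frac=0.0, seed=0)
        masks = segment_cell(pair, 100.0, 30.0)
        m0 = measure_nc_ratio(pair, masks)
        pair2 = CellImagePair(pair.nuclear, pair.signal * 7.5)
        m1 = measure_nc_ratio(pair2, masks)
        assert m1.nc_ratio == pytest.approx(m0.nc_ratio, rel=1e-12)

    def test_rawintden_additive_over_mask_split(self):
        pair, _ = gen_cell_image(1.3, noise_frac=0.05, seed=1)
        masks = segment_cell(pair, 100.0, 30.0)
        whole = pair.signal[masks.cytoplasm].sum()
        half = np.zeros_like(masks.cytoplasm)
        half[:, :96] = True
        a = pair.signal[masks.cytoplasm & half].sum()
        b = pair.signal[masks.cytoplasm & ~half].sum()
        assert a + b == pytest.approx(whole, rel=1e-12)

    def test_masks_disjoint_enforced(self):
        pair, _ = gen_cell_image(1.0, noise_frac=0.0, seed=0)
        masks = segment_cell(pair, 100.0, 30.0)
        from cmephys.imaging import SegmentationMasks

        bad = SegmentationMasks(masks.nucleus, masks.cell, masks.cell)
        with pytest.raises(ValueError, match="overlap"):
            measure_nc_ratio(pair, bad)


class TestCohortSummary:
    def test_mean_and_sd(self):
        import pandas as pd

        from cmephys.core import CohortTable

        df = pd.DataFrame({"group": ["a"] * 3, "nc_ratio": [1.0, 2.0, 3.0]})
        out = cohort_nc_summary(CohortTable(df, ("a",)))
        assert out["mean_nc_ratio"][0] == pytest.approx(2.0)
        assert out["sd_nc_ratio"][0] == pytest.approx(1.0)

    @pytest.mark.parametrize("preset", list(NC_PRESETS.values()))
    def test_preset_cohorts_recovered_within_5pct(self, preset):
        vals = []
        for i in range(5):
            pair, _ = gen_cell_image(preset, noise_frac=0.05, seed=100 + i)
            masks = segment_cell(pair, 100.0, 30.0)
            vals.append(measure_nc_ratio(pair, masks).nc_ratio)
        assert np.mean(vals) == pytest.approx(preset, rel=0.05)


def test_tiff_roundtrip_of_channel_pair(tmp_path):
    from cmephys.imaging import load_image_pair, save_image_pair

    pair, _ = gen_cell_image(1.3, noise_frac=0.05, seed=2)
    save_image_pair(pair, tmp_path / "nuc.tif", tmp_path / "sig.tif")
    back = load_image_pair(tmp_path / "nuc.tif", tmp_path / "sig.tif")
    assert np.allclose(back.signal, pair.signal, atol=1e-4)
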