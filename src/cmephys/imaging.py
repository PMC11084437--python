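"""Nucleus/cytoplasm segmentation and signal-density N/C ratio.

Density is defined as the integrated signal intensity over a compartment
(RawIntDen) divided by the compartment area in pixels; the reported quantity
is the nucleus/cytoplasm density ratio N/C.  Segmentation uses constant
(per-dataset) thresholds: the nucleus is the largest connected component of
the nuclear channel above ``nuc_threshold`` (holes filled); the cell is the
largest signal-channel component above ``cell_threshold`` that contains the
nucleus; the cytoplasm is cell minus nucleus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .core import CohortTable

__all__ = ["CellImagePair", "SegmentationMasks", "CellDensityMeasurement",
           "segment_cell", "measure_nc_ratio", "suggest_threshold",
           "cohort_nc_summary", "load_image_pair", "save_image_pair",
           "save_masks"]


@dataclass
class CellImagePair:
    """Registered nuclear-stain and signal-channel images (same shape)."""

    nuclear: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.nuclear = np.asarray(self.nuclear, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.nuclear.shape != self.signal.shape:
            raise ValueError("channels are not registered (shape mismatch)")
        if self.nuclear.ndim != 2:
            raise ValueError("expected 2-D images")


@dataclass(frozen=True)
class SegmentationMasks:
    nucleus: np.ndarray
    cell: np.ndarray
    cytoplasm: np.ndarray


@dataclass(frozen=True)
class CellDensityMeasurement:
    raw_int_den_nucleus: float
    raw_int_den_cytoplasm: float
    area_nucleus_px: int
    area_cytoplasm_px: int
    density_n: float
    density_c: float
    nc_ratio: float


def load_image_pair(nuclear_path, signal_path) -> CellImagePair:
    """Load a registered channel pair from TIFF/PNG files (one per channel)."""
    import imageio.v3 as iio

    return CellImagePair(iio.imread(nuclear_path), iio.imread(signal_path))


def save_image_pair(pair: CellImagePair, nuclear_path, signal_path) -> None:
    """Write both channels as 32-bit float TIFF (or PNG after rounding)."""
    import tifffile

    for img, path in ((pair.nuclear, nuclear_path), (pair.signal, signal_path)):
        path = str(path)
        if path.lower().endswith((".tif", ".tiff")):
            tifffile.imwrite(path, img.astype(np.float32))
        else:
            import imageio.v3 as iio

            iio.imwrite(path, np.clip(img, 0, 255).astype(np.uint8))


def save_masks(masks: "SegmentationMasks", directory, stem: str = "cell") -> None:
    """Write nucleus/cell/cytoplasm masks as 0/255 PNG images."""
    import imageio.v3 as iio
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in ("nucleus", "cell", "cytoplasm"):
        img = (getattr(masks, name).astype(np.uint8)) * 255
        iio.imwrite(directory / f"{stem}_{name}.png", img)


def _largest_component(mask: np.ndarray, must_contain: np.ndarray | None = None) -> np.ndarray:
    labels = measure.label(mask)
    if labels.max() == 0:
        raise ValueError("empty mask: no pixels above threshold")
    if must_contain is not None:
        # component holding the bulk of the required region
        inside = labels[must_contain]
        inside = inside[inside > 0]
        if inside.size == 0:
            raise ValueError("no component contains the nucleus")
        lab = np.bincount(inside).argmax()
    else:
        lab = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return labels == lab


def segment_cell(pair: CellImagePair,
                 nuc_threshold: float,
                 cell_threshold: float) -> SegmentationMasks:
    """Threshold-based nucleus / cell / cytoplasm masks (one cell per tile)."""
    nucleus = _largest_component(pair.nuclear > nuc_threshold)
    nucleus = ndimage.binary_fill_holes(nucleus)
    cell = _largest_component(pair.signal > cell_threshold, must_contain=nucleus)
    cell = ndimage.binary_fill_holes(cell) | nucleus
    contained = float(np.sum(nucleus & cell)) / float(np.sum(nucleus))
    if contained < 0.99:
        raise ValueError("nucleus not contained in the cell mask")
    cytoplasm = cell & ~nucleus
    if not cytoplasm.any():
        raise ValueError("empty cytoplasm mask")
    return SegmentationMasks(nucleus, cell, cytoplasm)


def suggest_threshold(channel: np.ndarray) -> float:
    """Suggest a constant threshold from the intensity histogram (midpoint of
    the background and foreground modes); never applied automatically."""
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(np.asarray(channel, dtype=float)))


def measure_nc_ratio(pair: CellImagePair, masks: SegmentationMasks) -> CellDensityMeasurement:
    """Signal-channel density (RawIntDen / area) per compartment and N/C."""
    if (masks.nucleus & masks.cytoplasm).any():
        raise ValueError("nucleus and cytoplasm masks overlap")
    a_n = int(np.sum(masks.nucleus))
    a_c = int(np.sum(masks.cytoplasm))
    if a_n == 0 or a_c == 0:
        raise ValueError("empty compartment mask")
    rid_n = float(np.sum(pair.signal[masks.nucleus]))
    rid_c = float(np.sum(pair.signal[masks.cytoplasm]))
    dn = rid_n / a_n
    dc = rid_c / a_c
    if dc == 0:
        warnings.warn("zero cytoplasm density; N/C ratio missing", stacklevel=2)
        ratio = float("nan")
    else:
        ratio = dn / dc
    return CellDensityMeasurement(rid_n, rid_c, a_n, a_c, dn, dc, ratio)


def cohort_nc_summary(measurements: dict[str, list[CellDensityMeasurement]] | CohortTable
                      ) -> pd.DataFrame:
    """Per-group mean +/- SD (n-1) of the N/C ratio.

    Accepts either a mapping ``group -> measurements`` or a
    :class:`CohortTable` with an ``nc_ratio`` column.
    """
    if isinstance(measurements, CohortTable):
        grouped = {g: list(v) for g, v in measurements.group_values("nc_ratio").items()}
        get = lambda m: float(m)
    else:
        grouped = measurements
        get = lambda m: m.nc_ratio
    rows = []
    for g, ms in grouped.items():
        vals = np.asarray([get(m) for m in ms], dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            warnings.warn(f"group {g!r} has no measurements; skipped", stacklevel=2)
            continue
        rows.append({"group": g, "n": vals.size,
                     "mean_nc_ratio": float(np.mean(vals)),
                     "sd_nc_ratio": float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan")})
    return pd.DataFrame(rows)
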