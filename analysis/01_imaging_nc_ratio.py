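#!/usr/bin/env python
"""Nucleus/cytoplasm proteasome-density ratio across treatment conditions.

Generates synthetic two-channel cell images at the four condition presets
(control 1.30, -AA 0.25, -AA+YWF 2.66, -AA+LMB 2.36), segments each cell,
measures the N/C density ratio, and compares groups with the
normality-gated statistics tree.

Finding: the measured group means recover the presets within a fraction of
a percent, and the group ordering -AA < control < -AA+LMB < -AA+YWF is
highly significant.
"""

import warnings
from pathlib import Path

from cmephys.core import CohortTable
from cmephys.pipeline import PipelineConfig, run_figure_preset
from cmephys.stats import compare_groups

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)


def main(seed: int = 1) -> None:
    cfg = PipelineConfig(seed=seed, cells_per_group=12)
    bundle = run_figure_preset("fig1_imaging", cfg)
    cells = bundle["tables"]["cells"]
    summary = bundle["tables"]["summary"]
    cells.to_csv(RESULTS / "01_nc_ratio_cells.csv", index=False)
    summary.to_csv(RESULTS / "01_nc_ratio_summary.csv", index=False)

    table = CohortTable(cells[["group", "nc_ratio"]],
                        tuple(cells["group"].unique()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        comp = compare_groups(table, "nc_ratio")
    print(summary.to_string(index=False))
    print(f"\nbranch: {comp.branch}; p = {comp.p_value:.3g} ({comp.stars})")
    for name, ok in bundle["checks"].items():
        print(f"check {name}: {'PASS' if ok else 'FAIL'}")


if __name__ == "__main__":
    main()
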