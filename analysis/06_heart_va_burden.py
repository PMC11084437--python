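#!/usr/bin/env python
"""Whole-heart ventricular-arrhythmia burden over 1.5 h perfusions.

Generates rat-heart beat sequences (5 Hz sinus) with injected VA episodes,
detects episodes from RR shortening, applies the > 30 s sustained rule, and
reports per-group VA incidence and fractional duration.

Finding: control hearts are VA-free; the -AA+YWF-like preset shows higher
incidence and a larger fractional duration than the -AA-like preset, and
detected fractions match the injected truth to hundredths of a percent.
"""

from pathlib import Path

from cmephys.pipeline import PipelineConfig, run_figure_preset

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)


def main(seed: int = 1) -> None:
    bundle = run_figure_preset("fig13_hearts", PipelineConfig(seed=seed))
    df = bundle["tables"]["hearts"]
    df.to_csv(RESULTS / "06_heart_va.csv", index=False)
    grp = df.groupby("group", sort=False)
    print(grp[["fractional_duration_pct", "true_fractional_pct"]].mean().round(4))
    print("sustained-VA incidence (%):",
          (100 * grp["any_sustained_va"].mean()).round(1).to_dict())
    for name, ok in bundle["checks"].items():
        print(f"check {name}: {'PASS' if ok else 'FAIL'}")


if __name__ == "__main__":
    main()
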