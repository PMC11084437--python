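#!/usr/bin/env python
"""Full deterministic reproduction run: every figure preset, one manifest.

Runs all presets with one configuration and seed, writes each table and a
manifest (versions, seed, config hash, per-preset pass/fail) under
``results/``.
"""

from pathlib import Path

from cmephys.pipeline import PipelineConfig, run_all

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    manifest = run_all(PipelineConfig(seed=seed, output_dir=str(RESULTS)))
    for name, p in manifest["presets"].items():
        print(f"{name}: {'PASS' if p['passed'] else 'FAIL'} ({p['elapsed_s']}s)")
    print("all passed:", manifest["all_passed"])
    print("config hash:", manifest["config_hash"])


if __name__ == "__main__":
    main()
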