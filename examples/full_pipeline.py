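"""Run the end-to-end pipeline on a reduced synthetic cohort.

Generates a small cohort (3 animals per cell, 1-h telemetry to keep this
example quick), runs every analysis stage and prints the run summary.  The
report directory holds one tidy CSV per figure-style analysis.
"""

import json

from agestress.pipeline import PipelineConfig, run_pipeline

sizes = {f"{a}-{s}": 3 for a in ("young", "aged") for s in ("control", "stress")}
config = PipelineConfig(seed=1, group_sizes=sizes, panel_sizes=sizes,
                        telemetry_duration_h=1.0,
                        out_dir="example_run")
report = run_pipeline(config)

print(f"config hash: {report.config_hash}")
print(f"tables written: {len(report.tables)} (in example_run/)")
print(json.dumps(report.summary, indent=2, default=str))
print("\nEvery table is a pure function of (config, seed); rerunning with the")
print("same config reproduces the directory byte-for-byte.")
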