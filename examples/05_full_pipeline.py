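"""Run the whole pipeline on a simulated cohort and inspect the bundle.

Simulates six subjects, preprocesses, clusters at both levels with the
meta-criterion, backfits with smoothing, computes metrics, and runs the
group statistics; everything lands in an output directory together with
the resolved configuration and a run log.
"""

from microstates import PipelineConfig, SimulationConfig, run_pipeline

config = PipelineConfig(
    out_dir="scratch/example_pipeline",
    seed=3,
    n_subjects=6,
    simulation=SimulationConfig(n_channels=64, duration_s=60.0, k_true=4, snr=2.0),
    k_min=2,
    k_max=6,
    individual_k=4,
    n_restarts=15,
)
result = run_pipeline(config)

print(f"selected K* = {result.model.K}")
print(f"group-level GEV of pooled prototypes: {result.model.gev_total:.3f}")
print("\nper-class mean metrics across subjects:")
print(
    result.metrics.groupby("class")[["duration_ms", "occurrence_per_s", "coverage"]]
    .mean()
    .round(2)
    .to_string()
)
print("\nfiles written:")
for p in sorted(result.out_dir.iterdir()):
    print(" ", p.name)
# The metrics table is tidy (one row per subject x class) and feeds the
# statistics stage directly; re-running with the same config reproduces
# every file byte for byte.
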