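# microstates

Resting-state EEG **microstate analysis**: polarity-invariant topographic
clustering, backfitting with temporal smoothing, temporal dynamics metrics,
and group/clinical statistics — plus a synthetic-EEG generator with planted
microstate structure so the whole pipeline can be validated by parameter
recovery.

## Who this is for

EEG researchers studying the sub-second dynamics of large-scale brain
networks — e.g. comparing patients and controls, or correlating microstate
dynamics with clinical scores — who want a tested, scriptable implementation
of the standard microstate workflow:

1. **Preprocess**: zero-phase 1–40 Hz band-pass, decimation to 125 Hz,
   average reference.
2. **Cluster**: modified k-means on the topographies at GFP peaks, ignoring
   map polarity; the number of classes K chosen by a meta-criterion that
   combines seven cluster-validity indices by median rank; two-level
   (subject → group) clustering for cohorts.
3. **Segment**: assign every sample to the class of highest |spatial
   correlation| and smooth the labels (window half-size 3, Besag factor 10)
   so low-GFP noise does not fragment segments.
4. **Quantify**: per-class mean duration (ms), occurrence (1/s), coverage,
   and global explained variance (GEV).
5. **Test**: FDR-corrected independent t-tests between groups and Spearman
   correlations with clinical covariates at α = 0.01.

The core quantities, for a recording `x_t` (channels × samples, average
referenced) and unit-norm prototype maps `a_k`:

- GFP: `gfp_t = std over channels of x_t`
- assignment: `L_t = argmax_k |corr(x_t, a_k)|`
- GEV: `Σ_t gfp_t² · corr(x_t, a_{L_t})² / Σ_t gfp_t²`

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
from microstates import SimulationConfig, PipelineConfig, run_pipeline

config = PipelineConfig(
    out_dir="demo_out", seed=3, n_subjects=6,
    simulation=SimulationConfig(n_channels=64, duration_s=60.0, k_true=4, snr=2.0),
    k_min=2, k_max=6, individual_k=4, n_restarts=15,
)
result = run_pipeline(config)
print(result.model.K)
print(result.metrics.groupby("class")[["duration_ms", "occurrence_per_s", "coverage"]]
      .mean().round(2))
```

Output (`examples/05_full_pipeline.py`):

```
selected K* = 4
group-level GEV of pooled prototypes: 0.999

per-class mean metrics across subjects:
       duration_ms  occurrence_per_s  coverage
class
A           101.46              2.56      0.26
B           102.11              2.46      0.25
C           105.51              2.31      0.24
D           104.57              2.34      0.24
```

The meta-criterion recovered the four planted classes; mean dwell times
near the planted 100 ms, occurrences near the planted ~2.5 segments/s and
coverages near ¼ show that backfitting plus smoothing reconstructed the
hidden state sequence.  The output directory holds the model maps, the
meta-criterion score table, per-subject segmentations, the tidy metrics
CSV, the statistics tables, the resolved configuration, and a run log with
all seeds — re-running the same configuration reproduces every file byte
for byte.

The `examples/` directory has one short script per capability (simulation,
clustering, segmentation and metrics, statistics, full pipeline).  A thin
CLI mirrors the pipeline stages (`microstates simulate|preprocess|cluster|
backfit|metrics|stats|run`); real recordings are read from EDF or from a
delimited channels × samples matrix with a JSON sidecar.

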