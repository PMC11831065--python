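# neurocoh

Resting-state EEG functional connectivity analysis: Welch-based
magnitude-squared coherence per channel pair, aggregated in canonical
frequency bands, compared edge-wise between two subject groups with
Mann–Whitney U tests and Benjamini–Hochberg FDR correction — plus a seeded
synthetic-cohort generator with analytically known coherence, so the whole
pipeline can be validated end to end without access to clinical recordings.

It is written for researchers analysing two-group resting-state EEG studies
(patients vs controls, eyes-open vs eyes-closed protocols) who want a
scriptable, reproducible pipeline whose every stage is testable.

## The analysis

For each subject and condition, the magnitude-squared coherence of every
channel pair (x, y) is estimated with Welch's method:

```
C_xy(f) = |P_xy(f)|² / (P_xx(f) · P_yy(f))  ∈ [0, 1]
```

where `P_xx`, `P_yy` are auto-spectral densities and `P_xy` the cross-spectral
density, averaged over K tapered, overlapping segments tiled within each
analysis epoch (defaults: 2-s Hann segments, 50 % overlap → 0.5 Hz
resolution; K ≈ 165 for 3 × 56-s epochs, so the 1/K bias of independent
signals is ≈ 0.006). Coherence is averaged within 11 bands — delta (1–4 Hz),
theta (4–7.5), theta1 (4–6), theta2 (6–7.5), alpha (7.5–13), alpha1
(7.5–9.5), alpha2 (9.5–11), alpha3 (11–13), beta (13–35), beta1 (13–20),
beta2 (20–35); band bins are half-open `[low, high)` so sub-bands partition
their parents.

Preprocessing follows the standard deterministic chain: zero-phase 0.5–35 Hz
band-pass (4th-order Butterworth, forward–backward), single-pass bad-channel
rejection by cross-channel kurtosis z-score (threshold 5), average
re-referencing, and segmentation of annotated eyes-open/eyes-closed blocks
into epochs with the first 4 s of each block discarded. An optional cleaning
hook (`Recording -> Recording`) slots in where interactive artifact removal
(e.g. ICA) would run.

Group inference is per (band × condition) family: a two-sided Mann–Whitney U
test per channel pair (exact enumeration when `n₁·n₂ ≤ 100` without ties,
otherwise normal approximation with tie and continuity corrections),
Benjamini–Hochberg step-up FDR across the family's pairs, thresholded
median-coherence group graphs (0.5 and 0.7), and a difference graph of
FDR-significant edges where the case-group median is below the control
median.

## Worked example

```python
from neurocoh import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig.demo(n_per_group=8, seed=5))
cell = report.cell("alpha3", "EO")
print(cell["n_deficit"], cell["region_summary"])
```

The demo cohort is 8 + 8 subjects (32 channels, 3 alternating 60-s EO/EC
blocks per condition at 250 Hz) in which the "case" group has a 60 %
reduction of a frontal 11.2–12.8 Hz source with eyes open. The run prints:

```
alpha3/EO: 4 significant case-deficit edges
region summary (cells with any difference edge):
  frontal-right|frontal-right      count   2  density 0.20
  frontal-right|midline            count   2  density 0.10
```

meaning: after FDR correction across all 496 channel pairs, the pipeline
finds significant case-deficit edges only in the alpha3 band with eyes open,
concentrated on right-frontal and frontal-midline connections — the planted
effect, in the planted place — while the other 21 band × condition cells
stay at the false-positive level. (At the default `n_per_group=12` the same
run recovers all 15 source-targeted pairs.)

Each stage can also be run from the shell via the `neurocoh` CLI
(`simulate`, `preprocess`, `coherence`, `compare`, `report`, `run`,
`validate`) with file contracts between stages — see
`examples/config_demo.yaml` — and the `examples/` directory holds one short
script per capability, including EDF+ export/import and questionnaire-table
t-statistics from published group summaries.

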