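# Methods

## Signal model of the synthetic cohorts

Each synthetic subject is a channels × samples matrix

```
x_c(t) = Σ_s g_s · γ_s(group) · κ_s(condition, t) · j_s · m_{s,c} · u_s(t)  +  n_c(t)
```

where `u_s` is a *source*: unit-variance Gaussian white noise band-pass
filtered to `center ± bandwidth/2` with a zero-phase (forward–backward)
4th-order Butterworth — stationary and analytically tractable, with one-sided
PSD `(2/fs)·|H(f)|⁴`. `g_s` is the mixing gain onto the source's target
channels, `γ_s` a per-group multiplier (how deficits are planted), `κ_s` a
per-condition multiplier applied sample-wise over the annotated EO/EC blocks
(how eyes-open/eyes-closed contrasts are planted), `j_s` a per-subject
lognormal gain multiplier (σ = 0.10 by default, i.e. ≈ ±10 % between-subject
spread), and `m_{s,c}` optional per-(subject, channel) lognormal multipliers
(see "diffuse synchrony" below). `n_c` is independent `1/f^α` background
noise (α = 1 by default), synthesised by frequency-domain shaping of white
noise — the slope is exact by construction and the amplitude is normalised to
a target standard deviation.

All randomness derives from `SeedSequence(seed, spawn_key=(group, subject))`
with one child stream per source plus streams for noise and jitter, so a
cohort is bit-reproducible and subjects are mutually independent.

Because the model is linear with independent sources and noise, the
population MSC of any pair is available in closed form; for a single shared
source,

```
C_xy = (g_x g_y S)² / ((g_x² S + N_x)(g_y² S + N_y))
```

with `S` the source PSD and `N` the noise PSD at the frequency of interest.
This is the oracle the estimator tests are checked against (tolerance ±0.05
at ≥ 10 min of signal).

### The default planted-deficit cohort

The demo configuration emulates a two-group resting-state study at desk
scale: 32 channels on a 10-20-like grid, 12 subjects per group, 3
alternating 60-s EO/EC blocks per condition at 250 Hz (preprocessing trims
each block to a 56-s epoch). Sources:

| source | band (Hz) | targets | role |
|---|---|---|---|
| posterior alpha | 7.5–10.5 | parieto-occipital | ×1.6 with eyes closed (Berger effect), group-neutral |
| frontal background alpha | 7.5–10.5 | frontal + midline | group-neutral, large between-subject spread (σ = 0.5) |
| midline theta | 4–7 | fronto-central midline | group-neutral |
| diffuse upper-alpha synchrony | 10.5–13.5 | all channels, per-subject scalp pattern (channel σ = 0.5) | group-neutral variability floor |
| frontal upper-alpha coupling | 11.2–12.8 | Fp2, AF4, F4, F8, FC6, Fz | eyes-open only; case gain ×0.4 (the planted deficit) |

Two design points matter and were chosen on mechanistic grounds:

1. **Average-reference leakage.** With an average reference, a source mixed
   into k of n channels leaks a −k/n copy of itself into *every* channel.
   The deficit source therefore sits on 6 of 32 channels; a large k/n would
   smear the group difference over the entire montage. The residual
   target×non-target effect is real (it radiates from the planted channels)
   and is visible as extra deficit edges touching the targeted channels.
2. **Between-subject variability as the detection floor.** With K ≈ 165
   Welch segments the coherence estimator is precise enough that *any*
   systematic group difference — including sub-percent reference leakage —
   would reach significance if subjects were identical replicates. The
   diffuse upper-alpha source gives every subject an individual scalp
   pattern of weak 10.5–13.5 Hz synchrony, which (as in real cohorts, where
   resting alpha topography varies widely between individuals) sets a
   group-neutral variability floor below which systematic artifacts stay
   undetected, while the planted 60 % reduction stands far above it.

What the generator does **not** emulate: volume conduction/leadfield mixing
beyond the reference effect, artifacts (blinks, EMG), non-stationarity, and
realistic 256-channel geometry. Passing recovery tests therefore show that
the *pipeline* detects band- and condition-specific coupling differences of
this magnitude under realistic between-subject variance — not that any
particular clinical effect has this structure.

## Preprocessing

* Band-pass 0.5–35 Hz, zero-phase 4th-order Butterworth (8th-order
  effective magnitude response; no phase distortion of cross-spectra). The
  filter family/order is a package choice; the band edges follow the
  standard resting-state convention.
* Bad channels: Fisher excess kurtosis per channel, z-scored across
  channels, single pass, |z| > 5 rejected. Note the z-score across n
  channels is bounded by √(n−1), so the rule can only fire on montages with
  a few dozen channels or more — with 32 channels one extreme channel
  reaches z ≈ 5.4. Rejected channels are dropped, never interpolated:
  interpolated channels are linear combinations of neighbours and would
  fabricate coherence.
* Average reference after rejection; coherence is always computed on
  average-referenced data.
* Epochs: each annotated EO/EC interval loses its first 4 s
  (auditory-cue transient), is truncated to 56 s if longer, and remainder
  epochs shorter than the target are kept with a warning (maximises data,
  preserves auditability). Intervals are half-open `[start, end)` in
  0-based samples.
* ICA or other interactive cleaning enters only through the pluggable
  `cleaning_hook`; the default is the identity.

## Spectral estimation

Welch with 2-s Hann segments, 50 % overlap, constant detrend; segments are
tiled **within** epochs (never straddling epoch boundaries) and pooled over
all epochs of one condition — coherence per condition comes from one pooled
estimate, not from averaging per-epoch coherences. Δf = 0.5 Hz resolves
every default band edge (all are multiples of 0.5 Hz) and gives the
narrowest band (alpha2, 1.5 Hz) three bins; K ≈ 165 segments make the
independent-signal bias 1/K ≈ 0.006. One-sided density normalisation
matches `scipy.signal.welch`/`csd` bit-for-bit on a single epoch (the
cross-spectral convention is scipy's `E[conj(X)·Y]`). Cross-spectra are
stored pair-indexed (i < j) rather than as dense channel × channel ×
frequency arrays.

MSC per pair is clipped to [0, 1] against rounding; bins with zero power on
either channel are flagged undefined (NaN) and excluded from band averages;
an estimate from K = 1 segment is rejected (MSC ≡ 1 carries no
information). Band averages are unweighted means over `[low, high)` bins;
a band with no bins on the grid is a configuration error.

## Group statistics

* Mann–Whitney U, two-sided, per channel pair. Exact enumeration when
  `n₁·n₂ ≤ 100` and the pooled sample is tie-free; otherwise the normal
  approximation with midranks, tie correction, and continuity correction.
  The exact and asymptotic paths agree within p ± 0.02 at n ≥ 8 per group.
* Benjamini–Hochberg step-up per (band × condition) family of all channel
  pairs (`q_(i) = min_{j≥i} m·p_(j)/j`, clipped at 1). The family scope
  follows the per-band, per-condition reading of the analysis; on null
  cohorts the measured proportion of families with any discovery is ≈ 0.02–0.05
  at nominal 0.05.
* Thresholded group graphs use the element-wise median across subjects
  (even counts: midpoint of the central order statistics) and a closed
  threshold (edge iff median ≥ t), so 0.7-graphs are nested in 0.5-graphs.
* Difference graphs keep FDR-significant pairs with case median < control
  median; significant pairs in the opposite direction are logged and
  reported separately. Default q cutoff 0.05, recorded in every output.
* Questionnaire-style comparisons from summary statistics use the
  pooled-variance two-sample t with df = n₁ + n₂ − 2 and sign convention
  control − case (negative when cases score higher). Cronbach's alpha is
  `k/(k−1)·(1 − Σ item variances / variance of total)` with ddof = 1.

## Problem sizes used in validation

* Planted-deficit recovery: the full demo cohort (32 channels, 12 + 12
  subjects, 2 × 3 × 56-s epochs, fixed seed) — the study design at reduced
  channel count and sample size.
* Null false-discovery control: 20 seeds of a reduced null cohort
  (16 channels, 10 + 10 subjects, 3 × 30-s blocks per condition), all 22
  band × condition families per seed; the reduced shape keeps many-seed
  Monte-Carlo affordable while preserving realistic inter-edge dependence.
* Estimator oracles run on 1–10 minutes of synthetic signal as noted in the
  tests.

## Numerical and degenerate-input choices

* Zero-spread channel kurtosis (all channels identical): no rejection
  rather than division by zero.
* Welch epochs shorter than one segment are skipped with a warning; if all
  are too short the estimate is refused.
* p-values entering BH are clipped away from 0 at the smallest positive
  float (the asymptotic path can underflow).
* EDF export uses 16-bit samples with per-channel symmetric physical
  ranges; reconstruction error is bounded by one quantisation step
  (≈ range/32767). Non-integer sampling rates are refused (1-s records).
* Band definitions, thresholds, seeds and the config hash are recorded in
  every run report for provenance.

## Known limitations

* Sensor-space coherence on average-referenced data: reference-induced
  correlations are inherent to the measure; the difference graphs therefore
  attribute deficits to *edges touching the affected channels*, not to
  anatomically localised sources.
* No multitaper/wavelet/imaginary-coherence estimators; no graph-theoretic
  summary metrics; no source-space analysis.
* The kurtosis rule is ineffective below ~26 channels (z-score bound), as
  on the reduced fixtures; this mirrors its intended use on dense arrays.
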