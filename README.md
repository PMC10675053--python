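# gait2dft

Discrimination of walking speed modalities (self-selected slow, normal
and fast walking) from a **single body-worn triaxial accelerometer**,
using two-dimensional Fourier transform features and a simple
PCA + discriminant-function-analysis classifier, with a quantitative
cluster-separation criterion.

The package is aimed at movement scientists and wearable-sensor
engineers who want to (a) tell walking modalities apart from one
accelerometer at the sacrum, thigh or shank, and (b) put a *number* on
how cleanly the modalities separate — e.g. to compare sensor attachment
sites or tune processing parameters — rather than only a binary
classification accuracy.

## Method

1. **Magnitude.** The triaxial trace (100 Hz, ±8 g) is resampled onto a
   uniform timebase by linear interpolation and collapsed to the
   orientation-free magnitude |a| = √(ax² + ay² + az²), in g.
2. **2DFT features.** From each 3-s slab of known walking, overlapping
   0.3-s segments (overlap factor 2, Hann taper, per-segment mean
   removal) give a magnitude spectrogram; a second Fourier transform
   along the segment-time axis yields the 2DFT — a signal-frequency ×
   repetition-rate image in which the gait cycle appears as energy at
   the step harmonics repeating at the cadence. Because both transforms
   keep magnitudes only, the feature is insensitive to the phasing of
   the analysis window. Ten slabs per condition give the low-density
   matrix; rescanning each slab at 0.1-s start-time shifts over 1 s
   gives the 300-row high-density training database.
3. **PCA.** The pooled training database is reduced to the smallest
   leading set of principal components explaining ≥ 80% of total
   variance.
4. **DFA.** Fisher linear discriminant analysis projects the retained
   PC scores onto two discriminant axes (the solution of
   S_b v = λ S_w v), maximising between-condition relative to
   within-condition scatter.
5. **Criterion.** With centroids c_i and scatters s_i (standard
   deviation of each point's distance to its centroid) of the three
   DF-score clusters,

   criterion = (D₁ · D₂ · D₃) / (s₁ · s₂ · s₃),

   where D₁…D₃ are the pairwise centroid distances
   (fast–normal, fast–slow, normal–slow). The ratio is invariant under
   rotation, translation and uniform scaling of the DF plane. A value
   **greater than 500** marks a successful (visually non-overlapping)
   discrimination.

A seeded synthetic-session generator (quasi-periodic cadence harmonics,
heel-strike transients, stride and bout jitter, turn gaps between
straight-line bouts) makes the whole pipeline testable without
participant data.

## Worked example

```python
from gait2dft import (SpectralParams, analyze_session, default_session_spec,
                      generate_session, magnitude)

spec = default_session_spec(seed=1, cadences=(1.4, 1.9, 2.4))
recording, selections = generate_session(spec)
art = analyze_session(magnitude(recording), selections, SpectralParams())
print("high-density rows:", art.high.n_rows)
print("retained PCs:", art.basis.retained_count,
      f"({100 * art.basis.retained_fraction:.1f}% of variance)")
print(f"criterion = {art.result.criterion:.0f}  success = {art.result.success}")
```

prints

```
high-density rows: 300
retained PCs: 1 (80.4% of variance)
criterion = 30789  success = True
```

300 rows are the 3 conditions × 10 slabs × 10 temporal shifts; the
retained components carry just over the 80% variance target; and a
criterion of ≈3.1 × 10⁴ ≫ 500 says the three cadence clusters are far
apart relative to their spread — a clearly successful discrimination.
With all three conditions forced to the same cadence and amplitude the
criterion drops to single digits and the run is flagged unsuccessful.

The same pipeline is available from the shell:

```bash
gait2dft simulate --seed 1 --out session/
gait2dft features session/session.csv session/selections.csv --out feats.h5
gait2dft fit feats.h5 --out model.h5 --scores-out df_scores.csv
gait2dft score df_scores.csv
# or end-to-end from a YAML config:
gait2dft run --config run.yaml --seed 1
```

`gait2dft run` writes the feature archives (HDF5), the fitted model,
DF-score and criterion CSVs, stacked-2DFT and DF-scatter plots, and a
manifest that reproduces the run bit-identically.

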