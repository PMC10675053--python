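# Methods

## Signal model and pre-processing

The input is a triaxial accelerometer trace in g, nominally 100 Hz with
an 8 g saturation limit. Loggers drift slightly around their preset
rate, so each axis is linearly interpolated onto an absolute uniform
grid at the configured rate spanning exactly the recorded interval —
never beyond it (extrapolation would fabricate samples). Duplicate
timestamps keep the first sample and emit a warning; any axis value
beyond the saturation limit aborts the load, because a clipped trace
biases every later magnitude. The analysis signal is the acceleration
magnitude |a| = √(ax²+ay²+az²): orientation-free, so no axis
calibration or gravity removal is needed. The static 1 g component is
removed later, per analysis segment.

## 2DFT features

Each 3-s slab is segmented into 0.3-s windows hopped by
0.3/overlap_factor s (default factor 2 → 0.15 s hop, adjacent windows
sharing exactly half their samples; at 100 Hz that is 19 windows of 30
samples). Per window the mean is removed — otherwise the gravity DC
term dominates every feature — a Hann taper limits leakage in the short
30-sample windows, and the one-sided DFT magnitude is kept (16 bins,
3.33 Hz resolution). The second DFT runs along the window-time axis
over the **full** 19-window extent (no power-of-two truncation; modern
FFTs need none, and truncation would discard data), again keeping the
one-sided magnitude (10 repetition-rate bins, 1/(19×0.15 s) ≈ 0.35
cycles/s resolution). The resulting 16×10 image is flattened
frequency-major (all repetition-rate bins of the lowest frequency
first) into a 160-element feature vector. Windows that would overrun a
slab are dropped, not zero-padded — padding would fabricate
low-repetition-rate energy. The full one-sided frequency range is kept
by default; `SpectralParams.max_frequency` can cap it.

Because both stages keep magnitudes only, shifting the slab start by an
integer number of gait cycles leaves the feature essentially unchanged
(the phase-robustness property, tested at < 5% relative L2 change).
Note the 0.3-s window is *shorter* than a gait period, so the 2DFT does
encode waveform shape (relative harmonic phasing) through the temporal
envelope of the spectrogram — only global window phasing is discarded.

The high-density scan recomputes each selected slab at 0.1-s start
shifts, forward in time, over 1 s: 10 shifted slabs per selection, 300
rows for a standard 10-selections-per-condition session. Slab
selections therefore need 4 s of clean walking (3 s slab + 1 s scan).

## Dimensionality reduction and discrimination

PCA is fitted on the pooled 300-row database — not per condition —
because the discriminant step needs a single coordinate space; the
retained set is the *smallest* leading set whose cumulative explained
variance reaches the 80% target, so the retained count varies between
sessions (often 1–3 for clean synthetic sessions, >10 when conditions
are indistinguishable and variance is spread over noise directions).
Features are mean-centred but not variance-standardised: 2DFT entries
share units, and standardising would inflate empty high-frequency bins.

The discriminant is the Fisher solution of the generalized eigenproblem
S_b v = λ S_w v in the retained-PC space, keeping the top two axes
(three classes span a between-class scatter of rank ≤ 2, so two axes
capture all linear discriminability). Working in the retained-PC
subspace keeps S_w well conditioned even though raw features (≈160)
exceed the effective sample count; if S_w is still singular a ridge of
1e-8 × mean diagonal is added. If only one PC survives the variance
rule, the second discriminant axis is degenerate and returned as zero —
the 2-D contract holds and the criterion is computed on the resulting
collinear clouds. Every PC and DF axis is oriented so its
largest-magnitude loading is positive, making repeated runs
byte-comparable; no step in the pipeline is randomized.

## Criterion

Each condition's DF cloud is summarised by its centroid (coordinate
mean) and scatter. Scatter is, by default, the **population** standard
deviation of the point-to-centroid distance set (`ddof=0`; a sample-SD
flag exists since the convention is a genuine choice, as is a
radial-RMS alternative — for a cluster whose points are equidistant
from the centroid the SD-of-distances is 0 while the RMS is the common
radius, which is why both are exposed). The criterion is the product of
the three pairwise centroid distances over the product of the three
scatters; numerator and denominator both scale as the cube of a
similarity factor, so the ratio is invariant under rotation,
translation and uniform scaling of the DF plane. Success is the strict
comparison criterion > 500. A zero scatter raises an error instead of
returning infinity — a silent infinity would always pass the threshold.

## Synthetic sessions

The generator emulates a three-condition overground protocol: per
condition, 10 straight-line bouts of 8 s separated by 2-s turn gaps
(turns are excluded from analysis, so they are modelled as gravity plus
noise only), condition blocks separated by 5 s of quiet standing.
Within a bout the vertical axis carries gravity plus three cadence
harmonics with decaying amplitudes (0.45/0.22/0.10 g at normal pace)
and one heel-strike transient per step — a Gaussian-windowed ~12 Hz
ring (30 ms envelope SD, 0.5 g at normal pace) — the dominant
high-frequency feature of real body-worn traces; 40%/25% copies of the
waveform leak onto the horizontal axes, and each axis carries 0.05 g
white noise. Defaults: cadences 1.5/1.9/2.3 steps/s for slow/normal/
fast (under, roughly at, and above two steps per second), amplitudes
and impacts scaled by 0.8/1.0/1.25 with speed, 10% per-stride
per-harmonic amplitude jitter, 3% per-stride cadence jitter, and 3%
bout-level cadence drift (stride-time variability in healthy gait is a
few percent; amplitude variability is larger). The relative phases of
the cadence harmonics — the walker's waveform shape — are drawn once
per *session* and shared across conditions: one walker, one gait
pattern. This matters: with 0.3-s windows the 2DFT is sensitive to
waveform shape, and per-condition phases would make even
identical-cadence conditions systematically separable, which a control
condition must not be.

What the generator does **not** emulate: multi-segment biomechanics,
sensor-site-specific waveforms (sacrum vs shank differ only through
amplitude/harmonic configuration), soft-tissue artefacts, real turn
dynamics, or between-participant diversity. Passing tests on synthetic
sessions therefore demonstrate the pipeline's correctness and its
threshold behaviour under controlled separability — not field accuracy
on real recordings.

All randomness flows from one session seed through
`numpy.random.SeedSequence.spawn`, so sessions are reproducible and
conditions statistically independent.

## Numerical and design choices

- Interpolation grid: absolute at the configured rate (no master
  sensor), clipped to the recorded span.
- Criterion degeneracies: fewer than 2 points per cluster, a missing
  condition, zero scatter, and non-finite criteria all raise typed
  errors rather than produce a number.
- Equal eigenvalue ties in PCA/DFA are resolved by the underlying
  LAPACK ordering plus the positive-loading sign convention.
- Problem sizes: the default session (three conditions × ten 8-s bouts,
  100 Hz, ≈ 304 s, 300-row training database of 160 features) runs the
  full pipeline in well under a second; the Monte-Carlo threshold
  checks use 100 seeded sessions.

## Known limitations

- The 80% rule can retain a single component when one variance
  direction dominates; the DF plane then degenerates to a line (handled
  explicitly, see above).
- The criterion compares exactly three conditions; it does not
  generalise to other cluster counts as written.
- Scatter conventions (population vs sample SD, SD vs RMS) change the
  criterion's absolute scale; comparisons across studies must fix one
  convention. The 500 threshold was calibrated for the SD-of-distances
  convention.
- Out-of-sample classification is deliberately out of scope: the
  criterion quantifies training-set cluster separation, which is the
  quantity the threshold was designed for.
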