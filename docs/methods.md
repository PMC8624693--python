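# Methods

## The measurement model

A thermal camera pointed at a face records, in the region under the nose
and around the mouth, a temperature that oscillates with breathing: exhaled
air (~body temperature) warms the skin and the boundary air layer, inhaled
ambient air cools them. The pipeline treats the *mean temperature of a
fixed region of interest* (ROI) as the respiration signal and derives all
quantities from it.

Two facts about low-cost thermal cameras shape the design. First, absolute
accuracy is poor (on the order of 3 °C or ±5%), but it enters as a bias:
the respiration signal is a temperature *change*, so detrending removes
calibration error and slow drift. Second, per-pixel temporal noise is
suppressed by averaging over the ROI — a 16×12 box averages 192 pixels and
reduces pixel noise by roughly a factor of 14.

## Synthetic recordings

Real thermal recordings of identifiable faces are rarely shareable, so the
generator (`thermospiro.synth`) renders the statistical structure the
pipeline relies on, with full ground truth:

- **Geometry and timing:** 160×120-pixel frames at 9 frames/s, 20 s default
  duration — the native format of the first-generation mobile thermal
  camera the pipeline targets. The frame count rounds down; partial
  trailing breaths are allowed. 9 Hz sampling comfortably satisfies Nyquist
  for breathing: even the neonatal maximum of 55 breaths/min is only
  ~0.92 Hz, and the config validator rejects rates above Nyquist.
- **Forward model:** ROI temperature deviation is *linear* in breath
  volume: `breath_amplitude` (°C/L, default 1.0) × `volume_per_breath` ×
  a normalized periodic waveform. The true physical mapping from airflow to
  skin temperature is unknown and surely nonlinear; an explicitly linear,
  configurable mapping was chosen because it makes parameter-recovery tests
  interpretable. Passing tests therefore demonstrates that the estimators
  recover the generator's structure — not that a real camera achieves
  these accuracies.
- **Waveforms:** `sinusoid` for relaxed tidal breathing; an
  `asymmetric-exhale` shape (raised-cosine rise over 20% of the cycle,
  exponential decay with time constant 25% of the cycle) for forced
  manoeuvres, which are anything but sinusoidal. Both are normalized to
  zero cycle-mean and unit peak magnitude.
- **Noise and drift:** i.i.d. Gaussian noise per pixel per frame
  (`noise_sd`, default 0.3 °C — a temporal-noise figure; the ~3 °C
  absolute accuracy is a bias handled by detrending, not simulated as
  noise) plus a shared linear drift (default 0.01 °C/s). Noise is applied
  *before* ROI averaging so the extraction stage genuinely earns its noise
  suppression. Camera distance is not modelled; signal degradation with
  distance is emulated by raising `noise_sd`.
- **Default physiology:** 18 breaths/min, 0.5 L per breath, 34 °C skin
  baseline. Training volumes span 0.2–3.5 L, from shallow paediatric
  breaths to a deep adult forced exhalation.
- **Corpus construction** (`generate_dataset`): each recording draws its
  volume uniformly from the requested range; the breathing rhythm and
  phase follow the template configuration, reflecting a protocol in which
  subjects are instructed to breathe at a set rhythm while only the moved
  volume differs. Per-subject rate variability can be emulated by varying
  `breath_rate` in the template across calls. Recordings get independent
  sub-seeds drawn from the dataset seed, so the corpus is reproducible
  bit-for-bit.

What the generator does **not** emulate: head motion, ROI drift,
emissivity/reflected-temperature effects, distance-dependent blur,
non-stationary breathing, and any physiological variation of the
temperature-volume coupling between subjects. Results on synthetic data
are upper bounds on real-world performance.

## ROI localization

Face detection needs a visible-light image; this package instead defines
the ROI as the position of a fixed-size box (default 16×12 px) that
maximizes the temporal variance of the box-mean temperature — breath
modulation dominates temporal variance wherever air flows over skin. The
scan is exact (integral images over all positions, identical to the
brute-force scan), deterministic, and ties break toward the smallest
(y0, x0). A constant stack has no signal to localize and raises an error.
The ROI is localized once per recording and held fixed; tracking under
head motion is out of scope.

## Respiration rate

Rate = number of detected peaks / duration × 60. Peaks are local maxima
with prominence ≥ 25% of the signal's peak-to-trough range and pairwise
separation ≥ one neonatal breath period (60/55 s). Neither threshold has a
canonical published value; 25% admits every genuine breath at the
generator's noise levels while rejecting camera-noise wiggles, and the
separation floor simply encodes that no human breathes faster than a
neonate. The separation is enforced in whole samples *rounded down*, so
the limiting 55 breaths/min itself (9.8 samples per breath at 9 Hz)
remains admissible. Endpoints never count as peaks and the completed-peak
count is not rounded, so rate resolution is one breath per recording
duration (3 breaths/min at 20 s). The 15–24 breaths/min normal band is
treated as inclusive at both ends.

## Volume regression

The feature vector is the signal itself: detrended, then linearly
interpolated to N = 180 points (9 Hz × 20 s), so recordings of any length
share one feature space. No summary features are crafted. Four regressors
are supported — decision tree (unlimited depth), random forest, gradient
boosting with squared-error loss, and AdaBoost (100 trees each; none of
these sizes is critical on the synthetic corpus) — all scikit-learn
estimators behind a thin, seeded interface. The random-forest prediction
is exactly the mean of its member trees, and `member_predictions` exposes
the members so the identity can be asserted rather than assumed.

Evaluation uses R², MSE, RMSE and MAE under 10-fold cross-validation.
Folds are assigned at the *recording* level by seeded shuffle, never at
the sample level, to avoid leakage. Headline metrics are computed on the
pooled out-of-fold prediction vector; per-fold metrics and their means are
reported alongside, since the two conventions differ and neither is
universal. Per-fold R² is undefined (NaN) when a fold's measured volumes
are constant; the direct `r_squared` call on constant truth raises.

On the default synthetic corpus (300 recordings, 0.2 °C pixel noise) the
cross-validated R² of the best regressor exceeds 0.999 with MAE of a few
millilitres. This mirrors the near-perfect tree-regression results
reported for thermal spirometry on real recordings, and the synthetic
experiment suggests why such numbers are attainable: when amplitude scales
cleanly with volume and recordings share a protocol rhythm, the mapping is
low-dimensional and trees interpolate it almost perfectly. It equally
warns that such scores reflect the protocol's regularity, not clinical
accuracy.

## Spirometry parameters

- **Tidal volume**: the model consumes exactly one peak-to-peak breath
  window, resampled to N; a model used here must be trained on
  single-breath windows (`generate_dataset(..., window="breath")`).
- **Volume trace**: for forced manoeuvres the cumulative volume-time curve
  is assembled by evaluating the scalar-volume model on growing prefixes
  of the signal (each prefix resampled to N). A directly measured
  `VolumeTrace` is accepted anywhere a trace is needed.
- **FVC** is the trace's final (maximal) value. The non-decreasing quality
  check has a configurable tolerance (default 1 mL for measured traces;
  model-driven traces wiggle at the level of the model's per-prefix error
  and need a looser setting, ~0.25 L).
- **FEV1** is the trace volume one second after exhalation onset. Onset is
  where the volume crosses 2% of the trace maximum — a conventional
  back-extrapolation stand-in — and both the crossing time and the volume
  at onset + 1 s are *linearly interpolated* between samples: snapping the
  onset to the next 9 Hz sample would bias FEV1 by ~2% on an exponential
  manoeuvre, whereas interpolation keeps the closed-form error below 0.5%.
  Times past the trace end clamp to the final volume. FEV1 is reported as
  the absolute trace volume at that time (not volume minus the 2% onset
  offset).
- **FEV1/FVC** is classified per American Thoracic Society thresholds:
  normal at ≥ 0.70 (adults) or ≥ 0.85 (children 5–18); below is "low"
  (obstructive pattern). A ratio ≥ 0.95 (configurable) is flagged
  "high-restrictive-flag" — an elevated ratio accompanies restrictive
  conditions, but no consensus numeric cut-off exists, so the flag marks
  the recording for review rather than diagnosing.

## Numerical choices and degenerate inputs

- All stochastic steps (generation, corpus seeds, ensemble fits, CV
  shuffles) take explicit integer seeds; identical seeds give identical
  bits.
- Detrending is ordinary least squares on the time axis; output mean is
  zero by construction. It is applied before feature construction but not
  before peak counting (peak counting tolerates drift).
- ROI tie-breaks: smallest (y0, x0) lexicographically, which `argmax` on
  the C-ordered variance map provides for free.
- Degenerate inputs raise typed errors (`ConfigurationError`,
  `InsufficientDataError`, `InsufficientSignalError`, `ManoeuvreError`,
  `UndefinedMetricError`) rather than returning sentinel values.
- Problem sizes in the test suite and acceptance script (300-recording
  corpus, 50 ROI stacks, 200 rate replicates, reduced 48×36 frames in unit
  tests) were chosen as the smallest sizes at which the measured
  quantities stabilize.

## Known limitations

- The ROI stand-in assumes breathing is the dominant temporal-variance
  source; specular reflections, moving warm objects or gross head motion
  would defeat it on real video.
- The linear temperature-volume forward model is a test harness, not a
  physiological claim; a real deployment needs per-camera, and plausibly
  per-subject, calibration against a reference spirometer.
- Tree regressors cannot extrapolate outside the training volume range;
  predictions saturate at the envelope edges.
- FEV1 from prefix evaluation inherits the volume model's error at every
  prefix; a flow-integrating sensor model would be more direct.
- No apnea detection, PEF, flow-volume loops, or manoeuvre-acceptability
  grading.
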