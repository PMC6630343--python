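# Methods

This note documents the models implemented in `drivestress`, the parameter
choices that matter, what the synthetic generator does and does not emulate,
and the numerical conventions. It states no empirical result beyond what the
test suite and `scripts/acceptance.py` compute.

## Session model

A session is two uniformly sampled, pre-synchronized traces — single-lead
ECG (mV) and single-axis vehicle acceleration (m/s²) — divided into three
stages: *before* (rest, default 60 s), *driving* (stressful driving, default
500 s) and *after* (rest, default 100 s, completing an 11-minute session).
The first 0.5 s of the recording is discarded as equipment warm-up. The two
traces may have different sampling rates (defaults: ECG 256 Hz,
accelerometer 50 Hz); no resynchronization is attempted.

## R-peak detection

The detector is built for low-quality mobile recordings, not clinical
delineation:

1. **Windowed normalization.** The ECG is z-scored over contiguous,
   non-overlapping windows of `norm_window_s` (default 2 s), each sample by
   its own window's mean and sample SD (n−1 denominator everywhere in the
   package). This removes baseline drift and makes detection invariant to
   absolute QRS amplitude — the property that lets one threshold serve both
   strong young QRS and the weaker elderly morphology. Zero-variance windows
   (flat leads) map to 0 rather than raising. Contiguous windows rather than
   a hopping window are a determinism/O(n) choice; the window length is
   configurable.
2. **Candidate threshold.** Within each stage, samples above the stage's
   mean + 1 SD of the *normalized* signal are candidates. Because the
   normalized signal has near-zero mean and near-unit SD by construction,
   this threshold sits ≈1 normalized unit — roughly 3σ of the residual noise
   when the QRS dominates the window variance.
3. **TWRD max-picking.** Time is tiled into frames of
   `TWRD = 60 / (0.77 · (220 − age))` seconds, anchored at the stage start.
   220 − age is the age-predicted maximum heart rate; 0.77 is the lower
   bound of the vigorous-exercise intensity zone, which a driver cannot
   sustain — so at most one true beat fits in a frame, and the largest
   candidate per frame is kept. The fraction is exposed in `StudyConfig`.
4. **Refractory cleanup.** Two accepted picks closer than
   `60 / (220 − age)` seconds (the maximum-heart-rate period) must be
   duplicate detections of one beat; the larger is kept, and on ties the
   later one is deleted. Keeping the larger matters in one specific failure
   mode: when a QRS tail crosses a frame edge, the spurious duplicate is the
   *earlier, smaller* pick, and deleting strictly by order would clip the
   true apex.

RR intervals are successive peak-to-peak differences (ms), stamped at the
later peak, never spanning a stage boundary.

**RR artifact gate.** Before clustering, driving-stage RR values outside
`[0.5, 1.3] ×` the driving median are excluded as detection artifacts
(a missed beat doubles the apparent interval; a mid-drive instantaneous
heart-rate drop beyond ~30% of the session median is not physiological).
This is standard HRV preprocessing; both factors are configurable and the
gate can be disabled. It matters because the tension threshold below gives
every cluster equal weight, so a singleton artifact cluster would otherwise
displace it.

## Palpitation flagging

Driving-stage RR values are clustered by k-means (Lloyd's algorithm,
k-means++ seeding with a fixed seed and 10 restarts; scikit-learn backend).
`k = 3` by default — low/medium/high tension; the source method leaves k
unspecified. A single tension threshold summarizes the fit:

    threshold = (1/k) Σ_i (μ_i + σ_i)

with μ_i the centroid and σ_i the within-cluster sample SD (0 for
singletons). Two flag directions are provided because the published rule is
ambiguous about sign:

* `above` — RR ≥ threshold (the literal published rule: long intervals are
  "high-tensioned");
* `below` — RR ≤ `(1/k) Σ_i (μ_i − σ_i)`, the mirrored rule, consistent
  with stress physiology (tension = faster heart rate = shorter RR).

The default is the literal `above`; all ground-truth recovery work uses
`below` against planted tachycardic episodes. An alternative clustering
variable — the SD of RR over 30-s windows (SDRR), a standard time-domain
stress index — is available via `rr_mode="sdrr30"`.

Equal cluster weights are deliberate: they let a small high-tension cluster
pull the threshold away from the dominant baseline mass, which is what makes
the rule a usable separator. The cost is sensitivity to artifact clusters,
handled by the RR gate above.

## SDI and CRT

For each flagged RR interval at time `t`, the maximum of |acceleration|
over the closed window `[t − MTW, t]` (MTW default 30 s) is found, at the
time of its first occurrence (ties → earliest, maximizing the lag
deterministically). The acceleration trace is median-centred first, removing
any gravity/DC offset; the method is silent on baseline handling. SDI is the
mean of the per-event maxima (m/s²), CRT the mean of the per-event lags (s).
Events whose lookback window misses the acceleration trace entirely are
dropped and counted; windows clipped at the trace start are computed on the
overlap and flagged. Multiple events may share one acceleration peak; each
is counted (the averaging is per event, not per peak).

## Gradient validation

Per-event maximum accelerations are binned half-open (`[edge, edge+0.1)`)
over 1.0–6.5 m/s² in 0.1 m/s² steps; events outside the range are excluded
but counted. "Gradient" is the difference of adjacent bin counts, and the
threshold estimate is the shared edge of the adjacent pair with the largest
absolute difference (ties → lowest edge). With fewer than two occupied bins
there is no gap to read and the estimate is reported as undetermined — the
method's own caveat, not an error. SDI and GV share the same event→
acceleration mapping, the minimal consistent reading of "validation in the
opposite direction". Both pooled and per-subject use are possible; the
per-subject GV values needed to reproduce the published SDI-vs-GV t-test
were never printed, so that comparison is exercised only on synthetic data.

## Statistics

M/SD summaries use the arithmetic mean and n−1 sample SD (n = 1 reports
SD 0 with a degeneracy flag). The group test is the pooled (equal-variance)
two-sample t, `df = n1 + n2 − 2`, two-sided p from the t distribution, with
a Welch variant available. Pearson's product-moment correlation compares
paired per-subject estimates. scipy.stats provides the distributions.

## Synthetic sessions

The generator emulates a Shimmer3-style in-vehicle recording with every
analysis target planted:

* **RR dynamics** — per-stage baselines defaulting to the published group
  means (elderly 812.29 / 752.87 / 803.36 ms before/driving/after, young
  649.43 / 624.63 / 657.93 ms) plus Gaussian beat-to-beat jitter of 10 ms SD
  (low-normal short-term HRV, appropriate for older adults under load).
  A cardiac episode starts `L` seconds after each burst peak — the RR
  interval in progress at that instant is the first affected — and
  multiplies `tachy_duration_beats` (default 5) intervals by `1 − drop`
  (default drop 0.3); a bradycardic mode (`1 + drop`) provides a positive
  control for the literal long-RR rule. Beat times are snapped to the ECG
  sample grid, so noise-free recovery is exact to the sample.
* **ECG** — each beat renders a Gaussian QRS template (SD 8 ms, ~40 ms
  support) at an age-dependent amplitude (young 1.0 mV, elderly 0.4 mV —
  the weak-QRS contrast), on a zero baseline plus noise. Noise is modeled
  as slow sinusoidal baseline wander (two incommensurate components around
  0.14 and 0.33 Hz, total SD 0.02 mV — the dominant, motion-artifact term
  in a vehicle) plus white sensor noise (SD 0.01 mV). Where a target SNR is
  required, SNR is defined as clean-signal power over total noise power,
  with 80% of the noise budget in wander.
* **Acceleration** — near-zero baseline with white noise (SD 0.02 m/s²) and
  raised-cosine bursts of known peak `A*` (default 3.2 m/s², width 4 s) at
  known times (default: every 60 s during driving), grid-aligned so the
  noise-free maximum is exactly `A*`. A planted-threshold layout
  (`threshold_session_params`) places bursts every 30 s with graded peaks —
  several below a response threshold (no cardiac episode), a dense group
  just above it, a sparse tail higher — so the palpitation histogram carries
  its largest gap at the threshold for gradient-validation recovery.

What the generator does **not** emulate: realistic ECG morphology (P/T
waves, the McSharry ODE family), respiratory sinus arrhythmia, electrode
motion transients, muscle noise, or autocorrelated HRV. Passing recovery
tests therefore demonstrates the pipeline's correctness and its behavior
under amplitude loss and wander-dominated noise — not clinical-grade
performance on real recordings.

## Problem sizes and numerical conventions

Recovery metrics use 20 full 660-s sessions (a grid over
`A* ∈ {2, 3, 4}` m/s² × `L ∈ {8, 14}` s, alternating groups) and three
planted-threshold sessions; detector metrics use 120-s trains at 10 dB SNR.
These sizes keep the whole suite and the acceptance script in the
tens-of-seconds range while giving each mean-error metric 20 independent
sessions. All randomness flows from explicit seeds
(`numpy.random.default_rng`); k-means ties (equidistant points) resolve to
the lower cluster index; fewer distinct RR values than k reduces k with a
flag; degenerate inputs (empty RR, no flagged events, all events dropped)
produce typed empty results rather than exceptions, distinguishing "no
events" from "events unusable".

## Known limitations

* CRT, as defined, averages lags over *every* flagged interval of an
  episode, so it estimates the planted lag plus roughly half the episode
  span (~1–1.5 s under the defaults); it is an upper-biased estimator of
  the physiological onset lag.
* The literal long-RR flag direction contradicts the tachycardic stress
  response; both directions are kept because the source is ambiguous, and
  the ambiguity is surfaced rather than resolved.
* The cluster-summary threshold sits only a few baseline-SDs below the
  baseline RR mass; with elevated short-term HRV it will flag a visible
  fraction of ordinary beats. The published per-subject t-statistics could
  not discriminate between these regimes, since the raw recordings were
  never deposited.
* The per-stage candidate threshold assumes the QRS dominates window
  variance; under white-noise-dominated recordings (SNR ≲ 12 dB with no
  wander structure) frame-level false positives appear — see the noise
  model above for why vehicle recordings are modeled wander-dominated.
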