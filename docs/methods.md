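# Methods

This note documents the models implemented in `figground`, the choices made
where the design was genuinely open, the calibration of the synthetic
cohorts, and what the validation suite does and does not establish.

## Stimulus model

A display of independent fair-coin black/white pixels is partitioned into
three fixed regions: an inner square nested in a square frame, embedded in
the background. On each of two screen refreshes every region's dots
translate coherently by one pixel along the region's direction
(45/135/225/315°). Two rules make the three stimulus kinds statistically
indistinguishable at the level of local motion:

- **No border crossing + refill.** A dot whose displaced position would
  leave its region is dropped; vacated trailing-border pixels are refilled
  i.i.d. Bernoulli(0.5). The refill strip depends only on geometry and the
  displacement magnitude (for diagonal motion on rectangles it is the same
  L-shaped strip whichever diagonal is chosen), so the expected
  "(dis)appearing-dot" flicker is identical across kinds and across
  direction draws. Wrap-around within a region is the main alternative to
  refill; refill was chosen because it reproduces the flicker-equality
  property directly.
- **Direction assignment.** Background direction is uniform on the four
  angles; regions sharing a border always move orthogonally (±90°, fair
  coin). For the stack, the pairwise-distinct constraint then forces the
  inner region opposite (180°) to the background — allowed, as they share
  no border. Orthogonality is enforced on *every* trial (not merely on
  average): each region's marginal direction stays uniform under this
  scheme, so motion energy remains balanced trial-wise, which is the
  stronger reading of the balance claims.

Pixel sizes are the operative geometry; nominal sizes in degrees of visual
angle (17.99°/3.23°/2.42°, offset 7.7°/10.64°, 0.64°/cm at ~90 cm) are
carried as metadata. At a plausible 17-inch 1024×768 pixel pitch those
printed values cannot all be realized on screen simultaneously, so the
pixel defaults (frame 150 px, inner 112 px, offset (−180, +180) px) were
chosen once to fit the screen while approximating the nominal extents; no
audit depends on absolute scale. Monte-Carlo audits run at 0.25× resolution
for speed — direction-share and flicker balance are resolution independent.
The binomial bound with n = number of movies is used for the
direction-share audit; within-movie region directions are dependent, but a
share in [0, 1] with mean ¼ has variance ≤ 3/16, so that bound is
conservative.

## Synthetic TMS-EEG cohort

The recording is additive:
`data = evoked + pink + white + line + blinks + artifact`.

- **Evoked components** are raised-cosine bumps with a Gaussian scalp
  profile (σ = 38° of angular distance from the peri-occipital centroid)
  normalised so the 10-channel pool mean equals the nominal amplitude. Two
  components are injected: a figure negativity (−1.5 µV, 137–211 ms, on
  stack and frame) and a surface positivity (+1.0 µV, 227–313 ms, stack
  only). Per-condition gains encode the TMS effects: early TMS multiplies
  both by 0.2; intermediate TMS leaves both at 1; late TMS halves only the
  surface component. The empirical waveshapes behind these windows are not
  public — the bump is the simplest compactly-supported smooth choice, and
  the amplitudes are calibration constants, not reproductions of measured
  effect sizes.
- **Noise**: 1/f (exponent 1, 9 µV), white (2 µV), 50 Hz line (2 µV,
  random phase per channel), blinks (4/min, 300 ms raised cosine, 150 µV
  on VEOG with a frontal-to-posterior scalp propagation), and a log-normal
  per-subject amplitude factor (log-SD 0.1).
- **TMS artifact**: two pulses 23 ms apart (a 45 Hz double pulse) at
  96/156/236 ms for the early/intermediate/late windows; each pulse is a
  biexponential envelope × 180 Hz damped oscillation peaking at 3 mV
  (≥ 10× any evoked component), truncated at 40 ms so the pair's artifact
  dies inside the −2…65 ms excision window, clipped at ±5 mV.
- **Behavior**: per-condition 3×3 confusion matrices encoding the
  qualitative pattern (early TMS: stack↔frame mix-ups rise, frame accuracy
  minimal; late TMS: selectively more stack→frame errors; any TMS slightly
  lowers homogenous accuracy), log-normal RTs (kind-specific medians
  560–625 ms, log-SD 0.25) with additive per-condition shifts (+32/+33/+51
  ms). A sham flag keeps the no-TMS confusion for all conditions while
  retaining the RT shifts (clicks slow responses but do not change
  accuracy). A "poor responder" profile (near-chance stack detection,
  overall accuracy ≤ 67 %) exercises the subject-exclusion rule.

## Preprocessing decisions

- **Excision + interpolation.** Samples in −2…65 ms around each pulse-pair
  onset are replaced by a *least-squares* cubic spline fitted on 250 ms of
  context per side with interior knots every 6 ms. An interpolating spline
  through every context sample chases single-sample noise and can swing by
  hundreds of µV across the 70-sample gap; the LSQ fit tracks band-limited
  EEG (5 Hz bridge error ≈ 4 % of amplitude) while remaining exact on
  polynomials. Samples outside the window are bit-identical to the input,
  and the interpolated mask is carried to the statistics.
- **Mirror filtering** is realized as reflect-padded forward–backward
  recursive filtering (4th-order Butterworth 0.5 Hz high-pass and 30 Hz
  low-pass, 2nd-order 50 Hz notch): the combination of the filtered signal
  and the filtered time-reversed signal yields exactly zero phase and no
  onset ringing — the defining contract of mirror filtering as used in
  proprietary acquisition software, whose exact combination rule is not
  published.
- **Stage order**: excise → filter → downsample (polyphase 32/131,
  1048→256 Hz exactly) → re-reference to Cz → ocular regression → epoch
  (−200…500 ms; covers the 100 ms baseline and the 200–350 ms window with
  settle margin) → reject (±75 µV, 50 µV/step, on µV epochs because the
  thresholds are potentials; steps across interpolated samples exempt) →
  surface Laplacian → baseline (−100…0 ms) → average → pool.
- **Ocular correction** is Gratton-style regression on blink-rich samples
  (joint least squares over the four EOG channels); component-based
  correction is out of scope because selection criteria cannot be made
  reproducible.
- **Surface Laplacian**: spherical-spline with stiffness m = 4,
  regularization 1e−5, Legendre truncation at degree 50, sphere radius
  0.095 m. The implementation returns the mathematical surface Laplacian
  (eigenvalue −ℓ(ℓ+1)/r² on degree-ℓ harmonics, verified at ℓ = 1); the
  common CSD convention is its negative, and the test suite pins the
  implementation to mne's CSD transform at machine precision up to that
  sign.

## Statistics decisions

- BH-FDR is applied across the tested (non-interpolated) samples of one
  window, one contrast, one TMS condition at a time; pooling families
  across conditions is the main alternative and would only make the
  correction more conservative. A window whose samples are *all*
  interpolated raises an explicit "cannot be tested" error; partially
  interpolated windows are tested on the remaining samples.
- Significant samples are reported as maximal contiguous runs in ms at
  256 Hz; single-sample runs are flagged as such.
- The RM-ANOVA computes the within-subject sums-of-squares decomposition
  from first principles (each effect tested against its effect-by-subject
  interaction); no sphericity correction is applied by default, matching
  the uncorrected df convention (6, 60) at n = 11.
- Zero-variance paired differences are reported as t = 0, p = 1 with a
  warning rather than ±∞.

## Problem sizes and calibration

Two simulation scales are used deliberately:

- The **continuous-recording simulator** (full 1048 Hz pipeline) runs at
  24–48 trials per subject in the validation suite — enough to exercise
  every stage (excision, filtering, rejection, Laplacian) and to measure
  artifact-removal recovery against stored clean ground truth.
- **Statistical recovery and error-control rates** use the ERP-level
  cohort generator (`simulate_pooled_erps`): per-subject pooled condition
  ERPs = injected template × subject factor + band-limited (0.5–30 Hz)
  pink+white residual with per-sample SD 0.2 µV, the residual scale of a
  ~200-trial average after pooling. The residual SD was calibrated by
  simulation so that an 11-subject × 200-trial cohort recovers both
  injected windows (Jaccard ≥ 0.5 against the injected support) in ≥ 90 %
  of replicates, which is the stated design point of the synthetic cohort;
  the FDR level under the null is checked at the same settings and does
  not depend on that calibration.
- The excision-recovery comparison disables the ±75 µV rejection in *both*
  arms: without excision every TMS trial would be rejected outright,
  leaving no ERP to compare, and the comparison is meant to isolate the
  interpolation stage itself.

## What passing tests do and do not show

The simulator matches the statistical structure the analysis assumes —
additivity, stationary colored noise, stereotyped blinks and artifacts,
condition-locked components of known support. Real TMS-EEG data violate
several of these (non-stationary artifacts, TMS-evoked potentials
overlapping in frequency with ERPs, correlated noise across conditions,
drifting electrode impedances). Recovery on these cohorts therefore
validates the *implementation* of the chain and its statistics, not the
physiological claims; the behavioral ANOVA F values on synthetic cohorts
are likewise not calibrated to any empirical effect size. Real-subject
headline numbers from human recordings are out of reach in a purely
synthetic setting and are not asserted anywhere in the suite.

## Known limitations

- No biophysical head model: scalp topographies are parametric Gaussians,
  and the Laplacian is validated analytically rather than against a
  forward solution.
- Ocular correction by regression slightly attenuates genuine frontal EEG
  that covaries with EOG; acceptable here because the components of
  interest are occipital.
- The BrainVision writer emits the minimal multiplexed IEEE-float triplet
  (sufficient for round-tripping through standard readers), not the full
  header vocabulary.
- The behavior sampler is trial-looped Python; at 11 × 2400 trials it runs
  in seconds, but much larger designs would want vectorization.
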