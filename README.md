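# figground

Synthetic TMS-EEG experiments on figure–ground segregation: balanced
random-dot motion stimuli, artifact-aware EEG preprocessing, and
difference-wave statistics — exercised end to end on simulated cohorts with
known ground truth.

## The problem

When a double TMS pulse transiently disrupts early visual cortex (V1/V2) at
different latencies after a motion-defined figure appears, both behavior and
stimulus-locked EEG change in a latency- and stimulus-specific way. Probing
this requires three tightly coupled pieces of machinery:

1. **Stimuli.** Three random-dot displays — *stack*, *frame*, and
   *homogenous* — share identical region geometry and local motion
   statistics and differ only in how many regions segregate from the
   background. Discriminating figure from homogenous requires only figure
   *border detection*; discriminating stack from frame requires *surface
   segregation*. The generator here enforces the balance properties this
   logic rests on: dots never cross region borders, vacated border pixels
   are refilled with fresh fair coins (equal flicker in expectation), and
   every region's motion direction is marginally uniform over
   {45°, 135°, 225°, 315°} (equal motion energy).
2. **Preprocessing.** The mV-scale TMS artifact must be excised (−2…65 ms
   around each pulse-pair onset) and bridged by a spline fitted on 250 ms of
   context *before* any filtering, then the data run through a zero-phase
   ("mirror") 0.5–30 Hz + 50 Hz-notch recursive cascade, downsampling to
   256 Hz, Cz re-referencing, regression-based ocular correction, ±75 µV /
   50 µV-step artifact rejection, a spherical-spline surface Laplacian,
   −100…0 ms baseline correction, and averaging with a 10-channel
   peri-occipital pool (O1, O2, Oz, POz, PO3–PO8). Interpolated samples are
   tracked and excluded from all statistics.
3. **Statistics.** Per-subject difference waves
   `figure − homogenous = ½(stack + frame) − homogenous` and
   `stack − frame` are tested sample-by-sample with paired t-tests
   (df = n−1) inside a-priori windows (80–230 ms and 200–350 ms), corrected
   with Benjamini–Hochberg FDR at q = 0.05; the cumulative statistic
   `Σ_t∈[227,313] (stack−frame)(t)` is compared between TMS conditions;
   behavior gets a from-scratch 3×4 within-subject ANOVA
   (stimulus × TMS window; interaction df = (6, 6(n−1))), RT (100–1500 ms)
   and accuracy (>67 %) filters, and an error-type (confusion) analysis.

Because no raw data from such experiments are public, the package ships a
calibrated simulator (64-channel EEG at 1048 Hz with 1/f + white + 50 Hz
noise, blinks, double-pulse artifacts at 96/119, 156/179 and 236/259 ms,
ERP components injected at 137–211 ms and 227–313 ms with TMS-condition
gains, and confusion-matrix behavior) so every stage can be validated by
parameter recovery against known ground truth.

It is written for cognitive-neurophysiology researchers and methods
developers who need a reproducible, fully testable TMS-EEG analysis chain
or a ground-truthed testbed for ERP statistics.

## Worked example

Recover the injected surface-segregation window from an 11-subject
synthetic cohort:

```python
from figground.synth import simulate_pooled_erps
from figground.stats import contrast_wave, samplewise_fdr_ttest, cumulative_diff_test

times, erps = simulate_pooled_erps(n_subjects=11, seed=7)
sf = contrast_wave(erps[("stack", "none")], erps[("frame", "none")], None, "stack-frame")
res = samplewise_fdr_ttest(sf, times, window_ms=(200, 350), q=0.05)
for iv in res.intervals:
    print(f"significant interval: {iv['start_ms']:.0f}-{iv['end_ms']:.0f} ms")

vals, tests = cumulative_diff_test(
    {c: erps[("stack", c)] for c in ("none", "early", "intermediate")},
    {c: erps[("frame", c)] for c in ("none", "early", "intermediate")},
    times,
)
print(tests.round(3).to_string(index=False))
```

prints

```
significant interval: 242-293 ms
cond_a       cond_b      t     p  n
  none        early  6.518 0.000 11
  none intermediate  1.040 0.323 11
 early intermediate -2.648 0.024 11
```

The FDR-significant interval falls inside the injected 227–313 ms support
(the raised-cosine tails are too small to reach significance), the
cumulative stack−frame difference is reduced by early TMS
(none > early, p < 0.001) and untouched by intermediate TMS (p = 0.32) —
the condition structure the simulator encodes.

The full pipeline (simulate → preprocess → stats) runs from the shell:

```bash
figground run --profile desk --seed 3 --out results/desk
figground simulate --profile tiny --seed 2 --out sim/
figground preprocess --profile tiny --in sim/ --out erps/
figground stats --in erps/ --contrast stack-frame --window 200 350 --out sf.json
```

## Layout

- `figground.stimuli` — region masks, movie generation, balance audits, schedules
- `figground.synth` — montage, ERP templates, noise/artifact/behavior models, simulators
- `figground.preprocess` — excision+interpolation, mirror filtering, the full chain
- `figground.laplacian` — spherical-spline surface Laplacian
- `figground.stats` — FDR t-tests, cumulative statistic, RM-ANOVA, error types
- `figground.design` — exact design arithmetic
- `figground.config` / `figground.pipeline` / `figground.cli` — orchestration
- `docs/methods.md` — models, assumptions, calibration, and limitations
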