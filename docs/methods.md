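# Methods

## The problem

Fluorescence imaging of organs in motion (beating heart, breathing lung)
produces image stacks in which usable, in-focus frames are interleaved with
blurred or badly defocused ones.  Manually culling thousands of frames is
impractical, and reference-frame matching tools both require per-stack
operator input and make binary keep/drop decisions that can destroy the
temporal structure of the recording.  `framepick` instead learns a *numeric
quality score* from a small manually scored sample and uses it to reject or
select frames for the whole stack.

## Quality model

Each frame contributes eleven statistics computed on its pixel grey values
treated as a population: unique grey values, mean, maximum, population
standard deviation, population skewness (Fisher–Pearson, `m3 / m2^1.5`),
population excess kurtosis (`m4 / m2^2 − 3`), Shannon entropy of the exact
integer grey-level histogram (bits), integrated density (Σ I), sum of squares
(Σ I²), and two custom statistics:

* **Sum pixel ramp** — Σ |I(x, y) − I(x, y − p)| over a subsampled lattice
  (stride = comparison offset = p in both axes, first compared row y = p).
  Bright cells have sharp edges; defocus spreads the gradient below the noise
  floor and erodes object peaks, lowering the statistic.
* **Segment intensity deviation (SID)** — the population standard deviation
  of per-segment sampled intensity sums over an R×C grid (default 4×4;
  remainder pixels are absorbed by the last row/column of segments).  Zero
  for a uniform field; large under uneven illumination or partial defocus.

With `normalize=true` (default) the ramp is divided by the number of sampled
comparisons and each SID segment sum by the segment's sampled count.  This
makes both statistics stable under pixel-step changes (and makes the SID of a
uniform image *exactly* zero for any grid despite the y = p sampling anchor
leaving the first segment row one sampled row short).  The normalization flag
and the moment/entropy conventions are recorded inside saved coefficient
files, and scoring warns when statistics were computed under a different
configuration than the model was trained with.

A manually scored sample (0–5 scale, integers or half-points) is fit by
ordinary least squares,

    y_i = β0 + β1 X_i1 + … + βn X_in ,

delegating the fit to `statsmodels` with explanatory variables standardized
internally for conditioning and coefficients reported on the original scale.
Two-sided t-test p-values and the adjusted R² are reported.  In automated
mode, backward elimination repeatedly removes the variable with the highest
p-value above 0.05; if a removal lowers the adjusted R², the variable is
restored and the procedure stops; removing the last variable is an explicit
failure requiring user intervention.  Ties in the worst p-value remove the
variable later in the canonical column order, for determinism.

Calculated scores are deliberately *not* clamped to [0, 5] (cross-set
coefficient transfer commonly range-shifts them); an explicit range
adjustment maps scores affinely onto [0, 5] via
`(C − C_min)/(C_max − C_min) × 5`, preserving rank order.

### Numerical choices

* Zero-variance frames: skewness and kurtosis are defined as 0 (not NaN) so
  constant frames remain scoreable; constant dependent scores fit exactly
  with zero slopes, p-values 1 and adjusted R² reported as 0.
* Aliased explanatory variables are dropped greedily in canonical order with
  a warning.  A column counts as aliased when its standardized projection
  residual against the kept columns falls below 1e−8 of its norm, or when its
  standard deviation is below 1e−12 relative to its magnitude.  The loose
  relative thresholds matter in practice: integrated density is an exact
  multiple of the mean on fixed-size frames *after* 10-significant-digit CSV
  rounding, and a float-rounded constant column would otherwise standardize
  into amplified rounding noise and receive an arbitrary huge coefficient.
* Degenerate range adjustment (all scores equal) maps to 0 with a warning
  rather than erroring, so pipelines continue.
* Correlations are refused (as errors) for zero-variance inputs and fewer
  than 3 pairs; the verbal strength bands for |r| (very weak < 0.20 ≤ weak
  < 0.40 ≤ moderate < 0.60 ≤ strong < 0.80 ≤ very strong) are applied after
  rounding |r| half-away-from-zero to two decimals, since the bands are
  two-decimal.

## Frame selection

* **QA (quality alone)**: retain frames with score ≥ cutoff (inclusive, so a
  frame exactly at the cutoff survives).  Can leave long temporal gaps.
* **FW (frame windowing)**: partition the stack into consecutive windows of
  length n and keep the best frame per window (ties → earliest frame; the
  trailing partial window is kept rather than silently truncating the
  record).  Exactly one frame survives per window, so consecutive retained
  frames are at most 2n − 1 apart — the macro-chronology is preserved.
* **Minimum window**: the smallest n ≤ floor(0.25 N) such that every window
  contains a frame meeting a quality target, found by scanning n = 1, 2, …;
  "not found" is a value, not an error.

## Synthetic benchmark

Real intravital stacks and their human scores are not publicly available, so
the package ships a generator whose output stands in for them in all tests.
It emulates a spinning-disk intravital capture of fluorescently labelled
circulating cells on a 256×256 16-bit sensor region:

| parameter | default | rationale |
|---|---|---|
| cells per frame | 24–30, radius 4–8 px | labelled-cell census during an inflammatory challenge at this field size; positions/counts redrawn per frame (cells circulate) |
| cell amplitude | 12000 over background 4000 | bright label over autofluorescence + camera offset; per-cell ±20% labelling heterogeneity |
| read noise sd | 1500 | EM-amplified camera noise; keeps adjacent-pixel differences noise-dominated, which is what makes normalized custom statistics pixel-step-stable |
| defocus | Gaussian blur, σ ≤ 8 px | out-of-plane motion surrogate; σ drives the ground-truth quality 5·(1 − σ/σ_max) |
| intensity loss | 50% at max defocus | out-of-focus objects lose peak signal |
| illumination | ±2% per frame (an optional zero-mean linear vignetting gradient is off by default) | excitation fluctuation between frames |
| quality profile "runs" | runs of 2–5 frames cycling through four defocus strata (shuffled per cycle) | a cardiac cycle at video rate produces short stretches of similar quality; any ~20-frame prefix then spans the full quality range, as in a real capture |
| simulated rater | true quality + N(0, 0.4), rounded and clipped to 0..5 | inter-rater variability of roughly half a grade |

One deep-defocus run of ≥ 5 frames is guaranteed (the last such run is pinned
near the top of its stratum, extended if all natural runs are shorter), so
every generated stack contains a stretch of genuinely unusable frames for
windowing experiments regardless of seed.

Design notes from the generator study (what the defaults balance):

* The noise-to-edge-contrast ratio trades two requirements against each
  other: pixel-step stability of the *normalized* custom statistics requires
  adjacent-pixel differences to be noise-dominated, while ramp sensitivity to
  deep defocus requires edge gradients to emerge from the noise.  The chosen
  contrast (12000 amplitude / 1500 noise) satisfies both with margin, and the
  cell census is dense enough that the per-frame edge content stands well
  above the sampling noise of the subsampled lattice.
* A background level well above the noise sd matters: with a low background,
  a quarter of background pixels clip at zero and the clipped-noise floor
  (modulated by background drift) becomes the dominant nuisance in the ramp.
* The short quality cycle is what makes a 20-frame training prefix
  *representative*: with long runs, 20 frames hold only two or three distinct
  quality levels, and ordinary least squares on ~10 collinear statistics then
  fits large mutually-cancelling coefficients whose cancellation fails on
  held-out frames — the multicollinearity weakness backward elimination is
  known for.  Even with short cycles a small residual tail remains: across
  random seeds, roughly one benchmark in twenty yields a held-out correlation
  below 0.7 from this mechanism.  Tests therefore quote the benchmark at its
  fixed seed, and the behaviour is inherent to the literal stepwise rule, not
  to the implementation.

What the generator does **not** emulate: lateral displacement and image
shear (frame-level blur is the quality surrogate; registration is out of
scope), photobleaching, vessel geometry, structured autofluorescence, and
rater idiosyncrasies beyond additive noise.  Passing tests therefore
demonstrate the pipeline's correctness and its behaviour under controlled,
realistic degradation — not performance on any particular instrument's data.

## Problem sizes used in tests and the acceptance script

Statistic-level checks run on small frames (≤ 64×64) against brute-force
loop oracles.  Pipeline-level checks use a 50-frame generated population and
the 200-frame standard benchmark; regression training uses 20 and 60 scored
frames, matching the regime where scoring saturates.  Windowing is verified
against exhaustive enumeration on 1000 random score vectors.

## Known limitations

* Backward elimination with α = 0.05 and the adjusted-R² stop is implemented
  literally; it remains vulnerable to multicollinearity on small training
  sets (by design — automated mode is meant to run under user oversight).
* Scores are linear in the statistics; saturating or non-monotone quality
  relationships are outside the model family.
* Coefficient transfer across bit depths or statistic configurations is
  warned about, not prevented.
* Directory stacks are ordered lexicographically; zero-pad numeric filenames.
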