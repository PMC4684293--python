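# Methods

## The motility statistic

A well clip is a stack of `N` grayscale frames (8-bit scale, stored as
float64). The chain is blur → rolling SD → second-order SD → threshold
average:

1. **Blur.** Each frame is blurred independently with a 2-D Gaussian,
   σ = 2 px by default, reflect boundary. "2 pixels" is read as the
   ImageJ Gaussian-Blur σ convention (not a radius). Blurring is purely
   spatial; frames never mix, because the temporal SDs downstream are the
   signal and must not be smoothed away.
2. **σ_FW.** For every pixel, the population SD (divisor `F`) of its
   intensity over each rolling window of `F` frames, step 1 frame,
   giving `W = N − F + 1` window values. Defaults `F = 150`, `N = 250`
   (10 s at 25 fps) give `W = 101`.
3. **σ_S.** Per pixel, the population SD (divisor `W`) of its `W` σ_FW
   values. `W = 1` yields σ_S = 0. Sample SDs (divisor `n − 1`) are
   available behind `sample_sd=True` for sensitivity checks; the defining
   formulas use the population divisors.
4. **WI.** The above-threshold σ_S sum, `T = 30` by default, divided by
   the well's total pixel count (`denominator="all"`, the default) or by
   the above-threshold count TA (`denominator="above"`). If no pixel
   reaches `T`, WI = 0 with TA = 0 — a motionless well, not a missing
   value, so time courses of immobilized larvae stay plottable.

**Why two denominators exist.** The two readings answer different
questions: Σ/TA is the mean intensity of whatever motion survived the
threshold (intensive; confined to {0} ∪ [T, σ_S max] ≈ [30, 64] on 8-bit
data), while Σ/N_pixels measures *total* motility (extensive; continuous
down to 0). Only the extensive reading can produce WI values well below
the threshold and relative-motility ratios that decay smoothly toward 0
as larvae stop moving — the behaviour the downstream statistics assume —
so it is the default. The intensive variant is retained because the
formula is sometimes quoted with TA as the denominator.

**What σ_S responds to.** SD-of-SD is blind to *stationary* motion: an
object oscillating steadily for the whole clip gives nearly identical
σ_FW in every window and hence σ_S ≈ 0. With `F/N = 150/250`, window
starts span only the first 40% of the clip, so σ_S is driven by activity
asymmetry between the early and late clip — bouts of movement that start,
stop, or relocate an animal. This also explains the threshold's power
against global disturbances: spatially uniform flicker gives every pixel
the same modest σ_S, which `T` removes wholesale.

**Numerical choices.** All statistics are computed on the stack after
subtracting each pixel's first-frame value — mathematically a no-op for
SDs, numerically a conditioning step that makes invariance to a uniform
intensity offset bit-exact on integer-valued input when blurring is off
(with the blur, offsets commute only to ~1e-13 because the convolution
rounds differently). The rolling SD uses an explicit two-pass
mean/SSD per window (101 vectorized passes) rather than a cumulative-sum
identity, avoiding the catastrophic cancellation that sum-of-squares
tricks suffer near zero variance.

## Imaging conventions

- Frames sort by natural-numeric order of their filenames (`frame_2`
  before `frame_10`); RGB converts to grayscale with BT.601 luma weights
  implemented as integer ratios `(299 R + 587 G + 114 B)/1000`, which maps
  already-gray pixels exactly to themselves.
- Intensities stay on the native 0–255 scale; `T = 30` is calibrated to
  8-bit σ_S magnitudes.
- Wells are axis-aligned rectangles, 0-based half-open pixel ranges; the
  crop is the full rectangle (no circular mask), matching how wells are
  cropped out of 4-well videos in practice.
- Heat maps are written by applying a colormap directly to the σ_S array
  (no figure machinery), so identical fields give byte-identical PNGs; the
  color scale is documented in a JSON sidecar. Raw σ_S maps can also be
  exported as 32-bit float TIFF.

## Response statistics

- **RMR** divides each well's WI(t) by the same well's WI(0). Wells whose
  baseline WI is 0 are excluded with a logged reason (the ratio is
  undefined); the exclusion is an error type (`BaselineZeroError`), never a
  silent NaN.
- **Group summaries** are per-time-point means with Student-t 95% CIs
  across wells (CIs need ≥ 2 wells; a single well reports a mean and an
  unavailable CI). CIs are across wells, not across plates.
- **Response Time** is evaluated on the sampled grid only (no
  interpolation): the earliest post-treatment sample whose mean + CI
  half-width < 1 with every later sample also qualifying ("significantly
  and irreversibly"). If none qualifies the result is censored as
  `> t_max`.
- **End Point RMR** is the final sample (240 min on the default grid);
  groups are compared with Tukey's HSD at α = 0.05 (statsmodels), which
  adjusts within its own family.
- **GLM β.** Per well, ordinary least squares of WI on g(t) with g the
  identity or log10(t + 1); the +1 keeps the t = 0 baseline point, which
  the raw log10 would drop. `auto` picks the transform with the larger
  adjusted R² = 1 − (1 − R²)(n − 1)/(n − 2), ties going to the identity.
  β = −slope, so stronger declines give larger positive β; the reciprocal
  reading 1/slope is exposed as `beta_convention="reciprocal"` but
  rejected as a default because it would map steeper declines toward 0.
  A constant response has slope 0 and, by convention, R² = 0 (no variance
  to explain). Gaussian-identity least squares is the model; no other
  family or link is implied by the data. β t tests against the control
  are reported unadjusted, with an optional Holm flag; degenerate
  (zero-variance) comparisons report the statistic as unavailable rather
  than fabricating p = 0 — except a group literally identical to the
  control, which is t = 0, p = 1.

## Synthetic data

The scene generator emulates what the camera sees: a bright liquid-filled
well disc (intensity 250) on a dark plate background (20), containing
dark elongated larvae (10) of semi-axes 16 × 3 px — a ~5 mm third-instar
larva in a ~15 mm well imaged 120 px across — 25 per well, 250 frames at
25 fps by default, with optional global flicker (uniform per-frame
intensity offset), Gaussian pixel noise, rounding to whole 8-bit levels,
and clipping to [0, 255]. A `mini_scene` preset (48 px, 5 larvae, 30
frames, pair with `F = 12`) keeps structural tests fast.

**Motion model.** Because σ_S only registers non-stationary activity (see
above), larvae are animated as bout-structured gyration, which is also
what real larvae do: each larva performs 1–2 bouts at random times; during
a bout it jitters (sharpened-sine oscillation — real strokes are jerky,
with dwell at the extremes, which a pure harmonic underrepresents), turns,
and lunges to a new resting pose. The `amplitude` knob (px) scales the
jitter excursion, the turn angle and the lunge distance (~1.8–3.2 ×
amplitude^0.8 px per lunge, lunge speed growing with amplitude so vigorous
animals relocate crisply); bout times, directions and frequencies are
drawn independently of amplitude, so scenes differing only in amplitude
share their bout structure. Under this model the default render yields a
WI that increases strictly with amplitude over {0, 1, 2, 4, 8} px for the
overwhelming majority of seeds (16/16 in the design-validation sweep).

What the generator does **not** emulate: peristaltic body deformation,
optical effects (shadows, refraction at the meniscus, motion blur),
compression artefacts, or larvae interacting. Passing tests therefore
demonstrate that the pipeline recovers known motion differences under
idealized imaging, not that it is robust to every artefact of real
footage.

**Time courses.** `DecaySpec` draws per-well WI series on the assay grid
(0, 5, 10, 15, 30, 45, 60, 120, 240 min): `none` is constant at the
baseline (default WI 10); `fast` drops at onset (default 5 min) toward a
dose-dependent plateau (default fraction 0.3, exponential τ = 5 min, with
half the drop landing instantly at onset so noiseless detection at the
onset sample itself is possible); `slow` holds baseline until a late
onset (default 45 min) then declines to a dose-independent plateau
(fraction 0.4, τ = 30 min). Noise is i.i.d. Gaussian per sample (default
SD 5% of baseline), truncated at 0. These defaults mirror the two
empirical response classes the assay distinguishes: rapid dose-dependent
collapse versus delayed decline to a common level.

## Problem sizes used in the test suite

Oracle-equivalence checks run on stacks up to 16 × 16 × 20 against a
triple-loop reference (tolerance 1e-9). The amplitude-monotonicity and
flicker-suppression checks run on the full default render (120 px wells,
250 frames, `F = 150`, `T = 30`). Ground-truth recovery uses 100 seeds of
10-well fast/slow ensembles at 5% noise; transform selection uses 200
replicates at noise SD 1. The full suite runs in well under five minutes
on one CPU.

## Known limitations

- The Response Time definition inherits the granularity of the sampling
  grid; between-sample onsets are reported at the next sample.
- WI is deliberately aggregate: it counts no larvae and tracks no
  trajectories, so per-animal phenotypes are out of reach.
- The σ_S statistic's sensitivity depends on `F/N`; with the default
  150/250 it is maximally sensitive to activity changes near the start or
  end of the clip and blind to perfectly steady motion. This is a
  property of the published statistic, reproduced faithfully, not of this
  implementation.
- Dose–response curve fitting (EC50), survival analysis and mixed-effects
  models across plates are out of scope.
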