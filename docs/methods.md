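# Methods

This note records the models, conventions and numerical choices behind
`conchvision`, in the spirit of a methods appendix.  Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Viewing geometry and expansion profiles

An object of physical width *w* at viewing distance *D* (default 50 mm,
the experimental distance; perpendicular viewing) subtends
`α = 2·arctan(w / 2D)`; `physical_width` is its exact inverse.  Pixel
sizes follow from the configured pixel pitch.  The display hardware of
the original experiments (pixel pitch, panel model) is unreported, so
absolute pixel sizes are configuration-dependent; the default pitch of
0.25 mm/px is typical of a desktop LCD at this scale, and the default
frame is 256 × 256 px, large enough to hold the whole checkerboard and
most of the loom while keeping rendering tests fast.

Two angular-size trajectories cover the two experiments, both reaching
α_max = 83 deg exactly at the end of the presentation:

* **linear** (resolution experiment, T = 5 s): `α(t) = α_max · t/T`;
* **exponential** (contrast experiment, T = 10 s):
  `α(t) = α_0 · e^{gt}` with `g = ln(α_max/α_0)/T`.

The trajectories are defined on angular size, matching the quantitative
presentation of event angles against the expansion curves (the
alternative reading — that stimulus *area* grows exponentially/linearly
— cannot be reconciled with those curves and is not implemented).  The
exponential ramp cannot start at 0 deg; α_0 defaults to the angular size
of one display pixel, the smallest renderable object (~0.3 deg at the
default geometry).  `α_0 = α_max` degenerates cleanly to a constant
trajectory.  The frame rate defaults to 60 fps, a common LCD refresh;
it only affects how densely sequences are sampled, not any analysis.

The cylindrical experimental vessel (radius 60 mm) is recorded in the
configuration but its refraction is not modelled; along the curved
plane it can only make a measured resolution a limiting (conservative)
value, and no optical model of the wall is available.

## Display model and photometry

Byte values map to relative luminance through `L = (b/255)^γ`.  The
default γ = 1 treats bytes as linear luminance; this is the convention
under which the byte series 0…230 against background 255 produces the
contrast labels 1.00 down to 0.05, including 0.07 (byte 220) and 0.10
(byte 210).  The documented grey byte of 153 as the isoluminant point
of a 0/255 checkerboard is *not* consistent with γ = 1 (which gives
127/128); it implies a non-linear display with γ ≈ 1.357.  Both facts
cannot hold at once for a single γ, so γ is exposed as configuration
with 1 as default, and `isoluminant_grey` reproduces 153 when given the
non-linear γ.  Contrasts are computed unrounded and rounded to two
decimals only for labelling.

Ties in the isoluminant-grey search (two bytes equally close to the
target luminance) break toward the lower byte — hence 127, not 128,
for the linear display.

Rendering conventions: the stimulus disc is centred on the frame; the
checkerboard is anchored with a black check at the frame's top-left;
check pixel width is the rounded pixel equivalent of the requested
angular width and must be ≥ 1 px (otherwise a configuration error names
the level).  With the calibrated grey, the frame's mean mapped
luminance is invariant over the expansion to well under 0.5 % when the
checks tile the frame evenly; a check width that does not divide the
frame leaves a partial row/column whose black-white imbalance adds a
further ~0.5 % — a property of the finite frame, not of the stimulus
design.

## Eye optics

* **Inter-receptor angle**: Δφ = s/f (small-angle form), s = rhabdom
  centre separation, f = focal length.  At anatomical magnitudes the
  difference from arctan(s/f) is < 1e-4 deg; a warning is raised if
  s/f > 0.1 rad.  Focal length may be supplied directly or checked
  against the f = 2r spherical-lens convention.
* **Angular resolution**: 2Δφ.  The *reported* figure follows the
  field's printing convention of doubling the already-rounded Δφ
  (0.52 deg → 1.04 deg); the exact product (1.0345 deg) is available
  separately as `anatomical_resolution`.  Tests and the acceptance
  script use the reported chain.
* **Optical sensitivity**:
  `S = (π/4)² A² (d/f)² (1 − e^{−kx})` with aperture A, rhabdom
  diameter d and length x, absorption coefficient k = 0.0067 µm⁻¹ (a
  crustacean rhabdom value commonly borrowed for molluscs).  The
  alternative absorption form `kx/(2.3 + kx)` is not used; it is
  inconsistent with the sensitivity figure the measured anatomy is
  known to produce (7.78 µm² sr).
* **Census extrapolation**: per-eye totals are
  `count · total_area / sampled_area`, rounded to the nearest 100
  cells; densities are reported unrounded (per mm²) and totals from
  densities to 3 significant figures.  Areas are stored in µm².  Note a
  unit pitfall in the source material: the sampled block-face area is
  printed as 2.048×10³ mm², which is dimensionally inconsistent with
  the extrapolation it supports; the correct value is
  2.048×10⁻³ mm² = 2048 µm² (204.8 µm block-face width × 10 µm of
  100-nm sections), which this package uses.
* **Acuity blurring**: Fourier filtering with
  `MTF(ν) = exp(−3.56 (α_min ν)²)`, ν in cycles/degree.  The constant
  3.56 sets contrast at the frequency `1/α_min` to e^(−3.56) ≈ 2.8 %,
  following the established acuity-visualisation convention.  The DC
  component is untouched (mean luminance preserved to machine
  precision); variance never increases.

## Trials and scoring

The ethogram has five ordered categories: stop feeding, partial/full
proboscis withdrawal, partial/full eyestalk withdrawal.  A trial counts
as a **response** only if some transition beyond stop-feeding occurred;
stop-feeding-only trials are excluded as likely false positives.  The
unit of analysis is the trial (individual × repeat), giving responder
denominators of 40 (20 × 2, contrast) and 38 (19 × 2, resolution); a
per-individual collapse (responded in ≥ 1 repeat) is available but not
default.  Event times are interchangeable with angular sizes through
the expansion profile, which supports summaries such as the fraction of
transitions occurring after the stimulus exceeded a given angle.
Re-emergence times are aggregated per level by the median (the
aggregator behind published per-level figures is not specified; the
median is robust at n ≤ 40 and configurable).

## Threshold inference

Per level, responder counts get Wilson score intervals (via
statsmodels).  Each level is compared with the control by Fisher's
exact test, two-sided under the probability-mass rule (sidedness is
configurable; the original analysis does not state it, and without the
control's raw responder count its printed p-values are not recoverable
either way — the implementation is instead validated against exhaustive
hypergeometric enumeration in the tests).  Bonferroni family size m
defaults to the number of non-control levels: 9 for the contrast
series, 8 for the resolution series.  The threshold is the smallest
level with adjusted p ≤ α (default 0.05) — detection requires
statistical significance against control, not merely any response —
and for the resolution experiment α_min = 2 × threshold check width.
If no level is significant, the result is an explicit no-threshold
outcome rather than an extrapolation.

Spearman correlations use average ranks; p-values are exact two-sided
permutation probabilities (full enumeration) for n ≤ 9 — the regime of
the per-level summaries here — and the t-approximation above.  The
paired Wilcoxon repeat check uses V = sum of positive-difference ranks,
exact p for n ≤ 15 without ties, normal approximation otherwise.

The model surface follows the statsmodels idiom:
`DetectionThresholdModel.from_trials(...)` → `fit()` →
`DetectionThresholdResults` with `summary()`, `plot()`, `to_dict()`.

## Synthetic observers

The generator emulates the *structure* of the behavioural data, not any
particular animal's numbers:

* log-normal psychometric core
  `P = g + (1 − g − λ)·Φ((ln level − ln θ)/σ)`; the log-level scale is
  natural because both level series span about a decade.  A logistic
  core would be an acceptable alternative behind the same interface.
* guess rate g (default 0.02) is the control's response probability; no
  spontaneous-response rate is published, so this is a synthetic
  convention, as is the lapse rate λ = 0.02.
* between-individual variation: ln θ_i ~ Normal(ln θ, 0.15) by default,
  a ±15 % threshold spread typical of small-n psychophysics.
* responding trials receive an escalating event sequence (stop feeding
  first; severe withdrawals only late in the expansion, placed by
  mapping sorted angular positions through `time_to_reach`) and a
  re-emergence time `max(0, base + gain·ln(level/θ) + noise)`;
  non-responding trials are eventless or, with probability 0.15,
  stop-feeding-only — exercising the scoring exclusion.  The timing
  distributions are synthetic conventions; only their ordering
  constraints mirror real withdrawal sequences.
* determinism: one root `SeedSequence` spawns a substream per
  individual, so tables are bit-reproducible from the seed and
  per-individual draws do not depend on iteration order.

Default designs reproduce the study conditions: nine contrast levels
(the byte-series contrasts) + control at 20 × 2 trials; eight check
widths + control at 19 × 2.  Only the endpoints (0.3, 3.2 deg) and the
threshold-adjacent member (0.53 deg) of the check series are published;
the intermediate widths {0.4, 0.8, 1.1, 1.6, 2.2} are a fixed
convention chosen once to spread roughly geometrically across the
range.

What passing tests show — and what they do not: recovery tests
demonstrate that the pipeline identifies the smallest designed level
above a simulated observer's threshold (exactly in the deterministic
limit, modally over 200 replicates for a stochastic near-threshold
observer at the study's sample size).  They do not validate the
published response probabilities, correlations or p-values, which
depend on unreleased animal data; the printed ρ ≈ 0.9 values are
mirrored only qualitatively by monotone generators.

## Problem sizes and numerical conventions

Simulation-based checks use the study's own sample sizes (≤ 40 trials
per level, 200 replicates for modal recovery); rendering tests use
256 × 256 px frames.  Angles are reported to 2 decimals, per-eye cell
totals to the nearest 100, densities to 3 significant figures.
Wilson bounds are clamped to [min(p̂,·), max(p̂,·)] ∩ [0, 1] to absorb
floating-point excursions at k = 0 and k = n.  Exact enumeration
comparisons in the tests use a relative guard of ~1e-12 when comparing
probability masses, the standard tolerance for "≤ observed" rules under
floating point.

## Known limitations

* The monitor calibration of the original experiments is unknown; the
  γ = 1 and γ ≈ 1.36 readings of the published byte values cannot be
  unified, and rendered stimuli are faithful to whichever display model
  the user configures, not to the original hardware.
* Fisher-exact p-values versus control cannot be compared with the
  published ones (control responder counts unpublished).
* Refraction by the cylindrical vessel wall and retinal features beyond
  the sampled block face (e.g. density gradients across the retina) are
  outside the model.
* The expansion profiles are deterministic; presentation-timing jitter
  and habituation across repeats are not modelled (no repeat effect was
  found in the original data, and none is generated).
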