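# Methods

This note records how `stimchar` defines its quantities, which choices
were genuinely open, and what the synthetic-data generators do and do
not emulate.

## Object mask

Stimulus databases of this kind standardize photographs onto a white
background, so "the object" is operationalized as every pixel that is
not white. White is never exactly 255 in practice (JPEG ringing,
anti-aliased borders), so a pixel counts as background iff **all three
channels ≥ `white_threshold`**, default **250**. The default tolerates
codec noise near the background while keeping near-white objects
(whipped cream, egg white) in the mask; it is configurable per run and
echoed into every output so results are reproducible from their
metadata. Raising the threshold can only grow the object set, which
the suite checks as a monotonicity property. Alpha channels are
composited over pure white before masking.

## Luminance

Gray conversion uses the Rec. 601 weights 0.2989/0.5870/0.1140 and
keeps fractional values on the 0–255 scale — no integer quantization —
so object means and SDs downstream are exact. The conversion is linear
and scale-agnostic (uint8 or 0–1 floats).

## Photometric metrics

- **Color contribution** is proportion-of-sums: channel sums over the
  object divided by the grand sum. The alternative (mean of per-pixel
  proportions) is ill-conditioned on near-black pixels, where single
  count differences flip the per-pixel proportion; both readings agree
  on uniformly colored objects. An all-black object carries no chroma
  information and reports (1/3, 1/3, 1/3) by symmetry.
- **Brightness** is 255 − mean object luminance, so the darkest (most
  salient) objects score highest.
- **Contrast** is the population SD (divisor n) of object luminance;
  this makes the two-pixel {0, 255} case exactly 127.5 and is the
  convention of array libraries operating on full populations. A
  `ddof=1` switch gives the sample convention.

## Spatial-frequency summary

The 2-D FFT is taken over the **full frame including background**,
with no windowing or padding: the statistic is a property of the image
as presented, and masking or tapering would entangle it with the
object segmentation. Power is the squared modulus of the centered
transform. Radial bins collect coefficients by **integer-rounded
Euclidean distance** from DC and average within the bin; bins beyond
⌊min(H, W)/2⌋ mix partially sampled annuli (frame corners) and are
discarded. The scalar summary is the **median of the radial bin values
with DC excluded** — including DC would make the statistic an alias
for mean luminance rather than spatial structure. Two strict-literal
switches exist: `include_dc=True`, and
`median_power_all_coefficients`, which takes the median over all raw
2-D coefficients instead of radial bins (the phrase "median across all
spatial frequencies" admits both readings; the bin median is the
default).

Sanity anchors: Parseval's identity (non-DC power = N² × pixel
variance) holds to 1e-6 relative on every fixture; a k-cycle grating
puts the radial argmax exactly at bin k for k = 2..32 at the standard
600 × 450 size.

## Complexity

Canny edge detection with σ = 1.0 and hysteresis thresholds 0.1/0.2
expressed as **fractions of the maximum gradient magnitude** of the
smoothed frame, so parameters mean the same thing regardless of the
image's intensity scale. The detector is scikit-image's Canny behind
the module surface; an independently written scipy-only Canny
(quantized non-maximum suppression, connected-component hysteresis)
serves as a cross-check in the tests and agrees within ±10% edge count
on solid shapes. The two implementations diverge more on dense
checkerboards, where interpolated versus sector-quantized suppression
treats the four-cell corner saddle points differently; for such
stimuli the suite asserts the behavioral ordering (textured object >
equal-area solid object under both detectors) rather than count
agreement.

**Complexity** is edge pixels / frame pixels. **Normalized
complexity** is edge pixels / object pixels (= complexity / size), the
dimensionally consistent reading of "edge proportion scaled by object
size"; a strict-literal mode divides the edge *proportion* by the raw
object count instead, a frame-size-dependent quantity kept only for
comparability with legacy scripts. Note that neither variant is
invariant under magnification: outlines grow linearly with object side
while area grows quadratically, so the normalized measure falls
roughly as 1/side (verified at sides 50/100/200, halving within ±15%).
We implement and document this behavior rather than substituting an
unstated scale-invariant statistic such as perimeter/√area.

## Nutrition

Portion totals scale per-100 g values by portion mass; a missing mass
yields NaN totals flagged unavailable (never silently zero), and a
zero mass is an error. The caloric-density split takes the median of
kcal/100 g over food records; **ties go to "low"** (density ≤ median),
a deterministic rule chosen so reruns reproduce the same split. The
even-count median is the mean of the central order statistics. Missing
densities propagate as missing and are excluded with a logged count.
`coder_agreement` exposes plain Pearson correlation for
cross-validating double-coded metadata.

## Norms

Raters are included when they have **complete** ratings (both
dichotomous items plus all applicable VAS scales) on at least
`min_food_images` food images (default 3). Aggregation reports
mean/SD/n per VAS scale and percent-yes per dichotomous item, per
image, overall and per subgroup level; subgroup cells partition the
overall n for any partitioning factor, which the suite checks.

Category contrasts average each participant's ratings within each
image group and run a paired *t*-test across participants
(df = n − 1). Published effect sizes for such designs are reported
under more than one convention, and the conventions disagree
numerically, so the result carries both **d_z** (mean difference /
SD of differences = t/√n) and **d_av** (mean difference / average of
the two group SDs), explicitly labeled. Hunger is averaged across the
pre- and post-survey items, falling back to the available one with a
single-source flag.

## Matched-set selection

Balance is measured as the absolute standardized mean difference per
feature, standardized by the **pooled SD of the full candidate pool**
(a denominator that does not move while subsets change), and the
objective is the **maximum** over features and condition pairs — a
minimax criterion guaranteeing no single feature stays badly
unbalanced. Two-condition instances with ≤ 10⁶ subset pairs are solved
**exactly by enumeration** (vectorized; deterministic); larger
instances fall back to seeded random starts with steepest-descent swap
hill-climbing, whose neighborhood includes simultaneous swaps in both
conditions — single swaps alone plateau far from the optimum under a
max-type objective. Constant features are excluded with a warning.
Determinism: identical input and seed give identical selections.

## Synthetic data

**Images.** Parametric objects (squares, disks, checkerboards,
composites, full-frame sinusoidal gratings) on a white canvas
defaulting to 600 × 450 px, the standard resolution of the databases
this toolkit targets. Ground truth — the exact object pixel set, size
fraction, and closed-form luminance mean/SD — is derived from the spec
parameters, not measured from the rendered image, so metric tests are
genuinely two-route. Fixtures are written as lossless PNG by default
(mask recovery is exact); a JPEG mode (quality 95, 4:4:4 sampling)
exercises threshold robustness against codec noise. Synthetic stimuli
are geometric, not photorealistic: they validate the arithmetic and
the pipeline, not the distribution of metric values over real food
photographs.

**Nutrition.** Macronutrients drawn uniformly (protein 0–25,
carbohydrate 0–70, fat 0–35 g/100 g); energy density follows the
Atwater factors 4/4/9 kcal/g plus optional Gaussian noise, floored at
0. Category labels use pool proportions typical of a western food
image set (about 13% fruit, 21% vegetables, 11% chocolate, 11% meat,
38% mixed/other; 43% sweet vs. 39% savory; 32% processed vs. 67%
whole).

**Surveys.** The default design mirrors a four-sample online survey
totalling 1988 raters (638 + 831 + 496 + 23) over 568 food and 315
non-food images, with per-sample quotas (80/40, 40/25, 35/17, 35/5
food/non-food images per rater), demographic compositions (gender,
diet style, dieting status, age and BMI distributions per sample), and
per-sample completion rates; partial completers rate a random fraction
of their quota. Responses are latent per-image means plus injected
subgroup effects plus normal noise, rounded and clamped to integers in
[1, 100] — the VAS digitization used by such surveys. Default injected
effects: men +8.3 on desire to eat, vegetarians/vegans −36.5 on meat
palatability and −23.8 on meat desire, and a linear hunger slope of
0.4 VAS points per hunger point on desire (hunger ~ N(28.5, 25.4)
truncated to [1, 100], averaged across a pre and post item). What the
simulation does **not** emulate: per-participant response styles
(anchoring, acquiescence), item nonresponse within a page,
culture-specific food familiarity, and any dependence of ratings on
the physical image metrics — so passing recovery tests validates the
estimators, not claims about real populations.

## Test problem sizes

The suite runs the statistical calibration at reduced scale chosen so
the whole battery stays quick while Monte-Carlo error stays inside the
asserted bands: 2000 null surveys of 40 raters × 12 images (8 rated
each) for the 5% ± 0.7% type-I check; 400 raters for the effect- and
slope-recovery checks (asserted within 3 standard errors of the
closed-form values); 5 pools of 12 + 12 candidates (subsets of 4)
against exhaustive search, plus 24 + 24 pools for the heuristic path.

## Known limitations

- The white threshold is a global channel rule; objects containing
  genuinely white interior regions (≥ 250 on all channels) lose those
  pixels from the mask.
- Median spectral power at the default setting depends on frame size
  through the radial bin count; compare images at a common resolution.
- The swap heuristic does not certify optimality outside the exact
  enumeration regime; `MatchResult.tolerance_met` reports whether the
  requested balance was reached.
- Nutrition values are metadata supplied by the user (or the
  generator); the toolkit does not estimate nutrition from images.
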