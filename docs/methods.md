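# Methods

## Colour model

All colour arithmetic uses the hexcone HSV model on decoded sRGB pixel
values with no colour management (the photographic protocol this tool
targets controls illumination physically, with a light tent and fixed
camera settings, rather than by calibration). Hue is a colour-wheel
fraction in [0, 1) — 0 red, 1/3 green, 2/3 blue — because the reference
phenotype intervals are published as fractions (e.g. 0.1625770), not
degrees. Saturation is (max−min)/max and value max/255.

Achromatic colours (r = g = b) have no hue. They are represented as
h = 0 with an explicit `achromatic` flag rather than a sentinel value;
every consumer that reads a hue must check the flag, and classification
maps achromatic samples to "other". This prevents greys from silently
landing in the red interval, which starts at 0.

`hsv_to_rgb` quantises with round-half-up to 8 bits. The forward
conversion accepts real-valued channels so that foreground channel
*means* are converted without an intermediate re-quantisation; the only
8-bit rounding in the pipeline is the one the image format itself
imposes. Consequences: on lossless noise-free fixtures the recovered
HSV sits within one quantisation step of the generating HSV
(empirically |Δh|, |Δs| ≤ 0.01 and |Δv| ≤ 0.005 at the default
saturation/value levels), and results are bit-reproducible.

## Background policy

The whiteness rule is min(r, g, b) ≥ τ, with τ = 240 by default and an
optional explicit white-list of hex codes. Pure white (#FFFFFF) is
background under every admissible τ. The threshold exists because JPEG
compression surrounds pasted regions with near-white halos; τ = 255 is
the right setting for lossless fixtures and is what the test suite
uses for exact assertions. Masking happens in RGB before any HSV
conversion, and deleting the background (replacing it with pure white)
is idempotent under the same policy.

The rule is a design choice: the original workflow compared pixels to a
white reference set whose contents are not published. A single
min-channel threshold reproduces its observable behaviour on both
lossless and JPEG inputs and is exposed as a configuration knob
(`--white-threshold`, `--white-list`).

## Phenotype ranges and learning

Classification intervals are closed at both ends, so a published
endpoint such as 0.1625770 classifies as its own phenotype. Intervals
must be pairwise disjoint; a `wrap` flag supports intervals crossing
the 1.0 → 0.0 seam (physically possible for reds, unused by the
published ranges, whose red mass sits at 0 without wrap).

The published ranges were derived from five selected individuals per
phenotype by an unspecified learning procedure. Here the rule is the
min–max envelope of the per-image mean hues of the training set — the
simplest rule consistent with closed printed intervals. This is an
interpretation, flagged as such: per-pixel extremes or a margin-padded
envelope would give wider ranges. The rule guarantees resubstitution
consistency (every training sample classifies back to its own label),
order invariance, and monotone stability (adding an interior-hue image
changes nothing). It is packaged as a scikit-learn estimator
(`HueRangeClassifier`) so ranges can be fitted, cloned, cross-validated
and persisted like any classifier; fitting fails when the learned
envelopes overlap.

## Statistics

- **Distinct hues** require a quantisation rule, which the source
  material leaves implicit; hues are rounded to 4 decimals by default
  (dominant hues are customarily printed at 2–4 decimals), exposed as a
  parameter. The diversity index is distinct hues / samples, counted
  over *all* samples of a group, consistent with published totals (138
  hues among 363 pearls).
- **Yates χ²** uses the closed form
  N·(max(|ad−bc|−N/2, 0))²/((a+b)(c+d)(a+c)(b+d)) with the correction
  clamped at zero, so near-independent tables cannot gain evidence from
  over-correction; p is the upper χ²₁ tail. The statistic never exceeds
  the uncorrected Pearson statistic and is invariant to row/column
  swaps. The implementation is cross-checked against
  `scipy.stats.chi2_contingency` in the tests.
- **Wilcoxon rank-sum** p-values are exact (full enumeration, via
  `scipy.stats.mannwhitneyu`) when the combined sample size is ≤ 20 and
  tie-free, otherwise the normal approximation with tie and continuity
  corrections. Two samples with all values identical are degenerate:
  p = 1 with a warning. The corrected normal approximation tracks exact
  enumeration to within ≈ 0.03 in the worst case over tie-free 4+4
  splits (the worst gap occurs mid-distribution, far from any
  significance threshold); the regression suite pins 0.04 as the bound.
- **Shapiro–Wilk** is reported as a screen only; no downstream
  branching depends on it, and constant samples are rejected as
  undefined.
- **Dominant hues** are local maxima of a Gaussian KDE (Silverman's
  rule) evaluated on a 512-point grid over [0, 1] with boundary
  reflection, so a red mode exactly at hue 0 is detected. Hue
  circularity is *not* modelled: published hue distributions are
  plotted on a linear axis and red mass sits at 0 without wrap. Peaks
  are filtered by prominence measured in probability-density units on
  the unit hue axis (uniform density = 1); the default threshold of 0.5
  sits well above the sampling wiggles of featureless distributions
  under Silverman bandwidths while passing the saddle depth of genuinely
  bimodal hue data. Results are ordered by density height.
- All p-values are two-sided. No multiple-testing correction is
  applied across the pairwise comparisons; reports are per-comparison
  and users performing many comparisons should correct accordingly.

## Synthetic data

The generator emulates the tool's real inputs — pre-clipped coloured
regions on white — not the photographs themselves. Regions are uniform
discs (pearls) or annulus sectors (shell margins) of a known HSV, with
optional i.i.d. Gaussian channel noise (clipped to [0, 255]) and either
lossless PNG or JPEG encoding; JPEG mode exists specifically to
exercise the near-white halo problem that motivates τ. Cohorts draw
per-sample H, S, V from independent clipped normals; depth effects are
additive shifts on the saturation and value means. Every sample's exact
HSV, foreground pixel count and seed are recorded in a truth CSV, and
identical spec + seed reproduce identical bytes.

The default study layout mirrors the published experiment: donor-shell
groups GS/GD/RS/RD of 9/6/5/7 and matched pearl groups
GPGS/GPGD/RPRS/RPRD of 132/66/84/118, green hues centred at 0.45 and
red at 0.05 (inside the published intervals), saturation 0.55 ± 0.08
and value 0.65 ± 0.08, with the deep (30 m) groups shifted by −0.10 in
saturation and −0.05 in value. Those dispersion levels are a choice:
nothing in the published material fixes them, and they were set once at
values giving realistic within-group spread at the published group
sizes. At that scale a −0.1 saturation shift is detected by the
rank-sum test at α = 0.05 in ≥ 95 of 100 seeded replicates.

What the generator does **not** model: nacre texture, iridescence,
specular highlights, illumination gradients, or any correlation between
hue, saturation and value. Passing tests therefore demonstrate the
correctness of the measurement chain on images that satisfy the tool's
stated input contract, not robustness to photographs that violate it.

## Problem sizes

The default test suite renders images at 48×48 (region radius 16,
~800 foreground pixels) and the full synthetic study at the published
group sizes (427 images), which keeps the whole suite and the
acceptance run in the seconds range while leaving the law-of-large-
numbers bounds comfortably tight. One test uses a 128×128 canvas
(~10⁴ foreground pixels) to check noisy-mean recovery at scale.

## Known limitations

- The white-reference rule and the range-learning rule are documented
  reconstructions of under-specified steps; both are configurable.
- Count-only group tables support diversity, match-rate and χ²
  statistics but not distribution tests (no per-sample colours exist).
- Mean-colour summaries discard within-sample colour variation;
  multi-modal samples (e.g. a bicolour shell margin) are reduced to one
  hue that may match neither mode.
- Dominant-hue detection under Silverman bandwidths merges modes closer
  than roughly one bandwidth; the published multi-modal hue lists are
  only recoverable from raw per-sample data, not from counts.
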