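# pearlhue

Quantitative colour phenotyping for pearl-oyster inner shells and
cultured pearls, from photographs on white backgrounds.

The black-lipped pearl oyster *Pinctada margaritifera* produces pearls
whose colour derives largely from the mantle-tissue donor used at
grafting. Scoring those colours by eye is irreproducible, so this
package implements a standardized HSV-based measurement: photographs in
which the coloured region of interest (a pearl sphere, or the clipped
peripheral margin of an inner shell) has been pasted onto a white
background are reduced to a single mean colour and a phenotype call,
and groups of such calls are compared statistically.

## Method

For each image:

1. **Background deletion.** A pixel is white background when its
   minimum RGB channel is ≥ τ (default 240; τ = 255 restricts the rule
   to pure white, appropriate for lossless images). An explicit
   white-list of hex triplets can extend the rule.
2. **Mean colour.** The surviving pixels are averaged per channel:
   R̄, Ḡ, B̄. The means are kept unquantised.
3. **HSV conversion.** The mean RGB is converted once with the hexcone
   transform — V = max/255, S = (max−min)/max, H the dominant-channel
   piecewise rule on [0, 1). Averaging is done in RGB *before*
   conversion; the two orders do not commute and the RGB-first order is
   the one implemented.
4. **Phenotype call.** H is compared to closed reference hue intervals:
   red = [0, 0.1625770], green = [0.3215928, 0.5637775]; anything
   outside both, or achromatic (S = 0), is "other". Ranges can be
   re-learned from labelled images as the min–max envelope of per-image
   mean hues (`HueRangeClassifier`, a scikit-learn estimator).

Group statistics on the resulting summaries: the hue **diversity index**
D = (distinct hues)/(samples), **colour-match rates** (pearls matching
their donor's phenotype), **Pearson χ² with Yates continuity
correction** on 2×2 match × depth tables, **Wilcoxon rank-sum** tests
on saturation and brightness, a **Shapiro–Wilk** normality screen, and
**dominant hues** as prominent local maxima of a boundary-reflected
Gaussian KDE of the hue distribution.

A seeded synthetic generator (`pearlhue simulate`) renders ground-truthed
sample images — uniform coloured discs or annulus sectors on white, with
optional pixel noise and JPEG encoding — so the whole chain is testable
without the original photographs.

## Worked example

```python
from pearlhue import BackgroundPolicy, generate_sample_image, summarize_sample

generate_sample_image((0.45, 0.8, 0.7), "s1.png")          # a known green
s = summarize_sample("s1.png", policy=BackgroundPolicy(tau=255))
print(s)
```

prints

```
SampleColorSummary(sample_id='s1', h=0.44988, s=0.79888, v=0.70196,
                   hex='#24B388', phenotype='green', n_foreground=812)
```

The generating hue 0.45 is recovered to 0.4499 (the residual is 8-bit
quantisation of the rendered image), the mean colour's hex code is
`#24B388`, and the hue falls inside the green reference interval, so the
sample is called "green". The same computation over a folder:

```
pearlhue process photos/ --white-threshold 240 -o report.csv
pearlhue compare report.csv --groups groups.csv -o comparisons.csv
```

`report.csv` carries one row per image
(`sample_id,hue,saturation,value,hex,phenotype,n_foreground,status`, 7
decimal places); failed files keep their row with a failure status.

## Layout

- `pearlhue.colorspace` — RGB / hex / HSV conversions.
- `pearlhue.segmentation` — white-background masking policy.
- `pearlhue.pipeline` — per-sample summaries and the batch CSV report.
- `pearlhue.phenotype` / `pearlhue.training` — hue ranges, the
  scikit-learn classifier, and range learning from labelled images.
- `pearlhue.stats` — diversity, contingency, rank-sum, normality and
  dominant-hue statistics; `compare_groups` reports.
- `pearlhue.synthetic` — seeded ground-truthed image cohorts.
- `pearlhue.reference_data` — the published count table the statistics
  layer can run on directly.
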