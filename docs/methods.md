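# Methods

`nightgrape` measures vineyard yield from high-resolution RGB images taken
at night under artificial (ring-flash) illumination. Controlled night
illumination removes most of the color variability that defeats daytime
fruit segmentation, so grape pixels can be classified one at a time from
color alone. The package implements the whole chain: color transforms,
five trainable pixel classifiers, morphological cleanup, per-cluster size
measurement, weight calibration, and yield estimation, plus a synthetic
scene generator that stands in for field imagery.

## Color representation

Images are H×W×3 floats in [0, 1]; 8-bit files are divided by 255, so a
threshold printed as an 8-bit level k corresponds to k/255. Two spaces are
used: the original RGB (plus a BT.601 luma gray layer I = 0.299R + 0.587G +
0.114B) and HSV with the hue plane rotated by 180° (H' = (H + 0.5) mod 1,
hue normalized to [0, 1]). Red grape skin straddles the 0/1 hue wrap; the
rotation moves it to a contiguous band around 0.5 that a single keep-above
threshold can isolate. Achromatic pixels (S = 0) take raw hue 0 by
convention, hence shifted hue 0.5; the choice is a convention, any constant
works. The luma formula for "gray" is likewise a convention — standard for
JPEG-derived imagery.

## Segmentation methods

All five classifiers are two-class (grape vs background), trained on a
designated reference frame, and pure functions thereafter. Ties always go
to background: this is deterministic and conservative for yield (it never
inflates grape area).

- **Threshold**: keep-above rule on one layer (R, G, B, I, or shifted H),
  with the level fixed by Otsu's method on the reference frame. Otsu is
  computed on the 256 quantized 8-bit levels; the returned threshold is
  k/255 for the level maximizing between-class variance. Values exactly
  equal to the threshold are background.
- **Mahalanobis**: each class is a Gaussian color model (sample mean and
  covariance of a circular template, regularized with ε = 1e-6 on the
  diagonal so near-uniform templates stay invertible); a pixel joins the
  class with the smaller Mahalanobis distance.
- **Bayes**: full quadratic Gaussian discriminant
  g_i(x) = −½ln|Σ_i| − ½(x−μ_i)ᵀΣ_i⁻¹(x−μ_i) + ln p_i with unequal class
  covariances and priors (defaults 0.4336 grape / 0.5664 background,
  configurable). With equal covariances and priors this reduces exactly to
  the Mahalanobis rule (tested).
- **Linear color models (LCM)**: each template selection defines a 3-D line
  (total least squares: centroid + first principal direction, so the fit is
  symmetric in the three channels, matching the point-to-line Euclidean
  distance used to classify). A pixel joins the class owning the nearest
  line. Several selections per class capture multi-modal color (three for
  grape shading, six for leaves/branches/soil).
- **Histogram**: the grape template's colors are quantized into a B³
  occupancy histogram (bin = floor(value·B), clamped at B−1), which is then
  dilated by the discrete Euclidean ball of radius r bins (implemented via
  the distance transform of the unoccupied bins — identical to ball
  dilation, much cheaper than convolution; clipped, not wrapped, at the
  histogram edges). A pixel is grape iff its bin is occupied — i.e. a zero
  threshold on the dilated histogram. Reference settings: B = 128 with
  r = 6 in RGB and r = 9 in HSV.

Template protocol: the two-class Gaussian and histogram methods use exactly
two selections — one grape circle (a patch of skin on one berry) and one
larger *mixed* background circle containing leaves, branches and dark areas
together. Only LCM consumes the full selection lists. This mirrors the
field protocol the package automates and is the main reason trained color
models generalize worse than the hue threshold: one berry's skin does not
span a cluster's brightness/saturation range.

## Morphological cleanup

Sequences are written in a compact notation ("HF + 4E + 4D" = hole fill,
four erosions, four dilations) applied left to right. E/D use the 3×3
square structuring element with out-of-image pixels treated as background;
a hole is a background component with no 4-connected path to the border
(the complement convention for 8-connected foreground). Equal erosion and
dilation counts are neutral on solids thicker than twice the depth, while
structures thinner than the erosion depth vanish — which is exactly how
foliage speckle is separated from berry-scale objects.

## Regions, area, volume

Foreground components are 8-connected (diagonal berry contacts keep a
cluster together) and returned in scan order; components below
`min_cluster_size` (default 0.1% of the frame) are dropped as residual
speckle. Area is the member pixel count. Volume treats the silhouette as a
solid of revolution about the cluster's vertical axis: a row spanning
columns s(k)..e(k) (extreme member columns, gaps included) contributes
π·((e(k) − s(k))/2)². Spans are measured per region, not per image row, so
side-by-side clusters do not mix. A rasterized disk of radius 100 px comes
within 3% of the analytic sphere volume (4/3)πR³.

## Calibration and yield

Reference clusters are photographed one at a time against a white
background, segmented by Otsu on the gray layer with keep-below polarity
followed by an equal number of erosions and dilations (10 at full scale;
the depth scales with berry radius, so quarter-scale synthetic runs use 3).
Weight is regressed on area and on volume by ordinary least squares with an
intercept; the Pearson correlation, slope, intercept and n are stored in a
small portable JSON model. Predictions clamp below at 0 g (weights are
physical). Yield is the sum of per-region predictions; when ground truth is
available the relative error (estimated − true)/true is reported. The
average of the area- and volume-based totals is exposed in the CLI but
flagged experimental: agreement between the two estimators' biases is not
guaranteed.

## Validation metrics

The XOR error counts pixels where the automatic and manual masks disagree,
divided by the manual cluster's pixel count — it can exceed 1 and reaches
2.0 for disjoint equal-area masks. Scoring is per cluster inside a window
that pads the manual bounding box by 25%, so distant false positives do not
pollute a cluster's score while rim errors are charged; per-cluster errors
are averaged unweighted. Cluster detection uses an any-overlap rule (the
weakest consistent reading of an all-100% detection column) and, inside the
comparison harness, a loose 0.01%-of-frame region filter: detection asks
only whether a method produced evidence of a cluster, while the XOR columns
carry the precision. Both conventions are recorded in the harness output.

## Synthetic scenes

The generator emulates night ring-flash vineyard frames at one quarter of
the source imaging scale by default (berry diameter ≈ 27 px, cluster area
≈ 15,000 px in 712×1072 frames; `paper_scale` restores 109 px berries on
4288×2848 frames, with the weight slope divided by 16 so cluster weights
are unchanged). Key defaults and why:

- **Clusters**: 25–40 berries (radius 13.5 ± 1.5 px) packed with ~0.72
  center spacing in units of summed radii and a hard footprint cap, giving
  compact unions of ≈ 12–18 k px. Berries are spherically shaded with a deep
  Lambert term (flash from the camera direction), per-berry brightness
  (uniform 0.45–1.0) and saturation (0.75 ± 0.15) variability, and a strong
  desaturating specular cap — the flash reflection carries the flash color,
  not the skin color. Hue is the one stable cue: shifted-hue 0.60 ± 0.02.
- **Background**: dark base with a cool tint at raw hue 0.75 (shifted 0.25
  — far from both the grape band and the hue wrap at raw 0.5, so sensor
  noise on dark pixels cannot flip them across the wrap), granular green
  foliage patches (leaflets of 2–4 px radius; raw hue ≈ 0.33, shifted
  ≈ 0.83), and bright gray branch strokes. Brightness is deliberately
  confusable with berries; hue distributions are separable by construction
  and the generator asserts a <1% histogram overlap between grape and
  background shifted hue when `hue_separable` is set.
- **Weights**: w = 0.04 g/px · area + N(0, 18 g), clamped at 1 g. The noise
  level was set from the design-time area spread so a 29-cluster
  calibration's weight-vs-area correlation lands in the mid-0.9s, the
  regime reported for laboratory calibrations of this kind.
- **Calibration shots**: single clusters on a white background (gray
  ≥ 0.9) with isolated dark speckle, rendered at 0.65 exposure (metered for
  the white background) so specular caps stay below the Otsu level and the
  silhouette is solid.
- **Templates**: auto-placed to emulate the operator — one inscribed circle
  per cluster (≤ 0.45 berry radius), one large mixed background circle
  centered on a foliage patch and kept clear of every cluster, then six
  material-specific circles for LCM.
- One `numpy` Generator seeded from `SceneSpec.seed` drives everything; the
  same spec is bit-reproducible.

What the generator does *not* emulate — and hence what passing tests do not
show about field data: leaf occlusion of clusters (the reference regime is
non-occluded), perspective/defocus blur and chromatic aberration, JPEG
artifacts, flash falloff with depth, wet-leaf specularities, mixed-variety
or unevenly ripened fruit, and genuinely overlapping clusters. Absolute
error levels on synthetic scenes (a few percent) are therefore better than
on real imagery (≈ 10–20%); the qualitative structure — hue thresholding
robust, single-template color models brittle, morphological filtering
helpful, area/volume calibration linear — is what the tests certify.

## Numerical choices

- Tie-breaks to background in every classifier; Otsu takes the first
  argmax level on ties.
- Covariance regularization ε = 1e-6; line fits reject zero-variance
  samples (max |centered| < 1e-12).
- Histogram dilation clips at the cube edges (no hue wrap; the shifted
  representation keeps grape hues away from the wrap anyway).
- Line directions are sign-canonicalized (first nonzero component
  positive) so fits are deterministic.
- Constant layers raise a degenerate-input error rather than returning an
  arbitrary threshold.

## Problem sizes

Default test/acceptance runs use quarter-scale scenes: a 3-frame labeled
benchmark (9 clusters) for method comparison, a 5-frame batch totaling 25
clusters for yield, 29 rendered calibration shots, and 200 cheap
(non-rendered) 29-pair simulations for calibration recovery. These sizes
keep the whole chain fast while leaving every statistic in its intended
regime; `paper_scale` exists for full-scale experiments.
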