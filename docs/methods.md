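# Methods

This note documents the models, parameter choices and numerical
decisions behind `visrep`, and what the synthetic benchmark does and
does not establish about real photo corpora.

## 1. Pixel-level features

All 17 features are population statistics over the full pixel set of
an 8-bit RGB image (sample corrections would be negligible at image
scale and would complicate closed-form checks). HSV follows the
standard hexcone conversion with hue in degrees [0, 360); saturation
and value are reported on a 0–255 scale so their magnitudes are
commensurate with the RGB channels. Luminance is YUV
Y = 0.299 R + 0.587 G + 0.114 B on 0–255.

**Hue peaks.** Hue is nominal, so it is summarized by the number of
modes of its histogram rather than by moments. The histogram has 360
one-degree bins over pixels whose saturation exceeds 26 (≈ 0.1 on the
0–1 scale; nearly-gray pixels have numerically meaningless hue),
smoothed by an exact circular Gaussian convolution (FFT) with a
bandwidth of 8 bins, and a mode is a strict local maximum with
circular topographic prominence of at least 1 % of the histogram mass.
These four constants are not forced by the feature's definition; they
are fixed defaults, exposed as parameters, chosen so a single-hue
image yields exactly one mode and broad two-hue images yield two.

**Contrast.** The default is the plain population SD of luminance.
A `literal` mode that divides the SD by the pixel count is provided
for sensitivity analyses; it makes the feature scale-dependent (two
images differing only in resolution get different values), which is
why it is not the default.

**Sharpness.** Per pixel `|∇²Y| / max(μ₃ₓ₃, 1)` with the 4-neighbor
Laplacian kernel and replicate borders, where μ₃ₓ₃ is the 3×3 local
luminance mean; the max with 1 floors the denominator so black regions
do not blow up the statistic. The default aggregate is the **sum**
over pixels (an extensive quantity, of order 10⁴–10⁵ for natural
photos); a `mean` aggregate is available when images of different
sizes must be compared.

**Naturalness (CNI).** Qualifying pixels need saturation > 0.1 and
luminance in [20, 80] on a 0–100 scale; luminance here is the same YUV
Y as the brightness feature, rescaled (the CNI literature's
"lightness" is not pinned to one colour space; using Y keeps one
luminance definition package-wide). Hue groups and natural-saturation
parameters: skin [25°, 70°] with (μ, σ) = (0.76, 0.52), grass
[95°, 135°] with (0.81, 0.53), sky [185°, 260°] with (0.43, 0.22).
The index is the pixel-count-weighted average of
`exp(−½((S̄_g − μ_g)/σ_g)²)` over non-empty groups, hence always in
[0, 1], and defined as 0 when no pixel qualifies.

Every feature is verified against a literal loop-based reference
implementation (pure Python, per-pixel) to 1e-9 relative tolerance on
random images, plus closed-form cases (e.g. uniform pure red has
colorfulness 0.3·√(255² + 127.5²) ≈ 85.53).

## 2. Embedding and clustering

The tested embedding is deliberately simple and deterministic: an 8×8
bilinear-downsampled luminance map (64 dims, scaled to [0, 1])
concatenated with 8-bin normalized histograms of R, G and B (24 dims).
It captures exactly the coarse layout and color distribution that
separate text-centered from people-centered photos. A deep
convolutional embedding (e.g. the penultimate layer of an
ImageNet-trained network) can be substituted behind the same
transformer interface; it is not exercised in tests because it
requires downloaded weights and adds nothing to the logic under test.

Embedding dimensions are z-scored before k-means (the two blocks of
the toy embedding have heterogeneous scales); zero-variance dimensions
are left centred. k-means uses k-means++ initialization with 10
restarts and a fixed seed. The WCSS curve includes k = 1 (the total
sum of squares, the exact one-cluster optimum) so the elbow criterion
— the k maximizing the discrete second difference of WCSS — is
defined at the lower end of the scanned range. Silhouette selection is
the argmax of the mean silhouette, subsampled to 2000 points (seeded)
for large corpora; ties in either criterion resolve to the smaller k.
An `agree` mode requires both criteria to concur and raises an
exception carrying both candidates otherwise — disagreement is
reported, never silently resolved. Final labels are relabeled by
descending cluster size, since k-means indices are arbitrary and
reports need a stable ordering.

## 3. Annotation aggregation

Content categories come from a fixed 15-class vocabulary; frequencies
are zero-filled over the full vocabulary so empty classes are visible.
Mean tag confidence defaults to averaging over the photos that carry
the tag (`present_only`); an `all_photos` mode dividing by corpus size
is provided because either reading of "averaged over all photos" is
defensible.

Per-photo facial features: face count; closeup (largest face area /
image area); face ratio (summed face areas / image area, so closeup ≤
face ratio always); mean age; gender as the **count** of female faces
(not a proportion); and the per-photo mean of each of the 8 emotion
scores, which are treated as simplex-normalized per face. Photos with
no faces carry all-zero features. Summaries come in two scopes:
`face_photos_only` (restrict to photos with ≥ 1 face — the natural
corpus-level report) and `all_photos` (zero-imputed — the scope that
makes cluster-level means comparable when clusters differ in their
share of faceless photos). The implied male-face mean is reported as
the face-count mean minus the female-count mean.

Word cleaning: lowercase; tokens matching `http(s)://…` or `www.…`
dropped; splitting on any character outside `[a-z0-9']` with edge
apostrophes stripped (so "don't" survives intact while "covid-19"
splits); then removal of the fixed 34-item stop list (a, about, am,
an, and, are, as, at, be, by, but, de, e, for, from, in, is, it, la,
o, of, on, or, so, that, the, this, to, up, was, •, 0, 1, 2). The
filter is idempotent. Frequency ties rank alphabetically for
deterministic reports.

## 4. Response metrics and comparison

Engagement is likes + comment count. A photo's comment sentiment is
the mean of its per-comment scores and is **missing** when it has no
comments — zero-imputation would bias group means because 0 is a valid
(neutral) sentiment. The group comparison runs one two-sample t test
per feature: Welch by default (the robust choice when cluster
variances differ), pooled Student as an option. Constant features
yield t = 0, p = 1 when the groups are identical and an explicit
not-computable marker otherwise — never a spurious star. No
multiple-testing correction drives the stars (the comparison is
descriptive, one star per feature at α = 0.05); a Benjamini–Hochberg
column is reported for readers who want it. Welch p-values are checked
against a seeded permutation oracle in the tests.

## 5. The synthetic corpus

The generator emulates the statistical structure the analysis is meant
to detect, with two latent classes mixed in a configurable proportion:

| quantity | text class | people class |
|---|---|---|
| words per photo (Poisson mean) | 5.519 | 0.398 |
| comment sentiment (Normal mean, SD 0.4, clipped to [−1,1]) | 0.073 | 0.198 |
| faces per photo | 0 | 1–3, mean 1.44 |
| female fraction per face | — | 0.6 (Bernoulli) |
| likes (lognormal μ, σ=1) | 3.6 | 4.2 |
| comments per photo (Poisson) | 3.0 | 4.2 |
| modal category (probability) | text (0.8) | people (0.7) |

Face ages are Normal(31, 11) clipped to [1, 90]; emotion vectors are
Dirichlet with α = 1.2 × the target mean profile (happiness 0.433,
neutral 0.499, six small classes), which reproduces the target means
exactly in expectation. Clipping the sentiment Normal shifts its mean
by ≈ 0.003 at the upper target, well inside the 3-standard-error
calibration band checked at n = 10⁴. The word vocabulary deliberately
contains stop words, URLs and bullet glyphs so the cleaning stage is
exercised; calibration targets refer to the raw word count the bundle
carries, and the cleaned per-photo count used in cluster comparisons
is correspondingly lower.

Text images are near-white (base gray 228–250) with 3–6 rows of dark
stroke rectangles (glyphs are rectangles, not rendered fonts — only
pixel statistics matter downstream and fonts would add a dependency).
People images split at a horizon into a sky band (hue 195–240°) and a
grass band (95–135°) with skin-tone ellipses (20–40°) at recorded
bounding boxes — the three palettes intentionally cover all three CNI
hue groups. Default image size is 64×64: every feature is intensive or
has an intensive variant, so small images preserve the features'
semantics while keeping corpus generation essentially free.

Reproducibility: each photo's random stream is derived from
(root seed, photo index) via `SeedSequence`, so corpora are
byte-identical under identical configs and independent of generation
order.

**What passing tests show — and don't.** The generator produces
well-separated classes by construction; recovering k = 2 with ARI ≈ 1
demonstrates that the pipeline's machinery is correct, not that real
hashtag corpora separate this cleanly (real separability depends on
the corpus and the embedding). Likewise the annotation distributions
are parametric idealizations: real tag vocabularies are heavy-tailed,
face detections are noisy and correlated with image content, and
likes/comments are far more overdispersed than a lognormal/Poisson
pair. The benchmark validates the analysis code, not any empirical
claim about social media.

## 6. Pipeline and problem sizes

`run_pipeline` executes corpus → corpus-level summaries → features →
embedding → k-selection → clustering → comparison, asserting the
partition invariant (cluster sizes sum to n) and the per-face emotion
simplex along the way, and writes every stage artifact as CSV/JSON
plus a Markdown report and a manifest recording the full configuration
(including every default), its hash, and library versions — so no
gap-filling decision is silent. Stages communicate only through files,
so real annotation exports in the documented schemas can replace the
synthetic corpus without code changes.

Default analysis conditions used throughout tests and the acceptance
script: 400 photos, balanced classes, 64×64 images, k scanned over
2–6, seed 42 in tests (the acceptance script takes its seed on the
command line); generator calibration checks use 10⁴ annotation
bundles per class. These sizes make the full suite and the acceptance
run complete in well under a minute each on one CPU while leaving all
statistical checks comfortably powered.
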