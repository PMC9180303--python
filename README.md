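# visrep

Visual-representation analysis of hashtag photo corpora.

`visrep` is a small analysis toolkit for researchers in health
communication and computational social science who study how a topic is
*visually* represented in a social-media photo corpus (e.g. all public
photos carrying a given hashtag). It implements the full quantitative
workflow around such a corpus:

1. **Pixel-level aesthetics** — 17 interpretable features per photo:
   RGB and HSV saturation/value means and variances, the number of
   modes in the KDE-smoothed circular hue histogram, luminance
   brightness, Hasler–Süsstrunk colorfulness, a color-naturalness index
   (CNI), luminance contrast and its RGB-space extension, and a
   normalized-Laplacian sharpness measure.
2. **Cluster discovery** — photos are embedded as vectors and grouped
   with k-means; the number of clusters k is chosen from the
   within-cluster sum of squares (elbow) and mean-silhouette curves.
3. **Annotation aggregation** — service-style per-photo annotations
   (content category from a fixed 15-class vocabulary, tags with
   confidence scores, face records with age/gender/8 emotion scores,
   words detected in the photo, likes, per-comment sentiment in
   [−1, 1]) are aggregated into corpus- and cluster-level summaries.
4. **Between-cluster comparison** — Welch two-sample t tests across the
   13 facial features, 17 pixel features, words per photo, engagement
   (likes + comments), and mean comment sentiment.

Because real social-media corpora generally cannot be redistributed,
the package ships a seeded **synthetic corpus generator** with two
latent visual classes — *text-centered* photos (bright, low-saturation
backgrounds with dark glyph-like strokes) and *people-centered* photos
(colorful sky/grass scenes with skin-tone face ellipses) — whose
annotation distributions are calibrated so the downstream analysis has
a known ground truth to recover.

## The statistics at the core

For an image with per-pixel opponent channels `rg = R − G` and
`yb = (R + G)/2 − B`, colorfulness is
`sqrt(σ²_rg + σ²_yb) + 0.3·sqrt(μ²_rg + μ²_yb)` (population moments).
The CNI groups qualifying pixels (luminance in [20, 80] on a 0–100
scale, saturation > 0.1) into skin/grass/sky hue bands and scores each
band by `exp(−½((S̄ − μ_g)/σ_g)²)` against empirically "natural" mean
saturations, averaging scores with pixel-count weights. Cluster count
selection uses `argmax_k silhouette(k)` and the maximal discrete second
difference of WCSS. Group comparisons use the Welch statistic with
Welch–Satterthwaite degrees of freedom, two-sided p, stars at p < 0.05
(a Benjamini–Hochberg column is reported alongside).

## Worked example

```python
import pandas as pd
import visrep

config = visrep.GeneratorConfig(n_photos=400, mix=0.5, image_size=(64, 64), seed=42)
photos = visrep.generate_corpus(config)

X = visrep.ToyImageEmbedder().fit_transform([p.image for p in photos])
sel = visrep.KMeansClusterSelector(k_range=(2, 6), random_state=42).fit(X)
print("selected k:", sel.k_)
print("cluster sizes:", sel.sizes_.tolist())
print("silhouette curve:", {k: round(v, 3) for k, v in sel.silhouette_curve_.items()})

pixel = pd.DataFrame(
    visrep.PixelFeatureExtractor().fit_transform([p.image for p in photos]),
    index=[p.photo_id for p in photos], columns=list(visrep.FEATURE_NAMES))
truth = [p.true_class for p in photos]
comp = visrep.compare_groups(pixel, truth, group_order=("text", "people"))
print(comp.set_index("feature").loc[
    ["brightness", "saturation_mean", "colorfulness", "naturalness"],
    ["mean_group1", "mean_group2", "t_statistic", "p_value"]].round(3))
```

prints

```
selected k: 2
cluster sizes: [200, 200]
silhouette curve: {2: 0.445, 3: 0.252, 4: 0.119, 5: 0.122, 6: 0.118}
                 mean_group1  mean_group2  t_statistic  p_value
feature
brightness           212.786      109.935       86.085      0.0
saturation_mean        8.063      143.567     -111.440      0.0
colorfulness           5.451       81.337      -81.002      0.0
naturalness            0.178        0.900      -46.430      0.0
```

The silhouette curve peaks at k = 2, matching the two generative
classes; text-centered photos are much brighter (group 1 means) while
people-centered photos are far more saturated, colorful and natural —
the qualitative pattern such corpora are expected to show, recovered
here with a known ground truth.

The same workflow is available from the shell:

```bash
visrep synth --n 400 --mix 0.5 --seed 42 --out corpus/
visrep run --out run_out --n 400 --seed 42   # full pipeline + Markdown report
```

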