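# mpmquant

Automated quantification of label-free multiphoton microscopy (MPM) images
of tissue, built around two endogenous optical biomarkers of treatment
response in carcinoma:

* **nuclear area** — in two-photon autofluorescence (TPAF) images, cells are
  bright (NAD(H)/FAD fluorescence) while nuclei are signal voids; nuclear
  size is measured by segmenting these dark voids and counting pixels;
* **collagen content** — second-harmonic generation (SHG) arises almost
  exclusively from fibrillar collagen; collagen content is the percentage of
  foreground pixels after binarizing the SHG image.

The package is aimed at image-analysis practitioners who have co-registered
TPAF/SHG tile pairs (e.g. pre- and post-chemotherapy tissue sections) and
want reproducible per-sample metrics plus group-level statistics. Because
no public image archive exists for this modality, a first-class phantom
generator ships with the package so every stage is testable against known
ground truth.

## Methods at a glance

**TPAF branch — spatially-constrained watershed superpixels (SWS).**
The image is histogram-equalized, Gaussian-smoothed, and opened by
morphological reconstruction. Superpixels are watershed basins flooded from
a square grid of seeds (spacing *s*) on the regularized relief

```
g_reg(p) = g(p) + λ · (2/s) · d(p, nearest seed)
```

where *g* is the Sobel gradient magnitude and *d* the Euclidean distance to
the nearest seed — the distance term is the spatial constraint that keeps
superpixels compact. Superpixel mean intensities are split by Otsu's
criterion; dark superpixels are nuclear, 4-connected unions of them are
nuclei, and nuclear area is the pixel count (filtered to a plausible
range). Note the seed grid can only delineate a nucleus that contains a
seed: choose `s ≤ b_min·√2` for the smallest nuclear inscribed radius
`b_min` you care about.

**SHG branch — robust automatic threshold selection (RATS).**
The segmentation threshold is the gradient-weighted mean intensity

```
T = Σ w·Ī / Σ w,   w = g²  (zeroed below a noise floor λ_n·σ̂)
```

evaluated per quadtree leaf and bilinearly interpolated into a per-pixel
threshold map; `Ī` is the 3×3 mid-range intensity, so each edge pixel
contributes the level midway between the two sides of its edge. Pixels
strictly above the map are collagen (255); content is
`100 · n_255 / n_ROI`.

**Statistics.** Each sample contributes one mean nuclear area and one
collagen content; groups are summarized as mean ± SD (n−1) and compared
with a two-sided pooled two-sample t-test (Welch available), significance
at p < 0.05.

## Worked example

```bash
python examples/02_nuclear_morphometry.py
```

prints

```
superpixels: 676; nuclei found: 8
ground-truth areas: [425, 600, 644, 648, 695, 729, 732, 1009]
measured areas:     [425, 600, 644, 647, 695, 729, 732, 1008]
mean nuclear area: 685.0 px^2 (ground truth 685.2)
```

i.e. on a noise-free phantom of eight elliptical nuclei the watershed
superpixel areas match the rasterized ground truth to within a pixel or
two, because basin boundaries settle on the nuclear edge gradient. Likewise

```bash
python examples/03_collagen_content.py
```

```
target  15.0% | ground truth 15.28% | measured 15.26% | threshold map spans [58.9, 108.3]
target  36.1% | ground truth 36.77% | measured 36.45% | threshold map spans [68.5, 109.3]
```

shows RATS recovering fiber area fractions to well under one percentage
point, with thresholds sitting between the background (~8) and fiber
(100–220) intensity levels. `examples/04_group_comparison.py` reproduces
the group comparison from printed summary statistics
(nuclear area: t = 4.3087, df = 58, p = 6.4e-05; collagen: t = 4.5239,
df = 58, p = 3.1e-05 — both p < 0.001), and `examples/05_full_pipeline.py`
runs the entire pipeline on a small synthetic cohort.

There is also a thin CLI:

```bash
mpmquant simulate --out cohort/ --seed 1 --n-per-group 5   # phantoms + manifest
mpmquant analyze --config run.yaml                          # full pipeline
mpmquant stats --samples outputs/<run-id>/tables/samples.csv
```

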