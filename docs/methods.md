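# Methods

This note documents the models, numerical choices and limitations behind
`mpmquant`. The package quantifies two-channel multiphoton images of tissue:
a TPAF (two-photon autofluorescence) channel in which cytoplasm and stroma
are bright and nuclei are signal voids, and a co-registered SHG
(second-harmonic generation) channel in which only fibrillar collagen is
bright. All measurements are in pixel units (areas in px², collagen in %);
physical pixel size is pass-through metadata only.

## Image model and I/O

Images are single-channel 8- or 16-bit rasters (TIFF canonical, PNG read).
RGB files are demuxed by the display convention TPAF→red, SHG→green.
Large-area acquisitions are plain row-major montages of fixed-size tiles
with no blending, registration or flat-field correction — tile (r, c)
occupies its block unchanged. Overlays rescale each channel independently
to 8-bit for display; quantification always runs on raw intensities.

## Nuclear morphometry (TPAF branch)

**Preprocessing.** Global histogram equalization (256 bins), Gaussian
smoothing (σ = 1 px), then grayscale erosion with a disk (radius 2 px)
followed, by default, by morphological reconstruction by dilation under the
smoothed image (opening-by-reconstruction). The reconstruction variant was
chosen because it removes bright speckle smaller than the structuring
element while leaving the dark nuclear voids with their original footprint;
plain erosion (available via `use_reconstruction: false`) dilates dark
regions by the disk radius and therefore inflates small-nucleus areas.
Equalization before gradient computation makes the relief scale-free with
respect to acquisition gain, at the cost of amplifying background noise
rank-wise; the Gaussian stage damps that amplification.

**Watershed superpixels.** Seeds sit on a centered square grid with spacing
`seed_spacing_px`. Flooding runs on

    g_reg(p) = g(p) + λ · (2/s) · d(p, nearest seed)

with g the Sobel magnitude of the preprocessed image, d the Euclidean
distance transform of the seed set, λ = 0.5 by default. The scaled distance
term is the "spatial constraint": it caps basin eccentricity and guarantees
seed-anchored, compact superpixels on flat regions (on gradient-free images
the partition reduces to the nearest-seed Voronoi tessellation, up to a
one-pixel tie band along equidistant ridges). Flooding order ties are
resolved by relief value then deterministic raster order, so label maps are
platform-stable. Every pixel receives exactly one of K labels (a
partition), and each region is 4-connected and contains its seed.

*Choosing the seed spacing.* A nucleus can only be delineated if at least
one seed falls inside it; a grid of spacing s always hits a disk of radius
b when s ≤ b·√2. The default spacing (24 px) suits nuclei ≥ ~580 px²;
analyses of phantoms whose smallest nuclei are ~300 px² (inscribed radius
≈ 8.7 px at eccentricity 0.6) use spacing 10 px. This is a property of the
geometry, not a tuning knob: spacing that exceeds the rule simply merges
small nuclei into cytoplasm superpixels.

**Classification and measurement.** Superpixel mean intensities are split
by Otsu's criterion; superpixels on the dark side are nuclear. (On an image
with no dark class — all means equal — the result is the empty set. On an
inverted image the convention still returns the dark side; bright-nucleus
data are out of contract.) Four-connected unions of nuclear superpixels
form nuclei (merging on by default so one nucleus covered by several
superpixels is counted once), areas outside [50, 20000] px² are discarded,
and border-touching nuclei are kept (an exclusion flag exists). A sample
with zero nuclei raises a flagged error rather than contributing zero.

Measured on noise-free phantoms with well-separated ellipses of 300–1500
px², per-nucleus areas land within a few pixels of the rasterized ground
truth (worst case well under the 15 % design bound) because basin
boundaries settle on the nuclear edge gradient.

## Collagen quantification (SHG branch)

**RATS.** The segmentation threshold is the gradient-weighted mean

    T = Σ w·Ī / Σ w,   w = g^q  with q = 2,

the classic result being that symmetric edge weighting places T midway
between foreground and background levels. Two numerical choices make the
quadtree variant behave like the ideal formula:

* **Edge-centered intensity.** Ī is the 3×3 mid-range, (local max + local
  min)/2, not the raw pixel value. The Sobel band of an ideal step is only
  two pixels wide; a quadtree leaf whose boundary falls exactly on the step
  sees one of them and, with raw intensities, would collapse its threshold
  onto one plateau level (and ties would then erase the foreground). The
  mid-range gives every high-gradient pixel the midpoint of its own edge,
  from either side. On a 10/200 step the resulting map is 105 everywhere.
* **Noise floor from the intensity domain.** Weights are zeroed where
  g < λ_n·σ̂ (λ_n = 3). σ̂ is the per-component noise scale of the Sobel
  magnitude obtained by estimating pixel noise with the wavelet-domain
  (Donoho) estimator and multiplying by the operator's noise gain
  √(12/16). A MAD of the gradient magnitude itself is *not* used: on
  fiber-dense images (≥ 40 % coverage) edge pixels are the majority, so
  that statistic measures edge density rather than noise and starves every
  leaf.

**Quadtree and interpolation.** The image splits recursively at axis
midpoints while both halves stay ≥ `min_leaf_px` (32 px default; floor 8).
A node whose total weight W passes the floor
`W_min = min_leaf_px² · (λ_n·σ̂)^q / 4` owns a threshold; leaves below the
floor inherit the nearest qualifying ancestor. Leaf-center thresholds are
bilinearly interpolated (clamped at borders) into a continuous per-pixel
map. If the root itself is weight-starved (e.g. a constant image) the map
is invalid and binarization returns an all-background mask.

**Binarization and content.** Foreground where intensity strictly exceeds
the local threshold — ties go to background, so degenerate flat inputs
yield 0 %. Collagen content is exactly `100 · n_255 / n_ROI`; the ROI
defaults to the whole image (a mask ROI is supported; which convention a
given published table used is generally unknowable, so both are provided).

Measured behaviour: on two-level steps with additive Gaussian noise at
SNR 5 (contrast/σ = 5), the binarization agrees with the exhaustive-search
best global threshold on ≥ 98.5 % of pixels over 20 seeded replicates; on
fiber phantoms at targets 10–50 % the recovered content is within 0.8
percentage points of ground truth and monotone in the target.

## Synthetic data

The generators emulate the structure that the pipeline exploits, not the
optics (no PSF, shot noise, or depth attenuation — passing tests therefore
demonstrates algorithmic correctness on idealized contrast, not performance
on real tissue):

* **TPAF phantoms**: background at a cytoplasm level (default 190/255),
  non-overlapping rotated ellipses at a nucleus level (default 25),
  eccentricity uniform in [0, 0.6], optional very bright disks mimicking
  necrosis/foam cells, additive Gaussian noise (default σ = 4) clipped to
  the bit range. Ellipses are rasterized by pixel-center inclusion, so a
  nominal area πab is met to ~1–2 %. Placement is rejection sampling with a
  4 px separation halo and bounded retries; overcrowded requests raise.
* **SHG phantoms**: smoothed random-walk fibers of fixed stroke width
  (default 3 px), each at its own intensity drawn from 100–220 over
  background 8, added until the ground-truth mask fraction reaches the
  target; fibers that would overshoot the ±2-point band are re-proposed
  shorter. The emitted mask *is* the ground truth.
* **Cohorts**: per-sample targets (mean nuclear area; collagen fraction)
  are drawn from truncated normal distributions parameterized by each
  group's published mean ± SD — normality is the minimal assumption when
  only mean ± SD is reported. Areas truncate to positive values and
  collagen to [0, 100] %, so group-mean recovery stays unbiased to well
  within sampling error. Individual rendered nuclei truncate at 50 px² for
  rasterizability. Child seeds derive from the master seed via
  `SeedSequence(master, spawn_key=(group_index, sample_index))`, making
  cohorts reproducible and samples independent. Default group parameters
  are n = 30 per group, 596.56 ± 208.69 px² / 22.81 ± 10.23 % (pre) and
  856.22 ± 255.74 px² / 36.10 ± 12.42 % (post). Rendered cohort images
  default to 256×256 with 10 nuclei per image — large enough for stable
  per-sample means, small enough that a full 60-sample cohort renders and
  analyzes in well under a minute.

## Group statistics

Per-sample aggregation precedes testing: each sample contributes one mean
nuclear area and one collagen content, and the group test runs across
samples. This avoids pseudo-replication across nuclei within a sample
(whether published SDs describe variation across patients, images or nuclei
is typically unstated; per-nucleus tables are still written so any
convention can be audited). The default test is the pooled two-sample t
(df = n_a + n_b − 2); Welch's variant with Satterthwaite df is computed
alongside and both appear in machine-readable output — with equal group
sizes the two t statistics coincide. Tests are two-sided. Conventions for
degenerate inputs: zero pooled variance with equal means gives t = 0,
p = 1; with unequal means, an infinite t with p = 0, flagged
(`zero_variance=True`). Exact p-values are reported plus the usual bins
(<0.001, <0.01, <0.05, ns).

Under the cohort model at the default group parameters the standardized
effects are ≈ 1.1–1.2, so a 30 + 30 cohort flags both metrics at p < 0.05
in ~98 % of replicates; under a null cohort (both groups from the
pre-treatment distribution) the empirical type-I rate at α = 0.05 sits
within [0.03, 0.07] over 1000 seeded replicates.

## Pipeline and reproducibility

A run is a validated config (YAML; unknown keys are errors, violations name
their field) plus a seed. Samples come from a manifest CSV
(`sample_id, group, tpaf_path, shg_path`) or from the cohort generator.
Per-sample failures (unreadable file, no nuclei, generation error) are
logged, flagged in the report and skipped; the run aborts only if a whole
group yields nothing. Outputs are per-nucleus, per-sample and comparison
CSVs plus a `report.json` carrying the canonical config, its hash, the
seed, the package version and per-sample statuses — enough to reproduce the
run. The run directory name is a hash of config + seed, and identical
config + seed reproduce byte-identical tables.

## Known limitations

* Phantoms have crisp two-level contrast; real TPAF tissue has textured
  cytoplasm, touching nuclei and uneven illumination, where watershed
  superpixel boundaries and the Otsu split will be less clean.
* The SWS seed-spacing rule must be chosen against the expected minimum
  nucleus size; a single spacing cannot serve arbitrarily mixed scales.
* RATS assumes approximately two-level local contrast; faint fibers below
  the noise floor are not recovered, and heavily saturated images lose the
  gradient information the threshold depends on.
* The t-test assumes approximate normality of per-sample metrics; no
  nonparametric alternative or multiple-testing correction is provided
  (only two prespecified metrics).
* Montage assembly does no overlap registration; tiles are assumed
  pre-aligned.
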