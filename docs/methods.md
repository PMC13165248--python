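# Methods

## Problem setting

`turfhsi` implements a proximal hyperspectral phenotyping workflow for
turfgrass (*Zoysia* spp.) breeding nurseries. The input is a VNIR
reflectance cube — nominally 204 bands over 400–1000 nm on a 512 × 512
spatial frame — per plot and acquisition date, together with per-genotype
trait tables. The output is a relative ranking of genotypes that combines
spectral *quality* (vegetation-index means) with growth *quantity*
(vegetation pixel count), plus the intermediate products: vegetation masks,
index maps, frequency histograms, and validation reports.

## Segmentation model

Vegetation/background separation is a hybrid of unsupervised structure
discovery and supervised generalisation:

1. **Scaling.** Pixel spectra from an ROI are min–max scaled per band to
   [0, 1]; constant bands map to 0. Scaling removes per-band gain
   differences so the embedding reflects spectral shape.
2. **Embedding.** UMAP projects the scaled spectra to 2-D
   (`n_neighbors = 15`, `min_dist = 0.1`, fixed seed 42). These are the
   common stable defaults; they are exposed in `SegmentationConfig` because
   no single setting suits every canopy.
3. **Density clustering.** DBSCAN on the embedding (`min_samples = 10`).
   The radius ε defaults to the knee of the sorted k-distance curve
   (maximum perpendicular distance to the end-to-end chord), standing in
   for the interactive per-image choice a breeder would otherwise make;
   an explicit ε always wins. Noise points are remapped to the background
   class (label 0) and clusters are renumbered 1..K by decreasing size so
   labels are stable across runs.
4. **Label bootstrapping.** The cluster labels train a Random Forest
   (200 trees, fixed seed) **on the scaled spectra**, not on the embedding
   coordinates. This is a deliberate design choice: a spectrum-space
   classifier can label pixels that were never embedded, which is what makes
   the subsampling contract work (ROIs above a 50,000-pixel budget are
   embedded on a seeded subsample, then classified in full).
5. **Cluster selection.** The vegetation cluster defaults to the cluster
   whose mean spectrum maximises NDVI, considering only clusters that hold
   at least 5% of the clustered pixels (falling back to all clusters if
   none do). The size floor matters: when the automatic ε slightly
   fragments the vegetation cloud, a handful of noisy pixels can otherwise
   post a marginally higher mean NDVI than the true vegetation cluster and
   hijack the pick. A user override always wins (user-in-the-loop
   contract).

The whole stage is a pure function of (spectra, parameters, seed).

## Mask refinement

The classifier mask is intersected with a pseudo-RGB colour-similarity
mask. Pseudo-RGB composites use bands (70, 52, 19) — taken as 0-based
indices into the 204-band stack — with a 2nd–98th percentile stretch per
channel. A pixel passes a colour target when every channel lies within
±tolerance of the target. The tolerance is interpreted as a fraction of the
full 8-bit scale (default 0.30, i.e. ±76.5 counts) rather than of the
target value, because a relative band collapses to zero width at dark
targets; a relative mode is provided for users who want it. Multiple
targets combine by union. When the pipeline runs unattended, a single
target is sampled as the mean RGB of the classifier mask. After
intersection, all bands of non-retained pixels are set to zero.

## Vegetation indices

Eleven indices are computed per pixel (NDVI, EVI, GNDVI, RE-NDVI, mND705,
GCI, VOG-REI1, SRI, PSSRa/b/c). Generic band names resolve to fixed
anchors — NIR = 800 nm, Red = 670 nm, Green = 550 nm, Blue = 450 nm,
red edge = 720 nm — and explicit `R_xxx` terms to the nearest sensed band
(ties to the lower index). The anchors are configurable; they are the
conventional choices for VNIR sensors but are not uniquely determined by
the index literature. EVI is evaluated on reflectance in [0, 1] with the
printed soil term (+1), which makes it the one non-ratio index: it is not
invariant to rescaling the cube.

Pixels whose formula denominator has magnitude below 1e-9 are marked
invalid and excluded from threshold masks, means and histograms, rather
than clamped — clamping would bias ROI statistics. Normalisation to [0, 1]
offers a `theoretical` mode (the definition's valid range, clipped) and an
`empirical` mode (observed min/max); a constant map normalises to 0.5.
Index threshold masks intersect (AND) across all enabled indices; with no
enabled masks the upstream refinement mask passes through. The default
unattended filter is NDVI ≥ 0.2, a deliberately permissive floor that
removes soil (NDVI ≈ 0.1) without cutting into mixed boundary pixels whose
majority component is vegetation.

## Combined Ranking Score

Per genotype and date, replicate observations are averaged after a QC step
that drops genotypes with fewer than 3 replicates at any date. Ranking uses
the later date (16 weeks after transplanting) by default — the date most
indicative of establishment success — and is configurable. Five quality
indices (PSSRb, NDVI, GCI, RE-NDVI, VOG-REI1) are each ranked across
genotypes (rank 1 = highest mean; ties share average ranks), and the
vegetation pixel count is ranked the same way (rank 1 = largest). The
score is

```
CRS = (Σ five index ranks + 5.0 × area rank) / 10
```

so the single area column carries the same total weight as the five quality
columns (50:50) and lower CRS is better. Final ordering is ascending CRS
with ties broken by area rank, then genotype id, making runs reproducible.
Strata: the top `n_top` CRS ranks are Superior, the bottom `n_bottom`
Inferior, and `n_mid` ranks centred on the median (starting on the lower
side for even splits) Intermediate — with (20, 10, 20) on 405 genotypes the
Intermediate block is ranks 198–207. A separate "quality rank"
(mean of the five per-index ranks, re-ranked) and "quantity rank" are
reported so the two halves of the score can be compared directly.

CRS–trait association uses Pearson correlation by default (Spearman
available) with the two-sided t-approximation p-value; group contrasts use
Welch's two-sample t-test between Superior and Inferior strata with stars
at 0.05/0.01/0.001.

## Temporal statistics

Per genotype, date and index, valid retained pixel values are binned into a
frequency histogram of absolute pixel counts — by default 20 uniform bins
over the index's valid range; bins are half-open with the last bin closed,
and out-of-range values are counted in the edge bins and flagged. Replicate
histograms are averaged element-wise (fractional counts are expected with
n = 3). The between-date area change ΔA = Σᵢ(f_late,i − f_early,i)
telescopes to the difference of total vegetation pixel counts, so it is
independent of binning; positive values indicate canopy expansion.

## Point-based validation

Masks are audited against manually annotated reference points: a uniform
without-replacement sample of pixels per image (200 per image in the
canonical design; 50 images give 10,000 points), labelled vegetation or
background, and compared with the mask value at each point. Metrics are
accuracy, precision, recall, specificity, F1 and Cohen's kappa, with
vegetation as the positive class; zero-denominator ratios are reported as
0 with an explicit flag. Reports are produced pooled and per canopy-
coverage group; coverage groups default to vegetation fraction < 0.2 → low,
≥ 0.5 → high, else intermediate (the cutpoints are a package default,
recorded in the report, not a community standard). The module also includes
an exhaustive integer-confusion-matrix reconstruction from rounded summary
rates, which recovers quantities (such as kappa) implied by a published
validation table.

## Synthetic data

The generators define the study conditions under which the pipeline is
tested; real imagery is not redistributable.

* **Endmembers** are parametric curves, not spectral-library samples:
  vegetation = 0.05 + 0.07·gauss(550, 40) + 0.50·sigmoid((λ−715)/10)
  (green peak, red edge, NIR plateau ≈ 0.55); soil = linear 0.15 → 0.40
  (bright, rising, no red edge); shadow = near-flat 0.04 → 0.055.
* **Scenes** place vegetation by thresholding a smoothed Gaussian random
  field at the coverage quantile, giving blob-shaped patches and hitting the
  target fraction to within pixel rounding; ~30% of the background is
  shadow. A seeded subset of boundary-band pixels (defaulting to 2% of the
  frame, capped by the band size) becomes convex mixtures with weight
  ~ U(0.3, 0.7), truth labelled by the majority component — emulating the
  mixed-pixel ambiguity of limited spatial resolution. Additive Gaussian
  noise (σ = 0.01 by default) is applied last, then values clip to [0, 1].
* **Populations** draw a latent vigor per genotype; quality and quantity
  latents are vigor plus independent Gaussian deviations scaled so their
  correlation equals `quality_quantity_corr` (default 0.3, matching the
  weak observed coupling between quality and quantity ranks in real
  populations). The eleven index means respond linearly to quality,
  pixel counts exponentially to quantity (always positive, strictly
  monotone), and traits to vigor: shoots ≈ 47 + 22·vigor, runners
  Poisson with log-link, height essentially independent. With full
  coupling and zero noise the CRS ordering provably equals the vigor
  ordering, which is the basis of the parameter-recovery test.

What the synthetic scenes do **not** emulate: illumination geometry and
specular structure, within-canopy spectral variability between genotypes,
sensor striping, and spatial autocorrelation of noise. Passing the
end-to-end tests therefore demonstrates the machinery is correct under
controlled mixing/noise, not that field accuracy will match.

## Problem sizes and numerical choices

End-to-end properties run on 64 × 64-pixel scenes (4,096 spectra, fully
embedded under the 50,000-pixel budget) with 10 seeds per condition — large
enough for stable blob geometry and coverage control, small enough that a
multi-seed sweep completes in minutes on one CPU. Reflectance is stored as
float32; ratio-index scale invariance therefore holds to ~1e-7 relative.
Calibration clamps reflectance at 1.5 (configurable) to contain specular
glints; negatives clip to zero. Band lookup ties resolve to the lower
index. Rank ties share average ranks, so every rank column sums to
N(N+1)/2.

## Known limitations

* The band-70/52/19 pseudo-RGB convention is treated as 0-based; a 1-based
  instrument export convention would shift each channel by one band
  (visually negligible, configurable).
* The automatic ε knee can over-merge when vegetation and soil form a
  continuous spectral gradient; the override exists precisely because the
  workflow is user-in-the-loop.
* CRS is a relative screening score. Its correlations with manual traits
  are moderate by construction of the problem (quality and quantity are
  partially decoupled), and it should not be read as a predictive model of
  any single trait.
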