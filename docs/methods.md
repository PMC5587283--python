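# Methods

This note documents the models behind `diamicro`: what each measurement
computes, what the synthetic-data generator emulates (and does not),
the tunable parameters with their defaults, and the numerical choices
made where the underlying protocol left the design open.

## Sarcomere length by 2D FFT

A striation image is thresholded (Otsu by default; a fixed-quantile
policy is available), mean-subtracted, zero-padded to the next power of
two at least twice each dimension, and transformed with a 2D FFT. The
physiological band is the radial annulus of spatial frequencies whose
periods lie in [1.5, 4.5] μm — lengths outside that window are not
physiological sarcomeres. The modal sarcomere length is the period of
the maximum-magnitude bin inside the annulus ("modal" because the
dominant spectral spacing is the most frequent banding period, not the
highest frequency present).

Numerical choices:

* **Bin width is reported** on every estimate
  (`frequency_bin_width_cyc_per_um`, 1/(padded size × pixel size)) so
  every tolerance can be stated in bins. With 512² images at
  0.1 μm/px the padded bin is ≈ 0.0098 cyc/μm.
* **Band edges are inclusive to within half a bin.** A grating whose
  period sits exactly on an edge has its spectral peak at the nearest
  lattice bin, which may fall half a bin outside the analytic window;
  the annulus is therefore extended by half a bin on each side. This
  realizes "1.5 μm is still physiological" without admitting 1.4 μm.
* **Error taxonomy.** If the strongest spectral peak overall (DC
  excluded) lies outside the annulus and dominates every in-band bin,
  the input has a real periodicity at an unphysiological length and an
  `OutOfBandError` is raised. If no annulus bin exceeds 5× the median
  annulus magnitude (configurable), there is nothing periodic in band
  and a `NoEstimateError` is raised — white noise must never yield a
  length. The 5× floor sits above the ≈ 4.4× max/median ratio of a
  Rayleigh-magnitude annulus of this size.
* **Ties** break toward the lower frequency (longer sarcomere), then
  the smaller orientation angle, making the output deterministic.
* The spectrum is computed on the **binarized** image by default (a
  flag allows grayscale for sensitivity checks).
* **Quantization limit.** The argmax of a 2D DFT lattice is at most
  √2/2 bins from the true radial frequency (half a bin per axis). On
  the frequency axes the error is ≤ 0.5 bins; at oblique orientations
  it can reach ≈ 0.7 bins. Sub-bin peak interpolation is deliberately
  out of scope; rotation invariance holds to within one bin.

## Autocorrelation oracle

The oracle mechanizes measuring sarcomeres "by hand": 16 intensity
profiles are sampled along the fiber axis, their autocorrelations are
averaged (weighted by profile variance), and the dominant in-band lag —
refined by 3-point parabolic interpolation — times the pixel size is
the period. If the orientation is not supplied, it is found by
maximizing the in-band autocorrelation peak over a 10° grid of profile
directions with local refinement; a gradient structure tensor is *not*
trusted here because interstitial edges can out-weigh long-period
banding and pull the tensor axis between the two. The oracle shares no
code with the spectral path, so their agreement (within one frequency
bin at noise SD ≤ 0.3) is a meaningful validation. A normalized peak
below 0.15 is a refusal (`NoEstimateError`), which white noise
reliably triggers.

## Interstitial ratio and branched fibers

A reference line is placed through the image center orthogonal to the
fibers (auto-placed from the mask's max-variation direction, or from a
supplied orientation), the fiber mask is run-length encoded along it,
partial runs at the frame are discarded, and the ratio is mean
interstitial width / mean fiber width. The aggregation is configurable
(`per_pair` averages adjacent gap/fiber ratios instead) because the
manual protocol does not pin it down; both are reported by the
pipeline's sensitivity path. When a banded grayscale image is the
input, a solid mask is first rebuilt by morphological closing with a
6 μm line element along the fiber axis — longer than any physiological
band period, shorter than realistic gaps are wide.

Branch detection skeletonizes each connected fiber component. A fiber
is branched iff some skeleton junction (degree ≥ 3 node cluster) has
two limbs, each at least 5 μm long (suppressing boundary spurs), whose
directions meet at no more than 150° — a "Y" is an acute bifurcation,
whereas limbs at ≈ 180° are two fibers touching or crossing, a merge
artifact, not a branch. Limb tracing stops at the next junction so a
short rung between touching fibers cannot masquerade as a daughter.

## Cross-section metrics

Fiber interiors (dark regions enclosed by the bright laminin boundary)
are labeled and grown through the boundary band by watershed, so the
boundary is split between adjacent fibers and per-fiber pixel counts
are unbiased to about half the boundary thickness (the 2% closure
tolerance against polygon ground truth reflects this). Fibers touching
the image border are excluded from every statistic, as their area is
truncated by the frame. Area is pixel count × (pixel size)²; pixel
coordinates are 0-based row-major; areas are μm², densities per mm²
(1 mm² = 10⁶ μm²).

A fiber is **centrally nucleated** iff a contained nucleus centroid has
normalized boundary distance ≥ 0.4 (Euclidean distance to the fiber
boundary over the fiber's maximum interior distance). The threshold is
a free parameter (exposed in config); 0.4 splits the generator's
central (≥ 0.8) and peripheral (≤ 0.15) placements with a wide margin,
and real peripheral myonuclei hug the basal lamina.

A **macrophage** is a CD68 connected component overlapping a nucleus
component by at least 30% of the smaller of the two; any-pixel overlap
is available as a sensitivity flag. Density divides the count by the
full field of view in mm², not a tissue-masked area.

## Synthetic data: what it emulates, what it does not

The generator produces the study's two image families with known truth:

* **Striation images**: parallel fibers with raised-cosine banding
  along the fiber axis (thresholdable, smooth, analytically known
  period), jittered fiber/gap widths realizing a target
  interstitial-to-fiber ratio, optional additive Gaussian noise, and an
  exact count round(branch_fraction × n_fibers) of Y-branched fibers.
  A branched fiber splits at a junction (uniform in the middle 60% of
  the frame, so the Y is fully in frame) into two quarter-width
  daughters diverging at ±15° whose centers settle at ±3w/8 — inside
  the trunk's own layout slot, so branching never merges neighbors, and
  striations stay parallel to the trunk. Defaults: 0.1 μm/px, 512²,
  6 μm fibers, gap ratio 0.26 (the pooled dystrophic value), noise 0.
* **Cross-sections**: Voronoi cells of jittered-grid (blue-noise) seed
  points tessellating a centered region sized to n_fibers × mean CSA —
  convex, space-filling, laminin-like; cell polygons (for the shoelace
  oracle) and the rasterized labels come from the same exact Voronoi
  geometry. One nucleus per fiber at the innermost point (central) or
  in the outer 15% band (peripheral); macrophages as disks present in
  both nuclei and CD68 channels, Poisson-counted at the requested
  density with a minimum separation so counts stay unambiguous;
  optional CD68-only blobs and free nuclei as colocalization
  distractors. Defaults: 0.25 μm/px, 512², 40 fibers.
* **Cohort tables**: per-image metric values drawn per group from a
  mean/SD table, redrawn while negative (all six metrics are
  nonnegative). The defaults reproduce the source study's printed
  group statistics, layered from pooled genotype values through
  age-resolved to (age × region)-resolved values where those were
  reported. The printed control interstitial SD (0.52, exceeding its
  0.12 mean) is treated as a misprint of 0.052. Because of the
  truncation, the generator's true expectation is the zero-truncated
  normal mean (`truncated_mean`), which is what recovery tests target;
  for hard-truncated metrics (e.g. control branching, 1.03 ± 5.11) it
  sits far above the nominal mean.

Not emulated: point-spread blur, photobleaching, staining variability,
3D stacks, fiber-type heterogeneity, curved or tapering fibers, and
correlated metrics within an image (cohort draws are independent across
metrics). Passing ground-truth closure on these images therefore shows
the measurement chain is correct, not that it is robust to every
real-world artifact; the noise-sweep and threshold-sensitivity tests
cover a first slice of that robustness.

## Statistics

Per metric, all pairwise comparisons among the 18 genotype × age ×
region groups plus a pooled mdx-vs-control contrast form one
Holm–Šidák family (the family boundary is a design choice, recorded in
the report header; the protocol's "every permutation" wording does not
fix it). Raw p-values come from Welch's t-test — the group variances
of these metrics are grossly unequal, and Welch is the robust default —
with a pooled-variance option for sensitivity. The step-down adjustment
for sorted p₍₁₎ ≤ … ≤ p₍ₖ₎ in a family of m is
adj₍ᵢ₎ = maxⱼ≤ᵢ [1 − (1 − p₍ⱼ₎)^(m−j+1)], clipped to 1, returned in
input order; it reduces to the raw p at m = 1 and to single-step Šidák
for the smallest p. Groups with n < 2 are skipped and logged. The unit
of analysis is the per-image measurement; animal-level clustering is
out of scope. The engine's family-wise error rate under a simulated
global null (18 groups, 2000 replicates) stays below α = 0.05 within
Monte-Carlo tolerance.

Derived quantities: `percent_difference(a, b) = 100(a−b)/b` (b > 0) and
`regional_spread`, the maximum pairwise percent difference among the
three regional means of one genotype × age.

## Problem sizes

Validation runs use 512² px images (the sarcomere sweeps), 40-fiber
sections, 20 seeds per branch fraction, 100-grating oracle sweeps,
2000-replicate null simulations, and 100 × 30-images/group cohort
recoveries; these sizes give sub-bin / sub-SEM resolution on every
quantity checked while keeping the full suite in the low minutes.

## Known limitations

* The spectral estimator's accuracy is bounded by lattice quantization
  (≈ √2/2 bins off-axis); applications needing finer resolution should
  enlarge or further pad the FFT window.
* Watershed boundary-splitting assumes boundaries of roughly uniform
  thickness; heavily over-stained laminin would bias CSA low.
* The branch detector reports whether a fiber branches, not trunk vs
  daughter identity, and a true X-crossing of two separate fibers in
  one optical plane can be read as branching (the ≤ 150° rule removes
  only touch/merge artifacts).
* The auto-placed reference line assumes one dominant fiber
  orientation per image; strongly curved fields need an explicit line.
* Cohort draws are independent normals per metric; they reproduce group
  means/SDs but not inter-metric correlations (e.g. the reported
  regeneration–sarcomere-length association).
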