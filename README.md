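# diamicro

Morphometry of striated-muscle confocal imagery for studies of the
dystrophic (mdx) mouse diaphragm. The package quantifies six
image-derived microstructure metrics and runs the accompanying
multi-way statistical comparison, with a seeded synthetic-image
generator that provides exact ground truth for every stage.

**Who it is for.** Muscle physiologists and image analysts quantifying
diaphragm (or other striated-muscle) remodeling across experimental
groups — genotype (mdx vs healthy control), age (3 / 7 / 10 months) and
anatomical region (dorsal / midcostal / ventral) — from 60x confocal
images of whole-mounted fibers and immunostained cross-sections.

## The measurements

From **longitudinal** (whole-mount, alpha-actinin-stained) images:

1. **Modal sarcomere length** — the image is thresholded, a 2D FFT is
   applied, the frequency plane is band-pass filtered to physiological
   sarcomere lengths (periods L with 1.5 ≤ L ≤ 4.5 μm, edges
   inclusive), and the modal length is the period of the
   maximum-magnitude bin in that annulus: L = 1/‖**f**_peak‖. Periods
   outside the band raise an error rather than a number. An independent
   autocorrelation oracle (mean profile autocorrelation along the fiber
   axis, parabolic-refined dominant lag) cross-checks the estimator.
2. **Interstitial space ratio** — mean interstitial width divided by
   mean fiber width, both read as run lengths along a reference line
   placed orthogonal to the fibers.
3. **Percent branched fibers** — fibers whose skeleton contains a
   "Y" junction (two limbs each ≥ 5 μm meeting at ≤ 150°), as a
   percentage of fibers in the image.

From **cross-section** (laminin / nuclei / CD68) images:

4. **Fiber cross-sectional area (CSA)** — watershed segmentation of
   fiber interiors bounded by the laminin signal; area = pixel count ×
   (pixel size)², in μm²; border-touching fibers excluded.
5. **Percent regenerating fibers** — fibers with a centrally located
   nucleus (nucleus centroid at normalized boundary distance ≥ 0.4).
6. **Macrophage density** — CD68⁺ objects overlapping a nucleus
   (≥ 30% of the smaller component), per mm² of field of view.

**Statistics.** Within each metric, every permutation of genotype ×
age × region is compared pairwise (plus a pooled genotype contrast)
with Welch's t-test; the Holm–Šidák step-down procedure controls the
family-wise error rate, with sorted p-values adjusted as
adj₍ᵢ₎ = maxⱼ≤ᵢ [1 − (1 − p₍ⱼ₎)^(m−j+1)], significance at α = 0.05.

## Worked example

```python
from diamicro import (StriationSpec, generate_striation_image,
                      estimate_sarcomere_length, sarcomere_oracle,
                      CohortComparisons, sample_cohort)
from diamicro.cohorts import default_cohort_spec

# a noisy synthetic striation image with a 2.53 um sarcomere period
spec = StriationSpec(period_um=2.53, noise_sd=0.2, seed=7)
image, truth = generate_striation_image(spec)
est = estimate_sarcomere_length(image)
print(f"modal sarcomere length: {est.modal_length_um:.3f} um")
print(f"autocorrelation oracle: {sarcomere_oracle(image):.3f} um")

# a full synthetic cohort (30 images/group) through the comparison engine
table = sample_cohort(default_cohort_spec(n_per_group=30, seed=1))
results = CohortComparisons(table).fit(alpha=0.05)
pooled = results.comparisons[results.comparisons.group_a == "mdx (pooled)"]
print(pooled[["metric", "mean_a", "mean_b", "adjusted_p", "significant"]])
```

prints

```
modal sarcomere length: 2.560 um
autocorrelation oracle: 2.518 um
                    metric     mean_a     mean_b   adjusted_p  significant
                   csa_um2 549.836121 522.321481 1.000000e+00        False
        interstitial_ratio   0.251902   0.114699 0.000000e+00         True
macrophage_density_per_mm2 350.167670  63.594966 0.000000e+00         True
          percent_branched  14.001721   2.591838 0.000000e+00         True
      percent_regenerating  16.016557   2.926093 0.000000e+00         True
       sarcomere_length_um   2.530979   2.716071 5.881517e-12         True
```

The spectral estimate (2.560 μm) and the oracle (2.518 μm) bracket the
true 2.53 μm period within one frequency bin. In the cohort run, the
pooled mdx-vs-control contrast is significant for five of the six
metrics; the CSA contrast — the smallest effect in the defaults — is
not at this sample size. `results.summary()` renders the full text
report; `mean_a`/`mean_b` are the pooled mdx/control group means.

A complete generate → measure → compare → report run is one command:

```sh
dia-micro run --config examples/demo_run.json
```

which writes `metrics.csv`, `comparisons.csv`, `summary.csv`, figures
and a reproducibility manifest to the configured output directory. Each
stage is also available standalone (`dia-micro generate|sarcomere|
longitudinal|section|stats|report`).

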