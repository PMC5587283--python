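"""Default cohort parameters for the synthetic-cohort generator.

The defaults reproduce the reported group statistics of the mdx /
control diaphragm study the package re-implements: pooled
genotype-level mean +/- SD for each of the six metrics, refined by the
age-level and (age x region)-level values that were reported for specific
metrics.  The layering is:

1. genotype pooled mean/SD for every metric (base layer),
2. age-specific overrides where age-resolved values exist (sarcomere and
   CSA in controls; CSA and branching in mdx; branching in controls;
   interstitial ratio in both genotypes),
3. (age x region) overrides where regionally resolved values exist
   (mdx macrophage density at 3/7/10 months; CSA in both genotypes at
   10 months).

Note the reported control interstitial ratio is 0.12 +/- 0.52, an SD
more than four times the mean of a nonnegative quantity and almost
certainly a misprint of 0.052; the default uses 0.052.  Neither number
is treated as ground truth by any test.
"""

from __future__ import annotations

from .synthesize import AGES_MONTHS, GENOTYPES, METRICS, REGIONS, CohortSpec

__all__ = ["POOLED_GENOTYPE_PARAMS", "default_group_params", "default_cohort_spec"]

#: pooled mean/SD per genotype for each metric
POOLED_GENOTYPE_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "control": {
        "sarcomere_length_um": (2.70, 0.35),
        "interstitial_ratio": (0.12, 0.052),  # printed SD 0.52, see module docstring
        "percent_branched": (1.03, 5.11),
        "csa_um2": (530.07, 260.45),
        "percent_regenerating": (1.29, 2.83),
        "macrophage_density_per_mm2": (51.97, 46.82),
    },
    "mdx": {
        "sarcomere_length_um": (2.53, 0.19),
        "interstitial_ratio": (0.26, 0.12),
        "percent_branched": (9.48, 13.91),
        "csa_um2": (502.37, 296.32),
        "percent_regenerating": (14.83, 8.97),
        "macrophage_density_per_mm2": (345.15, 213.63),
    },
}

#: age-resolved overrides: (genotype, age) -> {metric: (mean, sd)}
_AGE_OVERRIDES: dict[tuple[str, int], dict[str, tuple[float, float]]] = {
    ("control", 3): {
        "sarcomere_length_um": (2.69, 0.37),
        "csa_um2": (562.10, 250.51),
        "percent_branched": (1.79, 6.78),
        "interstitial_ratio": (0.12, 0.06),
    },
    ("control", 7): {
        "sarcomere_length_um": (2.66, 0.30),
        "csa_um2": (566.05, 264.32),
        "percent_branched": (0.14, 1.32),
        "interstitial_ratio": (0.10, 0.03),
    },
    ("control", 10): {
        "sarcomere_length_um": (2.79, 0.32),
        "csa_um2": (484.79, 257.43),
        "percent_branched": (0.12, 1.16),
        "interstitial_ratio": (0.13, 0.05),
    },
    ("mdx", 3): {
        "csa_um2": (683.98, 334.53),
        "percent_branched": (12.13, 15.71),
        "interstitial_ratio": (0.27, 0.11),
    },
    ("mdx", 7): {
        "csa_um2": (457.37, 254.91),
        "percent_branched": (8.79, 13.10),
        "interstitial_ratio": (0.20, 0.08),
    },
    ("mdx", 10): {
        "csa_um2": (442.33, 276.82),
        "percent_branched": (5.70, 10.02),
        "interstitial_ratio": (0.29, 0.13),
    },
}

#: (age x region)-resolved overrides: (genotype, age, region) -> {metric: (mean, sd)}
_REGION_OVERRIDES: dict[tuple[str, int, str], dict[str, tuple[float, float]]] = {
    # mdx macrophage density, all three ages
    ("mdx", 3, "dorsal"): {"macrophage_density_per_mm2": (256.08, 158.07)},
    ("mdx", 3, "midcostal"): {"macrophage_density_per_mm2": (519.81, 289.55)},
    ("mdx", 3, "ventral"): {"macrophage_density_per_mm2": (210.17, 182.32)},
    ("mdx", 7, "dorsal"): {"macrophage_density_per_mm2": (347.23, 162.20)},
    ("mdx", 7, "midcostal"): {"macrophage_density_per_mm2": (314.24, 141.28)},
    ("mdx", 7, "ventral"): {"macrophage_density_per_mm2": (328.74, 193.26)},
    # 10-month regional CSA, both genotypes
    ("mdx", 10, "dorsal"): {
        "macrophage_density_per_mm2": (361.93, 212.19),
        "csa_um2": (351.01, 282.23),
    },
    ("mdx", 10, "midcostal"): {
        "macrophage_density_per_mm2": (434.41, 193.70),
        "csa_um2": (488.34, 243.74),
    },
    ("mdx", 10, "ventral"): {
        "macrophage_density_per_mm2": (319.24, 201.02),
        "csa_um2": (509.59, 271.94),
    },
    ("control", 10, "dorsal"): {"csa_um2": (335.25, 220.58)},
    ("control", 10, "midcostal"): {"csa_um2": (464.25, 205.73)},
    ("control", 10, "ventral"): {"csa_um2": (589.47, 271.69)},
}


def default_group_params(
    pooled_only: bool = False,
) -> dict[tuple[str, int, str], dict[str, tuple[float, float]]]:
    """Full (genotype, age, region) -> {metric: (mean, sd)} table.

    ``pooled_only=True`` skips the age/region refinement layers and gives
    every group its genotype's pooled parameters — the configuration used
    for pooled-contrast parameter-recovery runs.
    """
    table: dict[tuple[str, int, str], dict[str, tuple[float, float]]] = {}
    for g in GENOTYPES:
        for a in AGES_MONTHS:
            for r in REGIONS:
                params = dict(POOLED_GENOTYPE_PARAMS[g])
                if not pooled_only:
                    params.update(_AGE_OVERRIDES.get((g, a), {}))
                    params.update(_REGION_OVERRIDES.get((g, a, r), {}))
                table[(g, a, r)] = {m: params[m] for m in METRICS}
    return table


def default_cohort_spec(n_per_group: int = 6, seed: int = 0, pooled_only: bool = False) -> CohortSpec:
    """CohortSpec with the study-default group parameters."""
    return CohortSpec(
        group_params=default_group_params(pooled_only=pooled_only),
        n_per_group=n_per_group,
        seed=seed,
    )
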