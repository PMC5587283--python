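"""Generator-side ground truth: determinism, geometry, cohort sampling."""

import numpy as np
import pytest

from diamicro import (
    CohortSpec,
    CrossSectionSpec,
    StriationSpec,
    generate_cross_section,
    generate_striation_image,
    sample_cohort,
)
from diamicro.cohorts import default_cohort_spec, default_group_params
from diamicro.errors import CalibrationError, ConfigurationError, PackingError
from diamicro.synthesize import METRICS, truncated_mean


def _census_ratio(mask: np.ndarray, axis: int) -> tuple[float, int]:
    """Brute-force per-boundary pixel census: mean gap / mean fiber width.

    Run-length encodes every line across the fibers, discarding border
    partial runs; independent of the package's profile code.
    """
    fibs, gaps = [], []
    n_lines = 0
    arr = mask if axis == 0 else mask.T
    for col in range(arr.shape[1]):
        line = arr[:, col]
        change = np.flatnonzero(np.diff(line.astype(np.int8))) + 1
        bounds = np.concatenate([[0], change, [len(line)]])
        runs = [(bool(line[a]), b - a) for a, b in zip(bounds[:-1], bounds[1:])][1:-1]
        if not runs:
            continue
        n_lines += 1
        fibs += [w for isfib, w in runs if isfib]
        gaps += [w for isfib, w in runs if not isfib]
    return float(np.mean(gaps)) / float(np.mean(fibs)), n_lines


class TestStriation:
    def test_seed_determinism_bit_identical(self):
        spec = StriationSpec(period_um=2.5, noise_sd=0.2, branch_fraction=0.25, seed=9)
        img1, t1 = generate_striation_image(spec)
        img2, t2 = generate_striation_image(spec)
        np.testing.assert_array_equal(img1.data, img2.data)
        assert t1.branched_fiber_ids == t2.branched_fiber_ids

    def test_nyquist_violation_rejected(self):
        with pytest.raises(CalibrationError):
            StriationSpec(period_um=0.19, pixel_size_um=0.1)

    def test_axis_profile_autocorrelation_peaks_at_period(self, grating_2p5):
        spec, img, _ = grating_2p5
        row = img.data[256].astype(float)
        row -= row.mean()
        ac = np.correlate(row, row, mode="full")[len(row) - 1:]
        lag = int(np.argmax(ac[10:40])) + 10  # period 2.5 um = 25 px
        assert lag == 25

    def test_zero_branch_fraction_means_no_branches(self, fibered_image):
        _, _, truth = fibered_image
        assert truth.branched_fiber_ids == []

    def test_gap_ratio_recovered_by_pixel_census(self):
        # thin fibers so ~40 fit the frame at the target ratio
        spec = StriationSpec(period_um=2.5, pixel_size_um=0.2, fiber_width_um=2.0,
                             gap_to_fiber_ratio=0.26, image_shape=(512, 256), seed=4)
        img, truth = generate_striation_image(spec)
        assert 35 <= len(truth.fiber_ids) <= 45
        ratio, n_lines = _census_ratio(truth.fiber_mask, axis=0)
        assert n_lines > 0
        assert 0.24 <= ratio <= 0.28
        assert truth.true_interstitial_ratio == pytest.approx(ratio, rel=0.08)

    def test_branch_count_is_rounded_fraction_of_fibers(self):
        for bf in (0.1, 0.5):
            _, truth = generate_striation_image(StriationSpec(branch_fraction=bf, seed=6))
            assert len(truth.branched_fiber_ids) == round(bf * len(truth.fiber_ids))


class TestCrossSection:
    def test_seed_determinism(self):
        spec = CrossSectionSpec(n_fibers=12, csa_mean_um2=200.0, image_shape=(256, 256),
                                macrophage_density_per_mm2=300.0, seed=5)
        img1, t1 = generate_cross_section(spec)
        img2, t2 = generate_cross_section(spec)
        np.testing.assert_array_equal(img1.data, img2.data)
        assert t1.polygon_areas_um2 == t2.polygon_areas_um2

    def test_all_central_when_fraction_one(self):
        spec = CrossSectionSpec(n_fibers=10, csa_mean_um2=150.0, image_shape=(256, 256),
                                central_nucleus_fraction=1.0, seed=1)
        _, truth = generate_cross_section(spec)
        assert all(truth.central_nucleus_flags)

    def test_zero_density_means_empty_cd68(self):
        spec = CrossSectionSpec(n_fibers=10, csa_mean_um2=150.0, image_shape=(256, 256),
                                macrophage_density_per_mm2=0.0, seed=1)
        img, truth = generate_cross_section(spec)
        assert not img.channel("cd68").any()
        assert truth.macrophage_count == 0

    def test_packing_error_when_fibers_cannot_tile(self):
        with pytest.raises(PackingError):
            generate_cross_section(
                CrossSectionSpec(n_fibers=40, csa_mean_um2=500.0,
                                 pixel_size_um=0.25, image_shape=(512, 512))
            )

    def test_macrophage_count_is_poisson_at_density(self):
        # 500 / mm^2 on a 0.25 mm^2 field: expectation 125
        devs = [
            abs(generate_cross_section(
                CrossSectionSpec(n_fibers=4, csa_mean_um2=500.0, pixel_size_um=1.0,
                                 image_shape=(500, 500),
                                 macrophage_density_per_mm2=500.0, seed=seed)
            )[1].macrophage_count - 125)
            for seed in range(20)
        ]
        assert np.mean(devs) < 2 * np.sqrt(125)  # mean |dev| ~ 0.8 sd
        assert max(devs) < 3 * np.sqrt(125) + 1

    def test_ground_truth_closure_every_object_listed_once(self):
        spec = CrossSectionSpec(n_fibers=15, csa_mean_um2=200.0, image_shape=(256, 256),
                                central_nucleus_fraction=0.4, seed=3)
        _, truth = generate_cross_section(spec)
        labels = set(np.unique(truth.label_mask)) - {0}
        assert labels == set(range(1, 16))
        assert len(truth.polygon_areas_um2) == 15
        assert len(truth.central_nucleus_flags) == 15
        assert len(truth.nucleus_centroids_um) == 15


class TestCohort:
    def test_zero_sd_draws_equal_group_means(self):
        params = {k: {m: (v[0], 0.0) for m, v in grp.items()}
                  for k, grp in default_group_params().items()}
        table = sample_cohort(CohortSpec(group_params=params, n_per_group=3, seed=0))
        for (g, a, r, m), sub in table.groupby(
            ["genotype", "age_months", "region", "metric"], observed=True
        ):
            assert (sub["value"] == params[(g, a, r)][m][0]).all()

    def test_large_n_sample_mean_converges(self):
        # pooled mdx sarcomere 2.53 +/- 0.19: SE at n=10000 is 0.0019
        table = sample_cohort(default_cohort_spec(n_per_group=10000, seed=11,
                                                  pooled_only=True))
        sub = table[(table.genotype == "mdx") & (table.metric == "sarcomere_length_um")
                    & (table.age_months == 3) & (table.region == "dorsal")]
        assert len(sub) == 10000
        assert abs(sub["value"].mean() - 2.53) <= 0.006

    def test_regional_csa_ordering_preserved_in_sample_means(self):
        # control 10-month regional CSA 335.25 < 464.25 < 589.47 um^2
        table = sample_cohort(default_cohort_spec(n_per_group=1000, seed=21))
        sub = table[(table.genotype == "control") & (table.age_months == 10)
                    & (table.metric == "csa_um2")]
        means = sub.groupby("region", observed=True)["value"].mean()
        assert means["dorsal"] < means["midcostal"] < means["ventral"]

    def test_draws_are_nonnegative_and_deterministic(self):
        spec = default_cohort_spec(n_per_group=50, seed=2)
        t1, t2 = sample_cohort(spec), sample_cohort(spec)
        assert (t1["value"] >= 0).all()
        assert t1.equals(t2)
        assert set(t1["metric"].unique()) == set(METRICS)

    def test_missing_group_is_a_configuration_error(self):
        params = default_group_params()
        params.pop(("mdx", 7, "ventral"))
        with pytest.raises(ConfigurationError):
            CohortSpec(group_params=params)

    def test_truncated_mean_matches_empirical_redraw_mean(self):
        # control branching 1.03 +/- 5.11 truncates hard at zero
        rng = np.random.default_rng(0)
        v = rng.normal(1.03, 5.11, 400000)
        v = v[v >= 0]
        assert truncated_mean(1.03, 5.11) == pytest.approx(v.mean(), abs=0.03)
        assert truncated_mean(2.53, 0.0) == 2.53
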