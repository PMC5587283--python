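"""Holm-Sidak engine: closed forms, invariances, error control, power."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from diamicro import (
    CohortComparisons,
    group_summary,
    holm_sidak,
    percent_difference,
    regional_spread,
    regional_spread_from_means,
    sample_cohort,
)
from diamicro.cohorts import default_cohort_spec
from diamicro.errors import ConfigurationError
from diamicro.stats import simulate_null_fwer


def _table(groups: dict[tuple, list[float]], metric="csa_um2") -> pd.DataFrame:
    rows = []
    for (g, a, r), vals in groups.items():
        for i, v in enumerate(vals):
            rows.append((g, a, r, f"{g}{a}{r}{i}", metric, v))
    return pd.DataFrame(rows, columns=["genotype", "age_months", "region",
                                       "image_id", "metric", "value"])


class TestSummary:
    def test_constant_group(self):
        out = group_summary(_table({("mdx", 3, "dorsal"): [2, 2, 2]}))
        assert out.iloc[0]["mean"] == 2 and out.iloc[0]["sd"] == 0 and out.iloc[0]["n"] == 3

    def test_simple_group(self):
        out = group_summary(_table({("mdx", 3, "dorsal"): [1, 2, 3]}))
        assert out.iloc[0]["mean"] == 2 and out.iloc[0]["sd"] == 1

    def test_sampled_cohort_summary_matches_parameters(self):
        table = sample_cohort(default_cohort_spec(n_per_group=2000, seed=3, pooled_only=True))
        out = group_summary(table)
        row = out[(out.metric == "sarcomere_length_um") & (out.genotype == "mdx")
                  & (out.age_months == 3) & (out.region == "dorsal")].iloc[0]
        assert row["mean"] == pytest.approx(2.53, abs=2 * 0.19 / np.sqrt(2000))
        assert row["sd"] == pytest.approx(0.19, rel=0.1)


class TestHolmSidak:
    def test_closed_form_triplet(self):
        np.testing.assert_allclose(
            holm_sidak([0.01, 0.02, 0.04]), [0.029701, 0.0396, 0.04], atol=1e-9)

    def test_single_comparison_unadjusted(self):
        assert holm_sidak([0.04]) == pytest.approx([0.04])

    def test_zeros_stay_zero(self):
        assert holm_sidak([0.0, 0.0, 0.0]) == pytest.approx([0.0, 0.0, 0.0])

    def test_domain_error(self):
        with pytest.raises(ValueError):
            holm_sidak([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=25))
    @settings(max_examples=60, deadline=None)
    def test_matches_statsmodels_and_is_monotone(self, pvals):
        adj = holm_sidak(pvals)
        ref = multipletests(pvals, method="holm-sidak")[1]
        np.testing.assert_allclose(adj, ref, atol=1e-12)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)
        # smallest p gets the single-step Sidak correction
        i = order[0]
        assert adj[i] == pytest.approx(1 - (1 - pvals[i]) ** len(pvals))


class TestPercentDifference:
    def test_macrophage_worked_example(self):
        assert percent_difference(519.81, 210.17) == pytest.approx(147.3, abs=0.05)
        assert round(percent_difference(519.81, 210.17)) == 147

    def test_identity_and_simple_cases(self):
        assert percent_difference(5.0, 5.0) == 0.0
        assert percent_difference(3.0, 2.0) == pytest.approx(50.0)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(1.0, 0.0)

    def test_regional_spread_examples(self):
        assert regional_spread_from_means([256.08, 519.81, 210.17]) == pytest.approx(147.3, abs=0.05)
        assert regional_spread_from_means([7.0, 7.0, 7.0]) == 0.0
        assert regional_spread_from_means([100.0, 150.0, 120.0]) == pytest.approx(50.0)

    def test_regional_spread_from_table_and_missing_region(self):
        t = _table({("mdx", 3, "dorsal"): [256.08], ("mdx", 3, "midcostal"): [519.81],
                    ("mdx", 3, "ventral"): [210.17]}, metric="macrophage_density_per_mm2")
        assert regional_spread(t, "macrophage_density_per_mm2", "mdx", 3) == pytest.approx(147.3, abs=0.05)
        with pytest.raises(ConfigurationError):
            regional_spread(t.iloc[:2], "macrophage_density_per_mm2", "mdx", 3)


class TestCompareAll:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        v = rng.normal(10, 1, 20).tolist()
        res = CohortComparisons(_table({("mdx", 3, "dorsal"): v,
                                        ("control", 3, "dorsal"): v})).fit()
        assert not res.comparisons["significant"].any()
        assert (res.comparisons["adjusted_p"] >= res.comparisons["raw_p"] - 1e-12).all()

    def test_welch_p_matches_scipy(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 12).tolist()
        b = rng.normal(1, 2, 17).tolist()
        res = CohortComparisons(_table({("mdx", 3, "dorsal"): a,
                                        ("control", 3, "dorsal"): b})).fit(
            include_pooled_genotype=False)
        expected = sps.ttest_ind(a, b, equal_var=False).pvalue
        assert res.comparisons.iloc[0]["raw_p"] == pytest.approx(expected, rel=1e-9)

    def test_pooled_variance_option(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 10).tolist()
        b = rng.normal(1, 1, 10).tolist()
        res = CohortComparisons(_table({("mdx", 3, "dorsal"): a,
                                        ("control", 3, "dorsal"): b})).fit(
            test="pooled", include_pooled_genotype=False)
        expected = sps.ttest_ind(a, b, equal_var=True).pvalue
        assert res.comparisons.iloc[0]["raw_p"] == pytest.approx(expected, rel=1e-9)

    def test_row_order_permutation_invariance(self):
        table = sample_cohort(default_cohort_spec(n_per_group=5, seed=4))
        res1 = CohortComparisons(table).fit()
        shuffled = table.sample(frac=1.0, random_state=99).reset_index(drop=True)
        res2 = CohortComparisons(shuffled).fit()
        c1 = res1.comparisons.sort_values(["metric", "group_a", "group_b"]).reset_index(drop=True)
        c2 = res2.comparisons.sort_values(["metric", "group_a", "group_b"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(c1, c2)

    def test_small_group_skipped_and_logged(self):
        res = CohortComparisons(_table({("mdx", 3, "dorsal"): [1.0],
                                        ("control", 3, "dorsal"): [1.0, 2.0, 3.0]})).fit()
        assert len(res.comparisons) == 0 or not (
            res.comparisons[["group_a", "group_b"]].apply(
                lambda r: "mdx/3/dorsal" in (r.group_a, r.group_b), axis=1).any())
        assert any("mdx" in str(s) for s in res.skipped)

    def test_summary_text_renders(self):
        table = sample_cohort(default_cohort_spec(n_per_group=4, seed=5))
        text = CohortComparisons(table).fit().summary()
        assert "Holm-Sidak" in text and "alpha" in text

    def test_fwer_bounded_under_global_null(self):
        fwer = simulate_null_fwer(n_groups=18, n_per_group=10, n_reps=400, seed=17)
        assert fwer <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 400)

    def test_pooled_genotype_contrast_has_power_at_study_effect_sizes(self):
        # regenerating-fiber contrast (14.83 vs 1.29) at n=30/group
        hits = 0
        for seed in range(25):
            table = sample_cohort(default_cohort_spec(n_per_group=30, seed=1000 + seed,
                                                      pooled_only=True))
            sub = table[table.metric == "percent_regenerating"]
            res = CohortComparisons(sub).fit()
            pooled = res.comparisons[res.comparisons.group_a == "mdx (pooled)"]
            hits += bool(pooled.iloc[0]["significant"])
        assert hits >= 24  # >95% power
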