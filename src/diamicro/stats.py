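"""Holm-Sidak family-wise comparison engine for cohort metric tables.

The analysis design mirrors the source study: within every metric, every
permutation of genotype (mdx / control), age (3, 7, 10 months) and
diaphragm region (dorsal / midcostal / ventral) is compared pairwise,
plus a pooled genotype contrast; raw p-values come from Welch's
two-sample t-test (robust to the unequal group variances these metrics
exhibit; a pooled-variance option exists for sensitivity analyses), and
the Holm-Sidak step-down procedure controls the family-wise error rate
within each metric's family.  Significance is asserted at alpha = 0.05.

The engine follows the Model/Results idiom: build a
:class:`CohortComparisons` model from a long-format metric table, call
``fit()``, and read estimates off the returned
:class:`ComparisonResults` (``summaries``, ``comparisons``,
``summary()``).

The step-down Sidak adjustment for sorted p-values p_(1) <= ... <= p_(k)
in a family of m comparisons is

    adj_(i) = max_{j <= i} [ 1 - (1 - p_(j))^(m - j + 1) ],   clipped to 1,

returned in the original order.  It reduces to the single-step Sidak
1 - (1 - p)^m for the smallest p and to the raw p at m = 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError
from .synthesize import GENOTYPES, METRICS, REGIONS

__all__ = [
    "group_summary",
    "holm_sidak",
    "percent_difference",
    "regional_spread",
    "regional_spread_from_means",
    "CohortComparisons",
    "ComparisonResults",
    "simulate_null_fwer",
]

GROUP_COLS = ["genotype", "age_months", "region"]


def group_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean, sample SD (n-1 denominator) and n per group per metric.

    Empty groups are simply absent from the output (they carry no rows).
    """
    _check_table(table)
    g = table.groupby(["metric", *GROUP_COLS], observed=True)["value"]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    return out


def holm_sidak(raw_p, m: int | None = None) -> np.ndarray:
    """Step-down Sidak adjusted p-values, in the input order."""
    p = np.asarray(raw_p, dtype=np.float64)
    if p.ndim != 1:
        raise ValueError("raw_p must be 1D; see _holm_sidak_2d for batches")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    k = len(p)
    if k == 0:
        return p.copy()
    if m is None:
        m = k
    if m < k:
        raise ValueError("family size m cannot be smaller than the number of p-values")
    order = np.argsort(p, kind="stable")
    exps = m - np.arange(k)  # m - j + 1 for 1-based rank j
    adj_sorted = np.maximum.accumulate(1.0 - (1.0 - p[order]) ** exps)
    adj = np.empty(k)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def _holm_sidak_2d(p: np.ndarray) -> np.ndarray:
    """Row-wise step-down Sidak for (reps, m) arrays (simulation path)."""
    m = p.shape[1]
    order = np.argsort(p, axis=1, kind="stable")
    psort = np.take_along_axis(p, order, axis=1)
    adj_sorted = np.minimum(
        np.maximum.accumulate(1.0 - (1.0 - psort) ** (m - np.arange(m)), axis=1), 1.0
    )
    adj = np.empty_like(p)
    np.put_along_axis(adj, order, adj_sorted, axis=1)
    return adj


def percent_difference(a: float, b: float) -> float:
    """100 * (a - b) / b; the reference value b must be positive."""
    if b <= 0:
        raise ValueError(f"reference mean must be positive, got {b}")
    return 100.0 * (a - b) / b


def regional_spread_from_means(means) -> float:
    """Max pairwise percent difference among three regional means."""
    vals = [float(v) for v in means]
    if len(vals) != 3:
        raise ValueError("need exactly three regional means")
    return max(
        percent_difference(max(a, b), min(a, b))
        for a, b in itertools.combinations(vals, 2)
    )


def regional_spread(table: pd.DataFrame, metric: str, genotype: str, age_months: int) -> float:
    """Regional spread of a metric for one genotype x age from a metric table."""
    sub = table[
        (table["metric"] == metric)
        & (table["genotype"] == genotype)
        & (table["age_months"] == age_months)
    ]
    means = sub.groupby("region", observed=True)["value"].mean()
    missing = set(REGIONS) - set(means.index)
    if missing:
        raise ConfigurationError(f"missing region(s) {sorted(missing)} for {genotype}/{age_months}m")
    return regional_spread_from_means([means[r] for r in REGIONS])


# ---------------------------------------------------------------------------
# Welch / pooled two-sample t from sufficient statistics
# ---------------------------------------------------------------------------

def _two_sample_p(ma, va, na, mb, vb, nb, test: str = "welch"):
    """Two-sided two-sample t-test p from means/variances/counts (vectorized)."""
    ma, va, na = (np.asarray(x, dtype=np.float64) for x in (ma, va, na))
    mb, vb, nb = (np.asarray(x, dtype=np.float64) for x in (mb, vb, nb))
    if test == "welch":
        sa, sb = va / na, vb / nb
        denom = np.sqrt(sa + sb)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    elif test == "pooled":
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        denom = np.sqrt(sp2 * (1 / na + 1 / nb))
    else:
        raise ValueError(f"unknown test {test!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
    p = 2.0 * sps.t.sf(np.abs(t), df)
    # identical constant groups: no evidence against the null
    p = np.where(np.isnan(p), 1.0, p)
    return t, df, p


def _check_table(table: pd.DataFrame) -> None:
    required = {"genotype", "age_months", "region", "metric", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ConfigurationError(f"metric table missing columns {sorted(missing)}")
    vals = table["value"].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ConfigurationError("metric table contains non-finite values")
    unknown = set(table["metric"].unique()) - set(METRICS)
    if unknown:
        raise ConfigurationError(f"unknown metric name(s) {sorted(unknown)}")


@dataclass
class ComparisonResults:
    """Fitted comparison family: estimates, adjusted p-values, diagnostics."""

    comparisons: pd.DataFrame
    summaries: pd.DataFrame
    alpha: float
    family: str
    test: str
    skipped: list[tuple] = dc_field(default_factory=list)

    def significant(self) -> pd.DataFrame:
        return self.comparisons[self.comparisons["significant"]]

    def regional_spread(self, metric: str, genotype: str, age_months: int) -> float:
        """Max pairwise percent difference among the three regional means."""
        sub = self.summaries[
            (self.summaries["metric"] == metric)
            & (self.summaries["genotype"] == genotype)
            & (self.summaries["age_months"] == age_months)
        ]
        means = sub.groupby("region", observed=True)["mean"].mean()
        if set(means.index) != set(REGIONS):
            raise ConfigurationError("regional spread needs all three regional means")
        return regional_spread_from_means([means[r] for r in REGIONS])

    def summary(self) -> str:
        """Human-readable report (statsmodels-style text block)."""
        lines = [
            "Cohort comparison results",
            "=" * 70,
            f"test: {self.test} t, two-sided    adjustment: Holm-Sidak",
            f"family: {self.family}    alpha: {self.alpha}",
            f"comparisons: {len(self.comparisons)}   "
            f"significant: {int(self.comparisons['significant'].sum())}   "
            f"skipped (n<2): {len(self.skipped)}",
            "",
            "Group means +/- SD",
            "-" * 70,
            self.summaries.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
            "",
            "Significant comparisons (adjusted p < alpha)",
            "-" * 70,
        ]
        sig = self.significant()
        lines.append(
            sig.to_string(index=False, float_format=lambda v: f"{v:.4g}")
            if len(sig)
            else "(none)"
        )
        return "\n".join(lines)

    def to_csv(self, out_dir) -> dict[str, str]:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "comparisons": str(out / "comparisons.csv"),
            "summary": str(out / "summary.csv"),
        }
        self.comparisons.to_csv(paths["comparisons"], index=False)
        self.summaries.to_csv(paths["summary"], index=False)
        return paths


class CohortComparisons:
    """Every-permutation comparison model over a long-format metric table.

    Parameters
    ----------
    table :
        DataFrame with columns ``genotype, age_months, region, image_id,
        metric, value`` (the unit of analysis is the per-image
        measurement).
    """

    def __init__(self, table: pd.DataFrame):
        _check_table(table)
        self.table = table.reset_index(drop=True)

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame) -> "CohortComparisons":
        return cls(table)

    @classmethod
    def from_csv(cls, path) -> "CohortComparisons":
        return cls(pd.read_csv(path))

    def fit(
        self,
        alpha: float = 0.05,
        family: str = "per_metric",
        test: str = "welch",
        include_pooled_genotype: bool = True,
    ) -> ComparisonResults:
        """Run all pairwise group comparisons and adjust per family.

        ``family="per_metric"`` (the only implemented family definition)
        treats all comparisons within one metric — the 18-group pairwise
        set plus, optionally, the pooled mdx-vs-control contrast — as
        one Holm-Sidak family.  Groups with fewer than two observations
        are skipped and recorded in ``results.skipped``.
        """
        if not 0 < alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if family != "per_metric":
            raise ConfigurationError(f"unknown family definition {family!r}")
        summaries = group_summary(self.table)
        rows = []
        skipped: list[tuple] = []
        for metric, mtab in self.table.groupby("metric", observed=True):
            stats_by_group: dict[tuple, tuple[float, float, int]] = {}
            for key, sub in mtab.groupby(GROUP_COLS, observed=True):
                v = sub["value"].to_numpy(dtype=float)
                stats_by_group[key] = (float(v.mean()), float(v.var(ddof=1)) if len(v) > 1 else np.nan, len(v))
            keys = sorted(stats_by_group)
            raws = []
            recs = []
            for ka, kb in itertools.combinations(keys, 2):
                ma, va, na = stats_by_group[ka]
                mb, vb, nb = stats_by_group[kb]
                if na < 2 or nb < 2:
                    skipped.append((metric, ka, kb))
                    continue
                _, _, p = _two_sample_p(ma, va, na, mb, vb, nb, test)
                raws.append(float(p))
                recs.append((metric, "/".join(map(str, ka)), "/".join(map(str, kb)),
                             na, nb, ma, mb))
            if include_pooled_genotype:
                pooled = {}
                for g in GENOTYPES:
                    v = mtab.loc[mtab["genotype"] == g, "value"].to_numpy(dtype=float)
                    pooled[g] = (float(v.mean()), float(v.var(ddof=1)), len(v)) if len(v) > 1 else None
                if pooled["mdx"] and pooled["control"]:
                    ma, va, na = pooled["mdx"]
                    mb, vb, nb = pooled["control"]
                    _, _, p = _two_sample_p(ma, va, na, mb, vb, nb, test)
                    raws.append(float(p))
                    recs.append((metric, "mdx (pooled)", "control (pooled)", na, nb, ma, mb))
                else:
                    skipped.append((metric, "mdx (pooled)", "control (pooled)"))
            adj = holm_sidak(np.array(raws)) if raws else np.array([])
            for (rec, rp, ap) in zip(recs, raws, adj):
                rows.append((*rec, rp, float(ap), bool(ap < alpha)))
        comparisons = pd.DataFrame(
            rows,
            columns=["metric", "group_a", "group_b", "n_a", "n_b",
                     "mean_a", "mean_b", "raw_p", "adjusted_p", "significant"],
        )
        return ComparisonResults(
            comparisons=comparisons, summaries=summaries, alpha=alpha,
            family=family, test=test, skipped=skipped,
        )


def simulate_null_fwer(
    n_groups: int = 18,
    n_per_group: int = 10,
    n_reps: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    include_pooled_genotype: bool = True,
) -> float:
    """Monte-Carlo family-wise error rate of the engine under a global null.

    All groups are drawn from one standard normal; a replicate errs when
    any Holm-Sidak-adjusted comparison (the full pairwise family, plus
    the pooled split-half contrast when requested) is significant at
    ``alpha``.  Returns the fraction of erring replicates, which the
    procedure guarantees to be at most ``alpha`` up to Monte-Carlo noise.
    """
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_reps, n_groups, n_per_group))
    means = data.mean(axis=2)
    varis = data.var(axis=2, ddof=1)
    ia, ib = np.triu_indices(n_groups, k=1)
    _, _, p = _two_sample_p(
        means[:, ia], varis[:, ia], n_per_group,
        means[:, ib], varis[:, ib], n_per_group,
    )
    if include_pooled_genotype:
        half = n_groups // 2
        a = data[:, :half].reshape(n_reps, -1)
        b = data[:, half:].reshape(n_reps, -1)
        _, _, pp = _two_sample_p(
            a.mean(1), a.var(1, ddof=1), a.shape[1],
            b.mean(1), b.var(1, ddof=1), b.shape[1],
        )
        p = np.column_stack([p, pp])
    adj = _holm_sidak_2d(p)
    return float(np.mean((adj < alpha).any(axis=1)))
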