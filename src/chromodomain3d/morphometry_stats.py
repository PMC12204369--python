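"""Condition-comparison statistics for domain feature tables.

Implements the statistics layer of the pipeline: one-sided two-sample
t-tests and per-batch t-statistic summaries, normality annotation
(Shapiro–Wilk, Kolmogorov–Smirnov), a Kruskal–Wallis omnibus followed
by Bonferroni-corrected pairwise Mann–Whitney U tests, per-cell Gini
indices as a heterogeneity measure, four-class volume distributions,
and length-vs-volume ordinary least squares.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

SIGNIFICANCE_THRESHOLDS = (0.05, 0.01, 0.001)


def significance_code(p: float, thresholds=SIGNIFICANCE_THRESHOLDS) -> str:
    """ns / * / ** / *** codes at the 0.05 / 0.01 / 0.001 conventions."""
    if p < thresholds[2]:
        return "***"
    if p < thresholds[1]:
        return "**"
    if p < thresholds[0]:
        return "*"
    return "ns"


@dataclass
class TestResult:
    test_name: str
    groups: tuple[str, ...]
    statistic: float
    p_value: float
    corrected_p: float | None = None
    n: tuple[int, ...] = ()

    @property
    def effective_p(self) -> float:
        return self.p_value if self.corrected_p is None else self.corrected_p

    @property
    def significance(self) -> str:
        return significance_code(self.effective_p)

    def to_dict(self) -> dict:
        return {
            "test": self.test_name,
            "groups": list(self.groups),
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "corrected_p": None if self.corrected_p is None else float(self.corrected_p),
            "significance": self.significance,
            "n": list(self.n),
        }


def one_sided_t(
    group_a: np.ndarray,
    group_b: np.ndarray,
    alternative: str = "greater",
    equal_var: bool = False,
) -> TestResult:
    """One-sided two-sample t-test (Welch by default).

    `alternative` states the direction of `group_a` relative to
    `group_b`: ``"greater"`` tests mean(a) > mean(b).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("zero variance in both groups: t undefined")
    res = stats.ttest_ind(a, b, equal_var=equal_var, alternative=alternative)
    return TestResult(
        test_name="welch_t" if not equal_var else "student_t",
        groups=("a", "b"),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(len(a), len(b)),
    )


def batch_t_summary(
    table: pd.DataFrame,
    feature: str,
    condition_pair: tuple[str, str],
    batch_col: str = "batch",
    condition_col: str = "condition",
    equal_var: bool = False,
) -> pd.DataFrame:
    """One t-statistic per batch for `condition_pair[0]` vs `[1]`.

    Sign convention: positive t means the feature is higher in the
    first condition of the pair (E2 in the paper-style comparisons).
    Batches missing either condition are skipped with a warning row
    omitted.
    """
    first, second = condition_pair
    rows = []
    for batch, sub in table.groupby(batch_col, sort=True):
        a = sub.loc[sub[condition_col] == first, feature].dropna().to_numpy()
        b = sub.loc[sub[condition_col] == second, feature].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            continue
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        rows.append({
            "batch": batch,
            "feature": feature,
            "t": float(res.statistic),
            "p_two_sided": float(res.pvalue),
            "n_first": len(a),
            "n_second": len(b),
        })
    return pd.DataFrame(rows)


@dataclass
class NonparametricBattery:
    """Kruskal–Wallis omnibus plus gated pairwise Mann–Whitney tests."""

    omnibus: TestResult
    pairwise: list[TestResult] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "omnibus": self.omnibus.to_dict(),
            "pairwise": [t.to_dict() for t in self.pairwise],
        }


def nonparametric_battery(
    table: pd.DataFrame,
    feature: str,
    conditions: list[str] | None = None,
    condition_col: str = "condition",
    omnibus_alpha: float = 0.05,
) -> NonparametricBattery:
    """Kruskal–Wallis across conditions; if p < alpha, all pairwise
    Mann–Whitney U tests with Bonferroni correction (raw p times the
    number of pairs, capped at 1)."""
    if conditions is None:
        conditions = sorted(table[condition_col].unique())
    samples = {
        c: table.loc[table[condition_col] == c, feature].dropna().to_numpy()
        for c in conditions
    }
    if len(samples) < 2 or any(len(v) < 3 for v in samples.values()):
        raise ValueError("need >= 2 conditions with n >= 3 each")
    h, p = stats.kruskal(*samples.values())
    omnibus = TestResult(
        test_name="kruskal_wallis",
        groups=tuple(conditions),
        statistic=float(h),
        p_value=float(p),
        n=tuple(len(v) for v in samples.values()),
    )
    battery = NonparametricBattery(omnibus=omnibus)
    if p < omnibus_alpha:
        pairs = list(itertools.combinations(conditions, 2))
        for ca, cb in pairs:
            u, pu = stats.mannwhitneyu(samples[ca], samples[cb], alternative="two-sided")
            battery.pairwise.append(
                TestResult(
                    test_name="mann_whitney_u",
                    groups=(ca, cb),
                    statistic=float(u),
                    p_value=float(pu),
                    corrected_p=float(min(pu * len(pairs), 1.0)),
                    n=(len(samples[ca]), len(samples[cb])),
                )
            )
    return battery


def normality_check(values: np.ndarray) -> tuple[TestResult, TestResult]:
    """Shapiro–Wilk and KS (vs a normal fitted by moments).

    Annotation only: the pipeline always runs the nonparametric
    battery on domain-level features regardless of the outcome.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 3:
        raise ValueError("need n >= 3 for normality tests")
    if np.ptp(x) == 0:
        raise ValueError("constant vector: normality tests undefined")
    sw_stat, sw_p = stats.shapiro(x)
    ks_stat, ks_p = stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    return (
        TestResult("shapiro_wilk", ("sample",), float(sw_stat), float(sw_p), n=(len(x),)),
        TestResult("kolmogorov_smirnov", ("sample",), float(ks_stat), float(ks_p), n=(len(x),)),
    )


def gini_index(values: np.ndarray) -> float:
    """Gini inequality index G = sum_ij |x_i - x_j| / (2 n^2 mu).

    0 for perfect equality, approaching 1 for total inequality.
    Computed via the sorted-rank identity, which equals the pairwise
    mean-absolute-difference formula exactly.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if x.size == 0:
        raise ValueError("empty value list")
    if (x < 0).any():
        raise ValueError("values must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero values: Gini undefined")
    n = x.size
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) @ x) / (n * total))


def per_cell_gini(
    table: pd.DataFrame,
    attributes: list[str],
    cell_cols: tuple[str, ...] = ("batch", "cell", "condition"),
) -> pd.DataFrame:
    """Gini index of each attribute within each cell."""
    rows = []
    for keys, sub in table.groupby(list(cell_cols), sort=True):
        for attr in attributes:
            vals = sub[attr].dropna().to_numpy()
            vals = vals[vals >= 0]
            if vals.size == 0 or vals.sum() == 0:
                continue
            row = dict(zip(cell_cols, keys))
            row.update({"attribute": attr, "gini": gini_index(vals), "n_domains": vals.size})
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class VolumeClassDistribution:
    condition: str
    edges: tuple[float, float, float]
    fractions: tuple[float, float, float, float]
    n: int

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "edges": list(self.edges),
            "fractions": list(self.fractions),
            "n": self.n,
        }


def volume_class_distribution(
    table: pd.DataFrame,
    conditions: list[str] | None = None,
    edges: tuple[float, float, float] | None = None,
    volume_col: str = "volume_vox",
    condition_col: str = "condition",
) -> list[VolumeClassDistribution]:
    """Fractions of domains in four volume classes per condition.

    When `edges` is not given it defaults to the quartiles of the
    pooled volume distribution across all requested conditions (the
    class boundaries are always reported).  Classes are ordered low to
    high volume.
    """
    if conditions is None:
        conditions = sorted(table[condition_col].unique())
    pool = table.loc[table[condition_col].isin(conditions), volume_col].dropna()
    if pool.empty:
        raise ValueError("no volumes available")
    if edges is None:
        q = np.percentile(pool, [25, 50, 75])
        if len(np.unique(q)) < 3 or pool.nunique() < 4:
            raise ValueError("too few distinct volumes to derive quartile edges")
        edges = tuple(float(v) for v in q)
    if not (edges[0] < edges[1] < edges[2]):
        raise ValueError("edges must be strictly increasing")
    out = []
    bins = [-np.inf, *edges, np.inf]
    for c in conditions:
        vals = table.loc[table[condition_col] == c, volume_col].dropna()
        if vals.empty:
            raise ValueError(f"condition {c!r} has no volumes")
        counts, _ = np.histogram(vals, bins=bins)
        fr = counts / counts.sum()
        out.append(
            VolumeClassDistribution(
                condition=c, edges=edges, fractions=tuple(float(f) for f in fr),
                n=int(counts.sum()),
            )
        )
    return out


def length_volume_regression(
    table: pd.DataFrame,
    condition: str | None = None,
    length_col: str = "length_um",
    volume_col: str = "volume_um3",
    condition_col: str = "condition",
) -> dict:
    """OLS of volume on length with fit diagnostics."""
    sub = table if condition is None else table[table[condition_col] == condition]
    xy = sub[[length_col, volume_col]].dropna()
    if len(xy) < 3:
        raise ValueError("need n >= 3 domains")
    x = xy[length_col].to_numpy()
    y = xy[volume_col].to_numpy()
    if np.ptp(x) == 0:
        raise ValueError("zero length variance")
    res = stats.linregress(x, y)
    return {
        "condition": condition,
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "p_value": float(res.pvalue),
        "stderr": float(res.stderr),
        "n": int(len(xy)),
    }
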