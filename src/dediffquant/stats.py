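"""Statistics on per-cell measurements: tumor aggregation, the mean - 1 SD
negativity rule, quadrant classification, and the genotype-level tests.

Tumors — not cells — are the independent statistical units: per-cell
medians are first averaged within each tumor ("mean of medians") before any
two-group comparison.  Positivity thresholds are fit on a reference
genotype whose cells uniformly express the marker: a cell is *negative*
when its compartment median falls strictly more than one standard deviation
below the reference mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

__all__ = [
    "ThresholdRule",
    "QUADRANT_CLASSES",
    "aggregate_tumors",
    "fit_threshold",
    "classify_quadrants",
    "chi_squared_genotype",
    "spearman_by_genotype",
    "tumor_wilcoxon",
    "anova_tukey",
    "power_n_per_group",
]

QUADRANT_CLASSES = ("A+B+", "A+B-", "A-B+", "A-B-")


@dataclass(frozen=True)
class ThresholdRule:
    """Negativity cutoff for one channel/compartment.

    ``cutoff = mean - 1 * SD`` of per-cell medians pooled over all cells of
    the reference genotype (sample SD, n-1 denominator).  A cell is positive
    iff its median is >= cutoff.
    """

    channel: str
    compartment: str
    reference_genotype: str
    cutoff: float
    n_reference_cells: int

    def is_positive(self, values: np.ndarray | pd.Series) -> np.ndarray:
        return np.asarray(values) >= self.cutoff


def _median_col(channel: str, compartment: str) -> str:
    return f"{channel}_{compartment}_median"


def aggregate_tumors(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-cell medians to per-tumor means ("mean of medians").

    Missing medians (e.g. empty cytoplasms) are excluded pairwise; the
    returned frame has one row per tumor with ``n_cells`` plus the mean of
    every ``*_median`` column.
    """
    if records.empty:
        return pd.DataFrame(columns=["tumor_id", "genotype", "n_cells"])
    med_cols = [c for c in records.columns if c.endswith("_median")]
    grouped = records.groupby(["tumor_id", "genotype"], sort=True)
    out = grouped[med_cols].mean().reset_index()
    out.insert(2, "n_cells", grouped.size().to_numpy())
    for c in med_cols:
        out[f"n_{c}"] = grouped[c].count().to_numpy()
    return out


def fit_threshold(
    records: pd.DataFrame, channel: str, compartment: str, reference_genotype: str | None = None
) -> ThresholdRule:
    """Fit the mean - 1 SD negativity cutoff on reference-genotype cells."""
    ref = records if reference_genotype is None else records[records["genotype"] == reference_genotype]
    vals = ref[_median_col(channel, compartment)].dropna().to_numpy(dtype=float)
    if vals.size < 2:
        raise ValueError(
            f"need >= 2 reference cells to fit a threshold, got {vals.size} "
            f"for genotype {reference_genotype!r}"
        )
    cutoff = float(vals.mean() - vals.std(ddof=1))
    geno = reference_genotype if reference_genotype is not None else "<all>"
    return ThresholdRule(channel, compartment, geno, cutoff, int(vals.size))


def classify_quadrants(
    records: pd.DataFrame, rule_a: ThresholdRule, rule_b: ThresholdRule
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Assign each cell a joint positivity class for two channels.

    Channel A is conventionally the nuclear transcription factor (scored on
    the nucleus compartment) and channel B a cytoplasmic marker.  Cells with
    a missing median in either channel are excluded and counted in the
    returned exclusion report.  Returns (per-cell labels, genotype x class
    contingency table, exclusion report).
    """
    col_a = _median_col(rule_a.channel, rule_a.compartment)
    col_b = _median_col(rule_b.channel, rule_b.compartment)
    for col in (col_a, col_b):
        if col not in records.columns:
            raise KeyError(f"records lack column {col!r}")
    complete = records[col_a].notna() & records[col_b].notna()
    excluded = {"n_excluded": int((~complete).sum()), "n_total": int(len(records))}
    sub = records[complete].copy()
    a_pos = rule_a.is_positive(sub[col_a])
    b_pos = rule_b.is_positive(sub[col_b])
    cls = np.where(
        a_pos, np.where(b_pos, "A+B+", "A+B-"), np.where(b_pos, "A-B+", "A-B-")
    )
    sub["quadrant_class"] = cls
    table = (
        sub.groupby("genotype")["quadrant_class"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(QUADRANT_CLASSES), fill_value=0)
    )
    table.columns.name = None
    return sub, table, excluded


def chi_squared_genotype(table: pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-squared for association of genotype with class distribution.

    No continuity correction; df = (r-1)(c-1).  Zero rows/columns raise;
    an expected count below 5 triggers a warning.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape[0] < 2:
        raise ValueError("need >= 2 genotypes")
    keep_cols = obs.sum(axis=0) > 0
    if (~keep_cols).all() or (obs.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: a genotype has zero cells")
    obs = obs[:, keep_cols]
    if obs.shape[1] < 2:
        raise ValueError("degenerate table: fewer than 2 populated classes")
    stat, p, dof, expected = sps.chi2_contingency(obs, correction=False)
    if (expected < 5).any():
        warnings.warn("some expected counts are below 5; chi-squared may be unreliable")
    return float(stat), int(dof), float(p)


def spearman_by_genotype(
    records: pd.DataFrame,
    channel_x: str,
    compartment_x: str,
    channel_y: str,
    compartment_y: str,
    *,
    n_boot: int = 0,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Per-genotype Spearman rank correlation of two channel/compartment medians.

    Cells are pooled across tumors within each genotype, matching per-cell
    scatter plots.  Average ranks handle ties; a constant input yields a
    NaN correlation with ``undefined=True`` rather than an error.  Optional
    percentile bootstrap CI over cells.
    """
    col_x = _median_col(channel_x, compartment_x)
    col_y = _median_col(channel_y, compartment_y)
    rng = np.random.default_rng(rng_seed)
    rows = []
    for geno, sub in records.groupby("genotype", sort=True):
        xy = sub[[col_x, col_y]].dropna()
        n = len(xy)
        if n < 3:
            raise ValueError(f"genotype {geno!r} has only {n} complete cells (need >= 3)")
        x, y = xy[col_x].to_numpy(float), xy[col_y].to_numpy(float)
        undefined = x.std() == 0 or y.std() == 0
        rho = np.nan if undefined else float(sps.spearmanr(x, y).statistic)
        row = {"genotype": geno, "n_cells": n, "rho": rho, "undefined": undefined}
        if n_boot > 0 and not undefined:
            boots = np.empty(n_boot)
            for b in range(n_boot):
                ix = rng.integers(0, n, n)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    boots[b] = sps.spearmanr(x[ix], y[ix]).statistic
            lo, hi = np.nanpercentile(boots, [2.5, 97.5])
            row.update(ci_low=float(lo), ci_high=float(hi))
        rows.append(row)
    return pd.DataFrame(rows)


def tumor_wilcoxon(
    summaries: pd.DataFrame,
    genotype_a: str,
    genotype_b: str,
    channel: str,
    compartment: str,
    *,
    exact_max_n: int = 12,
) -> tuple[float, float]:
    """Two-sided rank-sum test on tumor-level summaries.

    Exact null distribution when combined n <= ``exact_max_n`` and there are
    no ties; tie-corrected normal approximation otherwise.  Returns
    (Mann-Whitney U of group A, p).
    """
    col = _median_col(channel, compartment)
    x = summaries.loc[summaries["genotype"] == genotype_a, col].dropna().to_numpy(float)
    y = summaries.loc[summaries["genotype"] == genotype_b, col].dropna().to_numpy(float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both genotype groups must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= exact_max_n and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def anova_tukey(
    summaries: pd.DataFrame, channel: str, compartment: str, group_col: str = "genotype"
) -> tuple[float, float, pd.DataFrame]:
    """One-way fixed-effects ANOVA followed by Tukey's HSD on all pairs.

    Requires >= 3 groups with >= 2 observations each; returns (F, p,
    pairwise table with studentized-range adjusted p-values).
    """
    groups = {g: sub[_median_col(channel, compartment)].dropna().to_numpy(float)
              for g, sub in summaries.groupby(group_col, sort=True)}
    if len(groups) < 3:
        raise ValueError("need >= 3 groups for ANOVA + Tukey")
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    names = list(groups)
    arrays = [groups[g] for g in names]
    f_stat, p = sps.f_oneway(*arrays)
    hsd = sps.tukey_hsd(*arrays)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append(
                {
                    "group_1": names[i],
                    "group_2": names[j],
                    "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                    "p_adj": float(hsd.pvalue[i, j]),
                }
            )
    return float(f_stat), float(p), pd.DataFrame(rows)


def _t_test_power(n: float, delta_over_sd: float, alpha: float) -> float:
    """Power of the two-sided two-sample t-test at n per group (continuous n)."""
    df = 2.0 * (n - 1.0)
    ncp = delta_over_sd * np.sqrt(n / 2.0)
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))


def power_n_per_group(
    delta: float, sd: float, alpha: float = 0.05, target_power: float = 0.8
) -> float:
    """Per-group sample size of the two-sample t-test reaching ``target_power``.

    Solves power(n) = target_power by root-finding on continuous n with the
    noncentral-t power function (ncp = (delta/sd) * sqrt(n/2), df = 2(n-1)),
    the same computation R's ``power.t.test`` performs.  Depends on delta
    and sd only through their ratio.
    """
    if delta <= 0 or sd <= 0:
        raise ValueError("delta and sd must be positive")
    if not (0 < alpha < 1 and 0 < target_power < 1):
        raise ValueError("alpha and target_power must lie in (0, 1)")
    d = delta / sd

    def gap(n: float) -> float:
        pw = _t_test_power(n, d, alpha)
        if np.isnan(pw):  # extreme noncentrality: power is 1 to machine precision
            pw = 1.0
        return pw - target_power

    lo = 1.001
    if gap(lo) > 0:
        return lo
    hi = 4.0
    while gap(hi) < 0:  # power is increasing in n; expand until bracketed
        hi *= 2.0
        if hi > 1e7:
            raise RuntimeError("power target unreachable for n up to 1e7")
    return float(optimize.brentq(gap, lo, hi, xtol=1e-10))
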