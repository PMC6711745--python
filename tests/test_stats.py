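"""Statistical layer: worked examples, brute-force oracles and calibration."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import make_records
from dediffquant.simulate import ImageSimConfig, sample_cell_levels
from dediffquant.stats import (
    aggregate_tumors,
    anova_tukey,
    chi_squared_genotype,
    classify_quadrants,
    fit_threshold,
    power_n_per_group,
    spearman_by_genotype,
    tumor_wilcoxon,
)


# ---------------------------------------------------------------------- oracles
def chi2_oracle(obs):
    obs = np.asarray(obs, dtype=float)
    exp = obs.sum(axis=1, keepdims=True) * obs.sum(axis=0, keepdims=True) / obs.sum()
    return ((obs - exp) ** 2 / exp).sum()


def f_oracle(groups):
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = len(all_vals) - len(groups)
    return (ssb / dfb) / (ssw / dfw)


def wilcoxon_exact_oracle(x, y):
    """Two-sided rank-sum p by full enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = sps.rankdata(pooled)
    obs = ranks[:n].sum()
    mean_w = n * (len(pooled) + 1) / 2
    stats = [
        ranks[list(idx)].sum() for idx in itertools.combinations(range(len(pooled)), n)
    ]
    stats = np.asarray(stats)
    return np.mean(np.abs(stats - mean_w) >= abs(obs - mean_w) - 1e-12)


# ----------------------------------------------------------------- aggregation
class TestAggregation:
    def test_single_and_mean(self):
        rec = make_records([10.0, 20.0], [1.0, 3.0], tumor="T1")
        out = aggregate_tumors(rec)
        assert out.loc[0, "tf_nucleus_median"] == 15.0
        assert out.loc[0, "marker_cytoplasm_median"] == 2.0
        assert out.loc[0, "n_cells"] == 2

    def test_missing_medians_excluded_pairwise(self):
        rec = make_records([10.0, 20.0], [np.nan, 4.0])
        out = aggregate_tumors(rec)
        assert out.loc[0, "marker_cytoplasm_median"] == 4.0
        assert out.loc[0, "n_marker_cytoplasm_median"] == 1

    def test_empty_input(self):
        assert aggregate_tumors(pd.DataFrame(columns=["tumor_id", "genotype"])).empty


# ------------------------------------------------------------------- threshold
class TestThreshold:
    def test_hand_computed_cutoff(self):
        rec = make_records([0] * 5, [10.0, 12.0, 14.0, 16.0, 18.0], genotype="ref")
        rule = fit_threshold(rec, "marker", "cytoplasm", "ref")
        assert rule.cutoff == pytest.approx(14.0 - np.sqrt(10.0), abs=1e-10)
        assert rule.n_reference_cells == 5

    def test_zero_sd_cutoff_equals_mean(self):
        rec = make_records([0] * 4, [7.0] * 4, genotype="ref")
        assert fit_threshold(rec, "marker", "cytoplasm", "ref").cutoff == 7.0

    def test_insufficient_reference_cells(self):
        rec = make_records([0.0], [1.0], genotype="ref")
        with pytest.raises(ValueError, match="reference cells"):
            fit_threshold(rec, "marker", "cytoplasm", "ref")

    def test_normal_reference_negative_fraction_near_phi_minus_one(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(1000.0, 120.0, 5000)
        rec = make_records(np.zeros(5000), vals, genotype="ref")
        rule = fit_threshold(rec, "marker", "cytoplasm", "ref")
        frac = (vals < rule.cutoff).mean()
        assert abs(frac - sps.norm.cdf(-1)) < 0.02


# -------------------------------------------------------------- classification
class TestQuadrants:
    def _rules(self):
        ref = make_records([10.0, 10.0, 10.0], [10.0, 10.0, 10.0], genotype="ref")
        # zero-SD reference: cutoffs exactly 10 for both channels
        ra = fit_threshold(ref, "tf", "nucleus", "ref")
        rb = fit_threshold(ref, "marker", "cytoplasm", "ref")
        return ra, rb

    def test_one_cell_per_class(self):
        ra, rb = self._rules()
        rec = make_records([11, 11, 9, 9], [11, 9, 11, 9], genotype="mut")
        labeled, table, _ = classify_quadrants(rec, ra, rb)
        assert table.loc["mut"].tolist() == [1, 1, 1, 1]

    def test_saturating_case_all_double_positive(self):
        ra, rb = self._rules()
        rec = make_records([20] * 4, [20] * 4, genotype="mut")
        _, table, _ = classify_quadrants(rec, ra, rb)
        assert table.loc["mut", "A+B+"] == 4 and table.loc["mut"].sum() == 4

    def test_boundary_value_counts_positive(self):
        ra, rb = self._rules()
        rec = make_records([10.0], [9.99], genotype="mut")
        labeled, _, _ = classify_quadrants(rec, ra, rb)
        assert labeled["quadrant_class"].iloc[0] == "A+B-"

    def test_missing_median_excluded_and_reported(self):
        ra, rb = self._rules()
        rec = make_records([11, 11], [11, np.nan], genotype="mut")
        _, table, excl = classify_quadrants(rec, ra, rb)
        assert excl["n_excluded"] == 1 and table.loc["mut"].sum() == 1


# ----------------------------------------------------------------- chi-squared
class TestChiSquared:
    def test_homogeneous_table_gives_zero(self):
        table = pd.DataFrame([[10, 20, 30, 40]] * 2, index=["a", "b"])
        stat, dof, p = chi_squared_genotype(table)
        assert stat == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        table = pd.DataFrame([[20, 10], [10, 20]], index=["a", "b"])
        stat, dof, p = chi_squared_genotype(table)
        assert stat == pytest.approx(20.0 / 3.0, abs=1e-10)
        assert dof == 1
        assert p == pytest.approx(sps.chi2.sf(20.0 / 3.0, 1), abs=1e-10)

    def test_matches_brute_force_oracle_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            obs = rng.integers(5, 60, size=(rng.integers(2, 4), rng.integers(2, 5)))
            table = pd.DataFrame(obs, index=[f"g{i}" for i in range(obs.shape[0])])
            stat, _, _ = chi_squared_genotype(table)
            assert stat == pytest.approx(chi2_oracle(obs), abs=1e-10)

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            chi_squared_genotype(pd.DataFrame([[0, 0], [1, 2]], index=["a", "b"]))


# -------------------------------------------------------------------- spearman
class TestSpearman:
    def test_monotone_and_antitone(self):
        rec = make_records([1, 2, 3, 4, 5], [2, 4, 6, 8, 10], genotype="g")
        out = spearman_by_genotype(rec, "tf", "nucleus", "marker", "cytoplasm")
        assert out.loc[0, "rho"] == pytest.approx(1.0)
        rec = make_records([1, 2, 3, 4, 5], [5, 4, 3, 2, 1], genotype="g")
        out = spearman_by_genotype(rec, "tf", "nucleus", "marker", "cytoplasm")
        assert out.loc[0, "rho"] == pytest.approx(-1.0)

    def test_constant_vector_flagged_not_raised(self):
        rec = make_records([1, 2, 3, 4], [5, 5, 5, 5], genotype="g")
        out = spearman_by_genotype(rec, "tf", "nucleus", "marker", "cytoplasm")
        assert bool(out.loc[0, "undefined"]) and np.isnan(out.loc[0, "rho"])

    def test_copula_rank_correlation_recovered(self):
        cfg = ImageSimConfig(inter_channel_rank_correlation=0.5, marker_loss_fraction=0.0)
        levels, _ = sample_cell_levels(cfg, 2000, np.random.default_rng(8))
        rec = make_records(levels["tf"], levels["marker"], genotype="g")
        out = spearman_by_genotype(rec, "tf", "nucleus", "marker", "cytoplasm")
        assert out.loc[0, "rho"] == pytest.approx(0.5, abs=0.05)


# -------------------------------------------------------------------- wilcoxon
class TestWilcoxon:
    @staticmethod
    def _summaries(x, y):
        n = len(x) + len(y)
        return pd.DataFrame(
            {
                "tumor_id": [f"T{i}" for i in range(n)],
                "genotype": ["a"] * len(x) + ["b"] * len(y),
                "marker_cytoplasm_median": list(x) + list(y),
            }
        )

    def test_fully_separated_small_groups(self):
        _, p = tumor_wilcoxon(self._summaries([1, 2, 3], [4, 5, 6]), "a", "b", "marker", "cytoplasm")
        assert p == pytest.approx(0.1, abs=1e-12)  # 2 of C(6,3)=20 arrangements

    def test_identical_groups_give_p_one(self):
        _, p = tumor_wilcoxon(self._summaries([1, 2, 3], [1, 2, 3]), "a", "b", "marker", "cytoplasm")
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            nx, ny = rng.integers(2, 6, 2)
            x = rng.permutation(20)[:nx].astype(float)
            y = rng.permutation(np.arange(20, 40))[: ny].astype(float)
            _, p = tumor_wilcoxon(self._summaries(x, y), "a", "b", "marker", "cytoplasm")
            assert p == pytest.approx(wilcoxon_exact_oracle(x, y), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            tumor_wilcoxon(self._summaries([1.0], []), "a", "b", "marker", "cytoplasm")


# ----------------------------------------------------------------- anova+tukey
class TestAnovaTukey:
    @staticmethod
    def _summaries(groups):
        rows = []
        for g, vals in groups.items():
            for i, v in enumerate(vals):
                rows.append({"tumor_id": f"{g}{i}", "genotype": g, "tf_nucleus_median": v})
        return pd.DataFrame(rows)

    def test_identical_groups_null(self):
        s = self._summaries({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        f, p, pairs = anova_tukey(s, "tf", "nucleus")
        assert f == pytest.approx(0.0, abs=1e-12)
        assert (pairs["p_adj"] > 0.999).all()

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(1)
        s = self._summaries(
            {"a": rng.normal(0, 1, 5), "b": rng.normal(0, 1, 5), "c": rng.normal(10, 1, 5)}
        )
        f, p, pairs = anova_tukey(s, "tf", "nucleus")
        pairs = pairs.set_index(["group_1", "group_2"])
        assert pairs.loc[("a", "c"), "p_adj"] < 0.001
        assert pairs.loc[("b", "c"), "p_adj"] < 0.001
        assert pairs.loc[("a", "b"), "p_adj"] > 0.05  # unshifted pair stays null

    def test_f_matches_direct_mean_square_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            groups = {g: rng.normal(rng.uniform(-1, 1), 1, rng.integers(3, 7))
                      for g in "abc"}
            f, _, _ = anova_tukey(self._summaries(groups), "tf", "nucleus")
            assert f == pytest.approx(f_oracle(list(groups.values())), abs=1e-10)

    def test_undersized_group_rejected(self):
        s = self._summaries({"a": [1, 2], "b": [1, 2], "c": [5.0]})
        with pytest.raises(ValueError, match="'c'"):
            anova_tukey(s, "tf", "nucleus")


# ----------------------------------------------------------------------- power
class TestPower:
    def test_unit_effect_reference_value(self):
        # independent oracle: R power.t.test(delta=1, sd=1) -> 16.7147
        assert power_n_per_group(1, 1, 0.05, 0.8) == pytest.approx(16.7147, abs=0.001)

    def test_depends_only_on_delta_over_sd(self):
        a = power_n_per_group(2895.4, 918.0)
        b = power_n_per_group(2895.4 / 918.0, 1.0)
        assert a == pytest.approx(b, rel=1e-9)

    def test_monotone_decreasing_in_delta(self):
        ns = [power_n_per_group(d, 1.0) for d in (0.5, 1.0, 2.0, 4.0)]
        assert all(x > y for x, y in zip(ns, ns[1:]))

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            power_n_per_group(-1, 1)
        with pytest.raises(ValueError):
            power_n_per_group(1, 1, alpha=1.5)
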