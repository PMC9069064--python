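import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from gutresponse.differential import (
    anova_pvalues,
    bmi_adjusted_anova,
    enrichment_label,
    log_transform,
    run_differential,
    tukey_hsd,
)
from gutresponse.io import validate_cohort
from gutresponse.synthetic import CohortConfig, generate_cohort


class TestBmiAdjustedAnova:
    def test_matches_statsmodels_extra_sum_of_squares(self, rng):
        groups = np.repeat(["a", "b", "c"], 8)
        bmi = rng.normal(23, 2, size=24)
        y = rng.normal(size=24) + (groups == "b") * 0.5 + 0.1 * bmi
        p = bmi_adjusted_anova(y, groups, bmi)
        # independent oracle: two explicit OLS fits and the F test
        dummies = pd.get_dummies(pd.Series(groups), drop_first=True, dtype=float)
        X1 = sm.add_constant(np.column_stack([dummies.to_numpy(), bmi]))
        X0 = sm.add_constant(bmi)
        fit1 = sm.OLS(y, X1).fit()
        fit0 = sm.OLS(y, X0).fit()
        f, p_expected, _ = fit1.compare_f_test(fit0)
        assert p == pytest.approx(p_expected, abs=1e-10)

    def test_explicit_sums_of_squares_fixture(self):
        y = np.array([1.1, 0.9, 2.2, 1.8, 3.1, 2.9, 1.0, 2.0, 3.0])
        groups = np.array(["g1", "g1", "g2", "g2", "g3", "g3", "g1", "g2", "g3"])
        bmi = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 0.0, 0.0, 0.0])
        p = bmi_adjusted_anova(y, groups, bmi)
        rss = []
        for X in (
            np.column_stack(
                [np.ones(9), (groups == "g2") * 1.0, (groups == "g3") * 1.0, bmi]
            ),
            np.column_stack([np.ones(9), bmi]),
        ):
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            rss.append(((y - X @ beta) ** 2).sum())
        f = ((rss[1] - rss[0]) / 2) / (rss[0] / (9 - 4))
        assert p == pytest.approx(stats.f.sf(f, 2, 5), abs=1e-10)

    def test_constant_values_give_nan(self):
        groups = np.repeat(["a", "b", "c"], 4)
        bmi = np.arange(12.0)
        assert np.isnan(bmi_adjusted_anova(np.ones(12), groups, bmi))

    def test_null_calibration_uniform(self, rng):
        groups = np.repeat(["a", "b", "c"], 20)
        bmi = rng.normal(23, 2, size=60)
        Y = 0.3 * bmi[:, None] + rng.normal(size=(60, 1000))
        pvals = anova_pvalues(Y, groups, bmi)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_too_small_groups_rejected(self, rng):
        with pytest.raises(ValueError, match="3 samples"):
            bmi_adjusted_anova(
                rng.normal(size=4), np.array(["a", "a", "b", "b"]), np.ones(4)
            )


class TestTukeyHsd:
    def test_equal_means_p_near_one(self, rng):
        x = np.concatenate([rng.normal(0, 1, 20), rng.normal(0, 1, 20)])
        groups = np.repeat(["a", "b"], 20)
        x[:20] += x[20:].mean() - x[:20].mean()  # force exactly equal means
        p = tukey_hsd(x, groups)[("a", "b")]
        assert p >= 0.99

    def test_matches_studentized_range_oracle(self, rng):
        vals = {
            "a": rng.normal(0.0, 1.0, 6),
            "b": rng.normal(0.8, 1.0, 5),
            "c": rng.normal(-0.5, 1.0, 7),
        }
        x = np.concatenate(list(vals.values()))
        groups = np.concatenate([[g] * len(v) for g, v in vals.items()])
        result = tukey_hsd(x, groups)
        # independent oracle: Tukey-Kramer from first principles
        ns = {g: len(v) for g, v in vals.items()}
        means = {g: v.mean() for g, v in vals.items()}
        df = sum(ns.values()) - 3
        s2 = sum(((v - v.mean()) ** 2).sum() for v in vals.values()) / df
        for a, b in (("a", "b"), ("a", "c"), ("b", "c")):
            se = np.sqrt(s2 / 2 * (1 / ns[a] + 1 / ns[b]))
            q = abs(means[a] - means[b]) / se
            p_expected = stats.studentized_range.sf(q, 3, df)
            assert result[(a, b)] == pytest.approx(p_expected, abs=1e-6)

    def test_extreme_separation(self, rng):
        x = np.concatenate([rng.normal(0, 1, 5), rng.normal(10, 1, 5)])
        groups = np.repeat(["a", "b"], 5)
        assert tukey_hsd(x, groups)[("a", "b")] < 1e-6

    def test_singleton_group_pairs_are_nan(self, rng):
        x = np.array([1.0, 2.0, 3.0, 4.0, 9.0])
        groups = np.array(["a", "a", "b", "b", "c"])
        result = tukey_hsd(x, groups)
        assert np.isnan(result[("a", "c")])
        assert np.isfinite(result[("a", "b")])

    def test_not_below_unadjusted_two_sample_contrast(self, rng):
        vals = {g: rng.normal(m, 1.0, 8) for g, m in (("a", 0), ("b", 0.9), ("c", 0.2))}
        x = np.concatenate(list(vals.values()))
        groups = np.concatenate([[g] * 8 for g in vals])
        tukey_ab = tukey_hsd(x, groups)[("a", "b")]
        plain = stats.ttest_ind(vals["a"], vals["b"]).pvalue
        assert tukey_ab >= plain - 1e-12


class TestEnrichmentLabel:
    OCC = {"PR": 0.9, "SD": 0.9, "PD": 0.9}

    def test_basic_direction(self):
        med = {"PR": 1e-4, "SD": 1e-6, "PD": 0.0}
        assert enrichment_label(med, self.OCC) == ("PR", "PD")

    def test_low_occurrence_gives_na(self):
        med = {"PR": 1e-4, "SD": 1e-6, "PD": 0.0}
        occ = {"PR": 0.05, "SD": 0.04, "PD": 0.02}
        assert enrichment_label(med, occ, min_occurrence=0.2) == (None, None)

    def test_median_tie_broken_by_occurrence(self):
        med = {"PR": 1e-4, "SD": 1e-4, "PD": 0.0}
        occ = {"PR": 0.9, "SD": 0.5, "PD": 0.5}
        assert enrichment_label(med, occ)[0] == "PR"
        occ2 = {"PR": 0.5, "SD": 0.9, "PD": 0.5}
        assert enrichment_label(med, occ2)[0] == "SD"

    def test_full_tie_uses_group_order(self):
        med = {"PR": 1e-4, "SD": 1e-4, "PD": 1e-4}
        occ = {"PR": 0.5, "SD": 0.5, "PD": 0.5}
        hi, lo = enrichment_label(med, occ)
        assert hi == "PR"
        assert lo == "SD"  # lowest-median tie among the rest, group order
        assert hi != lo


class TestRunDifferential:
    def test_planted_truth_recovery(self):
        cfg = CohortConfig(seed=11, n_mgs=300, n_ko=60, n_pathways=5,
                           n_differential_mgs=10, mgs_effect_size=1.5,
                           n_differential_pathways=1)
        bundle = generate_cohort(cfg)
        val = validate_cohort(bundle.mgs_abundance, bundle.meta, exclude_atb=True)
        table = run_differential(val.abundance, val.meta, use_q=True)
        truth = set(bundle.truth.differential_mgs)
        found = set(table.index[table["significant"]])
        assert len(found & truth) / len(truth) >= 0.8

    def test_enrichment_matches_planted_group(self):
        hits = total = 0
        for seed in (21, 22, 23):
            cfg = CohortConfig(seed=seed, n_mgs=200, n_ko=60, n_pathways=5,
                               n_differential_mgs=9, mgs_effect_size=1.5,
                               n_differential_pathways=1)
            bundle = generate_cohort(cfg)
            val = validate_cohort(bundle.mgs_abundance, bundle.meta, exclude_atb=True)
            table = run_differential(val.abundance, val.meta, use_q=True)
            for mgs in table.index[table["significant"]]:
                planted = bundle.truth.differential_mgs.get(mgs)
                if planted is None:
                    continue
                total += 1
                hits += table.loc[mgs, "enrich_high"] == planted
        assert total > 0
        assert hits / total >= 0.95

    def test_bh_q_monotone_in_p(self, small_bundle):
        val = validate_cohort(small_bundle.mgs_abundance, small_bundle.meta)
        table = run_differential(val.abundance, val.meta).dropna(subset=["anova_p"])
        ordered = table.sort_values("anova_p")
        assert (ordered["bh_q"].diff().dropna() >= -1e-12).all()
        assert (table["bh_q"] >= table["anova_p"] - 1e-12).all()

    def test_empty_matrix_rejected(self, small_bundle):
        with pytest.raises(ValueError, match="empty"):
            run_differential(
                small_bundle.mgs_abundance.iloc[:, :0], small_bundle.meta
            )

    def test_log_transform_epsilon_is_half_min_nonzero(self):
        df = pd.DataFrame([[0.0, 0.5], [0.25, 0.125]])
        out = log_transform(df)
        eps = 0.125 / 2
        assert out.iloc[0, 0] == pytest.approx(np.log10(eps))
        assert out.iloc[0, 1] == pytest.approx(np.log10(0.5 + eps))
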