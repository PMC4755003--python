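"""Logistic fits, model selection, paired-change and nonparametric tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from tilquant import (
    CohortSpec,
    adjusted_model,
    backward_stepwise,
    build_analysis_table,
    correlation_matrix,
    decile_response_table,
    fit_logistic,
    group_distribution_tests,
    interaction_lrt,
    paired_change_analysis,
    pathologist_concordance,
    simulate_cohort,
    univariate_metric_screen,
)
from tilquant.cohort import fit_logistic_2x2
from tilquant.spatial import METRIC_FIELDS


def clean_cohort(n=600, seed=0, **kw):
    """Analysis table of a simulated cohort without missingness."""
    spec = CohortSpec(
        n_patients=n, direction_conditional=False,
        p_missing_pre=0, p_missing_post=0, p_missing_pcr=0,
        p_missing_grade=0, p_missing_receptors=0, p_missing_til=0, **kw,
    )
    return build_analysis_table(simulate_cohort(spec, seed=seed))


class TestFitLogistic:
    @given(
        st.tuples(*[st.integers(min_value=1, max_value=49) for _ in range(2)]),
        st.tuples(*[st.integers(min_value=1, max_value=49) for _ in range(2)]),
    )
    def test_single_binary_predictor_equals_cross_product_ratio(self, exp, unexp):
        """The one-predictor logistic MLE reproduces the 2x2 odds ratio."""
        a, b = exp          # events / non-events among exposed
        c, d = unexp
        fit = fit_logistic_2x2(a, a + b, c, c + d)
        assert fit.odds_ratio("exposed") == pytest.approx((a * d) / (b * c), rel=1e-6)

    def test_null_or_is_near_one(self):
        rng = np.random.default_rng(0)
        y = pd.Series(rng.random(10_000) < 0.3)
        x = pd.DataFrame({"x": rng.normal(size=10_000)})
        fit = fit_logistic(y.astype(float), x)
        assert 0.9 <= fit.odds_ratio("x") <= 1.1

    def test_constant_predictor_flagged(self):
        y = pd.Series([0, 1, 0, 1, 1, 0] * 5, dtype=float)
        fit = fit_logistic(y, pd.DataFrame({"c": np.ones(30)}))
        assert "non_identifiable:c" in fit.flags
        assert "c" not in fit.terms.index

    def test_duplicated_column_flagged_rank_deficient(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        y = pd.Series((rng.random(100) < 1 / (1 + np.exp(-x))).astype(float))
        fit = fit_logistic(y, pd.DataFrame({"a": x, "b": x}))
        assert "rank_deficient:b" in fit.flags
        assert "a" in fit.terms.index and "b" not in fit.terms.index

    def test_perfect_separation_flagged_not_silent(self):
        y = pd.Series([0.0] * 20 + [1.0] * 20)
        x = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)]})
        fit = fit_logistic(y, x)
        assert "perfect_separation" in fit.flags
        assert not fit.converged
        assert math.isnan(fit.terms.loc["x", "or"]) or not fit.converged

    def test_complete_case_counting(self):
        y = pd.Series([0, 1, 0, 1, 1, 0, 1, 0, np.nan, 1], dtype=float)
        x = pd.DataFrame({"x": [1.0, 2, 3, 4, np.nan, 6, 7, 8, 9, 10]})
        fit = fit_logistic(y, x)
        assert fit.n_observations == 8
        assert fit.n_dropped == 2

    def test_wald_ci_brackets_or(self):
        fit = fit_logistic_2x2(10, 100, 30, 100)
        row = fit.terms.loc["exposed"]
        assert row["ci_low"] <= row["or"] <= row["ci_high"]
        assert row["or"] == pytest.approx(math.exp(row["coef"]))

    def test_degenerate_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(pd.Series(np.ones(10)), pd.DataFrame({"x": np.arange(10.0)}))


class TestMetricScreen:
    def test_screen_has_fifteen_rows(self):
        table = clean_cohort(400, seed=1)
        screen = univariate_metric_screen(table)
        assert len(screen) == 15
        assert set(screen.index) == set(METRIC_FIELDS)

    def test_all_missing_metric_skipped_with_warning(self):
        table = clean_cohort(200, seed=2)
        table["dmax_s"] = np.nan
        with pytest.warns(UserWarning, match="dmax_s"):
            screen = univariate_metric_screen(table)
        assert len(screen) == 14

    def test_planted_density_effect_wins_the_screen(self):
        """With an effect planted on log median lymphocyte density, that
        metric dominates every unrelated metric in nearly all replicates.

        Its own order-statistic companions (min and max lymphocyte density
        are drawn from the same per-sample density distribution, r ~ 0.94)
        inherit most of the signal and can out-rank it by chance, so the
        outright-winner requirement applies to the 13-metric screen
        excluding them, with a plurality check over all 15.
        """
        companions = {"dmin_l", "dmax_l"}
        wins_ex, wins_all = 0, 0
        for seed in range(50):
            table = clean_cohort(600, seed=100 + seed, beta_density=math.log(4.5))
            screen = univariate_metric_screen(table)
            wins_all += screen["p"].idxmin() == "dmed_l"
            wins_ex += screen.drop(index=list(companions))["p"].idxmin() == "dmed_l"
        assert wins_ex >= 45
        assert wins_all >= 25

    def test_null_screen_false_positive_rate(self):
        hits = total = 0
        for seed in range(30):
            table = clean_cohort(400, seed=300 + seed)  # all betas zero
            screen = univariate_metric_screen(table)
            # lymphocyte metrics share the latent density draw and are not
            # mutually independent; the binomial band still applies per test
            hits += int((screen["p"] < 0.05).sum())
            total += len(screen)
        rate = hits / total
        assert 0.01 <= rate <= 0.10


class TestStepwise:
    def test_planted_predictor_survives_elimination(self):
        kept = 0
        for seed in range(25):
            table = clean_cohort(600, seed=500 + seed, beta_density=math.log(6.0))
            # one strong predictor plus pure-noise candidates isolates the
            # elimination logic from correlated companion metrics
            rng = np.random.default_rng(seed)
            cands = {"dmed_l": table["dmed_l"]}
            for j in range(14):
                cands[f"noise_{j:02d}"] = rng.normal(size=len(table))
            df = pd.DataFrame(cands)
            df["pcr"] = table["pcr"]
            res = backward_stepwise(df, tuple(cands), threshold=0.05)
            kept += "dmed_l" in res.final_terms
        assert kept >= 23

    def test_all_noise_gives_empty_final_set(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({f"n{j}": rng.normal(size=400) for j in range(5)})
        df["pcr"] = (rng.random(400) < 0.2).astype(float)
        res = backward_stepwise(df, tuple(f"n{j}" for j in range(5)), transform=False)
        # termination contract: either empty or every survivor significant
        if res.final_terms:
            assert (res.final_fit.terms.drop(index="const")["p"] < 0.05).all()
        assert len(res.removal_trace) + len(res.final_terms) == 5

    def test_strong_pair_among_two_candidates(self):
        table = clean_cohort(800, seed=7, beta_density=math.log(8.0))
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"dmed_l": np.log10(table["dmed_l"]), "noise": rng.normal(size=len(table))})
        df["pcr"] = table["pcr"]
        res = backward_stepwise(df, ("dmed_l", "noise"), transform=False)
        assert res.final_terms == ["dmed_l"]
        assert res.removal_trace[0][0] == "noise"

    def test_single_candidate_rejected(self):
        table = clean_cohort(100, seed=1)
        with pytest.raises(ValueError):
            backward_stepwise(table, ("dmed_l",))


class TestAdjustedModel:
    def test_reports_seven_terms(self):
        table = clean_cohort(500, seed=3)
        fit = adjusted_model(table, "dmed_l")
        assert len(fit.terms.drop(index="const")) == 7
        assert "grade" in fit.terms.index  # single ordinal term

    def test_dummy_grade_coding_available(self):
        table = clean_cohort(500, seed=3)
        fit = adjusted_model(table, "dmed_l", grade_coding="dummy")
        grade_terms = [t for t in fit.terms.index if t.startswith("grade_")]
        assert len(grade_terms) == 2

    def test_confounded_effect_shrinks_on_adjustment(self):
        """A metric associated with outcome only through grade moves
        towards the null once grade is adjusted for."""
        shrunk = 0
        for seed in range(20):
            rng = np.random.default_rng(900 + seed)
            n = 800
            grade = rng.choice([1.0, 2.0, 3.0], size=n)
            metric = 10 ** (2.0 + 0.5 * (grade - 2) + rng.normal(0, 0.3, n))
            eta = -1.8 + 1.0 * (grade - 2)
            df = pd.DataFrame(
                {
                    "dmed_l": metric,
                    "grade": grade,
                    "age": rng.normal(50, 8, n),
                    "tumour_size_gt50": (rng.random(n) < 0.2).astype(float),
                    "node_positive": (rng.random(n) < 0.5).astype(float),
                    "er_positive": (rng.random(n) < 0.6).astype(float),
                    "her2_positive": (rng.random(n) < 0.25).astype(float),
                    "pcr": (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float),
                }
            )
            uni = fit_logistic(df["pcr"], pd.DataFrame({"dmed_l": np.log10(df["dmed_l"])}))
            adj = adjusted_model(df, "dmed_l")
            shrunk += abs(math.log(adj.odds_ratio("dmed_l"))) < abs(
                math.log(uni.odds_ratio("dmed_l"))
            )
        assert shrunk >= 18

    def test_planted_effect_recovered_after_adjustment(self):
        covered = 0
        true_or = 4.5
        for seed in range(40):
            table = clean_cohort(600, seed=40 + seed, beta_density=math.log(true_or))
            fit = adjusted_model(table, "dmed_l")
            row = fit.terms.loc["dmed_l"]
            covered += row["ci_low"] <= true_or <= row["ci_high"]
        assert covered >= 33  # ~95% coverage, loose small-sample band


class TestInteractionLRT:
    def test_statistic_nonnegative_and_df_one(self):
        table = clean_cohort(500, seed=5, beta_delta=math.log(0.3))
        table["delta"] = np.log10(table["post_dmed_l"]) - np.log10(table["pre_dmed_l"])
        res = interaction_lrt(table, "delta", "taxane_second", transform=False)
        assert res.statistic >= 0
        assert res.df == 1
        assert 0 <= res.p <= 1

    def test_constant_group_rejected(self):
        table = clean_cohort(200, seed=5)
        table["taxane_second"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            interaction_lrt(table, "dmed_l", "taxane_second")

    def test_affine_group_recoding_keeps_statistic(self):
        table = clean_cohort(500, seed=6, beta_delta=math.log(0.3))
        table["delta"] = np.log10(table["post_dmed_l"]) - np.log10(table["pre_dmed_l"])
        r1 = interaction_lrt(table, "delta", "taxane_second", transform=False)
        table["recoded"] = 3.0 - 2.0 * table["taxane_second"]
        r2 = interaction_lrt(table, "delta", "recoded", transform=False)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-6)

    def test_power_at_published_group_effect_sizes(self):
        """Group odds ratios like the reported 0.12 vs 0.45 per log-unit
        change should be detectable in at least half the replicates."""
        hits = 0
        for seed in range(30):
            table = clean_cohort(
                550, seed=700 + seed,
                beta_delta=math.log(0.45),
                beta_delta_x_taxane=math.log(0.12) - math.log(0.45),
            )
            table["delta"] = np.log10(table["post_dmed_l"]) - np.log10(table["pre_dmed_l"])
            res = interaction_lrt(table, "delta", "taxane_second", transform=False)
            hits += res.p < 0.05
        assert hits / 30 >= 0.5


class TestPairedChange:
    def test_delta_example(self):
        df = pd.DataFrame(
            {
                "pre_dmed_l": [100.0, 200.0],
                "post_dmed_l": [50.0, 100.0],
                "pcr": [1.0, 0.0],
                "taxane_second": [0.0, 1.0],
            }
        )
        with pytest.raises(ValueError):
            paired_change_analysis(df.assign(post_dmed_l=np.nan))
        res = paired_change_analysis(df)
        assert res.table["delta_log_density"].iloc[0] == pytest.approx(-0.30103, abs=1e-4)
        assert (res.table["direction"] == "decrease").all()
        assert res.n_decrease == 2

    def test_no_change_flagged_non_identifiable(self):
        df = pd.DataFrame(
            {
                "pre_dmed_l": [100.0] * 10,
                "post_dmed_l": [100.0] * 10,
                "pcr": [0.0, 1.0] * 5,
                "taxane_second": [0.0, 1.0] * 5,
            }
        )
        res = paired_change_analysis(df)
        assert res.n_no_change == 10
        assert not res.fit.converged
        assert any("non_identifiable" in f or "perfect" in f for f in res.fit.flags)

    def test_waterfall_sorted_by_group_then_delta(self):
        table = clean_cohort(300, seed=8)
        res = paired_change_analysis(table)
        t = res.table
        for g, sub in t.groupby("taxane_second"):
            assert sub["delta_log_density"].is_monotonic_increasing
        assert t["taxane_second"].is_monotonic_increasing

    def test_planted_delta_effect_recovered(self):
        inside = 0
        for seed in range(50):
            table = clean_cohort(550, seed=1000 + seed, beta_delta=math.log(0.3))
            res = paired_change_analysis(table)
            inside += 0.15 <= res.fit.odds_ratio("delta_log_density") <= 0.6
        assert inside >= 45


class TestGroupTests:
    def test_exact_ranksum_small_samples(self):
        stat, p, name = group_distribution_tests({"A": [1, 2, 3], "B": [4, 5, 6]})
        assert name == "rank-sum"
        assert p == pytest.approx(0.1)

    def test_large_shift_is_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 50)
        stat, p, _ = group_distribution_tests({"A": a, "B": a + 100})
        assert p < 0.001

    def test_three_groups_use_kruskal_wallis(self):
        rng = np.random.default_rng(1)
        groups = {g: rng.normal(0, 1, 30) for g in "ABC"}
        stat, p, name = group_distribution_tests(groups)
        assert name == "kruskal-wallis"
        ref = stats.kruskal(*groups.values())
        assert stat == pytest.approx(ref.statistic)

    def test_kruskal_wallis_null_calibration(self):
        rng = np.random.default_rng(2)
        rej = 0
        n_rep = 1000
        for _ in range(n_rep):
            groups = {g: rng.normal(0, 1, 15) for g in "ABCD"}
            _, p, _ = group_distribution_tests(groups)
            rej += p < 0.05
        assert 0.03 <= rej / n_rep <= 0.07

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_distribution_tests({"A": [1.0], "B": []})


class TestCorrelations:
    def test_exact_linear_relations(self):
        df = pd.DataFrame({"x": [1.0, 2, 3], "y": [2.0, 4, 6], "z": [6.0, 4, 2]})
        res = correlation_matrix(df)
        assert res.matrix.loc["x", "x"] == 1.0
        assert res.matrix.loc["x", "y"] == pytest.approx(1.0)
        assert res.matrix.loc["x", "z"] == pytest.approx(-1.0)
        assert res.strongest_positive[2] == pytest.approx(1.0)
        assert res.strongest_negative[2] == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(200, 15)), columns=list(METRIC_FIELDS))
        res = correlation_matrix(df)
        x = df.to_numpy()
        xc = x - x.mean(axis=0)
        oracle = (xc.T @ xc) / (len(x) * x.std(axis=0)[:, None] * x.std(axis=0)[None, :])
        np.testing.assert_allclose(res.matrix.to_numpy(), oracle, atol=1e-12)

    def test_constant_metric_flagged_undefined(self):
        df = pd.DataFrame({"x": [1.0, 2, 3], "y": [5.0, 5, 5]})
        res = correlation_matrix(df)
        assert "y" in res.undefined
        assert math.isnan(res.matrix.loc["x", "y"])


class TestDeciles:
    def test_equal_bins_at_round_n(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"m": rng.normal(size=100), "pcr": (rng.random(100) < 0.2).astype(float)})
        t = decile_response_table(df, "m")
        assert list(t["n"]) == [10] * 10

    def test_remainder_spread_over_lowest_bins(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"m": rng.normal(size=103), "pcr": np.zeros(103)})
        t = decile_response_table(df, "m")
        assert list(t["n"]) == [11, 11, 11] + [10] * 7

    def test_ties_assigned_to_lower_decile(self):
        df = pd.DataFrame({"m": [1.0] * 15 + list(range(2, 87)), "pcr": np.zeros(100)})
        t = decile_response_table(df, "m")
        # the 15 tied minimal values straddle bins 1-2; all land in bin 1
        assert t.loc[t["decile"] == 1, "n"].iloc[0] == 15
        assert t["n"].sum() == 100

    def test_null_metric_has_flat_profile(self):
        worst = 0.0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(
                {"m": rng.normal(size=2000), "pcr": (rng.random(2000) < 0.16).astype(float)}
            )
            t = decile_response_table(df, "m")
            worst = max(worst, t["proportion"].max() - t["proportion"].min())
        assert worst < 0.15

    def test_planted_monotone_effect_orders_deciles(self):
        rhos = []
        for seed in range(10):
            table = clean_cohort(1000, seed=2000 + seed, beta_density=math.log(4.5))
            table["logd"] = np.log10(table["dmed_l"])
            t = decile_response_table(table, "logd")
            rhos.append(stats.spearmanr(t["decile"], t["proportion"]).statistic)
        assert np.mean(rhos) >= 0.8

    def test_insufficient_patients_rejected(self):
        df = pd.DataFrame({"m": np.arange(5.0), "pcr": np.zeros(5)})
        with pytest.raises(ValueError):
            decile_response_table(df, "m")


class TestPathologistConcordance:
    def test_planted_ordinal_alignment_detected(self):
        table = clean_cohort(300, seed=9)
        res = pathologist_concordance(table)
        assert set(res.index) == {"count_l", "frac_l", "dmed_l"}
        assert (res.loc[["frac_l", "dmed_l"], "p"] < 0.001).all()
        assert res.loc["dmed_l", "p"] < 1e-10

    def test_random_categories_calibrated(self):
        rej = 0
        n_rep = 200
        rng = np.random.default_rng(10)
        for _ in range(n_rep):
            df = pd.DataFrame(
                {
                    "dmed_l": rng.lognormal(5, 1, 150),
                    "til_category": rng.choice([1.0, 2.0, 3.0], 150),
                }
            )
            res = pathologist_concordance(df, metrics=("dmed_l",))
            rej += res.loc["dmed_l", "p"] < 0.05
        assert 0.01 <= rej / n_rep <= 0.10

    def test_single_category_rejected(self):
        df = pd.DataFrame({"dmed_l": [1.0, 2, 3], "til_category": [2.0, 2.0, 2.0]})
        with pytest.raises(ValueError):
            pathologist_concordance(df, metrics=("dmed_l",))
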