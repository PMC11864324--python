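"""Covariate table, ordinal regressions, stepwise AIC, and supporting tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from treecl.synthetic import generate_shape_dataset
from treecl.vulnerability import (
    INTERACTIONS,
    MAIN_EFFECTS,
    anova_tukey,
    build_covariate_table,
    collinearity_screen,
    encode_predictors,
    fisher_exact_shapes,
    fit_proportional_odds,
    nagelkerke_r2,
    stepwise_aic,
)


# ---------------------------------------------------------------------------
# covariate table
# ---------------------------------------------------------------------------


def toy_inputs():
    shapes = pd.DataFrame({
        "species": ["A", "A", "B", "C"],
        "division": ["21", "22", "21", "21"],
        "endpoint": "growth",
        "pollutant": "N",
        "shape": [1, 2, "not_applicable", 3],
    })
    plots = pd.DataFrame({
        "species": ["A"] * 3 + ["A", "B", "C"],
        "division": ["21"] * 3 + ["22", "21", "21"],
        "mat_C": [10.0, 12.0, 14.0, 9.0, 11.0, 13.0],
        "map_mm": [800.0, 900.0, 1000.0, 700.0, 950.0, 990.0],
        "soil_ph": [5.0, 6.0, 7.0, 5.5, 6.2, 6.4],
        "ndep": [8.0, 9.0, 10.0, 7.0, 9.5, 9.9],
        "sdep": [5.0, 6.0, 7.0, 4.0, 6.5, 6.9],
    })
    traits = pd.DataFrame({
        "species": ["A", "B"],
        "mycorrhiza": ["AM", "EcM"],
        "leaf_habit": ["deciduous", "evergreen"],
    })
    return shapes, plots, traits


class TestBuildCovariateTable:
    def test_division_level_species_means(self):
        shapes, plots, traits = toy_inputs()
        table, log = build_covariate_table(shapes, plots, traits)
        row = table[(table.species == "A") & (table.division == "21")].iloc[0]
        assert row["soil_pH"] == pytest.approx(6.0)  # mean of {5, 6, 7}
        assert row["MAT"] == pytest.approx(12.0)

    def test_not_applicable_rows_dropped(self):
        shapes, plots, traits = toy_inputs()
        table, log = build_covariate_table(shapes, plots, traits)
        assert log["dropped_not_applicable"] == 1
        assert "B" not in set(table.species)

    def test_species_missing_trait_dropped_with_count(self):
        shapes, plots, traits = toy_inputs()
        table, log = build_covariate_table(shapes, plots, traits)
        assert log["dropped_missing_trait"] == 1  # species C
        assert log["output_rows"] == len(table) == 2


class TestCollinearityScreen:
    def test_duplicated_column_flagged(self, rng):
        df = pd.DataFrame({"MAT": rng.normal(size=50)})
        df["MAP"] = df["MAT"]
        df["soil_pH"] = rng.normal(size=50)
        corr, flagged = collinearity_screen(df, columns=["MAT", "MAP", "soil_pH"])
        pairs = {(a, b) for a, b, *_ in flagged}
        assert ("MAT", "MAP") in pairs and len(pairs) == 1

    def test_independent_columns_not_flagged(self, rng):
        df = pd.DataFrame(rng.normal(size=(500, 3)),
                          columns=["MAT", "MAP", "soil_pH"])
        _, flagged = collinearity_screen(df, columns=["MAT", "MAP", "soil_pH"])
        assert flagged == []

    def test_threshold_is_strict(self):
        # r is exactly 0.5 here (all moments are exact in binary floating
        # point); a threshold equal to |r| must not flag (strict >)
        df = pd.DataFrame({"MAT": [1.0, 2.0, 3.0], "MAP": [1.0, 3.0, 2.0]})
        assert df["MAT"].corr(df["MAP"]) == 0.5
        _, flagged = collinearity_screen(df, threshold=0.5,
                                         columns=["MAT", "MAP"])
        assert flagged == []
        _, flagged = collinearity_screen(df, threshold=0.499,
                                         columns=["MAT", "MAP"])
        assert len(flagged) == 1

    def test_constant_column_flagged_undefined(self):
        df = pd.DataFrame({"MAT": [1.0, 2.0, 3.0], "MAP": [5.0, 5.0, 5.0]})
        _, flagged = collinearity_screen(df, columns=["MAT", "MAP"])
        assert any("undefined" in note for *_, note in flagged)


# ---------------------------------------------------------------------------
# proportional odds
# ---------------------------------------------------------------------------


class TestProportionalOdds:
    def test_null_fit_reproduces_sample_proportions(self):
        tab = pd.DataFrame({"shape": [0] * 10 + [1] * 30 + [2] * 40 + [3] * 20})
        fit = fit_proportional_odds(tab, [])
        probs = fit.predict_probs(np.empty((1, 0)))[0]
        assert probs == pytest.approx([0.1, 0.3, 0.4, 0.2], abs=1e-9)
        assert fit.nagelkerke_r2 == 0.0

    def test_predicted_probabilities_sum_to_one(self):
        tab, _ = generate_shape_dataset(300, seed=5)
        fit = fit_proportional_odds(tab, ["Ndep", "leaf_habit"])
        X = encode_predictors(tab, fit.terms)
        probs = fit.predict_probs(X)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(np.diff(fit.thresholds) > 0)

    def test_binary_case_matches_logistic_oracle(self, rng):
        import statsmodels.api as sm
        n = 400
        x = rng.normal(size=n)
        eta = 0.8 * x - 0.3
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        tab = pd.DataFrame({"shape": y, "MAT": x})
        fit = fit_proportional_odds(tab, ["MAT"])
        oracle = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        # P(Y<=0) = logistic(alpha - bx)  <=>  P(Y=1) = logistic(-alpha + bx)
        assert fit.beta["MAT"] == pytest.approx(oracle.params[1], abs=1e-6)
        assert -fit.thresholds[0] == pytest.approx(oracle.params[0], abs=1e-6)
        assert fit.logLik == pytest.approx(oracle.llf, abs=1e-8)

    def test_too_few_categories_rejected(self):
        tab = pd.DataFrame({"shape": [1] * 20, "MAT": range(20)})
        with pytest.raises(ValueError):
            fit_proportional_odds(tab, ["MAT"])

    def test_evergreen_effect_ci_coverage(self):
        """95% Wald CIs cover a true odds ratio of 2.3 in >= 90/100 draws."""
        true_or = 2.3
        covered = 0
        for rep in range(100):
            tab, _ = generate_shape_dataset(
                500, beta={"leaf_habit": math.log(true_or)}, seed=10_000 + rep)
            fit = fit_proportional_odds(tab, ["leaf_habit"])
            _, lo, hi = fit.odds_ratios["leaf_habit"]
            if lo <= true_or <= hi:
                covered += 1
        assert covered >= 90

    def test_zero_effect_predictor_wilks_calibration(self):
        """Adding a null predictor exceeds the chi2(1) 95% cutoff ~5% of the time."""
        rejections = 0
        n_rep = 100
        rng = np.random.default_rng(77)
        for rep in range(n_rep):
            tab, _ = generate_shape_dataset(300, beta={}, seed=20_000 + rep)
            tab["junk"] = rng.normal(size=len(tab))
            null = fit_proportional_odds(tab, [])
            with_junk = fit_proportional_odds(tab, ["junk"])
            lr = 2 * (with_junk.logLik - null.logLik)
            if lr > 3.841:
                rejections += 1
        assert rejections <= 12  # ~5% expected; binomial slack


class TestNagelkerke:
    def test_equal_likelihoods_give_zero(self):
        assert nagelkerke_r2(-50.0, -50.0, 80) == 0.0

    def test_hand_computation(self):
        assert nagelkerke_r2(-90.0, -100.0, 100) == \
            pytest.approx(0.20964108215325955, abs=1e-9)

    def test_monotone_in_fit_likelihood(self):
        vals = [nagelkerke_r2(L1, -100.0, 100) for L1 in (-95, -90, -80, -60)]
        assert vals == sorted(vals)
        assert all(0 <= v <= 1 for v in vals)


class TestStepwise:
    def test_scope_lists_exactly_six_interactions(self):
        assert len(INTERACTIONS) == 6
        for term in INTERACTIONS:
            a, b = term.split(":")
            assert a in MAIN_EFFECTS and b in MAIN_EFFECTS

    def test_trace_monotone_and_marginality(self):
        tab, _ = generate_shape_dataset(
            400, beta={"MAP": 0.004, "Ndep": 0.08}, seed=99)
        fit = stepwise_aic(tab)
        aics = [a for _, a in fit.step_trace]
        assert all(b <= a + 1e-9 for a, b in zip(aics, aics[1:]))
        for term in fit.terms:
            if ":" in term:
                assert all(m in fit.terms for m in term.split(":"))

    def test_single_map_effect_recovered(self):
        hits = 0
        for rep in range(20):
            tab, _ = generate_shape_dataset(
                400, beta={"MAP": 0.006}, seed=30_000 + rep)
            fit = stepwise_aic(tab, scope_main=("MAT", "MAP", "Ndep",
                                                "leaf_habit"),
                               scope_interactions=("MAT:MAP", "MAT:Ndep"))
            if "MAP" in fit.terms and not any(":" in t for t in fit.terms):
                hits += 1
        assert hits >= 16


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------


def log_table_prob(tab):
    r, c, n = tab.sum(1), tab.sum(0), tab.sum()
    return (gammaln(r + 1).sum() + gammaln(c + 1).sum()
            - gammaln(n + 1) - gammaln(tab + 1).sum())


def enumerate_exact_p(obs):
    """Exhaustive two-sided Fisher p for a small RxC table (oracle)."""
    obs = np.asarray(obs, dtype=np.int64)
    rows, cols = obs.sum(1), obs.sum(0)
    R, C = obs.shape
    lp_obs = log_table_prob(obs)
    total = 0.0
    extreme = 0.0

    def rec(i, remaining_cols, built):
        nonlocal total, extreme
        if i == R - 1:
            tab = np.vstack(built + [remaining_cols])
            if np.all(tab >= 0):
                lp = log_table_prob(tab)
                p = math.exp(lp)
                total += p
                if lp <= lp_obs + 1e-9:
                    extreme += p
            return
        ranges = [range(min(rows[i], remaining_cols[j]) + 1) for j in range(C)]
        for combo in itertools.product(*ranges):
            if sum(combo) == rows[i]:
                rec(i + 1, remaining_cols - np.array(combo),
                    built + [np.array(combo)])

    rec(0, cols.copy(), [])
    return extreme / total


class TestFisherExact:
    def test_diagonal_2x2_exact(self):
        p = fisher_exact_shapes([[5, 0], [0, 5]])
        assert p == pytest.approx(2 / 252, abs=1e-12)

    def test_identical_columns_no_association(self):
        p = fisher_exact_shapes([[6, 6], [4, 4]])
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_monte_carlo_matches_enumeration_3x3(self):
        obs = np.array([[3, 1, 0], [0, 3, 1], [1, 0, 3]])
        exact = enumerate_exact_p(obs)
        mc = fisher_exact_shapes(obs, B=20_000, seed=11)
        assert mc == pytest.approx(exact, abs=0.01)

    def test_reproducible_and_converging(self):
        obs = np.array([[3, 1, 0], [0, 3, 1], [1, 0, 3]])
        p1 = fisher_exact_shapes(obs, B=8000, seed=3)
        assert p1 == fisher_exact_shapes(obs, B=8000, seed=3)
        p2 = fisher_exact_shapes(obs, B=16_000, seed=3)
        assert p2 == pytest.approx(p1, abs=0.005 + 0.005)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_shapes([[0, 0], [0, 0]])


# ---------------------------------------------------------------------------
# ANOVA / Tukey
# ---------------------------------------------------------------------------


class TestAnovaTukey:
    def test_equal_means_give_zero_f(self):
        res = anova_tukey({"a": [1, 2, 3], "b": [0, 2, 4], "c": [2, 2, 2]})
        assert res["F"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0, abs=1e-9)
        assert (res["tukey"]["p-adj"].astype(float) > 0.95).all()

    def test_two_groups_f_equals_t_squared(self, rng):
        from scipy import stats
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 25)
        res = anova_tukey({"a": a, "b": b})
        t, _ = stats.ttest_ind(a, b)
        assert res["F"] == pytest.approx(t**2, rel=1e-10)

    def test_three_groups_against_sums_of_squares_oracle(self):
        groups = {"g1": [6.0, 8.0, 4.0, 5.0, 3.0, 4.0],
                  "g2": [8.0, 12.0, 9.0, 11.0, 6.0, 8.0],
                  "g3": [13.0, 9.0, 11.0, 8.0, 7.0, 12.0]}
        allv = np.concatenate([np.asarray(v) for v in groups.values()])
        grand = allv.mean()
        ss_between = sum(len(v) * (np.mean(v) - grand) ** 2
                         for v in groups.values())
        ss_within = sum(((np.asarray(v) - np.mean(v)) ** 2).sum()
                        for v in groups.values())
        f_oracle = (ss_between / 2) / (ss_within / 15)
        res = anova_tukey(groups)
        assert res["F"] == pytest.approx(f_oracle, abs=1e-10)
        assert res["df"] == (2, 15)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey({"only": [1, 2, 3]})
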