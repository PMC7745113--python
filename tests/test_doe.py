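"""Factorial design construction, effect estimation and regression."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from flowtube.doe import (
    DesignError,
    DesignSpec,
    FactorialModel,
    RegressionModel,
    build_design,
    estimate_effects,
    fit_model,
    lenth_screen,
    predict_surface,
    two_way_terms,
)


@pytest.fixture()
def full():
    return build_design(DesignSpec())


@pytest.fixture()
def fractional():
    return build_design(DesignSpec(design_kind="fractional_2k_minus_1"))


class TestBuildDesign:
    def test_full_design_has_32_unique_runs(self, full):
        assert len(full) == 32
        assert len(full[list("ABCDE")].drop_duplicates()) == 32

    def test_fractional_design_has_16_runs_with_generator(self, fractional):
        assert len(fractional) == 16
        prod = fractional[list("ABCD")].prod(axis=1)
        assert np.array_equal(prod.to_numpy(), fractional["E"].to_numpy())

    def test_coded_columns_are_balanced(self, full, fractional):
        for df in (full, fractional):
            assert np.allclose(df[list("ABCDE")].sum(), 0.0)

    def test_natural_units_match_levels(self, full):
        assert set(full["ID_mm"]) == {0.25, 1.0}
        assert set(full["T_C"]) == {10.0, 40.0}
        low_row = full[(full[list("ABCDE")] == -1).all(axis=1)]
        assert float(low_row["L_m"].iloc[0]) == 1.0

    def test_replicates_and_bad_generator(self):
        rep = build_design(DesignSpec(replicates=3))
        assert len(rep) == 96
        assert set(rep["replicate"]) == {1, 2, 3}
        with pytest.raises(DesignError):
            DesignSpec(design_kind="fractional_2k_minus_1", generator="E=AB")


class TestEstimateEffects:
    def test_constant_response_gives_zero_effects(self, full):
        eff = estimate_effects(full, np.full(32, 7.0))
        assert np.allclose(eff["effect"], 0.0)

    def test_pure_contrast_response(self, full):
        eff = estimate_effects(full, full["B"].to_numpy())
        by_term = eff.set_index("term")["effect"]
        assert by_term["B"] == pytest.approx(2.0)
        assert np.allclose(by_term.drop("B"), 0.0, atol=1e-12)

    def test_effects_equal_twice_regression_coefficients(self, full):
        """Contrast effects on an orthogonal design coincide with OLS
        coefficients times two."""
        rng = np.random.default_rng(3)
        y = rng.normal(size=32)
        terms = two_way_terms()
        eff = estimate_effects(full, y, terms).set_index("term")
        X = np.column_stack(
            [np.prod([full[l].to_numpy() for l in t], axis=0) for t in terms]
        )
        beta = sm.OLS(y, sm.add_constant(X)).fit().params[1:]
        for t, b in zip(terms, beta):
            assert eff.loc[t, "coefficient"] == pytest.approx(b, abs=1e-10)

    def test_fractional_aliasing_sums_effects(self, fractional):
        """In the E=ABCD half fraction, a three-way term folds onto its
        aliased two-way partner: BC is aliased with ADE."""
        A, B, C, D, E = (fractional[l].to_numpy() for l in "ABCDE")
        y = 1.0 + 0.3 * B * C + 0.2 * A * D * E
        eff = estimate_effects(fractional, y).set_index("term")
        assert eff.loc["BC", "effect"] == pytest.approx(2 * (0.3 + 0.2))


class TestLenth:
    def test_hand_worked_example(self):
        effects = [10, 0.1, -0.12, 0.08, 0.11, -0.09, 0.1]
        df = pd.DataFrame(
            {"term": [f"e{i}" for i in range(7)], "effect": effects}
        )
        out, res = lenth_screen(df, alpha=0.05)
        assert res.significant == ("e0",)
        assert res.s0 == pytest.approx(0.15)
        assert res.pse == pytest.approx(0.15)

    def test_equal_effects_none_flagged(self):
        df = pd.DataFrame(
            {"term": list("abcdefg"), "effect": [0.2] * 7}
        )
        _, res = lenth_screen(df)
        assert res.significant == ()

    def test_all_zero_effects(self):
        df = pd.DataFrame({"term": list("abcdefg"), "effect": [0.0] * 7})
        _, res = lenth_screen(df)
        assert res.significant == ()
        assert res.margin == 0.0

    def test_too_few_effects_rejected(self):
        df = pd.DataFrame({"term": list("abc"), "effect": [1, 2, 3]})
        with pytest.raises(ValueError):
            lenth_screen(df)


class TestFactorialModel:
    def test_exact_recovery_of_generating_model(self, full):
        y_log = (
            0.8 + 0.3 * full["A"] + 0.5 * full["B"] - 0.2 * full["C"]
        ).to_numpy()
        res = FactorialModel(full, 10.0**y_log, ["A", "B", "C"]).fit()
        assert res.intercept == pytest.approx(0.8, abs=1e-10)
        assert res.coefficients["B"] == pytest.approx(0.5, abs=1e-10)
        assert res.anova.r_squared == pytest.approx(1.0)

    def test_anova_ordering_on_noisy_data(self, full):
        rng = np.random.default_rng(11)
        y_log = 1.0 + 0.4 * full["B"].to_numpy() + rng.normal(0, 0.1, 32)
        _, anova = fit_model(full, 10.0**y_log, ["A", "B", "C", "D"])
        assert anova.pred_r_squared <= anova.adj_r_squared <= anova.r_squared

    def test_pure_error_and_lack_of_fit_with_replicates(self):
        design = build_design(
            DesignSpec(design_kind="fractional_2k_minus_1", replicates=3)
        )
        rng = np.random.default_rng(5)
        base = 1.0 + 0.3 * design["B"].to_numpy()
        noisy = 10.0 ** (base + rng.normal(0, 0.05, len(design)))
        res = FactorialModel(design, noisy, ["A", "B", "C", "D"]).fit()
        assert res.anova.pure_error_ms > 0.0
        assert res.anova.lack_of_fit_f is not None
        clean = FactorialModel(design, 10.0**base, ["B"]).fit()
        assert clean.anova.pure_error_ms == pytest.approx(0.0, abs=1e-20)

    def test_rank_deficiency_names_aliased_terms(self, fractional):
        with pytest.raises(DesignError, match="alias"):
            FactorialModel(
                fractional, np.ones(16) + fractional["A"], ["A", "BCDE"]
            ).fit()

    def test_hierarchy_terms_added(self, full):
        model = FactorialModel(full, np.ones(32), ["DE"])
        assert "D" in model.terms and "E" in model.terms
        assert model.hierarchy_terms == ("D", "E")

    def test_zero_yields_guarded_by_floor(self, full):
        y = np.zeros(32)
        res = FactorialModel(full, y).fit()  # floored at 0.01%
        assert res.intercept == pytest.approx(-2.0)


class TestPredictSurface:
    def test_no_interaction_gives_parallel_slices(self):
        model = RegressionModel(1.0, {"D": 0.2, "E": 0.05})
        surf = predict_surface(model, "D", "E", n=5)
        wide = surf.pivot(index="D", columns="E", values="yield_pct")
        logw = np.log10(wide.to_numpy())
        slopes = logw[:, -1] - logw[:, 0]
        assert np.allclose(slopes, slopes[0])

    def test_interaction_changes_ratio_slope_with_temperature(self):
        """With the reported D-E interaction, the molar-ratio slope of
        log-yield is 0.013 - 0.047 = -0.034 at low temperature and
        0.013 + 0.047 = 0.060 at high temperature."""
        model = RegressionModel(1.09, {"E": 0.013, "D": 0.13, "DE": 0.047})
        coded = pd.DataFrame(0.0, index=range(4), columns=list("ABCDE"))
        coded.loc[1, "E"] = 1.0
        coded.loc[2, "D"] = 1.0
        coded.loc[3, ["D", "E"]] = 1.0
        pred = model.predict_transformed(coded)
        slope_low = pred[1] - pred[0]  # D = 0 baseline slope: 0.013
        slope_high = pred[3] - pred[2]
        assert slope_high == pytest.approx(0.060, abs=1e-12)
        coded_neg = coded.copy()
        coded_neg["D"] = -1.0
        pred_neg = model.predict_transformed(coded_neg)
        assert pred_neg[1] - pred_neg[0] == pytest.approx(-0.034, abs=1e-12)
        assert slope_low == pytest.approx(0.013, abs=1e-12)

    def test_centre_point_returns_inverse_intercept(self):
        model = RegressionModel(1.09, {"D": 0.13})
        surf = predict_surface(model, "D", "E", n=3)
        centre = surf[(surf["D"] == 0.0) & (surf["E"] == 0.0)]
        assert float(centre["yield_pct"].iloc[0]) == pytest.approx(10**1.09)

    def test_extrapolation_warns(self):
        model = RegressionModel(1.0, {"D": 0.1})
        with pytest.warns(UserWarning, match="beyond"):
            predict_surface(model, "D", "E", n=3, limits=(-2.0, 2.0))
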