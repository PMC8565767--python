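"""Penalized-spline binomial GAM: basis and penalty algebra, P-IRLS
fitting against a from-scratch Newton logistic oracle, prediction,
partial effects and coefficient surfaces."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from firegam.features import COVARIATES
from firegam.gam import (
    FittedGAM,
    SmoothTermSpec,
    build_spline_basis,
    coefficient_surface,
    fit_binomial_gam,
    fit_leave_one_year_out,
    partial_effect,
    predict_linear,
    predict_probability,
    term_significance,
)
from firegam.synthetic import make_effect


def newton_logistic(X, y, tol=1e-12, max_iter=200):
    """Independent oracle: plain Newton-Raphson logistic regression."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        mu = expit(X @ beta)
        W = mu * (1 - mu)
        grad = X.T @ (y - mu)
        hess = X.T @ (X * W[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    return beta


class TestSplineBasis:
    def test_penalty_annihilates_straight_lines(self):
        x = np.linspace(0, 10, 50)
        _, S, basis = build_spline_basis(x, 5)
        line = 2.0 + 3.0 * basis.knots  # spline through knot values of a line
        assert line @ S @ line == pytest.approx(0.0, abs=1e-10)

    def test_penalty_positive_for_curved_functions(self):
        x = np.linspace(0, 10, 50)
        _, S, basis = build_spline_basis(x, 5)
        curved = basis.knots**2
        assert curved @ S @ curved > 1e-6

    def test_basis_interpolates_knot_values(self):
        """The parameterization is by values at the knots: evaluating at a
        knot returns exactly that coordinate."""
        x = np.linspace(-2, 7, 40)
        _, _, basis = build_spline_basis(x, 5)
        B = basis.design(basis.knots)
        np.testing.assert_allclose(B, np.eye(5), atol=1e-10)

    def test_c2_continuity_at_interior_knots(self):
        """Value, first and second derivative are continuous across each
        interior knot (finite-difference audit)."""
        x = np.linspace(0, 1, 30)
        _, _, basis = build_spline_basis(x, 5)
        rng = np.random.default_rng(0)
        beta = rng.normal(size=5)
        h = 1e-5
        for knot in basis.knots[1:-1]:
            pts = np.array([knot - 2 * h, knot - h, knot,
                            knot + h, knot + 2 * h])
            f = basis.design(pts) @ beta
            d_left = (f[2] - f[0]) / (2 * h)
            d_right = (f[4] - f[2]) / (2 * h)
            assert d_left == pytest.approx(d_right, rel=1e-3, abs=1e-4)
            s_left = (f[2] - 2 * f[1] + f[0]) / h**2
            s_right = (f[4] - 2 * f[3] + f[2]) / h**2
            assert s_left == pytest.approx(s_right, rel=1e-2, abs=1e-2)

    def test_out_of_span_evaluation_clamps(self):
        x = np.linspace(0, 1, 20)
        _, _, basis = build_spline_basis(x, 4)
        np.testing.assert_allclose(basis.design(np.array([-5.0])),
                                   basis.design(np.array([0.0])))
        np.testing.assert_allclose(basis.design(np.array([9.0])),
                                   basis.design(np.array([1.0])))

    def test_decreasing_knots_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            build_spline_basis(np.linspace(0, 1, 20), 4,
                               knots=np.array([0.0, 0.5, 0.2, 1.0]))

    def test_basis_dim_below_three_rejected(self):
        with pytest.raises(ValueError, match="basis_dim"):
            SmoothTermSpec("aet_normal", basis_dim=2)


def _toy_records(n, seed, effect=None, name="aet_normal"):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 10, n)
    eta = -1.0 + (effect(x) if effect else 0.4 * x - 2.0)
    y = (rng.random(n) < expit(eta)).astype(int)
    return pd.DataFrame({name: x, "burned": y, "year": 2000})


class TestFitting:
    def test_intercept_only_is_logit_of_positive_fraction(self):
        rng = np.random.default_rng(1)
        y = (rng.random(2000) < 0.3).astype(int)
        rec = pd.DataFrame({"burned": y, "year": 2000})
        m = fit_binomial_gam(rec, [])
        assert m.intercept == pytest.approx(float(logit(y.mean())), abs=1e-8)

    def test_single_class_rejected(self):
        rec = pd.DataFrame({"burned": np.zeros(50, int), "year": 2000})
        with pytest.raises(ValueError, match="single class"):
            fit_binomial_gam(rec, [])

    @pytest.mark.parametrize("seed", range(5))
    def test_linear_basis_matches_newton_oracle(self, seed):
        """Unpenalized single-column fit equals a from-scratch Newton
        logistic regression to 1e-6."""
        rec = _toy_records(500, seed)
        m = fit_binomial_gam(rec, [SmoothTermSpec("aet_normal",
                                                  basis="linear")])
        X = np.column_stack([np.ones(len(rec)), rec["aet_normal"]])
        ref = newton_logistic(X, rec["burned"].to_numpy(float))
        assert m.intercept == pytest.approx(ref[0], abs=1e-6)
        assert m.terms[0].coef[0] == pytest.approx(ref[1], abs=1e-6)

    def test_large_lambda_flattens_curve_to_line_and_edf_to_one(self):
        """As lambda grows the smooth collapses onto the penalty null space
        (lines; one free dimension once centered), so the partial-effect
        curve straightens and the term EDF approaches 1."""
        rec = _toy_records(3000, 2, effect=lambda x: 0.3 * (x - 5) ** 2 - 2)
        m = fit_binomial_gam(rec, [SmoothTermSpec("aet_normal", 5)],
                             lambda_rule=1e9)
        t = m.terms[0]
        assert t.edf == pytest.approx(1.0, abs=0.05)
        grid = np.linspace(0.5, 9.5, 30)
        curve = partial_effect(m, "aet_normal", grid)["effect"].to_numpy()
        resid = curve - np.polyval(np.polyfit(grid, curve, 1), grid)
        assert np.abs(resid).max() < 1e-3 * (np.abs(curve).max() + 1)

    def test_penalized_fit_beats_null_deviance(self):
        rec = _toy_records(2000, 3)
        m = fit_binomial_gam(rec, [SmoothTermSpec("aet_normal", 5)])
        assert m.deviance < m.null_deviance
        assert m.converged

    def test_edf_bounds_and_trace_identity(self, small_model):
        for t in small_model.terms:
            assert 0 < t.edf <= t.n_coef + 1e-9
        assert (sum(t.edf for t in small_model.terms) + 1
                == pytest.approx(small_model.edf_total, abs=0.1))

    def test_fixed_per_term_lambdas_accepted(self):
        rec = _toy_records(800, 4)
        m = fit_binomial_gam(rec, [SmoothTermSpec("aet_normal", 5)],
                             lambda_rule=[10.0])
        assert m.terms[0].lam == 10.0

    def test_leave_one_year_out_excludes_the_year(self):
        rng = np.random.default_rng(5)
        rec = pd.DataFrame({
            "aet_normal": rng.uniform(0, 10, 900),
            "burned": rng.integers(0, 2, 900),
            "year": np.repeat([2000, 2001, 2002], 300),
        })
        models = fit_leave_one_year_out(
            rec, [SmoothTermSpec("aet_normal", basis="linear")])
        assert set(models) == {2000, 2001, 2002}
        assert all(m.n_train == 600 for m in models.values())
        # and the excluded-year model differs from the pooled fit
        pooled = fit_binomial_gam(rec, [SmoothTermSpec("aet_normal",
                                                       basis="linear")])
        assert models[2000].intercept != pooled.intercept


class TestPrediction:
    def test_mean_prediction_matches_positive_fraction(self, small_model,
                                                       small_table):
        """The IRLS score equation at the intercept forces the mean fitted
        probability to equal the training positive fraction."""
        p = predict_probability(small_model, small_table)
        assert p.mean() == pytest.approx(
            small_model.train_positive_fraction, abs=1e-6)
        assert np.all((p > 0) & (p < 1))

    def test_prediction_decomposes_into_intercept_plus_terms(self,
                                                             small_model):
        """The linear predictor is exactly the intercept plus the sum of
        the per-term partial effects (additive decomposition identity)."""
        at_means = pd.DataFrame({
            name: [small_model.training_summary[name]["mean"]]
            for name in COVARIATES
        })
        eta = predict_linear(small_model, at_means)[0]
        contributions = sum(
            partial_effect(small_model, name,
                           at_means[name].to_numpy())["effect"][0]
            for name in COVARIATES
        )
        assert eta == pytest.approx(small_model.intercept + contributions,
                                    abs=1e-10)

    def test_missing_covariate_named_in_error(self, small_model):
        with pytest.raises(KeyError, match="cwd_normal"):
            predict_probability(small_model,
                                pd.DataFrame({"aet_normal": [1.0]}))

    def test_out_of_range_prediction_clamps(self, small_model, small_table):
        row = small_table.head(1).copy()
        s = small_model.training_summary["aet_normal"]
        row["aet_normal"] = s["max"] + 1e6
        hi = predict_probability(small_model, row)
        row["aet_normal"] = s["max"]
        at_max = predict_probability(small_model, row)
        assert hi[0] == pytest.approx(at_max[0])

    def test_monotone_truth_gives_monotone_prediction_gradient(self):
        """On data generated with a monotone effect, predictions increase
        along that covariate with everything else fixed."""
        rec = _toy_records(20000, 6, effect=lambda x: 0.5 * x - 3)
        m = fit_binomial_gam(rec, [SmoothTermSpec("aet_normal", 5)])
        grid = pd.DataFrame({"aet_normal": np.linspace(0.5, 9.5, 20)})
        p = predict_probability(m, grid)
        assert np.all(np.diff(p) > 0)

    def test_serialization_round_trip_reproduces_predictions(
            self, small_model, small_table, tmp_path):
        path = tmp_path / "model.json"
        small_model.to_json(path)
        back = FittedGAM.from_json(path)
        np.testing.assert_allclose(
            predict_linear(back, small_table.head(500)),
            predict_linear(small_model, small_table.head(500)),
            rtol=0, atol=1e-12)


class TestPartialEffects:
    def test_curve_sums_to_zero_over_training_values(self, small_model,
                                                     small_table):
        for name in ("aet_normal", "years_since_fire"):
            x = small_table[name].to_numpy()
            eff = partial_effect(small_model, name, x)["effect"]
            assert abs(eff.mean()) < 1e-8 * (np.abs(eff).max() + 1)

    def test_out_of_span_grid_points_are_flagged(self, small_model):
        s = small_model.training_summary["aet_normal"]
        grid = np.array([s["min"] - 1, s["mean"], s["max"] + 1])
        pe = partial_effect(small_model, "aet_normal", grid)
        assert pe["clamped"].tolist() == [True, False, True]

    def test_se_band_is_positive_and_finite(self, small_model):
        s = small_model.training_summary["cwd_normal"]
        pe = partial_effect(small_model, "cwd_normal",
                            np.linspace(s["min"], s["max"], 50))
        assert np.isfinite(pe["se"]).all() and (pe["se"] > 0).all()

    def test_unknown_term_rejected(self, small_model):
        with pytest.raises(KeyError):
            partial_effect(small_model, "no_such_term", np.arange(3.0))

    def test_shape_recovery_against_generating_truth(self, small_model,
                                                     small_table, small_panel):
        """Fitted smooths track the generating effect functions (data-
        quantile grid; correlation is invariant to the centering offset).
        At this deliberately small fixture size the bar is 0.8; the
        full-size landscape run in the acceptance suite asserts 0.9."""
        effects = small_panel.truth["effects"]
        for name in ("aet_normal", "cwd_normal", "years_since_fire"):
            x = small_table[name].to_numpy()
            grid = np.unique(np.quantile(x, np.linspace(0.01, 0.99, 60)))
            fitted = partial_effect(small_model, name, grid)["effect"]
            truth = make_effect(effects[name])(grid)
            assert np.corrcoef(fitted, truth)[0, 1] > 0.8


class TestCoefficientSurface:
    def test_constant_raster_gives_constant_surface(self, small_model):
        s = small_model.training_summary["aet_normal"]
        raster = np.full((7, 7), s["mean"])
        surf = coefficient_surface(small_model, "aet_normal", raster)
        expected = partial_effect(small_model, "aet_normal",
                                  np.array([s["mean"]]))["effect"][0]
        np.testing.assert_allclose(surf, expected)

    def test_surface_matches_curve_pointwise(self, small_model, small_panel):
        raster = small_panel.truth["aet_normal"]
        surf = coefficient_surface(small_model, "aet_normal", raster)
        rng = np.random.default_rng(2)
        rr = rng.integers(0, raster.shape[0], 100)
        cc = rng.integers(0, raster.shape[1], 100)
        curve = partial_effect(small_model, "aet_normal",
                               raster[rr, cc])["effect"].to_numpy()
        np.testing.assert_allclose(surf[rr, cc], curve, atol=1e-12)

    def test_masked_cells_stay_masked(self, small_model):
        raster = np.full((4, 4), 100.0)
        raster[1, 2] = np.nan
        surf = coefficient_surface(small_model, "aet_normal", raster)
        assert np.isnan(surf[1, 2])
        assert np.isfinite(np.delete(surf.ravel(), 6)).all()


class TestTermSignificance:
    def test_reports_one_row_per_term_with_valid_pvalues(self, small_model):
        tab = term_significance(small_model)
        assert list(tab["term"]) == [t.name for t in small_model.terms]
        assert ((tab["p_value_approx"] >= 0) & (tab["p_value_approx"] <= 1)).all()
        assert (tab["ref_df"] == 4).all()
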