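import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.stattools import durbin_watson as sm_durbin_watson

from diabrisk import (
    PATTERN_NAMES,
    FittedCurve,
    compute_fit_stats,
    durbin_watson,
    fit_all,
    fit_pattern,
    predict,
    select_best,
)
from diabrisk.curvefit import adjusted_stats

from conftest import make_dataset

# closed-form generators for exact-recovery checks, one per pattern
GENERATORS = {
    "linear": ((2.0, 3.0), lambda b, x: b[0] + b[1] * x),
    "logarithmic": ((1.5, 4.0), lambda b, x: b[0] + b[1] * np.log(x)),
    "quadratic": ((10.0, -2.0, 0.5), lambda b, x: b[0] + b[1] * x + b[2] * x**2),
    "cubic": (
        (10.0, -2.0, 0.5, 0.1),
        lambda b, x: b[0] + b[1] * x + b[2] * x**2 + b[3] * x**3,
    ),
    "power": ((2.0, 1.3), lambda b, x: b[0] * x ** b[1]),
    "s": ((1.0, 2.0), lambda b, x: np.exp(b[0] + b[1] / x)),
    "exponential": ((3.0, 0.4), lambda b, x: b[0] * np.exp(b[1] * x)),
}


class TestExactRecovery:
    @pytest.mark.parametrize("pattern", PATTERN_NAMES)
    def test_refit_recovers_generating_coefficients(self, pattern):
        coefs, gen = GENERATORS[pattern]
        x = np.linspace(1.0, 6.0, 8)
        ds = make_dataset(x, gen(coefs, x))
        fit = fit_pattern(ds, pattern)
        assert fit.coefficients == pytest.approx(coefs, rel=1e-8)
        assert fit.stats.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_s_pattern_four_points(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        ds = make_dataset(x, np.exp(1.0 + 2.0 / x))
        fit = fit_pattern(ds, "s")
        assert fit.coefficients == pytest.approx((1.0, 2.0))


class TestNormalEquationsOracle:
    """lstsq solution must match (X'X)^-1 X'y computed independently."""

    @pytest.mark.parametrize("pattern,ncol", [("linear", 2), ("quadratic", 3), ("cubic", 4)])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_polynomials_match_normal_equations(self, pattern, ncol, seed):
        rng = np.random.default_rng(seed)
        x = np.sort(rng.uniform(1, 10, size=10))
        y = rng.uniform(5, 50, size=10)
        ds = make_dataset(x, y)
        fit = fit_pattern(ds, pattern)
        X = np.vander(x, ncol, increasing=True)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.coefficients == pytest.approx(tuple(beta), rel=1e-8)


class TestFitStats:
    def test_reference_row_from_packaged_table(self, hba1c_npdr):
        s = fit_pattern(hba1c_npdr, "linear").stats
        assert round(s.r_squared, 3) == 0.542
        assert round(s.wherry_adj, 3) == 0.509
        assert round(s.durbin_watson, 3) == 2.104
        assert s.n == 16 and s.k_predictors == 1
        assert s.p_value == pytest.approx(0.00115, abs=2e-4)

    def test_perfect_fit_fixed_point(self):
        y = [1.0, 2.0, 3.0, 4.0, 5.0]
        s = compute_fit_stats(y, y, k_predictors=1)
        assert s.r_squared == pytest.approx(1.0)
        assert s.wherry_adj == pytest.approx(1.0)
        assert s.stein_adj == pytest.approx(1.0)
        assert s.see == 0.0
        assert math.isinf(s.f_ratio) and s.p_value == 0.0

    def test_hand_derived_r2_half_n20_k2(self):
        # direct arithmetic from the two displayed shrinkage formulas
        wherry, stein, f = adjusted_stats(0.5, n=20, k_predictors=2)
        assert wherry == pytest.approx(1 - 0.5 * 19 / 17)
        assert stein == pytest.approx(1 - (19 / 17) * (18 / 16) * (21 / 20) * 0.5)
        assert f == pytest.approx((0.5 / 2) / (0.5 / 17))
        assert f == pytest.approx(8.5)

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            compute_fit_stats([2.0] * 6, [2.0] * 6, 1)

    def test_stein_below_wherry_below_r2(self, hba1c_npdr):
        for fit in fit_all(hba1c_npdr):
            s = fit.stats
            assert s.stein_adj <= s.wherry_adj <= s.r_squared


class TestDurbinWatson:
    def test_constant_residuals_give_zero(self):
        assert durbin_watson([1.0, 1.0, 1.0, 1.0]) == 0.0

    def test_alternating_residuals(self):
        # sum of squared successive diffs 12, sum of squares 4
        assert durbin_watson([1.0, -1.0, 1.0, -1.0]) == pytest.approx(3.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            durbin_watson([0.0, 0.0, 0.0])

    @given(st.lists(st.floats(min_value=-10, max_value=10), min_size=2, max_size=30))
    def test_range_and_reversal_invariance(self, resid):
        if not any(r != 0 for r in resid):
            resid[0] = 1.0
        dw = durbin_watson(resid)
        assert 0.0 <= dw <= 4.0
        assert durbin_watson(resid[::-1]) == pytest.approx(dw)

    @pytest.mark.parametrize("seed", [0, 5])
    def test_matches_statsmodels(self, seed):
        e = np.random.default_rng(seed).normal(size=25)
        assert durbin_watson(e) == pytest.approx(float(sm_durbin_watson(e)))


class TestSelection:
    def test_packaged_table_selects_linear(self, hba1c_npdr):
        assert select_best(fit_all(hba1c_npdr)).pattern == "linear"

    def test_singleton(self, hba1c_npdr):
        fit = fit_pattern(hba1c_npdr, "s")
        assert select_best([fit]) is fit

    def test_tie_breaks_to_fewer_coefficients(self, line_dataset):
        lin = fit_pattern(line_dataset, "linear")
        quad = fit_pattern(line_dataset, "quadratic")
        # both fit the line perfectly -> identical adjusted R²
        assert select_best([quad, lin]).pattern == "linear"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best([])

    def test_best_dominates_on_selection_scale(self, hba1c_npdr):
        fits = fit_all(hba1c_npdr)
        best = select_best(fits)
        assert all(best.stats.wherry_adj >= f.stats.wherry_adj for f in fits)

    def test_fit_all_skips_log_patterns_on_zero_risk(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])  # zero risk blocks log fits
        fits = fit_all(make_dataset(x, y))
        names = {f.pattern for f in fits}
        assert {"power", "s", "exponential"}.isdisjoint(names)
        assert "linear" in names


class TestPredict:
    def test_linear(self, line_dataset):
        fit = fit_pattern(line_dataset, "linear")
        assert predict(fit, 4.0) == pytest.approx(14.0)

    def test_power_response_scale(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        ds = make_dataset(x, 2.0 * x)  # y = 2 x^1
        fit = fit_pattern(ds, "power")
        assert predict(fit, 5.0) == pytest.approx(10.0)

    def test_best_curve_prediction_matches_ols_solution(self, hba1c_npdr):
        best = select_best(fit_all(hba1c_npdr))
        b0, b1 = best.coefficients
        assert predict(best, 9.5) == pytest.approx(b0 + b1 * 9.5)

    def test_domain_violation_rejected(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        fit = fit_pattern(make_dataset(x, 2.0 * x), "power")
        with pytest.raises(ValueError):
            predict(fit, -1.0)


class TestPreconditions:
    def test_too_few_points(self):
        ds = make_dataset([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="at least"):
            fit_pattern(ds, "cubic")

    def test_nonpositive_x_rejected_for_log_patterns(self):
        ds = make_dataset([-1.0, 1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="-1"):
            fit_pattern(ds, "logarithmic")

    def test_rank_deficient_design_rejected(self):
        ds = make_dataset([2.0, 2.0, 2.0, 2.0], [1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="rank"):
            fit_pattern(ds, "linear")

    def test_unknown_pattern_rejected(self, line_dataset):
        with pytest.raises(ValueError, match="unknown pattern"):
            fit_pattern(line_dataset, "sigmoid")


def test_fitted_curve_json_round_trip(tmp_path, hba1c_npdr):
    fit = fit_pattern(hba1c_npdr, "linear")
    path = tmp_path / "model.json"
    fit.to_json(path)
    assert FittedCurve.from_json(path) == fit
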