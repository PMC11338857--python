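"""Regression machinery: OLS correctness, F statistics, degeneracy handling."""

import math

import numpy as np
import pytest
from scipy import special

from topoqspr import qspr
from topoqspr.qspr import (
    DegenerateFitError,
    condition_check,
    f_pvalue,
    fit,
    fit_all,
    predict,
)


@pytest.fixture(scope="module")
def table():
    return fit_all("published")


def normal_equations(X, y):
    """Independent OLS oracle: direct normal-equations solve."""
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestFit:
    def test_perfect_linear_fit(self):
        x = np.arange(1.0, 11.0)
        res = fit("linear", x, 2 * x)
        assert res.A == pytest.approx(0.0, abs=1e-10)
        assert res.b == pytest.approx(2.0, rel=1e-12)
        assert res.r == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    @pytest.mark.parametrize("family", ["linear", "quadratic", "logarithmic"])
    def test_coefficients_match_normal_equations(self, family):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(6, 30))
            x = rng.uniform(0.5, 20.0, size=n)
            y = rng.normal(50.0, 10.0, size=n) + 3.0 * x
            res = fit(family, x, y)
            if family == "linear":
                X = np.column_stack([np.ones(n), x])
            elif family == "quadratic":
                X = np.column_stack([np.ones(n), x, x * x])
            else:
                X = np.column_stack([np.ones(n), np.log(x)])
            beta = normal_equations(X, y)
            got = [res.A, res.b] + ([res.c] if family == "quadratic" else [])
            assert np.allclose(got, beta, rtol=1e-9, atol=1e-9)

    def test_through_the_means(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(1, 50, size=15)
        y = rng.normal(0, 5, size=15) + 2 * x
        for family in ("linear", "logarithmic"):
            res = fit(family, x, y)
            x_mean = np.log(x).mean() if family == "logarithmic" else x.mean()
            assert res.A + res.b * x_mean == pytest.approx(y.mean(), abs=1e-9)

    def test_quadratic_on_linear_data_reduces(self):
        x = np.linspace(1, 10, 12)
        y = 5.0 + 3.0 * x
        res = fit("quadratic", x, y)
        assert res.A == pytest.approx(5.0, abs=1e-8)
        assert res.b == pytest.approx(3.0, abs=1e-8)
        assert res.c == pytest.approx(0.0, abs=1e-9)

    def test_r_sign_follows_slope(self):
        x = np.arange(1.0, 16.0)
        res = fit("linear", x, 100.0 - 2.0 * x + np.sin(x))
        assert res.b < 0 and res.r < 0
        assert res.r == pytest.approx(-math.sqrt(res.r2))

    def test_minimal_quadratic_n(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        res = fit("quadratic", x, np.array([1.0, 3.0, 7.0, 20.0]))
        assert res.n == 4  # df2 = 1

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            fit("quadratic", [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_logarithmic_rejects_nonpositive(self):
        with pytest.raises(ValueError, match="positive"):
            fit("logarithmic", [-1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])

    def test_huge_values_raise_degenerate(self):
        x = np.geomspace(1e40, 1e60, 15)
        with pytest.raises(DegenerateFitError) as err:
            fit("linear", x, np.arange(15.0))
        assert not err.value.diagnostic.passed


class TestFPValue:
    def test_trivial_points(self):
        assert f_pvalue(0.0, 1, 13) == pytest.approx(1.0)
        assert f_pvalue(1.0, 1, 1) == pytest.approx(0.5)

    def test_against_incomplete_beta_oracle(self):
        # P(F > f) = I_{df2/(df2 + df1 f)}(df2/2, df1/2)
        for F, df1, df2 in [(249.667, 1, 13), (5.0, 2, 12), (0.3, 1, 8)]:
            x = df2 / (df2 + df1 * F)
            oracle = special.betainc(df2 / 2, df1 / 2, x)
            assert f_pvalue(F, df1, df2) == pytest.approx(oracle, rel=1e-12)
        assert f_pvalue(249.667, 1, 13) < 1e-8

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            f_pvalue(1.0, 0, 5)
        with pytest.raises(ValueError):
            f_pvalue(-1.0, 1, 5)


class TestConditionCheck:
    def test_benign_design_passes(self):
        x = np.linspace(1, 100, 15)
        assert condition_check(np.column_stack([np.ones(15), x])).passed

    def test_astronomical_design_fails(self):
        x = np.full(15, 1e50) * np.linspace(0.5, 2.0, 15)
        diag = condition_check(np.column_stack([np.ones(15), x, x * x]))
        assert not diag.passed

    def test_standardisation_rescues_conditioning(self):
        x = np.full(15, 1e50) * np.linspace(0.5, 2.0, 15)
        z = (x - x.mean()) / x.std()
        diag = condition_check(np.column_stack([np.ones(15), z, z * z]))
        assert diag.passed


class TestPredict:
    def test_through_means_prediction(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(20, 100, size=15)
        y = rng.normal(250, 30, size=15)
        res = fit("linear", x, y)
        assert predict(res, x.mean()) == pytest.approx(y.mean(), abs=1e-9)

    def test_printed_equation_evaluation(self):
        # MW = 25.384 + 4.962 * SDD at the thalidomide SDD value
        printed = qspr.FitResult("linear", 15, 25.384, 4.962, None, 0.979, 0.959,
                                 300.379, 0.0, np.zeros(15))
        assert predict(printed, 48.3333) == pytest.approx(265.2, abs=0.05)

    def test_constant_model(self):
        res = qspr.FitResult("quadratic", 15, 7.5, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0,
                             np.zeros(15))
        assert predict(res, 123.0) == 7.5

    def test_logarithmic_rejects_nonpositive_point(self):
        res = qspr.FitResult("logarithmic", 15, 1.0, 2.0, None, 0.9, 0.81, 50.0,
                             1e-5, np.zeros(15))
        with pytest.raises(ValueError):
            predict(res, 0.0)


class TestFitAll:
    def test_all_combinations_present(self, table):
        assert len(table.fits) == 6 * 6 * 3

    def test_exponential_linear_quadratic_degenerate_on_computed(self):
        computed = fit_all("computed")
        for idx in ("EPi1", "EPi2"):
            for family in ("linear", "quadratic"):
                for prop in ("MP", "BP", "D", "WS", "MW", "VP"):
                    assert isinstance(
                        computed.result(idx, prop, family), DegenerateFitError
                    )

    def test_sdd_mw_row(self, table):
        res = table.result("SDD", "MW", "linear")
        assert res.b == pytest.approx(4.962, abs=0.01)
        assert res.r2 == pytest.approx(0.959, abs=0.001)

    def test_frame_layout(self, table):
        frame = table.to_frame("SDD")
        assert list(frame["Family"].unique()) == ["linear", "quadratic", "logarithmic"]
        assert len(frame) == 18

    def test_json_round_trip(self, table):
        import json

        payload = json.loads(table.to_json())
        assert payload["SDD|MW|linear"]["n"] == 15
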