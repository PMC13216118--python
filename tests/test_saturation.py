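import math

import numpy as np
import pytest

from themesat import (
    ModelKind,
    SaturationModel,
    compare,
    emergence_series,
    fit,
    fit_series,
    fit_stats,
    model_eval,
)
from themesat.saturation import prepend_origin


def exp_model(tc):
    return SaturationModel(ModelKind.EXPONENTIAL, {"Tc": tc})


def logistic_model(a, b):
    return SaturationModel(ModelKind.LOGISTIC, {"a": a, "b": b})


class TestModelEval:
    def test_exponential_origin_and_time_constant(self):
        m = exp_model(8.2)
        assert model_eval(m, 0.0) == 0.0
        assert model_eval(m, 8.2) == pytest.approx(100 * (1 - math.exp(-1)))

    def test_logistic_midpoint(self):
        m = logistic_model(9.0, 0.2)
        assert model_eval(m, math.log(9) / 0.2) == pytest.approx(50.0)

    def test_vectorized(self):
        out = model_eval(exp_model(5.0), np.array([0.0, 5.0, 50.0]))
        assert out.shape == (3,)
        assert out[0] == 0.0 and out[2] > 99.99

    def test_negative_t_rejected(self):
        with pytest.raises(ValueError):
            model_eval(exp_model(5.0), -1.0)

    @pytest.mark.parametrize("params", [{"Tc": 0.0}, {"Tc": -3.0}])
    def test_nonpositive_params_rejected(self, params):
        with pytest.raises(ValueError):
            SaturationModel(ModelKind.EXPONENTIAL, params)


class TestFit:
    def test_noiseless_exponential_self_consistency(self):
        x = np.arange(1.0, 11.0)
        y = model_eval(exp_model(10.0), x)
        fr = fit(np.column_stack([x, y]), "exponential")
        assert fr.model.params["Tc"] == pytest.approx(10.0, abs=1e-6)
        assert fr.rmse == pytest.approx(0.0, abs=1e-8)
        assert fr.r2_adj == pytest.approx(1.0, abs=1e-10)

    def test_noiseless_logistic_self_consistency(self):
        x = np.linspace(0.5, 30, 15)
        y = model_eval(logistic_model(20.0, 0.3), x)
        fr = fit(np.column_stack([x, y]), "logistic")
        assert fr.model.params["a"] == pytest.approx(20.0, rel=1e-5)
        assert fr.model.params["b"] == pytest.approx(0.3, rel=1e-5)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        x = np.linspace(1, 40, 19)
        y = np.clip(model_eval(exp_model(9.0), x) + rng.normal(0, 2, x.size), 0, 100)
        tc1 = fit(np.column_stack([x, y]), "exponential").model.params["Tc"]
        c = 3.7
        tc2 = fit(np.column_stack([c * x, y]), "exponential").model.params["Tc"]
        assert tc2 == pytest.approx(c * tc1, rel=1e-8)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            fit([[1.0, 10.0], [2.0, 20.0]], "logistic")

    def test_invalid_y_rejected(self):
        with pytest.raises(ValueError):
            fit([[1.0, 120.0], [2.0, 20.0]], "exponential")

    def test_ci_width_shrinks_with_n(self):
        rng = np.random.default_rng(17)
        widths = []
        for n in (20, 80, 320):
            x = np.linspace(0.5, 40, n)
            y = np.clip(model_eval(exp_model(8.0), x) + rng.normal(0, 3, n), 0, 100)
            fr = fit(np.column_stack([x, y]), "exponential")
            lo, hi = fr.param_ci["Tc"]
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]
        # O(1/sqrt(n)): a 16x larger sample shrinks the width ~4x
        assert widths[0] / widths[2] == pytest.approx(4.0, rel=0.5)


class TestFitStats:
    def test_matches_manual_formulas(self):
        x = np.linspace(1, 30, 12)
        rng = np.random.default_rng(5)
        y = np.clip(model_eval(exp_model(7.0), x) + rng.normal(0, 2, x.size), 0, 100)
        fr = fit(np.column_stack([x, y]), "exponential")
        rss, rmse, r2_adj, aicc = fit_stats(x, y, fr.model)
        res = y - model_eval(fr.model, x)
        assert rss == pytest.approx(res @ res)
        assert rmse == pytest.approx(math.sqrt(rss / 12))
        r2 = 1 - rss / np.sum((y - y.mean()) ** 2)
        assert r2_adj == pytest.approx(1 - (1 - r2) * 11 / 10)
        k = 2
        assert aicc == pytest.approx(12 * math.log(rss / 12) + 2 * k + 2 * k * (k + 1) / (12 - k - 1))

    def test_perfect_fit_flags_aicc_undefined(self):
        x = np.arange(1.0, 9.0)
        y = model_eval(exp_model(4.0), x)
        rss, rmse, r2_adj, aicc = fit_stats(x, y, exp_model(4.0))
        assert rss == pytest.approx(0.0, abs=1e-18)
        assert aicc is None

    def test_constant_y_guard(self):
        x = np.arange(1.0, 9.0)
        y = np.full_like(x, 60.0)
        rss, rmse, r2_adj, _ = fit_stats(x, y, exp_model(4.0))
        assert r2_adj == -math.inf  # no variance to explain, worse than mean model

    def test_aicc_needs_enough_points(self):
        with pytest.raises(ValueError, match="AICc"):
            fit_stats(np.array([1.0, 2.0, 3.0]), np.array([10.0, 20.0, 30.0]), exp_model(4.0))


class TestCompare:
    def test_recovers_logistic_generator(self):
        rng = np.random.default_rng(8)
        x = np.linspace(1, 25, 25)
        y = np.clip(model_eval(logistic_model(20.0, 0.3), x) + rng.normal(0, 1, 25), 0, 100)
        comp = compare(np.column_stack([x, y]))
        assert comp.selected == ModelKind.LOGISTIC
        assert comp.margins["delta_aicc"] > 0

    def test_recovers_exponential_generator(self):
        rng = np.random.default_rng(9)
        x = np.linspace(0.5, 40, 25)
        y = np.clip(model_eval(exp_model(8.0), x) + rng.normal(0, 1, 25), 0, 100)
        pts = prepend_origin(np.column_stack([x, y]))
        assert compare(pts).selected == ModelKind.EXPONENTIAL

    def test_singleton_candidate(self):
        x = np.arange(1.0, 10.0)
        y = model_eval(exp_model(5.0), x) + 0.5
        y = np.clip(y, 0, 100)
        comp = compare(np.column_stack([x, y]), kinds=["exponential"])
        assert comp.selected == ModelKind.EXPONENTIAL
        assert comp.margins["delta_aicc"] == 0.0

    def test_no_candidates_rejected(self):
        with pytest.raises(ValueError):
            compare([[1.0, 10.0], [2.0, 20.0]], kinds=[])


class TestFixtureFits:
    """The reference corpus: exponential time constants and origin anchoring."""

    def test_origin_does_not_move_exponential_tc(self, davinci):
        matrix, window = davinci
        s = emergence_series(matrix, window, "utility", "months")
        with_o = fit_series(s, "exponential", include_origin=True)
        without = fit_series(s, "exponential", include_origin=False)
        assert with_o.model.params["Tc"] == pytest.approx(
            without.model.params["Tc"], rel=1e-6
        )
        assert with_o.n == without.n + 1

    @pytest.mark.parametrize(
        "category,axis,tc",
        [
            ("utility", "months", 8.2),
            ("issue", "months", 16.2),
            ("utility", "publications", 1.3),
            ("issue", "publications", 3.99),
        ],
    )
    def test_time_constants(self, davinci, category, axis, tc):
        matrix, window = davinci
        s = emergence_series(matrix, window, category, axis)
        fr = fit_series(s, "exponential")
        assert fr.model.params["Tc"] == pytest.approx(tc, rel=0.05)
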