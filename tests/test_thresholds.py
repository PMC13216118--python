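import math

import numpy as np
import pytest

from themesat import (
    ModelKind,
    SaturationModel,
    emergence_series,
    fit,
    fit_series,
    invert,
    model_eval,
    threshold_ci,
    threshold_table,
)
from themesat.thresholds import CiMethod, write_threshold_table


def exp_model(tc):
    return SaturationModel(ModelKind.EXPONENTIAL, {"Tc": tc})


def logistic_model(a, b):
    return SaturationModel(ModelKind.LOGISTIC, {"a": a, "b": b})


class TestInvert:
    @pytest.mark.parametrize(
        "model",
        [exp_model(8.2), exp_model(0.3), logistic_model(9.0, 0.2), logistic_model(150.0, 0.05)],
    )
    @pytest.mark.parametrize("target", [1.0, 10.0, 50.0, 80.0, 99.0, 99.9])
    def test_inverse_identity(self, model, target):
        # a logistic curve never takes values below f(0) = 100/(1+a) at
        # t >= 0: such targets are documented to map to 0 with a warning
        if target <= model_eval(model, 0.0):
            with pytest.warns(UserWarning, match="before the origin"):
                assert invert(model, target) == 0.0
            return
        t = invert(model, target)
        assert model_eval(model, t) == pytest.approx(target, abs=1e-9)

    def test_half_life_formula(self):
        assert invert(exp_model(8.2), 50.0) == pytest.approx(8.2 * math.log(2))

    def test_saturation_to_half_ratio_is_universal(self):
        ratio = math.log(1000) / math.log(2)
        for tc in (1.3, 8.2, 16.2, 50.0):
            m = exp_model(tc)
            assert invert(m, 99.9) / invert(m, 50.0) == pytest.approx(ratio, rel=1e-12)

    def test_monotone_in_target(self):
        m = logistic_model(12.0, 0.15)
        vals = [invert(m, t) for t in (20, 40, 60, 80, 99)]
        assert vals == sorted(vals)

    def test_target_bounds_rejected(self):
        with pytest.raises(ValueError):
            invert(exp_model(5.0), 100.0)
        with pytest.raises(ValueError):
            invert(exp_model(5.0), 0.0)

    def test_logistic_target_below_f0_warns_and_returns_zero(self):
        m = logistic_model(1.0, 0.2)  # f(0) = 50%
        with pytest.warns(UserWarning, match="before the origin"):
            assert invert(m, 30.0) == 0.0


class TestThresholdCi:
    def _fixture_fit(self, davinci, category, axis):
        matrix, window = davinci
        return fit_series(emergence_series(matrix, window, category, axis), "exponential")

    def test_transform_maps_tc_interval_endpoints(self, davinci):
        fr = self._fixture_fit(davinci, "utility", "months")
        est = threshold_ci(fr, 50.0, method="transform", axis="months")
        lo_tc, hi_tc = fr.param_ci["Tc"]
        assert est.ci95[0] == pytest.approx(lo_tc * math.log(2))
        assert est.ci95[1] == pytest.approx(hi_tc * math.log(2))
        assert est.ci95[0] < est.estimate < est.ci95[1]

    @pytest.mark.parametrize(
        "tc_ci,expected",
        [((7.4, 9.1), (5.13, 6.31)), ((14.6, 17.7), (10.12, 12.27))],
    )
    def test_transform_against_hand_endpoints(self, tc_ci, expected):
        # direct endpoint transform: Tc_lo*ln2, Tc_hi*ln2
        lo, hi = (v * math.log(2) for v in tc_ci)
        assert (round(lo, 2), round(hi, 2)) == expected

    def test_transform_equals_grid_image_of_interval(self, davinci):
        fr = self._fixture_fit(davinci, "issue", "months")
        est = threshold_ci(fr, 80.0, method="transform")
        lo_tc, hi_tc = fr.param_ci["Tc"]
        grid = np.linspace(lo_tc, hi_tc, 2001)
        image = [-tc * math.log1p(-0.8) for tc in grid]
        assert est.ci95[0] == pytest.approx(min(image), rel=1e-9)
        assert est.ci95[1] == pytest.approx(max(image), rel=1e-9)

    def test_delta_matches_transform_for_exponential(self, davinci):
        # one-parameter linear map: delta and transform coincide exactly
        fr = self._fixture_fit(davinci, "utility", "months")
        t = threshold_ci(fr, 50.0, method="transform")
        d = threshold_ci(fr, 50.0, method="delta")
        assert d.ci95[0] == pytest.approx(t.ci95[0], rel=1e-9)
        assert d.ci95[1] == pytest.approx(t.ci95[1], rel=1e-9)

    def test_bootstrap_agrees_with_transform_on_simulated_data(self):
        rng = np.random.default_rng(12)
        x = np.linspace(1, 40, 30)
        y = np.clip(model_eval(exp_model(9.0), x) + rng.normal(0, 2.0, 30), 0, 100)
        fr = fit(np.column_stack([x, y]), "exponential")
        t = threshold_ci(fr, 80.0, method="transform")
        b = threshold_ci(fr, 80.0, method="bootstrap", n_boot=600, seed=5)
        width_t = t.ci95[1] - t.ci95[0]
        width_b = b.ci95[1] - b.ci95[0]
        assert width_b == pytest.approx(width_t, rel=0.5)
        assert abs((b.ci95[0] + b.ci95[1]) / 2 - t.estimate) < width_t

    def test_transform_rejected_for_logistic(self):
        rng = np.random.default_rng(1)
        x = np.linspace(1, 25, 20)
        y = np.clip(model_eval(logistic_model(20.0, 0.3), x) + rng.normal(0, 1, 20), 0, 100)
        fr = fit(np.column_stack([x, y]), "logistic")
        with pytest.raises(ValueError, match="delta or bootstrap"):
            threshold_ci(fr, 50.0, method="transform")
        d = threshold_ci(fr, 50.0, method="delta")
        assert d.ci95[0] < d.estimate < d.ci95[1]

    def test_degenerate_zero_se_gives_zero_width(self):
        x = np.arange(1.0, 12.0)
        y = model_eval(exp_model(6.0), x)
        fr = fit(np.column_stack([x, y]), "exponential")
        est = threshold_ci(fr, 50.0, method="delta")
        assert est.ci95[0] == pytest.approx(est.estimate, abs=1e-6)
        assert est.ci95[1] == pytest.approx(est.estimate, abs=1e-6)


class TestThresholdTable:
    def test_full_grid(self, davinci):
        matrix, window = davinci
        fits = {
            (cat, ax): fit_series(emergence_series(matrix, window, cat, ax), "exponential")
            for cat in ("utility", "issue")
            for ax in ("months", "publications")
        }
        rows = threshold_table(fits)
        assert len(rows) == 2 * 2 * 3
        util_50 = next(
            r for r in rows
            if r["category"] == "utility" and r["axis"] == "months" and r["target_pct"] == 50.0
        )
        assert util_50["estimate"] == pytest.approx(5.7, abs=0.15)

    def test_empty_targets(self, davinci):
        matrix, window = davinci
        fr = fit_series(emergence_series(matrix, window, "utility", "months"), "exponential")
        assert threshold_table({("utility", "months"): fr}, targets=[]) == []

    def test_csv_export(self, davinci, tmp_path):
        matrix, window = davinci
        fr = fit_series(emergence_series(matrix, window, "issue", "publications"), "exponential")
        rows = threshold_table({("issue", "publications"): fr})
        path = tmp_path / "thresholds.csv"
        write_threshold_table(rows, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "category,axis,target_pct,estimate,ci_low,ci_high,method"
        assert len(lines) == 4
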