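"""Threshold-time estimation: inverting fitted saturation curves.

Given a fitted model of the cumulative occurrence proportion, estimate the
elapsed time (or publication count) at which a target proportion -- by
convention 50%, 80% and 99.9% (the saturation proxy) -- is reached, with a
95% confidence interval.

CI methods
----------
``transform``  (exponential only) maps the Tc interval endpoints through
    the inversion t = -Tc ln(1 - q); exact for a monotone scalar
    reparameterization and the default for the one-parameter model.
``delta``      first-order error propagation through the inversion using
    the fit's parameter covariance; works for both model kinds.
``bootstrap``  residual resampling with refitting, percentile interval;
    seeded, used as a cross-check.
"""

from __future__ import annotations

import csv
import enum
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .emergence import Axis, Category
from .saturation import FitResult, ModelKind, SaturationModel, fit

__all__ = [
    "CiMethod",
    "ThresholdEstimate",
    "invert",
    "threshold_ci",
    "threshold_table",
    "write_threshold_table",
    "DEFAULT_TARGETS",
]

DEFAULT_TARGETS = (50.0, 80.0, 99.9)


class CiMethod(str, enum.Enum):
    TRANSFORM = "transform"
    DELTA = "delta"
    BOOTSTRAP = "bootstrap"


@dataclass(frozen=True)
class ThresholdEstimate:
    target_pct: float
    estimate: float
    ci95: tuple[float, float]
    axis: Axis | None
    method: CiMethod

    def to_dict(self) -> dict:
        return {
            "target_pct": self.target_pct,
            "estimate": self.estimate,
            "ci_low": self.ci95[0],
            "ci_high": self.ci95[1],
            "axis": self.axis.value if self.axis else None,
            "method": self.method.value,
        }


def invert(model: SaturationModel, target_pct: float) -> float:
    """Axis value at which the model reaches ``target_pct`` percent.

    Exponential: t = -Tc ln(1 - q); logistic: t = -(1/b) ln((100/q - 1)/a).
    A logistic target at or below f(0) = 100/(1+a) is reached before the
    origin; 0 is returned with a warning.
    """
    if not 0 < target_pct < 100:
        raise ValueError(f"target_pct must lie in (0, 100), got {target_pct}")
    q = target_pct / 100.0
    if model.kind == ModelKind.EXPONENTIAL:
        return -model.params["Tc"] * math.log1p(-q)
    a, b = model.params["a"], model.params["b"]
    arg = (1.0 / q - 1.0) / a  # (100/target - 1)/a
    if arg >= 1.0:
        warnings.warn(
            f"logistic target {target_pct}% <= f(0) = {100 / (1 + a):.3f}%: "
            "reached before the origin; returning 0",
            stacklevel=2,
        )
        return 0.0
    return -math.log(arg) / b


def _invert_params(kind: ModelKind, theta: np.ndarray, q: float) -> float:
    if kind == ModelKind.EXPONENTIAL:
        return -theta[0] * math.log1p(-q)
    a, b = theta
    return (math.log(a) - math.log(1.0 / q - 1.0)) / b


def _delta_se(fit_result: FitResult, target_pct: float) -> float:
    q = target_pct / 100.0
    cov = np.asarray(fit_result.param_cov, dtype=float)
    if fit_result.model.kind == ModelKind.EXPONENTIAL:
        grad = np.array([-math.log1p(-q)])
    else:
        a, b = fit_result.model.params["a"], fit_result.model.params["b"]
        t = invert(fit_result.model, target_pct)
        grad = np.array([1.0 / (a * b), -t / b])
    return float(np.sqrt(grad @ cov @ grad))


def _bootstrap_ci(
    fit_result: FitResult,
    target_pct: float,
    n_reps: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    if fit_result.x is None or fit_result.y is None:
        raise ValueError("bootstrap requires the fitted points stored on the FitResult")
    x, y = fit_result.x, fit_result.y
    from .saturation import model_eval  # local import avoids cycle at module load

    fitted = model_eval(fit_result.model, x)
    resid = y - fitted
    q = target_pct / 100.0
    kind = fit_result.model.kind
    reps = []
    for _ in range(n_reps):
        y_star = np.clip(fitted + rng.choice(resid, size=len(resid), replace=True), 0.0, 100.0)
        try:
            f_star = fit(np.column_stack([x, y_star]), kind)
        except RuntimeError:
            continue  # rare non-convergence: drop the replicate
        theta = np.array(list(f_star.model.params.values()))
        reps.append(_invert_params(kind, theta, q))
    if len(reps) < max(50, n_reps // 2):
        raise RuntimeError(f"too few bootstrap replicates converged ({len(reps)}/{n_reps})")
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return float(lo), float(hi)


def threshold_ci(
    fit_result: FitResult,
    target_pct: float,
    method: CiMethod | str = CiMethod.TRANSFORM,
    axis: Axis | str | None = None,
    n_boot: int = 2000,
    seed: int | None = 0,
) -> ThresholdEstimate:
    """Threshold estimate with a 95% CI from a fitted model."""
    method = CiMethod(method)
    axis = Axis(axis) if axis is not None else None
    est = invert(fit_result.model, target_pct)
    kind = fit_result.model.kind
    if method == CiMethod.TRANSFORM:
        if kind != ModelKind.EXPONENTIAL:
            raise ValueError(
                "transform CI applies only to the one-parameter exponential model "
                "(monotone scalar reparameterization); use delta or bootstrap for logistic"
            )
        lo_tc, hi_tc = fit_result.param_ci["Tc"]
        factor = -math.log1p(-target_pct / 100.0)
        ci = (max(lo_tc, 0.0) * factor, hi_tc * factor)
    elif method == CiMethod.DELTA:
        from scipy import stats

        se = _delta_se(fit_result, target_pct)
        tq = stats.t.ppf(0.975, max(fit_result.n - fit_result.p, 1))
        ci = (est - tq * se, est + tq * se)
    else:
        rng = np.random.default_rng(seed)
        ci = _bootstrap_ci(fit_result, target_pct, n_boot, rng)
    return ThresholdEstimate(
        target_pct=float(target_pct), estimate=est, ci95=ci, axis=axis, method=method
    )


def threshold_table(
    fits: Mapping[tuple[Category, Axis] | tuple[str, str], FitResult],
    targets: Iterable[float] = DEFAULT_TARGETS,
    method: CiMethod | str = CiMethod.TRANSFORM,
    seed: int | None = 0,
) -> list[dict]:
    """Category x axis x target grid of threshold estimates.

    ``fits`` maps (category, axis) to a fitted model; each requested
    target is inverted for every cell.  Returns a list of flat records
    (category, axis, target_pct, estimate, ci_low, ci_high, method).
    """
    rows = []
    for (cat, ax), fr in fits.items():
        cat, ax = Category(cat), Axis(ax)
        m = CiMethod(method)
        if m == CiMethod.TRANSFORM and fr.model.kind != ModelKind.EXPONENTIAL:
            m = CiMethod.DELTA
        for tgt in targets:
            est = threshold_ci(fr, tgt, method=m, axis=ax, seed=seed)
            rows.append({"category": cat.value, "axis": ax.value, **est.to_dict()})
    return rows


def write_threshold_table(rows: Sequence[dict], path: str | Path) -> None:
    cols = ["category", "axis", "target_pct", "estimate", "ci_low", "ci_high", "method"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols, extrasaction="ignore")
        writer.writeheader()
        for r in rows:
            writer.writerow(r)
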