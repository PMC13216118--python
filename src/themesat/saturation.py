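"""Saturation models for cumulative theme emergence.

Two candidate curves for the cumulative occurrence proportion f(t), both
saturating at 100%:

* exponential plateau  f(t) = 100 (1 - exp(-t / Tc)), one parameter, the
  time constant Tc (f(Tc) ~= 63.2%); passes through the origin exactly;
* logistic             f(t) = 100 / (1 + a exp(-b t)), two parameters;
  f(0) = 100 / (1 + a) > 0.

Fitting is unweighted nonlinear least squares (Levenberg-Marquardt via
:func:`scipy.optimize.curve_fit`); candidates are ranked by small-sample
AICc, with adjusted R-squared and RMSE reported alongside.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .emergence import EmergenceSeries, series_points

__all__ = [
    "ModelKind",
    "SaturationModel",
    "FitResult",
    "ModelComparison",
    "model_eval",
    "fit",
    "fit_series",
    "fit_stats",
    "compare",
    "prepend_origin",
]


class ModelKind(str, enum.Enum):
    EXPONENTIAL = "exponential"
    LOGISTIC = "logistic"


@dataclass(frozen=True)
class SaturationModel:
    """A saturation curve with fixed parameters.

    ``params``: {"Tc": ...} for exponential; {"a": ..., "b": ...} for
    logistic.  All parameters must be strictly positive so the curve is
    increasing and bounded by 100.
    """

    kind: ModelKind
    params: dict[str, float]

    def __post_init__(self) -> None:
        kind = ModelKind(self.kind)
        object.__setattr__(self, "kind", kind)
        expected = ("Tc",) if kind == ModelKind.EXPONENTIAL else ("a", "b")
        if set(self.params) != set(expected):
            raise ValueError(f"{kind.value} model expects params {expected}, got {set(self.params)}")
        for name, v in self.params.items():
            if not v > 0:
                raise ValueError(f"parameter {name} must be > 0, got {v}")

    @property
    def n_params(self) -> int:
        return len(self.params)


def _exp_curve(t: np.ndarray, tc: float) -> np.ndarray:
    return 100.0 * (1.0 - np.exp(-t / tc))


def _logistic_curve(t: np.ndarray, a: float, b: float) -> np.ndarray:
    return 100.0 / (1.0 + a * np.exp(-b * t))


def model_eval(model: SaturationModel, t):
    """Evaluate the model at axis value(s) t >= 0; returns percent."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if model.kind == ModelKind.EXPONENTIAL:
        out = _exp_curve(t, model.params["Tc"])
    else:
        out = _logistic_curve(t, model.params["a"], model.params["b"])
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class FitResult:
    """A fitted saturation model with goodness and selection statistics.

    Standard errors come from the Jacobian-based covariance scaled by
    rss / (n - p); 95% CIs are Wald intervals with Student-t quantiles on
    n - p degrees of freedom.  ``aicc`` uses the Gaussian concentrated
    likelihood (without the 2*pi constant) with k = p + 1 parameters, the
    error variance included; it is None for a numerically perfect fit
    (rss = 0, criterion diverges to -inf).
    """

    model: SaturationModel
    n: int
    p: int
    rss: float
    rmse: float
    r2: float
    r2_adj: float
    aicc: float | None
    param_se: dict[str, float]
    param_ci: dict[str, tuple[float, float]]
    converged: bool = True
    param_cov: np.ndarray = field(repr=False, default=None)
    x: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "kind": self.model.kind.value,
            "params": dict(self.model.params),
            "se": dict(self.param_se),
            "ci95": {k: list(v) for k, v in self.param_ci.items()},
            "n": self.n,
            "p": self.p,
            "rss": self.rss,
            "rmse": self.rmse,
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "aicc": self.aicc,
            "converged": self.converged,
        }


def fit_stats(x: np.ndarray, y: np.ndarray, model: SaturationModel) -> tuple[float, float, float, float | None]:
    """(rss, rmse, r2_adj, aicc) of a model on points (x, y).

    r2_adj = 1 - (1 - R^2)(n - 1)/(n - p - 1) with R^2 measured against
    the mean-only model; zero-variance y yields R^2 <= 0 without error.
    aicc = n ln(rss/n) + 2k + 2k(k+1)/(n-k-1), k = p + 1; undefined (None)
    when rss = 0 and an error when n <= k + 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    p = model.n_params
    res = y - model_eval(model, x)
    rss = float(res @ res)
    rmse = math.sqrt(rss / n)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else -math.inf)
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n - p - 1 > 0 else r2
    k = p + 1
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} points and k={k} parameters")
    aicc = None if rss == 0 else n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)
    return rss, rmse, r2_adj, aicc


def _initial_guess(kind: ModelKind, x: np.ndarray, y: np.ndarray) -> list[float]:
    tc0 = max(x.max() / 3.0, 1e-6)
    if kind == ModelKind.EXPONENTIAL:
        return [tc0]
    y1 = y[np.argmin(x)]
    a0 = max(100.0 / y1 - 1.0, 0.1) if y1 > 0 else 10.0
    return [a0, 1.0 / tc0]


def fit(points, kind: ModelKind | str) -> FitResult:
    """Least-squares fit of one model kind to (x, y) points.

    ``points`` is any (n, 2) array-like of (axis value, proportion %).
    Requires at least p + 1 points.  Parameters are kept positive by a
    bounded trust-region solver; tolerances are tight (1e-12) since the
    problems are 1-2 parameter and smooth.
    """
    kind = ModelKind(kind)
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (x, y)")
    x, y = pts[:, 0], pts[:, 1]
    if np.any(x < 0):
        raise ValueError("x values must be >= 0")
    if np.any((y < 0) | (y > 100)):
        raise ValueError("y values must lie in [0, 100]")
    names = ["Tc"] if kind == ModelKind.EXPONENTIAL else ["a", "b"]
    n, p = len(x), len(names)
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} points to fit {kind.value}, got {n}")
    curve = _exp_curve if kind == ModelKind.EXPONENTIAL else _logistic_curve
    p0 = _initial_guess(kind, x, y)
    try:
        popt, pcov = optimize.curve_fit(
            curve, x, y, p0=p0,
            bounds=(1e-12, np.inf), method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-12, maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"{kind.value} fit did not converge: {exc}") from exc
    model = SaturationModel(kind=kind, params=dict(zip(names, map(float, popt))))
    rss, rmse, r2_adj, aicc = fit_stats(x, y, model)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else -math.inf)
    dof = max(n - p, 1)
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    tq = stats.t.ppf(0.975, dof)
    param_se = dict(zip(names, map(float, se)))
    param_ci = {
        nm: (float(v - tq * s), float(v + tq * s))
        for nm, v, s in zip(names, popt, se)
    }
    return FitResult(
        model=model, n=n, p=p, rss=rss, rmse=rmse, r2=r2, r2_adj=r2_adj,
        aicc=aicc, param_se=param_se, param_ci=param_ci, converged=True,
        param_cov=pcov, x=x, y=y,
    )


def prepend_origin(points) -> np.ndarray:
    """Prepend the (0, 0) anchor -- zero themes observed at the window start."""
    pts = np.asarray(points, dtype=float)
    return np.vstack([[0.0, 0.0], pts])


def fit_series(
    series: EmergenceSeries,
    kind: ModelKind | str,
    include_origin: bool = True,
) -> FitResult:
    """Fit a saturation model to an emergence series.

    By default the (0, 0) anchor is prepended to the article points: at
    the window start no article has been published, so the cumulative
    proportion is zero by construction, and anchoring the fit there lets
    the goodness-of-fit statistics reflect the full trajectory from
    device clearance.  Set ``include_origin=False`` to fit the article
    points alone (Tc is unaffected for the exponential model, which passes
    through the origin analytically; the comparison statistics change).
    """
    pts = series_points(series)
    if include_origin:
        pts = prepend_origin(pts)
    return fit(pts, kind)


@dataclass(frozen=True)
class ModelComparison:
    """Per-kind fits on identical points, ranked by AICc."""

    fits: dict[ModelKind, FitResult]
    selected: ModelKind

    @property
    def margins(self) -> dict[str, float]:
        """Selected-vs-best-rival margins (positive favours selected)."""
        sel = self.fits[self.selected]
        rivals = [f for k, f in self.fits.items() if k != self.selected]
        if not rivals:
            return {"delta_aicc": 0.0, "delta_r2_adj": 0.0, "delta_rmse": 0.0}
        rival = min(rivals, key=_aicc_key)
        return {
            "delta_aicc": _aicc_key(rival) - _aicc_key(sel),
            "delta_r2_adj": sel.r2_adj - rival.r2_adj,
            "delta_rmse": rival.rmse - sel.rmse,
        }

    def to_dict(self) -> dict:
        return {
            "selected": self.selected.value,
            "margins": self.margins,
            "fits": {k.value: f.to_dict() for k, f in self.fits.items()},
        }


def _aicc_key(f: FitResult) -> float:
    return -math.inf if f.aicc is None else f.aicc


def compare(points, kinds=(ModelKind.EXPONENTIAL, ModelKind.LOGISTIC)) -> ModelComparison:
    """Fit every candidate kind on identical points; select minimum AICc.

    A perfect fit (rss = 0, AICc diverging to -inf) outranks any finite
    AICc.  Ties break toward the model with fewer parameters.
    """
    kinds = [ModelKind(k) for k in kinds]
    if not kinds:
        raise ValueError("at least one candidate kind required")
    fits = {k: fit(points, k) for k in kinds}
    selected = min(kinds, key=lambda k: (_aicc_key(fits[k]), fits[k].p))
    return ModelComparison(fits=fits, selected=selected)


def compare_series(
    series: EmergenceSeries,
    kinds=(ModelKind.EXPONENTIAL, ModelKind.LOGISTIC),
    include_origin: bool = True,
) -> ModelComparison:
    """:func:`compare` on a series' points (origin anchor by default)."""
    pts = series_points(series)
    if include_origin:
        pts = prepend_origin(pts)
    return compare(pts, kinds)
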