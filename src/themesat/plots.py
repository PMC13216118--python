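"""Report figures: saturation-fit panels and per-theme cumulative counts."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .corpus import PresenceMatrix, StudyWindow, elapsed_months
from .emergence import Axis, Category, EmergenceSeries, series_points
from .saturation import FitResult, model_eval

__all__ = ["plot_fit_panel", "plot_theme_counts", "fit_report_figure"]


def plot_fit_panel(
    ax: plt.Axes,
    series_fits: dict[Category, tuple[EmergenceSeries, FitResult]],
    axis: Axis,
) -> None:
    """Observed cumulative proportions with fitted curve and Wald CI band."""
    markers = {Category.UTILITY: "o", Category.ISSUE: "s", Category.ALL: "^"}
    for cat, (series, fr) in series_fits.items():
        pts = series_points(series)
        ax.plot(pts[:, 0], pts[:, 1], markers.get(cat, "o"), ms=5, label=f"{cat.value} (observed)")
        grid = np.linspace(0, pts[:, 0].max() * 1.05, 200)
        ax.plot(grid, model_eval(fr.model, grid), "-", lw=1.2,
                label=f"{cat.value} fit ({fr.model.kind.value})")
        if fr.model.kind.value == "exponential":
            lo, hi = fr.param_ci["Tc"]
            if lo > 0:
                band_lo = 100 * (1 - np.exp(-grid / lo))
                band_hi = 100 * (1 - np.exp(-grid / hi))
                ax.fill_between(grid, np.minimum(band_lo, band_hi),
                                np.maximum(band_lo, band_hi), alpha=0.15)
    ax.set_xlabel("months since clearance" if axis == Axis.MONTHS else "publication count")
    ax.set_ylabel("cumulative occurrence proportion (%)")
    ax.set_ylim(0, 105)
    if series_fits:
        ax.legend(fontsize=7)


def plot_theme_counts(
    ax: plt.Axes, matrix: PresenceMatrix, window: StudyWindow, category: Category
) -> None:
    """Per-theme cumulative mention counts over elapsed months (step curves)."""
    from .emergence import _category_columns, _ordered_articles  # shared ordering

    cols = _category_columns(matrix, category)
    ordered = _ordered_articles(matrix)
    t = [elapsed_months(a.resolved_date, window) for _, a in ordered]
    for j in cols:
        counts = np.cumsum([matrix.cells[i, j] for i, _ in ordered])
        ax.step(t, counts, where="post", lw=1.0, label=matrix.themes[j].theme_id)
    ax.set_xlabel("months since clearance")
    ax.set_ylabel("cumulative mentions")
    ax.set_title(category.value)
    ax.legend(fontsize=6, ncol=2)


def fit_report_figure(
    matrix: PresenceMatrix,
    window: StudyWindow,
    months_fits: dict[Category, tuple[EmergenceSeries, FitResult]],
    pubs_fits: dict[Category, tuple[EmergenceSeries, FitResult]],
    path: str | Path,
) -> None:
    """Four-panel figure: two fit panels (months / publications axes) over
    both categories, plus per-theme cumulative mention counts."""
    fig, axes = plt.subplots(2, 2, figsize=(11, 8))
    plot_fit_panel(axes[0, 0], months_fits, Axis.MONTHS)
    plot_fit_panel(axes[0, 1], pubs_fits, Axis.PUBLICATIONS)
    plot_theme_counts(axes[1, 0], matrix, window, Category.UTILITY)
    plot_theme_counts(axes[1, 1], matrix, window, Category.ISSUE)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
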