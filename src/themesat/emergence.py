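"""Cumulative theme-emergence series under the first-occurrence rule.

Articles are ordered by resolved publication date (table-row order breaks
ties).  A theme "occurs" only at the earliest article mentioning it; the
cumulative count of distinct themes observed by article n, normalized by
the final count, gives the cumulative occurrence proportion (%) -- the
outcome variable of the saturation analysis.  Both explanatory axes are
supported: elapsed months since the window anchor, and publication count.
"""

from __future__ import annotations

import csv
import datetime as dt
import enum
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus import (
    ArticleRecord,
    PresenceMatrix,
    StudyWindow,
    ThemeCategory,
    elapsed_months,
)

__all__ = [
    "Axis",
    "Category",
    "EmergenceEvent",
    "EmergenceSeries",
    "first_occurrences",
    "emergence_series",
    "series_points",
    "write_series",
]


class Axis(str, enum.Enum):
    MONTHS = "months"
    PUBLICATIONS = "publications"


class Category(str, enum.Enum):
    UTILITY = "utility"
    ISSUE = "issue"
    ALL = "all"


@dataclass(frozen=True)
class EmergenceEvent:
    """One article's contribution to the cumulative curve."""

    article_index: int
    study_label: str
    date: dt.date
    t_months: float
    pub_count: int
    t_new: int  # themes first appearing at this article
    t_sum: int  # cumulative distinct themes observed
    proportion: float  # percent of t_sum_end


@dataclass(frozen=True)
class EmergenceSeries:
    category: Category
    axis: Axis
    events: tuple[EmergenceEvent, ...]
    t_sum_end: int


def _category_columns(matrix: PresenceMatrix, category: Category | str) -> list[int]:
    category = Category(category)
    if category == Category.ALL:
        return list(range(matrix.n_themes))
    want = ThemeCategory(category.value)
    return [j for j, t in enumerate(matrix.themes) if t.category == want]


def _ordered_articles(matrix: PresenceMatrix) -> list[tuple[int, ArticleRecord]]:
    for a in matrix.articles:
        if a.resolved_date is None:
            raise ValueError(
                f"article {a.article_index} has no resolved date; call resolve_dates first"
            )
    order = sorted(
        range(matrix.n_articles),
        key=lambda i: (matrix.articles[i].resolved_date, matrix.articles[i].article_index),
    )
    return [(i, matrix.articles[i]) for i in order]


def first_occurrences(
    matrix: PresenceMatrix, category: Category | str = Category.ALL
) -> dict[str, tuple[int, dt.date]]:
    """Earliest article per theme: theme_id -> (article_index, date).

    Themes never present anywhere are omitted; ties in date resolve to the
    smaller table-row ordinal.
    """
    cols = _category_columns(matrix, category)
    out: dict[str, tuple[int, dt.date]] = {}
    for row_i, article in _ordered_articles(matrix):
        for j in cols:
            tid = matrix.themes[j].theme_id
            if tid not in out and matrix.cells[row_i, j]:
                out[tid] = (article.article_index, article.resolved_date)
    return out


def emergence_series(
    matrix: PresenceMatrix,
    window: StudyWindow,
    category: Category | str = Category.ALL,
    axis: Axis | str = Axis.MONTHS,
) -> EmergenceSeries:
    """Build the cumulative emergence series for a theme category.

    One event per article in date order -- articles contributing zero new
    themes are retained as flat segments, since each published article is
    an observation on both axes.
    """
    category = Category(category)
    axis = Axis(axis)
    cols = _category_columns(matrix, category)
    ordered = _ordered_articles(matrix)
    seen: set[int] = set()
    events: list[EmergenceEvent] = []
    running = 0
    for pub_count, (row_i, article) in enumerate(ordered, start=1):
        new = [j for j in cols if j not in seen and matrix.cells[row_i, j]]
        seen.update(new)
        running += len(new)
        events.append(
            EmergenceEvent(
                article_index=article.article_index,
                study_label=article.study_label,
                date=article.resolved_date,
                t_months=elapsed_months(article.resolved_date, window),
                pub_count=pub_count,
                t_new=len(new),
                t_sum=running,
                proportion=0.0,  # filled below once t_sum_end is known
            )
        )
    t_sum_end = running
    if t_sum_end == 0:
        raise ValueError(f"no theme of category {category.value!r} is present in the matrix")
    events = [
        EmergenceEvent(
            **{**e.__dict__, "proportion": 100.0 * e.t_sum / t_sum_end}
        )
        for e in events
    ]
    return EmergenceSeries(category=category, axis=axis, events=tuple(events), t_sum_end=t_sum_end)


def series_points(series: EmergenceSeries) -> np.ndarray:
    """(n, 2) array of (x, y): x per the series axis, y = proportion (%)."""
    if series.axis == Axis.MONTHS:
        x = [e.t_months for e in series.events]
    else:
        x = [float(e.pub_count) for e in series.events]
    y = [e.proportion for e in series.events]
    return np.column_stack([x, y])


def write_series(series: EmergenceSeries, path: str | Path) -> None:
    """Export the series as CSV, one row per article event."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["article_index", "study_label", "date", "t_months", "pub_count",
             "t_new", "t_sum", "proportion_pct"]
        )
        for e in series.events:
            writer.writerow(
                [e.article_index, e.study_label, e.date.isoformat(),
                 f"{e.t_months:.6f}", e.pub_count, e.t_new, e.t_sum,
                 f"{e.proportion:.6f}"]
            )
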