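"""Data model for articles, themes and presence matrices.

The fundamental object of the analysis is the binary article x theme
incidence ("presence") matrix: each cell records whether an article's text
addresses a given descriptive theme (a device utility or an operational
issue).  Articles carry publication months; a :class:`StudyWindow` anchors
the elapsed-time axis at the day after the device's regulatory clearance.

The module also embeds the da Vinci early-adoption corpus (19 articles
published 2001-2004, 16 themes) used throughout the package as the
reference dataset.
"""

from __future__ import annotations

import csv
import datetime as dt
import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DAYS_PER_MONTH",
    "ThemeCategory",
    "DayConvention",
    "ThemeDef",
    "ArticleRecord",
    "StudyWindow",
    "PresenceMatrix",
    "load_matrix",
    "write_matrix",
    "davinci_fixture",
    "resolve_dates",
    "elapsed_months",
]

#: Fixed month length (365.25 / 12 days) used for the elapsed-time axis.
#: Calendar-independent, hence reproducible across locales and libraries.
DAYS_PER_MONTH = 30.4375


class ThemeCategory(str, enum.Enum):
    """Whether a theme describes a device utility or an operational issue."""

    UTILITY = "utility"
    ISSUE = "issue"


class DayConvention(str, enum.Enum):
    """How a year/month publication stamp is resolved to a calendar day."""

    FIRST = "first"
    MID = "mid"
    LAST = "last"


@dataclass(frozen=True)
class ThemeDef:
    """A coded theme: short id (e.g. ``T1-1``), label, and category."""

    theme_id: str
    label: str
    category: ThemeCategory

    def __post_init__(self) -> None:
        object.__setattr__(self, "category", ThemeCategory(self.category))


@dataclass(frozen=True)
class ArticleRecord:
    """One corpus article.

    ``article_index`` is the 1-based table-row ordinal and breaks date
    ties, so the publication-count axis is deterministic.
    """

    article_index: int
    study_label: str
    pub_year_month: tuple[int, int]
    resolved_date: dt.date | None = None

    @property
    def year(self) -> int:
        return self.pub_year_month[0]

    @property
    def month(self) -> int:
        return self.pub_year_month[1]


@dataclass(frozen=True)
class StudyWindow:
    """Observation window [anchor_date, end_date].

    The anchor is the day after regulatory clearance; elapsed time is
    measured from it.
    """

    anchor_date: dt.date
    end_date: dt.date

    def __post_init__(self) -> None:
        if self.anchor_date >= self.end_date:
            raise ValueError(
                f"anchor_date {self.anchor_date} must precede end_date {self.end_date}"
            )

    def contains(self, date: dt.date) -> bool:
        return self.anchor_date <= date <= self.end_date


@dataclass
class PresenceMatrix:
    """Binary article x theme incidence with theme categories.

    ``cells`` is an (n_articles, n_themes) uint8 array aligned with the
    ``articles`` and ``themes`` orderings.
    """

    articles: list[ArticleRecord]
    themes: list[ThemeDef]
    cells: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells)
        if self.cells.shape != (len(self.articles), len(self.themes)):
            raise ValueError(
                f"cells shape {self.cells.shape} does not match "
                f"{len(self.articles)} articles x {len(self.themes)} themes"
            )
        bad = ~np.isin(self.cells, (0, 1))
        if bad.any():
            raise ValueError(f"non-binary cell values: {np.unique(self.cells[bad])}")
        self.cells = self.cells.astype(np.uint8)
        ids = [t.theme_id for t in self.themes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate theme ids")

    # -- basic shape/queries -------------------------------------------------

    @property
    def n_articles(self) -> int:
        return len(self.articles)

    @property
    def n_themes(self) -> int:
        return len(self.themes)

    @property
    def n_total(self) -> int:
        """Total cell count N_theme x N_article."""
        return self.n_articles * self.n_themes

    def theme_ids(self, category: ThemeCategory | str | None = None) -> list[str]:
        if category is None:
            return [t.theme_id for t in self.themes]
        category = ThemeCategory(category)
        return [t.theme_id for t in self.themes if t.category == category]

    def column_sums(self, category: ThemeCategory | str | None = None) -> dict[str, int]:
        """Per-theme article counts (the tables' "Count of *" row)."""
        sums = self.cells.sum(axis=0)
        out = {t.theme_id: int(s) for t, s in zip(self.themes, sums)}
        if category is not None:
            keep = set(self.theme_ids(category))
            out = {k: v for k, v in out.items() if k in keep}
        return out

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: one row per article, one 0/1 column per theme."""
        df = pd.DataFrame(
            self.cells,
            columns=[t.theme_id for t in self.themes],
            index=[a.article_index for a in self.articles],
        )
        df.insert(0, "study_label", [a.study_label for a in self.articles])
        df.insert(
            1,
            "pub_year_month",
            [f"{a.year:04d}/{a.month:02d}" for a in self.articles],
        )
        df.index.name = "article_id"
        return df

    def subset(self, category: ThemeCategory | str) -> "PresenceMatrix":
        category = ThemeCategory(category)
        idx = [i for i, t in enumerate(self.themes) if t.category == category]
        return PresenceMatrix(
            articles=list(self.articles),
            themes=[self.themes[i] for i in idx],
            cells=self.cells[:, idx].copy(),
        )


# ---------------------------------------------------------------------------
# Date handling


def _resolve_day(year: int, month: int, convention: DayConvention) -> dt.date:
    if convention == DayConvention.FIRST:
        return dt.date(year, month, 1)
    if convention == DayConvention.MID:
        return dt.date(year, month, 15)
    # last day of month
    nxt = dt.date(year + (month == 12), month % 12 + 1, 1)
    return nxt - dt.timedelta(days=1)


def resolve_dates(
    matrix: PresenceMatrix,
    day_convention: DayConvention | str = DayConvention.MID,
    window: StudyWindow | None = None,
) -> PresenceMatrix:
    """Return a copy with every article's ``resolved_date`` set.

    Only publication months are recorded; the day within the month is
    fixed by convention (default mid-month, day 15 -- unbiased placement).
    If ``window`` is given, a resolved date outside it is an error.
    """
    convention = DayConvention(day_convention)
    articles = []
    for a in matrix.articles:
        d = _resolve_day(a.year, a.month, convention)
        if window is not None and not window.contains(d):
            raise ValueError(
                f"article {a.article_index} ({a.study_label}) resolves to {d}, "
                f"outside window [{window.anchor_date}, {window.end_date}]"
            )
        articles.append(replace(a, resolved_date=d))
    return PresenceMatrix(articles=articles, themes=list(matrix.themes), cells=matrix.cells.copy())


def elapsed_months(date: dt.date, window: StudyWindow) -> float:
    """Months between the window anchor and ``date`` (fixed 30.4375 d/month)."""
    delta = (date - window.anchor_date).days
    if delta < 0:
        raise ValueError(f"{date} precedes window anchor {window.anchor_date}")
    return delta / DAYS_PER_MONTH


# ---------------------------------------------------------------------------
# Readers / writers


def _parse_year_month(text: str) -> tuple[int, int]:
    try:
        y, m = text.strip().split("/")
        ym = (int(y), int(m))
    except ValueError as exc:
        raise ValueError(f"unparseable year-month {text!r} (expected YYYY/MM)") from exc
    if not 1 <= ym[1] <= 12:
        raise ValueError(f"month out of range in {text!r}")
    return ym


def _parse_cell(value: str, where: str) -> int:
    v = value.strip()
    if v not in ("0", "1"):
        raise ValueError(f"non-binary cell value {value!r} at {where}")
    return int(v)


def load_codebook(path: str | Path) -> list[ThemeDef]:
    """Read a JSON codebook: list of {theme_id, label, category}."""
    with open(path) as fh:
        raw = json.load(fh)
    return [ThemeDef(d["theme_id"], d.get("label", d["theme_id"]), d["category"]) for d in raw]


def write_codebook(themes: Sequence[ThemeDef], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            [
                {"theme_id": t.theme_id, "label": t.label, "category": t.category.value}
                for t in themes
            ],
            fh,
            indent=1,
        )


def load_matrix(
    source: str | Path,
    dialect: str = "wide",
    codebook: Sequence[ThemeDef] | None = None,
) -> PresenceMatrix:
    """Load a presence matrix from CSV.

    ``wide``: header ``article_id,study_label,pub_year_month,<theme>,...``,
    one row per article, cells 0/1.  Theme columns not in the codebook are
    rejected when a codebook is supplied; without one, every non-metadata
    column is accepted as a theme (category defaults to utility unless the
    id starts with T4/T5/T6, mirroring the reference taxonomy's split).

    ``long``: header ``article_id,theme_id,present`` triples; pairs absent
    from the file default to 0 (a codebook is required to pin the theme
    set; article metadata defaults are synthesized from the ids).
    """
    source = Path(source)
    if dialect == "wide":
        return _load_wide(source, codebook)
    if dialect == "long":
        return _load_long(source, codebook)
    raise ValueError(f"unknown dialect {dialect!r}")


_META_COLS = ("article_id", "study_label", "pub_year_month")


def _default_category(theme_id: str) -> ThemeCategory:
    return (
        ThemeCategory.ISSUE
        if theme_id.split("-")[0] in ("T4", "T5", "T6")
        else ThemeCategory.UTILITY
    )


def _load_wide(source: Path, codebook: Sequence[ThemeDef] | None) -> PresenceMatrix:
    with open(source, newline="") as fh:
        reader = csv.DictReader(fh)
        fields = reader.fieldnames or []
        theme_cols = [c for c in fields if c not in _META_COLS]
        if codebook is not None:
            known = {t.theme_id: t for t in codebook}
            unknown = [c for c in theme_cols if c not in known]
            if unknown:
                raise ValueError(f"unknown theme columns {unknown} not in codebook")
            themes = [known[c] for c in theme_cols]
        else:
            themes = [ThemeDef(c, c, _default_category(c)) for c in theme_cols]
        articles, rows = [], []
        seen_ids: set[int] = set()
        for row in reader:
            aid = int(row["article_id"])
            if aid in seen_ids:
                raise ValueError(f"duplicate article_id {aid}")
            seen_ids.add(aid)
            articles.append(
                ArticleRecord(
                    article_index=aid,
                    study_label=row.get("study_label", f"article{aid}"),
                    pub_year_month=_parse_year_month(row["pub_year_month"]),
                )
            )
            rows.append(
                [_parse_cell(row[c], f"(article {aid}, {c})") for c in theme_cols]
            )
    return PresenceMatrix(articles=articles, themes=themes, cells=np.array(rows, dtype=np.uint8))


def _load_long(source: Path, codebook: Sequence[ThemeDef] | None) -> PresenceMatrix:
    if codebook is None:
        raise ValueError("long dialect requires a codebook to fix the theme set")
    themes = list(codebook)
    theme_pos = {t.theme_id: j for j, t in enumerate(themes)}
    entries: dict[tuple[int, str], int] = {}
    with open(source, newline="") as fh:
        for row in csv.DictReader(fh):
            aid = int(row["article_id"])
            tid = row["theme_id"].strip()
            if tid not in theme_pos:
                raise ValueError(f"unknown theme_id {tid!r} not in codebook")
            key = (aid, tid)
            if key in entries:
                raise ValueError(f"duplicate (article, theme) pair {key}")
            entries[key] = _parse_cell(row["present"], str(key))
    article_ids = sorted({aid for aid, _ in entries})
    articles = [
        ArticleRecord(article_index=aid, study_label=f"article{aid}", pub_year_month=(1900, 1))
        for aid in article_ids
    ]
    cells = np.zeros((len(articles), len(themes)), dtype=np.uint8)
    row_pos = {aid: i for i, aid in enumerate(article_ids)}
    for (aid, tid), v in entries.items():
        cells[row_pos[aid], theme_pos[tid]] = v
    return PresenceMatrix(articles=articles, themes=themes, cells=cells)


def write_matrix(matrix: PresenceMatrix, path: str | Path, dialect: str = "wide") -> None:
    """Write a presence matrix as CSV in the wide or long dialect."""
    path = Path(path)
    if dialect == "wide":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(list(_META_COLS) + [t.theme_id for t in matrix.themes])
            for a, row in zip(matrix.articles, matrix.cells):
                writer.writerow(
                    [a.article_index, a.study_label, f"{a.year:04d}/{a.month:02d}"]
                    + [int(v) for v in row]
                )
    elif dialect == "long":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["article_id", "theme_id", "present"])
            for a, row in zip(matrix.articles, matrix.cells):
                for t, v in zip(matrix.themes, row):
                    writer.writerow([a.article_index, t.theme_id, int(v)])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Embedded da Vinci early-adoption corpus
#
# 19 articles (2001/05 - 2004/09) x 16 themes (7 utilities, 9 issues).
# Per-theme article sets follow the published per-theme study lists, which
# are self-consistent with the printed per-theme counts; the observation
# window runs from the day after FDA clearance to the day before the first
# in-scope RCT's publication.

_FIXTURE_ARTICLES: list[tuple[str, str]] = [
    ("Mohr2001", "2001/05"),
    ("Rassweiler2001", "2001/07"),
    ("Pasticier2001", "2001/07"),
    ("Ruurda2002", "2002/02"),
    ("Horgan2002", "2002/02"),
    ("Melfi2002", "2002/05"),
    ("Gutt2002", "2002/07"),
    ("Gettman2002", "2002/09"),
    ("Ruurda2003", "2003/02"),
    ("Giulianotti2003", "2003/07"),
    ("Bentas2003", "2003/08"),
    ("Talamini2003", "2003/08"),
    ("Muhlmann2003", "2003/12"),
    ("Munz2004", "2004/01"),
    ("Desgranges2004", "2004/05"),
    ("Bodner2004-1", "2004/05"),
    ("Bodner2004-2", "2004/07"),
    ("Newlin2004", "2004/07"),
    ("Ayav2004", "2004/09"),
]

_FIXTURE_THEMES: list[tuple[str, str, ThemeCategory]] = [
    ("T1-1", "Dexterity - tasks enabled by instrument dexterity", ThemeCategory.UTILITY),
    ("T1-2", "Precision - motion scaling and tremor filtering", ThemeCategory.UTILITY),
    ("T2-1", "Depth perception with stereoscopic vision", ThemeCategory.UTILITY),
    ("T2-2", "Surgeon-controlled viewpoint", ThemeCategory.UTILITY),
    ("T3-1", "Improved hand-eye coordination", ThemeCategory.UTILITY),
    ("T3-2", "Reduced physical strain; neutral posture", ThemeCategory.UTILITY),
    ("T3-3", "Indexing function", ThemeCategory.UTILITY),
    ("T4-1", "Loss of haptic feedback", ThemeCategory.ISSUE),
    ("T4-2", "Instrument limitations", ThemeCategory.ISSUE),
    ("T4-3", "Device failures", ThemeCategory.ISSUE),
    ("T4-4", "Control stability", ThemeCategory.ISSUE),
    ("T5-1", "Cumbersome setup pre- and intraoperatively", ThemeCategory.ISSUE),
    ("T5-2", "Collisions with bulky arms", ThemeCategory.ISSUE),
    ("T5-3", "Disrupted coordination with assistants", ThemeCategory.ISSUE),
    ("T5-4", "Other workflow constraints", ThemeCategory.ISSUE),
    ("T6-1", "High costs", ThemeCategory.ISSUE),
]

# theme_id -> 1-based article indices addressing the theme
_FIXTURE_PRESENT: Mapping[str, Iterable[int]] = {
    "T1-1": (1, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 16, 17, 18, 19),
    "T1-2": (1, 4, 5, 6, 8, 18, 19),
    "T2-1": (1, 4, 5, 7, 8, 11, 12, 13, 16, 17, 18, 19),
    "T2-2": (7, 18),
    "T3-1": (1, 4, 7, 11, 15),
    "T3-2": (3, 12, 13, 15, 19),
    "T3-3": (1, 6, 7),
    "T4-1": (1, 2, 3, 4, 6, 7, 8, 10, 11, 12, 13, 15, 16, 17, 18, 19),
    "T4-2": (3, 4, 6, 8, 9, 10, 11, 13, 16),
    "T4-3": (4, 11, 12, 19),
    "T4-4": (1,),
    "T5-1": (6, 7, 9, 10, 12, 13, 14, 15, 16, 17, 18, 19),
    "T5-2": (1, 4, 8, 10, 15, 19),
    "T5-3": (15, 17),
    "T5-4": (8, 12, 14, 16, 17, 19),
    "T6-1": (2, 7, 8, 13, 15, 19),
}

FIXTURE_WINDOW = StudyWindow(dt.date(2000, 7, 12), dt.date(2004, 10, 24))


def davinci_fixture() -> tuple[PresenceMatrix, StudyWindow]:
    """The embedded da Vinci early-adoption corpus (19 articles x 16 themes)."""
    articles = [
        ArticleRecord(
            article_index=i + 1,
            study_label=label,
            pub_year_month=_parse_year_month(ym),
        )
        for i, (label, ym) in enumerate(_FIXTURE_ARTICLES)
    ]
    themes = [ThemeDef(tid, label, cat) for tid, label, cat in _FIXTURE_THEMES]
    cells = np.zeros((len(articles), len(themes)), dtype=np.uint8)
    for j, t in enumerate(themes):
        for aid in _FIXTURE_PRESENT[t.theme_id]:
            cells[aid - 1, j] = 1
    return PresenceMatrix(articles=articles, themes=themes, cells=cells), FIXTURE_WINDOW
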