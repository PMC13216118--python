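"""Inter-rater reliability of binary theme coding.

Two analysts independently fill the same article x theme presence matrix;
reliability is assessed on the pooled cells with the raw agreement rate
and Cohen's kappa (chance-corrected via each coder's marginal
present/absent frequencies), interpreted on the Landis-Koch scale.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, asdict

import numpy as np

from .corpus import PresenceMatrix

__all__ = [
    "KappaBand",
    "AgreementResult",
    "agreement_rate",
    "cohens_kappa",
    "interpret_kappa",
    "per_theme_kappa",
]

#: Observed-agreement threshold below which coders revisit theme definitions.
RATE_THRESHOLD = 0.90
#: Kappa threshold for acceptable matrix-level reliability.
KAPPA_THRESHOLD = 0.80


class KappaBand(str, enum.Enum):
    POOR = "poor"
    SLIGHT = "slight"
    FAIR = "fair"
    MODERATE = "moderate"
    SUBSTANTIAL = "substantial"
    ALMOST_PERFECT = "almost_perfect"
    UNDEFINED = "undefined"


@dataclass(frozen=True)
class AgreementResult:
    """Cell counts, p_o, p_e, kappa, interpretation and threshold verdicts."""

    n_total: int
    n_agree: int
    p_o: float
    p_e: float
    kappa: float | None
    band: KappaBand
    pass_rate_threshold: bool
    pass_kappa_threshold: bool

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band"] = self.band.value
        return d


def _aligned_cells(coder_a: PresenceMatrix, coder_b: PresenceMatrix) -> tuple[np.ndarray, np.ndarray]:
    if coder_a.cells.shape != coder_b.cells.shape:
        raise ValueError(
            f"matrix shapes differ: {coder_a.cells.shape} vs {coder_b.cells.shape}"
        )
    ids_a = [t.theme_id for t in coder_a.themes]
    ids_b = [t.theme_id for t in coder_b.themes]
    if ids_a != ids_b:
        raise ValueError(f"theme orderings differ: {ids_a} vs {ids_b}")
    aidx_a = [a.article_index for a in coder_a.articles]
    aidx_b = [a.article_index for a in coder_b.articles]
    if aidx_a != aidx_b:
        raise ValueError("article orderings differ")
    return coder_a.cells.ravel(), coder_b.cells.ravel()


def agreement_rate(coder_a: PresenceMatrix, coder_b: PresenceMatrix) -> float:
    """Fraction of pooled cells on which the two coders agree."""
    a, b = _aligned_cells(coder_a, coder_b)
    return float(np.mean(a == b))


def interpret_kappa(kappa: float) -> KappaBand:
    """Landis-Koch band for a kappa value.

    Printed band boundaries (0.00-0.20, 0.21-0.40, ...) leave gaps between
    two-decimal bounds; bands are implemented as half-open intervals on the
    upper bound so every value in [-1, 1] maps to exactly one band while
    each printed boundary keeps its printed membership.
    """
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa {kappa} outside [-1, 1]")
    if kappa < 0.0:
        return KappaBand.POOR
    if kappa < 0.21:
        return KappaBand.SLIGHT
    if kappa < 0.41:
        return KappaBand.FAIR
    if kappa < 0.61:
        return KappaBand.MODERATE
    if kappa < 0.81:
        return KappaBand.SUBSTANTIAL
    return KappaBand.ALMOST_PERFECT


def _kappa_from_cells(a: np.ndarray, b: np.ndarray) -> AgreementResult:
    n = a.size
    n_agree = int(np.sum(a == b))
    p_o = n_agree / n
    pa1 = float(np.mean(a))
    pb1 = float(np.mean(b))
    p_e = pa1 * pb1 + (1 - pa1) * (1 - pb1)
    if math.isclose(p_e, 1.0):
        # both coders used a single category: kappa is 0/0
        kappa: float | None = None
        band = KappaBand.UNDEFINED
        pass_kappa = False
    else:
        kappa = (p_o - p_e) / (1 - p_e)
        band = interpret_kappa(kappa)
        pass_kappa = kappa >= KAPPA_THRESHOLD
    return AgreementResult(
        n_total=n,
        n_agree=n_agree,
        p_o=p_o,
        p_e=p_e,
        kappa=kappa,
        band=band,
        pass_rate_threshold=p_o > RATE_THRESHOLD,
        pass_kappa_threshold=pass_kappa,
    )


def cohens_kappa(coder_a: PresenceMatrix, coder_b: PresenceMatrix) -> AgreementResult:
    """Cohen's kappa on the pooled cells of two same-shape matrices.

    Expected chance agreement uses each coder's own marginal frequencies:
    p_e = pA(1) pB(1) + pA(0) pB(0).  When both coders used only one
    category p_e = 1 and kappa is reported as undefined rather than being
    silently substituted.
    """
    a, b = _aligned_cells(coder_a, coder_b)
    return _kappa_from_cells(a, b)


def per_theme_kappa(coder_a: PresenceMatrix, coder_b: PresenceMatrix) -> dict[str, AgreementResult]:
    """Column-wise kappa, one result per theme (supplementary diagnostic).

    The headline statistic is the pooled matrix-level kappa; per-theme
    values are noisier (n = n_articles each) but localize disagreement.
    """
    _aligned_cells(coder_a, coder_b)  # validates alignment
    return {
        t.theme_id: _kappa_from_cells(coder_a.cells[:, j], coder_b.cells[:, j])
        for j, t in enumerate(coder_a.themes)
    }
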