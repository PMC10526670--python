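"""ISH/IHC composite scoring, grade banding, and Youden-index cutoff.

Staining intensity is scored 0-3 and the proportion of positive cells is
banded into categories 0-4; the composite score is their product (0-12).
Composite 0 is negative, 1-4 weak, 5-8 moderate, 9-12 strong; 0-4 forms the
low-expression group and 5-12 the high-expression group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "IshSpecimen",
    "IshGrade",
    "proportion_category",
    "composite_score",
    "grade",
    "youden_cutoff",
    "ATTAINABLE_SCORES",
]

#: every product of intensity {0..3} x proportion category {0..4}
ATTAINABLE_SCORES = sorted({i * c for i in range(4) for c in range(5)})

_BANDS = (
    (0, 0, "negative"),
    (1, 4, "weak"),
    (5, 8, "moderate"),
    (9, 12, "strong"),
)
HIGH_GROUP_MIN = 5  # composite 0-4 -> low, 5-12 -> high


@dataclass
class IshSpecimen:
    id: str
    intensity: int  # 0-3
    proportion_pct: float  # [0, 100] % positive cells
    outcome_5y: Optional[int] = None  # 1 died within horizon, 0 alive
    time: Optional[float] = None
    event: Optional[int] = None

    def __post_init__(self) -> None:
        if self.intensity not in (0, 1, 2, 3):
            raise ValueError(f"specimen {self.id!r}: intensity must be 0-3")
        if not 0 <= self.proportion_pct <= 100:
            raise ValueError(f"specimen {self.id!r}: proportion outside [0, 100]")

    @property
    def composite(self) -> int:
        return composite_score(self.intensity, self.proportion_pct)


@dataclass(frozen=True)
class IshGrade:
    composite: int
    band: str  # negative | weak | moderate | strong
    group: str  # low | high


def proportion_category(pct: float) -> int:
    """Positive-cell proportion band: 0 iff 0%; 1 for (0,10]; 2 for (10,50];
    3 for (50,75]; 4 for (75,100]."""
    if not (0 <= pct <= 100):
        raise ValueError(f"proportion {pct} outside [0, 100]")
    if pct == 0:
        return 0
    if pct <= 10:
        return 1
    if pct <= 50:
        return 2
    if pct <= 75:
        return 3
    return 4


def composite_score(intensity: int, pct: float) -> int:
    """Intensity (0-3) multiplied by the proportion category (0-4)."""
    if intensity not in (0, 1, 2, 3):
        raise ValueError(f"intensity must be an integer in 0-3, got {intensity!r}")
    return intensity * proportion_category(pct)


def grade(composite: int) -> IshGrade:
    """Band and low/high group assignment for a composite score."""
    if not isinstance(composite, (int, np.integer)) or not 0 <= composite <= 12:
        raise ValueError(f"composite score must be an integer in 0-12, got {composite!r}")
    band = next(name for lo, hi, name in _BANDS if lo <= composite <= hi)
    group = "high" if composite >= HIGH_GROUP_MIN else "low"
    return IshGrade(composite=int(composite), band=band, group=group)


def youden_cutoff(
    scores: Sequence[float],
    outcomes: Sequence[int],
    candidates: Optional[Sequence[float]] = None,
) -> Tuple[float, float]:
    """Youden-optimal positivity threshold.

    For each candidate cutoff c (default the composite-score grid 1..12),
    classify high iff score >= c against outcome == 1 and compute
    J(c) = sensitivity + specificity - 1.  Returns the argmax (smallest c on
    ties) and the maximal J.
    """
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=int)
    if scores.shape != outcomes.shape:
        raise ValueError("scores and outcomes must have equal length")
    if scores.size == 0:
        raise ValueError("empty input")
    if set(np.unique(outcomes)) - {0, 1}:
        raise ValueError("outcomes must be binary 0/1")
    n_pos = int((outcomes == 1).sum())
    n_neg = int((outcomes == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    if candidates is None:
        candidates = range(1, 13)
    best_c, best_j = None, -math.inf
    for c in candidates:
        pred_high = scores >= c
        sens = float((pred_high & (outcomes == 1)).sum()) / n_pos
        spec = float((~pred_high & (outcomes == 0)).sum()) / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_c, best_j = c, j
    if best_c is None:
        raise ValueError("no candidate thresholds")
    return best_c, best_j
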