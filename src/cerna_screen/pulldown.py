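"""Pull-down miRNA tag libraries: TPA normalization and enrichment ranking."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Set

__all__ = [
    "TagLibrary",
    "EnrichmentRecord",
    "tpa_normalize",
    "enrichment_scores",
    "select_enriched",
    "top_k",
]

TPA_SCALE = 1_000_000.0


@dataclass
class TagLibrary:
    """Raw miRNA tag counts for one sequencing library.

    ``total_aligned`` is derived from the counts; the raw tag count of each
    mature miRNA is its raw expression level.
    """

    cell_line: str
    probe: str  # "pulldown" | "control"
    counts: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.probe not in ("pulldown", "control"):
            raise ValueError(f"probe must be 'pulldown' or 'control', got {self.probe!r}")
        for mid, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative tag count for {mid!r}: {c}")

    @property
    def total_aligned(self) -> int:
        return int(sum(self.counts.values()))

    def mirnas(self) -> Set[str]:
        return set(self.counts)


@dataclass(frozen=True)
class EnrichmentRecord:
    mirna: str
    tpa_pulldown: float
    tpa_control: float
    log2_enrichment: float
    rank: int


def tpa_normalize(lib: TagLibrary) -> Dict[str, float]:
    """Tags-per-million-aligned: counts scaled so the library sums to 1e6."""
    if not lib.counts:
        raise ValueError("empty tag library")
    total = lib.total_aligned
    if total <= 0:
        raise ValueError("library has zero aligned tags")
    return {m: c / total * TPA_SCALE for m, c in lib.counts.items()}


def enrichment_scores(
    pulldown: TagLibrary,
    control: TagLibrary,
    pseudocount: float = 1.0,
) -> List[EnrichmentRecord]:
    """Per-miRNA log2 TPA enrichment of pull-down over control, ranked.

    log2_enrichment(m) = log2((TPA_pd(m) + pc) / (TPA_ctrl(m) + pc)).
    Ranking: log2_enrichment desc, then tpa_pulldown desc, then id asc.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    universe_pd, universe_ctrl = pulldown.mirnas(), control.mirnas()
    if universe_pd != universe_ctrl:
        diff = sorted(universe_pd ^ universe_ctrl)
        raise ValueError(f"miRNA universes differ; symmetric difference: {diff}")
    tpa_pd = tpa_normalize(pulldown)
    tpa_ctrl = tpa_normalize(control)
    rows = []
    for m in universe_pd:
        score = math.log2((tpa_pd[m] + pseudocount) / (tpa_ctrl[m] + pseudocount))
        rows.append((m, tpa_pd[m], tpa_ctrl[m], score))
    rows.sort(key=lambda r: (-r[3], -r[1], r[0]))
    return [
        EnrichmentRecord(m, pd, ct, score, rank)
        for rank, (m, pd, ct, score) in enumerate(rows, start=1)
    ]


def select_enriched(
    records: Sequence[EnrichmentRecord],
    min_log2: float = 1.0,
    min_tpa: float = 10.0,
) -> Set[str]:
    """miRNAs passing both the fold and the pull-down abundance threshold."""
    if not (math.isfinite(min_log2) and math.isfinite(min_tpa)):
        raise ValueError("thresholds must be finite")
    return {
        r.mirna
        for r in records
        if r.log2_enrichment >= min_log2 and r.tpa_pulldown >= min_tpa
    }


def top_k(records: Sequence[EnrichmentRecord], k: int) -> List[str]:
    """Ids of the k most enriched miRNAs under the deterministic rank order."""
    if k < 0:
        raise ValueError("k must be >= 0")
    ordered = sorted(
        records, key=lambda r: (-r.log2_enrichment, -r.tpa_pulldown, r.mirna)
    )
    return [r.mirna for r in ordered[:k]]
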