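"""RPKM quantification and the |log2FC| / p-value DEG filter.

The differential test is deliberately simple: an exact two-sided binomial
test of pooled case counts against the library-depth expectation for
unreplicated designs, or a Welch t-test on log2(RPKM + 1) when replicates
exist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "CountMatrix",
    "DegRecord",
    "rpkm_matrix",
    "log2_fold_change",
    "de_test",
    "deg_table",
    "filter_degs",
]


@dataclass
class CountMatrix:
    """Gene x sample read counts with per-gene lengths and sample conditions."""

    gene_ids: List[str]
    lengths: np.ndarray  # nucleotides, > 0
    samples: List[str]
    counts: np.ndarray  # shape (n_genes, n_samples), non-negative ints
    condition: List[str]  # "case" | "control" per sample

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.counts = np.asarray(self.counts)
        n_genes, n_samples = len(self.gene_ids), len(self.samples)
        if self.lengths.shape != (n_genes,):
            raise ValueError("lengths must align with gene_ids")
        if self.counts.shape != (n_genes, n_samples):
            raise ValueError(
                f"counts shape {self.counts.shape} != ({n_genes}, {n_samples})"
            )
        if len(self.condition) != n_samples:
            raise ValueError("condition must align with samples")
        if np.any(self.lengths <= 0):
            raise ValueError("gene lengths must be > 0")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        bad = set(self.condition) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def columns(self, condition: str) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.condition) if c == condition])


@dataclass(frozen=True)
class DegRecord:
    gene: str
    log2fc: float
    p_value: float
    direction: str  # "up" | "down" | "ns"


def rpkm_matrix(cm: CountMatrix) -> np.ndarray:
    """RPKM(g, s) = 1e9 * counts(g, s) / (total(s) * length(g))."""
    totals = cm.counts.sum(axis=0).astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"zero-depth sample(s): {[cm.samples[i] for i in zero]}")
    return 1e9 * cm.counts / (totals[None, :] * cm.lengths[:, None])


def log2_fold_change(
    case_rpkm: np.ndarray, ctrl_rpkm: np.ndarray, pseudocount: float = 1.0
) -> np.ndarray:
    """log2((mean_case + pc) / (mean_ctrl + pc)) per gene."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    case_mean = np.asarray(case_rpkm, dtype=float)
    ctrl_mean = np.asarray(ctrl_rpkm, dtype=float)
    if case_mean.ndim == 2:
        case_mean = case_mean.mean(axis=1)
    if ctrl_mean.ndim == 2:
        ctrl_mean = ctrl_mean.mean(axis=1)
    return np.log2((case_mean + pseudocount) / (ctrl_mean + pseudocount))


def de_test(cm: CountMatrix, gene: str, mode: str = "exact_unreplicated") -> float:
    """Two-sided differential-expression p-value for one gene.

    exact_unreplicated: exact binomial test of the gene's pooled case count
    among its pooled total, against p = pooled case depth / pooled depth.
    welch_replicated: unequal-variance t-test on log2(RPKM + 1).
    """
    gi = cm.gene_index(gene)
    case_cols, ctrl_cols = cm.columns("case"), cm.columns("control")
    if case_cols.size == 0 or ctrl_cols.size == 0:
        raise ValueError("need at least one sample per condition")
    if mode == "exact_unreplicated":
        depth_case = float(cm.counts[:, case_cols].sum())
        depth_ctrl = float(cm.counts[:, ctrl_cols].sum())
        k = int(cm.counts[gi, case_cols].sum())
        n = k + int(cm.counts[gi, ctrl_cols].sum())
        if n == 0:
            return 1.0
        p_null = depth_case / (depth_case + depth_ctrl)
        return float(stats.binomtest(k, n, p_null, alternative="two-sided").pvalue)
    if mode == "welch_replicated":
        if case_cols.size < 2 or ctrl_cols.size < 2:
            raise ValueError("welch_replicated requires >= 2 replicates per condition")
        rpkm = np.log2(rpkm_matrix(cm) + 1.0)
        res = stats.ttest_ind(
            rpkm[gi, case_cols], rpkm[gi, ctrl_cols], equal_var=False
        )
        p = float(res.pvalue)
        return 1.0 if math.isnan(p) else p
    raise ValueError(f"unknown mode {mode!r}")


def deg_table(
    cm: CountMatrix,
    mode: str = "exact_unreplicated",
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> List[DegRecord]:
    """Per-gene fold change, p-value and up/down/ns call for a count matrix."""
    rpkm = rpkm_matrix(cm)
    case_cols, ctrl_cols = cm.columns("case"), cm.columns("control")
    lfc = log2_fold_change(rpkm[:, case_cols], rpkm[:, ctrl_cols], pseudocount)
    if mode == "welch_replicated":
        if case_cols.size < 2 or ctrl_cols.size < 2:
            raise ValueError("welch_replicated requires >= 2 replicates per condition")
        log_rpkm = np.log2(rpkm + 1.0)
        res = stats.ttest_ind(
            log_rpkm[:, case_cols], log_rpkm[:, ctrl_cols], axis=1, equal_var=False
        )
        pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    else:
        pvals = np.array([de_test(cm, g, mode=mode) for g in cm.gene_ids])
    out = []
    for gi, gene in enumerate(cm.gene_ids):
        p = float(pvals[gi])
        if lfc[gi] > lfc_threshold and p < alpha:
            direction = "up"
        elif lfc[gi] < -lfc_threshold and p < alpha:
            direction = "down"
        else:
            direction = "ns"
        out.append(DegRecord(gene, float(lfc[gi]), p, direction))
    return out


def filter_degs(
    records: Sequence[DegRecord],
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> Tuple[Set[str], Set[str]]:
    """Partition genes into (up, down) at |log2FC| > threshold and p < alpha."""
    if not (math.isfinite(lfc_threshold) and math.isfinite(alpha)):
        raise ValueError("thresholds must be finite")
    up = {r.gene for r in records if r.log2fc > lfc_threshold and r.p_value < alpha}
    down = {r.gene for r in records if r.log2fc < -lfc_threshold and r.p_value < alpha}
    return up, down
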