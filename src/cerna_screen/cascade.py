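"""The multi-stage screening cascade and the core-anchored ceRNA network.

Stage order: per-line enrichment selection -> common set -> per-line top-k
union/intersection -> seed-match target prediction -> overlap with
upregulated DEGs -> prognostic filter -> core-miRNA restriction -> Spearman
ranking against the core gene -> (miRNA, gene) core axis.  Every stage logs
its cardinality; an empty stage empties everything downstream but never
crashes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .diffexpr import CountMatrix, deg_table, filter_degs
from .pulldown import TagLibrary, enrichment_scores, select_enriched, top_k
from .seed_targets import (
    MatureMiRNA,
    SeedSite,
    TargetMap,
    UtrSequence,
    class_rank,
    find_seed_sites,
    predict_targets,
)
from .survival import (
    SubjectRecord,
    dichotomize,
    km_estimate,
    logrank_test,
    spearman_rho,
    survival_at,
)

logger = logging.getLogger("cerna_screen.cascade")

__all__ = [
    "CascadeConfig",
    "CascadeReport",
    "CeRNANetwork",
    "merge_topk",
    "prognostic_filter",
    "rank_core_axis",
    "run_screen",
    "export_network",
    "read_network",
]


@dataclass(frozen=True)
class CascadeConfig:
    k_top: int = 10
    lfc_threshold: float = 1.0
    alpha: float = 0.05
    min_log2_enrichment: float = 1.0
    min_tpa: float = 10.0
    min_site_class: str = "7mer-A1"
    combine_mode: str = "union"
    split_method: str = "median"
    horizon_months: float = 60.0
    de_mode: str = "auto"  # auto | exact_unreplicated | welch_replicated
    candidate_pool: str = "topk_union"  # or "common"
    pseudocount_tpa: float = 1.0

    def __post_init__(self) -> None:
        if self.k_top < 1:
            raise ValueError("k_top must be >= 1")
        class_rank(self.min_site_class)  # validates


@dataclass
class CascadeReport:
    """Per-stage cardinalities of one cascade run."""

    n_enriched: Dict[str, int] = field(default_factory=dict)
    n_common: int = 0
    top_union: List[str] = field(default_factory=list)
    core_mirnas: List[str] = field(default_factory=list)
    n_up: int = 0
    n_down: int = 0
    n_degs_total: int = 0
    n_targets: int = 0
    n_target_up_overlap: int = 0
    n_prognostic: int = 0
    final_genes: List[str] = field(default_factory=list)
    core_axis: Optional[Tuple[str, str]] = None


@dataclass
class CeRNANetwork:
    """Bipartite-ish network anchored at the core 3'-UTR node."""

    core: str
    mirna_nodes: List[str] = field(default_factory=list)
    gene_nodes: List[str] = field(default_factory=list)
    core_edges: Dict[str, List[SeedSite]] = field(default_factory=dict)
    target_edges: Dict[Tuple[str, str], List[SeedSite]] = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return len(self.core_edges) + len(self.target_edges)


def merge_topk(a: Sequence[str], b: Sequence[str]) -> Tuple[Set[str], Set[str]]:
    """Union and intersection of two ranked top-k id lists."""
    sa, sb = set(a), set(b)
    return sa | sb, sa & sb


def prognostic_filter(
    genes: Set[str],
    cohort: Sequence[SubjectRecord],
    cfg: CascadeConfig,
) -> Set[str]:
    """Keep genes whose high-expression group fares significantly worse.

    A gene survives iff the low/high log-rank p < alpha AND the high group's
    Kaplan-Meier survival at the horizon is below the low group's.
    """
    kept: Set[str] = set()
    for gene in sorted(genes):
        values = []
        for r in cohort:
            if gene not in r.expr:
                raise KeyError(f"cohort is missing expression for gene {gene!r}")
            values.append(r.expr[gene])
        try:
            labels = dichotomize(values, method=cfg.split_method)
        except ValueError:
            logger.warning("gene %s: cannot dichotomize, dropped", gene)
            continue
        low = [r for r, g in zip(cohort, labels) if g == "low"]
        high = [r for r, g in zip(cohort, labels) if g == "high"]
        if not low or not high:
            continue
        try:
            lr = logrank_test(low, high)
        except ValueError:
            continue
        s_low = survival_at(km_estimate(low), cfg.horizon_months)
        s_high = survival_at(km_estimate(high), cfg.horizon_months)
        if lr.p_value < cfg.alpha and s_high < s_low:
            kept.add(gene)
    return kept


def rank_core_axis(
    final_genes: Set[str],
    core_gene: str,
    cohort: Sequence[SubjectRecord],
) -> List[Tuple[str, float]]:
    """Final genes sorted by Spearman correlation with the core gene, desc."""
    if not final_genes:
        return []
    core_expr = [r.expr[core_gene] for r in cohort]
    scored = []
    for gene in sorted(final_genes):
        expr = [r.expr[gene] for r in cohort]
        rho, _ = spearman_rho(core_expr, expr)
        scored.append((gene, rho))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored


def _best_site_key(sites: Sequence[SeedSite]) -> Tuple[int, int]:
    return (max(class_rank(s.site_class) for s in sites), len(sites))


def run_screen(
    cfg: CascadeConfig,
    pulldown: Mapping[str, Tuple[TagLibrary, TagLibrary]],
    counts: CountMatrix,
    mirnas: Sequence[MatureMiRNA],
    core_utr: UtrSequence,
    target_utrs: Sequence[UtrSequence],
    cohort: Sequence[SubjectRecord],
    core_gene: str,
) -> Tuple[CeRNANetwork, CascadeReport]:
    """Execute the full screening cascade.

    ``pulldown`` maps cell-line label -> (pulldown library, control library);
    ``counts`` holds both conditions of the overexpression RNA-seq.
    """
    if len(pulldown) < 2:
        raise ValueError("need pull-down data for at least 2 cell lines")
    report = CascadeReport()
    by_id = {m.id: m for m in mirnas}

    # (1)-(2) per-line enrichment and the common enriched set
    enriched_sets, topk_lists = [], []
    for line in sorted(pulldown):
        pd_lib, ctrl_lib = pulldown[line]
        records = enrichment_scores(pd_lib, ctrl_lib, pseudocount=cfg.pseudocount_tpa)
        sel = select_enriched(records, cfg.min_log2_enrichment, cfg.min_tpa)
        report.n_enriched[line] = len(sel)
        logger.info("line %s: %d enriched miRNAs", line, len(sel))
        enriched_sets.append(sel)
        topk_lists.append(top_k(records, cfg.k_top))
    common = set.intersection(*enriched_sets)
    report.n_common = len(common)
    logger.info("common enriched miRNAs: %d", len(common))

    # (3)-(4) per-line top-k union and intersection
    top_union, core_mirnas = merge_topk(topk_lists[0], topk_lists[1])
    for extra in topk_lists[2:]:
        top_union |= set(extra)
        core_mirnas &= set(extra)
    report.top_union = sorted(top_union)
    report.core_mirnas = sorted(core_mirnas)
    logger.info(
        "top-%d union: %d, intersection (core): %d",
        cfg.k_top, len(top_union), len(core_mirnas),
    )

    # (5) target prediction for the candidate pool, overlap with up-DEGs
    pool = top_union if cfg.candidate_pool == "topk_union" else common
    candidates = [by_id[m] for m in sorted(pool) if m in by_id]
    if len(candidates) < len(pool):
        logger.warning(
            "%d candidate miRNAs have no sequence and were dropped",
            len(pool) - len(candidates),
        )
    tm = predict_targets(candidates, target_utrs, min_class=cfg.min_site_class)
    all_targets = tm.all_targets()
    report.n_targets = len(all_targets)

    de_mode = cfg.de_mode
    if de_mode == "auto":
        reps = min(counts.condition.count("case"), counts.condition.count("control"))
        de_mode = "welch_replicated" if reps >= 2 else "exact_unreplicated"
    degs = deg_table(
        counts, mode=de_mode, lfc_threshold=cfg.lfc_threshold, alpha=cfg.alpha
    )
    up, down = filter_degs(degs, cfg.lfc_threshold, cfg.alpha)
    report.n_up, report.n_down = len(up), len(down)
    report.n_degs_total = len(up) + len(down)
    overlap = all_targets & up
    report.n_target_up_overlap = len(overlap)
    logger.info(
        "%d predicted targets; %d up / %d down DEGs; overlap %d",
        len(all_targets), len(up), len(down), len(overlap),
    )

    # (6) prognostic screen
    prognostic = prognostic_filter(overlap, cohort, cfg) if overlap else set()
    report.n_prognostic = len(prognostic)
    logger.info("prognostic genes: %d", len(prognostic))

    # (7) restrict to targets of the core miRNAs
    core_targets = tm.all_targets(core_mirnas)
    final = core_targets & prognostic
    report.final_genes = sorted(final)
    logger.info("final genes: %d", len(final))

    # (8) Spearman ranking against the core gene -> core axis
    ranked = rank_core_axis(final, core_gene, cohort) if final else []
    report.final_genes = [g for g, _ in ranked] if ranked else sorted(final)
    if ranked:
        top_gene = ranked[0][0]
        linked = [
            m for m in core_mirnas if top_gene in tm.edges.get(m, set())
        ]
        if linked:
            best = max(
                linked, key=lambda m: _best_site_key(tm.provenance[(m, top_gene)])
            )
            report.core_axis = (best, top_gene)
    if report.core_axis is None:
        logger.warning("cascade produced no core axis")

    # network: candidate miRNAs with core-UTR sites + prognostic genes
    net = CeRNANetwork(core=core_utr.id)
    for mid in sorted(pool):
        m = by_id.get(mid)
        if m is None:
            continue
        sites = [
            s
            for s in find_seed_sites(m, core_utr)
            if class_rank(s.site_class) >= class_rank(cfg.min_site_class)
        ]
        if sites:
            net.mirna_nodes.append(mid)
            net.core_edges[mid] = sites
    net.gene_nodes = sorted(prognostic)
    for mid in net.mirna_nodes:
        for gene in net.gene_nodes:
            sites = tm.provenance.get((mid, gene))
            if sites:
                net.target_edges[(mid, gene)] = list(sites)
    return net, report


# ---------------------------------------------------------------------------
# serialization


def _evidence(sites: Sequence[SeedSite]) -> str:
    parts = sorted(f"{s.site_class}@{s.start}-{s.end}" for s in sites)
    return ";".join(parts)


def _parse_evidence(ev: str, mirna: str, utr: str) -> List[SeedSite]:
    sites = []
    if not ev:
        return sites
    for part in ev.split(";"):
        cls, _, span = part.partition("@")
        start, _, end = span.partition("-")
        sites.append(SeedSite(mirna, utr, int(start), int(end), cls))
    return sites


def export_network(net: CeRNANetwork, report: CascadeReport, outdir) -> Dict[str, Path]:
    """Write the edge-list TSV and the report JSON; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    edges_path = outdir / "network_edges.tsv"
    report_path = outdir / "cascade_report.json"
    lines = ["source\ttarget\tedge_type\tevidence"]
    for mid in sorted(net.core_edges):
        lines.append(
            f"{net.core}\t{mid}\tcore_mirna\t{_evidence(net.core_edges[mid])}"
        )
    for (mid, gene) in sorted(net.target_edges):
        lines.append(
            f"{mid}\t{gene}\tmirna_target\t{_evidence(net.target_edges[(mid, gene)])}"
        )
    edges_path.write_text("\n".join(lines) + "\n")
    payload = asdict(report)
    payload["core"] = net.core
    payload["core_axis"] = list(report.core_axis) if report.core_axis else None
    report_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return {"edges": edges_path, "report": report_path}


def read_network(outdir) -> Tuple[CeRNANetwork, CascadeReport]:
    """Inverse of export_network (lossless for the exported fields)."""
    outdir = Path(outdir)
    payload = json.loads((outdir / "cascade_report.json").read_text())
    core = payload.pop("core")
    axis = payload.pop("core_axis")
    report = CascadeReport(**payload)
    report.core_axis = tuple(axis) if axis else None
    net = CeRNANetwork(core=core)
    text = (outdir / "network_edges.tsv").read_text().rstrip("\n")
    rows = text.split("\n")[1:] if text else []
    for row in rows:
        source, target, edge_type, ev = (row.split("\t") + [""])[:4]
        if edge_type == "core_mirna":
            net.mirna_nodes.append(target)
            net.core_edges[target] = _parse_evidence(ev, target, core)
        else:
            net.target_edges[(source, target)] = _parse_evidence(ev, source, target)
            if target not in net.gene_nodes:
                net.gene_nodes.append(target)
    return net, report
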