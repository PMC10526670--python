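"""Synthetic inputs with planted ground truth for every pipeline stage.

Generates overdispersed tag/read counts with planted enriched miRNAs and
planted DEGs, UTR sequences with planted seed sites, survival cohorts whose
hazard rises with a core gene's expression, ISH score tables linked to
outcome, and a full multi-dataset bundle with one planted (miRNA, gene) axis.

Noise model: negative binomial with variance mu + dispersion * mu^2
(Poisson when dispersion == 0).  Each dataset draws from its own RNG stream
derived from the master seed, so regenerating one dataset never perturbs the
others.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .diffexpr import CountMatrix
from .ish import IshSpecimen, composite_score
from .pulldown import TagLibrary
from .seed_targets import (
    MatureMiRNA,
    SeedSite,
    UtrSequence,
    find_seed_sites,
    reverse_complement_dna,
)
from .survival import SubjectRecord

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticBundle",
    "simulate_pulldown",
    "simulate_counts",
    "simulate_mirnas",
    "simulate_sequences",
    "simulate_cohort",
    "simulate_ish",
    "simulate_bundle",
    "random_sequence",
]

_BASES = np.array(list("ACGT"))

# fixed RNG stream offsets (one stream per dataset)
_STREAM_PULLDOWN_A = 0
_STREAM_PULLDOWN_B = 1
_STREAM_COUNTS = 2
_STREAM_SEQUENCES = 3
_STREAM_COHORT = 4
_STREAM_ISH = 5
_STREAM_MIRNAS = 6


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs for the synthetic generators; validated on construction."""

    seed: int = 0
    # pull-down libraries
    n_mirna: int = 300
    n_planted_mirna: int = 20
    enrichment_fold: float = 8.0
    library_depth: int = 500_000
    # count matrices
    n_genes: int = 1000
    n_up: int = 40
    n_down: int = 20
    planted_lfc: float = 2.0
    dispersion: float = 0.1
    n_reps: int = 3
    # sequences
    utr_length: int = 150
    site_classes: Tuple[str, ...] = ("8mer",)
    # cohort
    n_patients: int = 500
    beta: float = 0.8
    censor_rate: float = 0.2
    horizon_months: float = 60.0
    target_rho: float = 0.7
    median_survival_months: float = 30.0
    # ISH specimens
    n_specimens: int = 222
    ish_cutoff: int = 5
    ish_p_low: float = 0.15
    ish_p_high: float = 0.8
    # bundle wiring
    n_core_mirna: int = 4
    core_fold_boost: float = 4.0
    n_decoy_targets: int = 3
    n_background_utrs: int = 20

    def __post_init__(self) -> None:
        checks = [
            ("n_mirna", self.n_mirna >= 1),
            ("n_planted_mirna", 0 <= self.n_planted_mirna <= self.n_mirna),
            ("enrichment_fold", self.enrichment_fold >= 1),
            ("library_depth", self.library_depth >= 1),
            ("n_genes", self.n_genes >= 1),
            ("n_up/n_down", self.n_up >= 0 and self.n_down >= 0
             and self.n_up + self.n_down <= self.n_genes),
            ("dispersion", self.dispersion >= 0),
            ("n_reps", self.n_reps >= 1),
            ("utr_length", self.utr_length >= 8),
            ("n_patients", self.n_patients >= 2),
            ("beta", math.isfinite(self.beta)),
            ("censor_rate", 0 <= self.censor_rate < 1),
            ("horizon_months", self.horizon_months > 0),
            ("target_rho", -1 <= self.target_rho <= 1),
            ("n_specimens", self.n_specimens >= 2),
            ("ish_cutoff", 1 <= self.ish_cutoff <= 12),
            ("ish_p_low", 0 <= self.ish_p_low <= 1),
            ("ish_p_high", 0 <= self.ish_p_high <= 1),
            ("n_core_mirna", 0 <= self.n_core_mirna <= max(self.n_planted_mirna, 0)),
        ]
        for name, ok in checks:
            if not ok:
                raise ValueError(f"invalid SimulationConfig field: {name}")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """What was planted, so recovery can be checked exactly."""

    planted_mirnas: Set[str] = field(default_factory=set)
    planted_up: Set[str] = field(default_factory=set)
    planted_down: Set[str] = field(default_factory=set)
    planted_sites: List[SeedSite] = field(default_factory=list)
    core_gene: Optional[str] = None
    true_beta: Optional[float] = None
    core_mirnas: Set[str] = field(default_factory=set)
    axis: Optional[Tuple[str, str]] = None  # (mirna, gene)
    ish_cutoff: Optional[int] = None


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _draw_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB(mean, var = mean + dispersion * mean^2); Poisson at dispersion 0."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _mirna_ids(n: int) -> List[str]:
    return [f"miR-{i:04d}" for i in range(1, n + 1)]


def _gene_ids(n: int) -> List[str]:
    return [f"gene-{i:04d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# pull-down tag libraries


def simulate_pulldown(
    cfg: SimulationConfig,
    fold_map: Optional[Mapping[str, float]] = None,
    cell_line: str = "lineA",
    stream: int = _STREAM_PULLDOWN_A,
) -> Tuple[TagLibrary, TagLibrary, GroundTruth]:
    """One pull-down / control library pair with planted enriched miRNAs.

    Planted miRNAs have expected pull-down abundance ``enrichment_fold`` times
    their control abundance (before per-library depth renormalization);
    ``fold_map`` overrides the fold per miRNA id.
    """
    rng = _rng(cfg, stream)
    ids = _mirna_ids(cfg.n_mirna)
    planted = set(
        rng.choice(ids, size=cfg.n_planted_mirna, replace=False).tolist()
    )
    rel = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_mirna)
    rel /= rel.sum()
    folds = np.array(
        [
            (fold_map or {}).get(m, cfg.enrichment_fold if m in planted else 1.0)
            for m in ids
        ]
    )
    ctrl_mean = cfg.library_depth * rel
    pd_rel = rel * folds
    pd_mean = cfg.library_depth * pd_rel / pd_rel.sum()
    ctrl_counts = _draw_counts(rng, ctrl_mean, cfg.dispersion)
    pd_counts = _draw_counts(rng, pd_mean, cfg.dispersion)
    pulldown = TagLibrary(cell_line, "pulldown", dict(zip(ids, map(int, pd_counts))))
    control = TagLibrary(cell_line, "control", dict(zip(ids, map(int, ctrl_counts))))
    return pulldown, control, GroundTruth(planted_mirnas=planted)


# ---------------------------------------------------------------------------
# RNA-seq count matrices


def simulate_counts(
    cfg: SimulationConfig,
    up_genes: Optional[Sequence[str]] = None,
    down_genes: Optional[Sequence[str]] = None,
) -> Tuple[CountMatrix, CountMatrix, GroundTruth]:
    """Paired case/control count matrices with planted up/down genes.

    Planted genes have expected log2 RPKM difference +/- ``planted_lfc``;
    gene lengths are shared across conditions.
    """
    rng = _rng(cfg, _STREAM_COUNTS)
    genes = _gene_ids(cfg.n_genes)
    lengths = rng.integers(500, 3001, size=cfg.n_genes).astype(float)
    base = rng.lognormal(mean=1.0, sigma=1.0, size=cfg.n_genes)
    if up_genes is None or down_genes is None:
        chosen = rng.choice(genes, size=cfg.n_up + cfg.n_down, replace=False).tolist()
        up_genes = chosen[: cfg.n_up]
        down_genes = chosen[cfg.n_up :]
    up_set, down_set = set(up_genes), set(down_genes)
    if up_set & down_set:
        raise ValueError("up and down gene sets overlap")
    shift = np.ones(cfg.n_genes)
    for i, g in enumerate(genes):
        if g in up_set:
            shift[i] = 2.0**cfg.planted_lfc
        elif g in down_set:
            shift[i] = 2.0**-cfg.planted_lfc

    def matrix(expr: np.ndarray, condition: str, prefix: str) -> CountMatrix:
        w = expr * lengths
        mean = cfg.library_depth * w / w.sum()
        cols = [
            _draw_counts(rng, mean, cfg.dispersion) for _ in range(cfg.n_reps)
        ]
        counts = np.column_stack(cols).astype(int)
        samples = [f"{prefix}{r + 1}" for r in range(cfg.n_reps)]
        return CountMatrix(
            gene_ids=list(genes),
            lengths=lengths.copy(),
            samples=samples,
            counts=counts,
            condition=[condition] * cfg.n_reps,
        )

    ctrl = matrix(base, "control", "ctrl_")
    case = matrix(base * shift, "case", "case_")
    truth = GroundTruth(planted_up=up_set, planted_down=down_set)
    return case, ctrl, truth


# ---------------------------------------------------------------------------
# sequences


def random_sequence(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA string (no site filtering)."""
    return "".join(rng.choice(_BASES, size=length))


def _scan_all(
    mirnas: Sequence[MatureMiRNA], utr: UtrSequence
) -> List[SeedSite]:
    out: List[SeedSite] = []
    for m in mirnas:
        out.extend(find_seed_sites(m, utr))
    return out


def _site_core(mirna: MatureMiRNA, site_class: str, rng) -> Tuple[str, int, int]:
    """8-nt block encoding one site of the requested class.

    Returns (block, site_start_offset, site_end_offset); flanking bases inside
    the block are constrained so the scanner classifies the site exactly as
    requested (e.g. a 7mer-m8 must not be followed by A).
    """
    match7 = reverse_complement_dna(mirna.sequence[1:8])
    match6 = reverse_complement_dna(mirna.sequence[1:7])
    comp_m8 = match7[0]
    not_a = rng.choice([b for b in "CGT"])
    not_m8 = rng.choice([b for b in "ACGT" if b != comp_m8])
    if site_class == "8mer":
        return match7 + "A", 0, 8
    if site_class == "7mer-m8":
        return match7 + not_a, 0, 7
    if site_class == "7mer-A1":
        return not_m8 + match6 + "A", 1, 8
    if site_class == "6mer":
        return not_m8 + match6 + not_a, 1, 7
    raise ValueError(f"unknown site class: {site_class!r}")


def _build_utr(
    rng: np.random.Generator,
    utr_id: str,
    length: int,
    plants: Sequence[Tuple[MatureMiRNA, str]],
    scan_mirnas: Sequence[MatureMiRNA],
    max_iter: int = 500,
    tolerate_fixed_conflicts: bool = False,
) -> Tuple[UtrSequence, List[SeedSite]]:
    """A UTR carrying exactly the requested sites for ``scan_mirnas``.

    Background bases are uniform; any accidental site for a scanned miRNA is
    removed by re-randomizing its non-fixed bases (rejection).  A site lying
    wholly inside the planted blocks cannot be removed; with
    ``tolerate_fixed_conflicts`` the sequence is accepted anyway, otherwise
    this is an error.
    """
    blocks = [_site_core(m, cls, rng) for m, cls in plants]
    need = 8 * len(blocks)
    if need > length:
        raise ValueError(
            f"utr_length {length} too short to host {len(blocks)} sites"
        )
    # spread the 8-nt blocks over evenly sized slots, jittered
    starts = []
    slot = length // max(len(blocks), 1)
    for i in range(len(blocks)):
        lo = i * slot
        hi = min((i + 1) * slot, length) - 8
        starts.append(int(rng.integers(lo, hi + 1)))
    fixed = np.zeros(length, dtype=bool)
    seq = rng.choice(_BASES, size=length)
    planted_sites: List[Tuple[str, int, int, str]] = []
    for (block, off_s, off_e), (m, cls), s in zip(blocks, plants, starts):
        seq[s : s + 8] = list(block)
        fixed[s : s + 8] = True
        planted_sites.append((m.id, s + off_s, s + off_e, cls))
    allowed = {(mid, a, b) for mid, a, b, _ in planted_sites}
    for _ in range(max_iter):
        utr = UtrSequence(utr_id, "".join(seq))
        offenders = [
            st
            for st in _scan_all(scan_mirnas, utr)
            if (st.mirna, st.start, st.end) not in allowed
        ]
        fixable = [
            st for st in offenders if any(not fixed[p] for p in range(st.start, st.end))
        ]
        if not fixable:
            if offenders and not tolerate_fixed_conflicts:
                break
            sites = [
                SeedSite(mid, utr_id, a, b, cls)
                for mid, a, b, cls in planted_sites
            ]
            return utr, sites
        for st in fixable:
            for pos in range(st.start, st.end):
                if not fixed[pos]:
                    seq[pos] = rng.choice(_BASES)
    raise RuntimeError(
        f"could not build site-free background for {utr_id!r} "
        f"(conflicting miRNA seeds?)"
    )


def simulate_mirnas(
    cfg: SimulationConfig, length: int = 22
) -> List[MatureMiRNA]:
    """Random mature miRNA sequences with pairwise-distinct 6-nt seed cores."""
    rng = _rng(cfg, _STREAM_MIRNAS)
    ids = _mirna_ids(cfg.n_mirna)
    seen: Set[str] = set()
    out = []
    for mid in ids:
        for _ in range(1000):
            seq = "".join(rng.choice(_BASES, size=length)).replace("T", "U")
            core = seq[1:7]
            if core not in seen:
                seen.add(core)
                out.append(MatureMiRNA(mid, seq))
                break
        else:
            raise RuntimeError("could not draw distinct miRNA seeds")
    return out


def simulate_sequences(
    cfg: SimulationConfig,
    mirnas: Sequence[MatureMiRNA],
    target_spec: Optional[Mapping[str, Sequence[str]]] = None,
    core_utr_id: str = "CORE-UTR",
) -> Tuple[UtrSequence, List[UtrSequence], GroundTruth]:
    """Core UTR + target UTRs with planted seed sites.

    The core UTR carries >= 1 site for every given (planted) miRNA; each
    entry of ``target_spec`` (utr id -> miRNA ids) gets one site per listed
    miRNA (empty list = site-free decoy UTR).  Default spec: one target UTR
    per miRNA.  Backgrounds are rejection-sampled to be free of accidental
    sites for the given miRNAs.
    """
    if not mirnas:
        raise ValueError("mirnas must be non-empty")
    rng = _rng(cfg, _STREAM_SEQUENCES)
    by_id = {m.id: m for m in mirnas}
    if target_spec is None:
        target_spec = {f"target-{m.id}": [m.id] for m in mirnas}
    classes = cfg.site_classes
    truth = GroundTruth(planted_mirnas={m.id for m in mirnas})

    core_plants = [
        (m, classes[i % len(classes)]) for i, m in enumerate(mirnas)
    ]
    # leave >= 4 free bases per planted block so rejection can always act
    core_len = max(cfg.utr_length, 12 * len(core_plants))
    core_utr, core_sites = _build_utr(
        rng, core_utr_id, core_len, core_plants, mirnas,
        tolerate_fixed_conflicts=True,
    )
    truth.planted_sites.extend(core_sites)

    targets = []
    for utr_id, mirna_ids in target_spec.items():
        plants = [
            (by_id[mid], classes[i % len(classes)])
            for i, mid in enumerate(mirna_ids)
        ]
        utr, sites = _build_utr(
            rng, utr_id, max(cfg.utr_length, 12 * len(plants)), plants, mirnas,
            tolerate_fixed_conflicts=True,
        )
        truth.planted_sites.extend(sites)
        targets.append(utr)
    return core_utr, targets, truth


# ---------------------------------------------------------------------------
# survival cohort


def simulate_cohort(
    cfg: SimulationConfig,
    corr_genes: Optional[Mapping[str, float]] = None,
    core_gene: str = "COREGENE",
) -> Tuple[List[SubjectRecord], GroundTruth]:
    """Cohort with exponential event times; log-hazard = beta * z_core.

    ``corr_genes`` maps gene id -> correlation of its (standardized)
    expression with the core gene; defaults to one target at
    ``cfg.target_rho``.  Censoring: with probability ``censor_rate`` a subject
    is censored uniformly before its event time.
    """
    if not math.isfinite(cfg.beta):
        raise ValueError("beta must be finite")
    rng = _rng(cfg, _STREAM_COHORT)
    if corr_genes is None:
        corr_genes = {"TARGET": cfg.target_rho}
    n = cfg.n_patients
    z = rng.standard_normal(n)
    expr: Dict[str, np.ndarray] = {core_gene: z}
    for g, rho in corr_genes.items():
        eps = rng.standard_normal(n)
        expr[g] = rho * z + math.sqrt(max(0.0, 1 - rho * rho)) * eps
    lam0 = math.log(2.0) / cfg.median_survival_months
    lam = lam0 * np.exp(cfg.beta * z)
    t_event = rng.exponential(1.0 / lam)
    censored = rng.random(n) < cfg.censor_rate
    u = rng.random(n)
    times = np.where(censored, np.maximum(u * t_event, 1e-6), t_event)
    records = [
        SubjectRecord(
            id=f"pt-{i + 1:04d}",
            time=float(times[i]),
            event=0 if censored[i] else 1,
            expr={g: float(v[i]) for g, v in expr.items()},
        )
        for i in range(n)
    ]
    truth = GroundTruth(core_gene=core_gene, true_beta=cfg.beta)
    return records, truth


# ---------------------------------------------------------------------------
# ISH specimens


def simulate_ish(cfg: SimulationConfig) -> Tuple[List[IshSpecimen], GroundTruth]:
    """ISH specimen table; 5-year death probability steps up at the planted
    composite-score cutoff (set ish_p_low == ish_p_high for a null table)."""
    rng = _rng(cfg, _STREAM_ISH)
    specimens = []
    for i in range(cfg.n_specimens):
        intensity = int(rng.integers(0, 4))
        pct = float(rng.uniform(0, 100))
        score = composite_score(intensity, pct)
        p = cfg.ish_p_high if score >= cfg.ish_cutoff else cfg.ish_p_low
        outcome = int(rng.random() < p)
        specimens.append(
            IshSpecimen(
                id=f"spec-{i + 1:04d}",
                intensity=intensity,
                proportion_pct=pct,
                outcome_5y=outcome,
            )
        )
    truth = GroundTruth(ish_cutoff=cfg.ish_cutoff)
    return specimens, truth


# ---------------------------------------------------------------------------
# full bundle


@dataclass
class SyntheticBundle:
    """Everything run_screen needs, with one planted (miRNA, gene) axis."""

    pulldown: Dict[str, Tuple[TagLibrary, TagLibrary]]
    counts_case: CountMatrix
    counts_ctrl: CountMatrix
    mirnas: List[MatureMiRNA]
    core_utr: UtrSequence
    target_utrs: List[UtrSequence]
    cohort: List[SubjectRecord]
    truth: GroundTruth


def simulate_bundle(cfg: SimulationConfig) -> SyntheticBundle:
    """Generate coherent inputs for the whole screening cascade.

    A planted miRNA set is enriched in both cell lines; a small "core" subset
    gets a boosted fold so it lands in both per-line top-k lists.  The axis
    gene is a planted up-DEG whose UTR carries a site for the first core
    miRNA and whose cohort expression is strongly correlated with the
    hazardous core gene; decoy targets carry sites for other core miRNAs but
    only weak cohort correlation.
    """
    mirnas = simulate_mirnas(cfg)
    rng = _rng(cfg, 100)  # bundle wiring choices
    ids = [m.id for m in mirnas]
    planted = rng.choice(ids, size=cfg.n_planted_mirna, replace=False).tolist()
    core_mirnas = planted[: cfg.n_core_mirna]
    axis_mirna = core_mirnas[0] if core_mirnas else planted[0]
    fold_map = {m: cfg.enrichment_fold for m in planted}
    for m in core_mirnas:
        fold_map[m] = cfg.enrichment_fold * cfg.core_fold_boost

    pd_a, ctrl_a, _ = simulate_pulldown(
        cfg, fold_map=fold_map, cell_line="lineA", stream=_STREAM_PULLDOWN_A
    )
    pd_b, ctrl_b, _ = simulate_pulldown(
        cfg, fold_map=fold_map, cell_line="lineB", stream=_STREAM_PULLDOWN_B
    )

    genes = _gene_ids(cfg.n_genes)
    chosen = rng.choice(genes, size=cfg.n_up + cfg.n_down, replace=False).tolist()
    up_genes = chosen[: cfg.n_up]
    down_genes = chosen[cfg.n_up :]
    case, ctrl, _ = simulate_counts(cfg, up_genes=up_genes, down_genes=down_genes)

    axis_gene = up_genes[0]
    decoys = up_genes[1 : 1 + cfg.n_decoy_targets]
    target_spec: Dict[str, List[str]] = {axis_gene: [axis_mirna]}
    for i, g in enumerate(decoys):
        donor = core_mirnas[(i + 1) % len(core_mirnas)] if core_mirnas else planted[0]
        target_spec[g] = [donor]
    background = [g for g in genes if g not in target_spec][: cfg.n_background_utrs]
    for g in background:
        target_spec[g] = []

    by_id = {m.id: m for m in mirnas}
    scan_set = [by_id[m] for m in planted]
    core_utr, target_utrs, seq_truth = simulate_sequences(
        cfg,
        scan_set,
        target_spec=target_spec,
        core_utr_id="CORE-UTR",
    )

    corr = {axis_gene: cfg.target_rho}
    for g in decoys:
        corr[g] = 0.15
    for g in background:
        corr[g] = 0.0
    cohort, cohort_truth = simulate_cohort(cfg, corr_genes=corr)

    truth = GroundTruth(
        planted_mirnas=set(planted),
        planted_up=set(up_genes),
        planted_down=set(down_genes),
        planted_sites=list(seq_truth.planted_sites),
        core_gene=cohort_truth.core_gene,
        true_beta=cfg.beta,
        core_mirnas=set(core_mirnas),
        axis=(axis_mirna, axis_gene),
    )
    return SyntheticBundle(
        pulldown={"lineA": (pd_a, ctrl_a), "lineB": (pd_b, ctrl_b)},
        counts_case=case,
        counts_ctrl=ctrl,
        mirnas=mirnas,
        core_utr=core_utr,
        target_utrs=target_utrs,
        cohort=cohort,
        truth=truth,
    )
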