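"""Readers and writers for the plain-text interchange formats.

Tag libraries and count matrices are TSV, sequences FASTA, cohorts and ISH
specimen tables CSV, target maps / reports / truth JSON.  All writers are
deterministic (sorted keys) so identical inputs produce identical bytes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .diffexpr import CountMatrix, DegRecord
from .ish import IshSpecimen
from .pulldown import EnrichmentRecord, TagLibrary
from .seed_targets import MatureMiRNA, SeedSite, TargetMap, UtrSequence
from .simdata import GroundTruth
from .survival import SubjectRecord

__all__ = [
    "read_tag_library", "write_tag_library",
    "read_count_matrix", "write_count_matrix",
    "read_fasta_mirnas", "read_fasta_utrs", "write_fasta",
    "read_cohort", "write_cohort",
    "read_specimens", "write_specimens",
    "write_enrichment_table", "write_deg_table",
    "write_sites", "write_target_map",
    "write_truth",
]


# --- tag libraries ---------------------------------------------------------

def read_tag_library(path, cell_line: str = "", probe: str = "pulldown") -> TagLibrary:
    df = pd.read_csv(path, sep="\t", dtype={"mirna_id": str})
    if not {"mirna_id", "count"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns mirna_id, count")
    counts = dict(zip(df["mirna_id"], df["count"].astype(int)))
    return TagLibrary(cell_line or Path(path).stem, probe, counts)


def write_tag_library(lib: TagLibrary, path) -> None:
    rows = sorted(lib.counts.items())
    with open(path, "w") as fh:
        fh.write("mirna_id\tcount\n")
        for mid, c in rows:
            fh.write(f"{mid}\t{c}\n")


# --- count matrices --------------------------------------------------------

def write_count_matrix(cm: CountMatrix, path, design_path=None) -> None:
    df = pd.DataFrame(cm.counts, columns=cm.samples)
    df.insert(0, "length", cm.lengths.astype(int))
    df.insert(0, "gene_id", cm.gene_ids)
    df.to_csv(path, sep="\t", index=False)
    if design_path is not None:
        design = dict(zip(cm.samples, cm.condition))
        Path(design_path).write_text(json.dumps(design, indent=2, sort_keys=True) + "\n")


def read_count_matrix(path, design_path=None, condition=None) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    samples = [c for c in df.columns if c not in ("gene_id", "length")]
    if design_path is not None:
        design = json.loads(Path(design_path).read_text())
        cond = [design[s] for s in samples]
    elif condition is not None:
        cond = [condition] * len(samples)
    else:
        raise ValueError("provide design_path or condition")
    return CountMatrix(
        gene_ids=df["gene_id"].tolist(),
        lengths=df["length"].to_numpy(dtype=float),
        samples=samples,
        counts=df[samples].to_numpy(dtype=int),
        condition=cond,
    )


def concat_count_matrices(case: CountMatrix, ctrl: CountMatrix) -> CountMatrix:
    """Column-bind a case and a control matrix over the same genes."""
    if case.gene_ids != ctrl.gene_ids:
        raise ValueError("gene universes differ")
    if not np.array_equal(case.lengths, ctrl.lengths):
        raise ValueError("gene lengths differ between matrices")
    return CountMatrix(
        gene_ids=list(case.gene_ids),
        lengths=case.lengths.copy(),
        samples=case.samples + ctrl.samples,
        counts=np.hstack([case.counts, ctrl.counts]),
        condition=case.condition + ctrl.condition,
    )


# --- FASTA -----------------------------------------------------------------

def write_fasta(entries: Sequence[Tuple[str, str]], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in entries
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta_mirnas(path) -> List[MatureMiRNA]:
    return [
        MatureMiRNA(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_fasta_utrs(path) -> List[UtrSequence]:
    return [
        UtrSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


# --- cohort ----------------------------------------------------------------

def write_cohort(records: Sequence[SubjectRecord], path) -> None:
    genes = sorted({g for r in records for g in r.expr})
    rows = []
    for r in records:
        row = {"patient_id": r.id, "time_months": r.time, "event": r.event}
        for g in genes:
            row[f"expr_{g}"] = r.expr.get(g, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cohort(path) -> List[SubjectRecord]:
    df = pd.read_csv(path)
    expr_cols = [c for c in df.columns if c.startswith("expr_")]
    out = []
    for _, row in df.iterrows():
        expr = {c[len("expr_"):]: float(row[c]) for c in expr_cols
                if pd.notna(row[c])}
        out.append(
            SubjectRecord(
                id=str(row["patient_id"]),
                time=float(row["time_months"]),
                event=int(row["event"]),
                expr=expr,
            )
        )
    return out


# --- ISH specimens ---------------------------------------------------------

def write_specimens(specimens: Sequence[IshSpecimen], path) -> None:
    rows = [
        {
            "specimen_id": s.id,
            "intensity": s.intensity,
            "proportion_pct": s.proportion_pct,
            "outcome_5y": "" if s.outcome_5y is None else s.outcome_5y,
        }
        for s in specimens
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_specimens(path) -> List[IshSpecimen]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        outcome = row.get("outcome_5y")
        out.append(
            IshSpecimen(
                id=str(row["specimen_id"]),
                intensity=int(row["intensity"]),
                proportion_pct=float(row["proportion_pct"]),
                outcome_5y=None if pd.isna(outcome) else int(outcome),
            )
        )
    return out


# --- result tables ---------------------------------------------------------

def write_enrichment_table(records: Sequence[EnrichmentRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\ttpa_pulldown\ttpa_control\tlog2_enrichment\trank\n")
        for r in records:
            fh.write(
                f"{r.mirna}\t{r.tpa_pulldown:.6g}\t{r.tpa_control:.6g}"
                f"\t{r.log2_enrichment:.6g}\t{r.rank}\n"
            )


def write_deg_table(records: Sequence[DegRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlog2fc\tp_value\tdirection\n")
        for r in records:
            fh.write(f"{r.gene}\t{r.log2fc:.6g}\t{r.p_value:.6g}\t{r.direction}\n")


def write_sites(sites: Sequence[SeedSite], path) -> None:
    """BED-like TSV: utr_id, start, end, mirna_id, site_class."""
    with open(path, "w") as fh:
        fh.write("utr_id\tstart\tend\tmirna_id\tsite_class\n")
        for s in sorted(sites, key=lambda s: (s.utr, s.start, s.mirna)):
            fh.write(f"{s.utr}\t{s.start}\t{s.end}\t{s.mirna}\t{s.site_class}\n")


def write_target_map(tm: TargetMap, path) -> None:
    payload = {
        "predictor": tm.predictor,
        "edges": {m: sorted(gs) for m, gs in sorted(tm.edges.items())},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_truth(truth: GroundTruth, path) -> None:
    payload = {
        "planted_mirnas": sorted(truth.planted_mirnas),
        "planted_up": sorted(truth.planted_up),
        "planted_down": sorted(truth.planted_down),
        "planted_sites": [
            [s.mirna, s.utr, s.start, s.end, s.site_class]
            for s in truth.planted_sites
        ],
        "core_gene": truth.core_gene,
        "true_beta": truth.true_beta,
        "core_mirnas": sorted(truth.core_mirnas),
        "axis": list(truth.axis) if truth.axis else None,
        "ish_cutoff": truth.ish_cutoff,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
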