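# cerna-screen

A tested, reusable implementation of a ceRNA-axis screening pipeline for a
core 3'-UTR acting as a miRNA sponge:

- **pulldown** — TPA normalization (tags per million aligned) of pull-down
  vs control miRNA tag libraries and log2 enrichment ranking.
- **diffexpr** — RPKM quantification, log2 fold changes, an exact binomial or
  Welch differential test, and the `|log2FC| > 1, P < 0.05` DEG filter.
- **seed_targets** — canonical seed-match binding-site prediction
  (8mer / 7mer-m8 / 7mer-A1 / 6mer) as a transparent stand-in for database
  target predictors, plus union/intersection combination of predictors.
- **survival** — from-scratch Kaplan-Meier, log-rank, Cox proportional
  hazards (Efron ties, damped Newton), Spearman rank correlation, and
  low/high expression dichotomization (median / fixed cutoff / Youden).
- **ish** — ISH/IHC composite scoring (intensity 0-3 × proportion category
  0-4), grade banding, low/high grouping, and the Youden-index optimal
  cutoff.
- **cascade** — the multi-stage screen: per-line enrichment → common set →
  top-k union/intersection → target prediction → up-DEG overlap →
  prognostic filter → core-miRNA restriction → Spearman ranking → the
  nominated (miRNA, gene) core axis, exported as an edge-list network and a
  per-stage report.
- **simdata** — synthetic generators for every input (tag libraries, count
  matrices, miRNA/UTR sequences with planted seed sites, survival cohorts,
  ISH tables) with planted ground truth, so the whole cascade is testable
  end to end without any external data.

## CLI

```bash
# generate a synthetic bundle with a planted axis
cerna-screen simulate --seed 11 --outdir bundle/

# individual stages
cerna-screen enrich --pulldown bundle/pulldown_lineA.tsv \
    --control bundle/control_lineA.tsv --min-log2 1 --min-tpa 10 -o enrich.tsv
cerna-screen de --counts bundle/counts.tsv --design bundle/design.json \
    --mode welch_replicated -o degs.tsv
cerna-screen predict --mirnas bundle/mirnas.fa --utrs bundle/utrs.fa \
    --min-class 7mer-A1 -o sites.tsv
cerna-screen survival --cohort bundle/cohort.csv --gene COREGENE
cerna-screen ish --specimens specimens.csv --horizon 60

# the full cascade
cerna-screen screen \
    --pulldown-a bundle/pulldown_lineA.tsv --control-a bundle/control_lineA.tsv \
    --pulldown-b bundle/pulldown_lineB.tsv --control-b bundle/control_lineB.tsv \
    --counts bundle/counts.tsv --design bundle/design.json \
    --mirnas bundle/mirnas.fa --utrs bundle/utrs.fa \
    --cohort bundle/cohort.csv -o screen_out/
```

`screen_out/` holds `network_edges.tsv` (core→miRNA and miRNA→gene edges
with binding-site evidence) and `cascade_report.json` (per-stage
cardinalities and the nominated core axis). Add `--verbose` before the
subcommand to log stage sizes to stderr.

## File formats

All text: TSV tag libraries (`mirna_id`, `count`), TSV count matrices
(`gene_id`, `length`, sample columns + JSON design sidecar), FASTA
sequences, CSV cohorts (`patient_id`, `time_months`, `event`, `expr_*`),
CSV ISH specimen tables, JSON reports/target maps/ground truth.
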