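# methpipe

Analysis pipeline for paired tumor/normal nanopore methylomes carrying two
DNA-methylation marks (5mC and 6mA). Starting from per-site methylation
score tables, it:

1. **calls differential sites** — drops sites scoring zero in every sample,
   then calls a site up/down when the tumor/normal score ratio strictly
   exceeds 2-fold, with a rescue rule for one-sided zeros (other side > 0.6);
2. **maps sites to genes** by interval overlap (bedtools-intersect
   semantics, strand-agnostic, 0-based half-open) and tallies per-gene
   up/down counts per mark;
3. **classifies genes** — a gene is *unstable* when it carries all four
   categories (5mC up & down and 6mA up & down); reports 4-set Venn region
   counts, biotype composition vs. the genome background, per-mark Pearson
   correlation of up/down counts, and the ranked top-N unstable list;
4. **tests methylation–expression association** — RPKM normalization,
   strict 2-fold DE calling, and Pearson chi-square of gene class × DE
   status;
5. **screens survival** — median-expression split, Kaplan–Meier curves and
   log-rank tests per gene, selecting p < 0.05 genes and flagging
   tumor-suppressor candidates (down-regulated in tumor, low expression
   associated with worse survival).

Because the motivating data are controlled-access, the package ships a
first-class **synthetic cohort generator** (`methpipe.synthetic`) that emits
all four inputs with planted, parameterized effect structure — per-mark
instability labels, up/down count correlation targets solved in closed form,
DE coupling odds ratios, and survival hazard effects — plus a
`truth.json` ground truth for recovery testing.

## CLI

Each stage is a subcommand; `run` chains them from one YAML config:

```sh
# full run on a synthetic cohort
cat > cfg.yaml <<EOF
top_n: 100
simulate:
  seed: 1
  n_genes: 500
  n_patients: 200
EOF
methpipe run --config cfg.yaml --outdir out/
# -> out/report.json, diff_5mC.tsv, profiles.tsv, labels.tsv, de.tsv, screen.tsv

# or stage by stage
methpipe simulate --config sim.yaml --outdir cohort/
methpipe call-sites --sites cohort/sites_5mC.tsv --sample-sheet cohort/sample_sheet.tsv \
    --mark 5mC --fold 2.0 --zero-rescue 0.6 -o diff_5mC.tsv
methpipe map-genes --diff diff_5mC.tsv --diff diff_6mA.tsv --genes cohort/genes.bed -o profiles.tsv
methpipe classify --profiles profiles.tsv --genes cohort/genes.bed -o labels.tsv --report stats.json
methpipe associate --labels labels.tsv --counts cohort/counts.tsv \
    --sample-sheet cohort/sample_sheet.tsv -o association.json
methpipe screen --survival cohort/survival.tsv --genes top100.txt --de de.tsv -o screen.tsv
```

Exit codes: 0 success, 2 configuration error, 3 data/format error,
4 degenerate-statistics error.

## Formats

* `sites_<mark>.tsv` — chrom, pos0 (0-based), mark, one score column per
  sample (scores in [0,1]); sample sheet maps columns to (pair, condition).
* `genes.bed` — BED6 + biotype (GFF3 gene features also accepted).
* `counts.tsv` — gene_id, length_bp, one count column per sample.
* `survival.tsv` — sample_id, time_days, event, one expression column per gene.
* differential sites — 8-column BED-like TSV (chrom, pos0, end, mark,
  direction, tumor_score, normal_score, rule), natural chromosome order.
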