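# lncflux

Reusable, fully seeded analysis pipeline for fatty-liver (foie-gras-style
force-feeding) goose transcriptomes — and for any bulk RNA-seq design of the
same shape (tissues × two treatments × replicates). It is aimed at
researchers who have assembled transcripts, a reference annotation and an
FPKM-like expression matrix, and want the downstream desk-scale analysis to
be reproducible and testable end to end:

- **lncRNA discovery** by an ordered filter cascade: remove candidates whose
  structure matches the reference (class codes `=` identical intron chain,
  `c` contained), then spliced length < 200 bp, then coding-potential
  score > 1 (built-in longest-ORF heuristic, `score = ORF codons / 100`, or
  an external score table), then mono-exonic transcripts.
- **Positional classification** of each lncRNA against its nearest
  protein-coding gene into sense intergenic, sense genic, convergent
  (3′–3′ facing), divergent (5′–5′ facing) and antisense intergenic, with
  gene-strand-signed distances (downstream negative) and cis-candidate
  annotation for every lncRNA–gene pair within 10 kb.
- **Expression statistics**: FPKM > 0.1 expression filter, per-tissue
  Welch-t/Benjamini–Hochberg differential expression on `log2(FPKM+1)`,
  printed-style DE percentages (half-up, 2 decimals), Venn region counts,
  sample correlation overviews, and PVCA (principal variance component
  analysis) attributing variance to tissue, treatment, their interaction
  and residual via eigenvalue-weighted ANOVA variance components.
- **Co-expression function prediction**: all lncRNA–mRNA pairs with
  Pearson `r > 0.80` and `p < 0.05` across the pooled samples, joined with
  cis proximity and ranked into top cis-regulatory candidates.
- **Ortholog families and enrichment**: longest-CDS transcript selection
  (≥ 50 aa), family categorisation from per-species copy counts
  (one-to-one / expansion / contraction / many-to-many / species-specific),
  DE proportions per category, and 2×2 chi-square gene-set enrichment.
- **Feeding-energy model** of the experimental design: phased force-feeding
  schedule with linearly growing meals vs an ad-libitum control, with exact
  closed-form/day-loop agreement.
- **Synthetic-data generator** that emulates the study's data structure
  with planted ground truth (lncRNA categories, DE genes, correlated
  pairs, family categories), so the whole pipeline is testable without any
  download.

See `docs/methods.md` for the models, estimators and their limits.

## Worked example

The packaged feeding schedule (130 g meals on day 1 growing by 5 g/day;
2 meals/day on days 1–3, 3 on 4–6, 4 on 7–17, 3 on day 18; control eating
325 g/day; both on a 14.29 MJ/kg diet):

```console
$ lncflux energy
{
 "treated_total_g": 10945.0,
 "control_total_g": 5850.0,
 "energy_difference_mj": 72.81
}
```

The force-fed bird eats 10,945 g over 18 days against the control's
5,850 g; the 5,095 g surplus at 14.29 MJ/kg is a cumulative energy-intake
difference of 72.81 MJ per bird.

A full pipeline run on the default synthetic fixture (200 genes + 30
planted lncRNAs, 18 samples):

```python
import lncflux as lx
report = lx.run_pipeline(lx.RunConfig(outdir="demo", seed=42))
```

prints per-stage timers to stderr and writes `demo/report.json` containing,
among others:

```text
discover: {"input_count": 40, "removed_by": {"class": 4, "length": 2,
           "coding": 2, "monoexonic": 2}, "n_lncrna": 30}
classify: {"sense_intergenic": 6, "sense_genic": 6, "convergent": 6,
           "divergent": 6, "antisense_intergenic": 6}
de liver: {"n_de": 19, "percent_de": 8.26}   (of 230 expressed features)
pvca:     {"tissue": 0.992, "treatment": 0.0,
           "tissue:treatment": 0.008, "residual": 0.001}
enrich:   chi-square 61.14, p = 5.3e-15
```

All 40 candidates are accounted for (4 reference-matching, 2 short,
2 coding, 2 mono-exonic removed; the 30 planted lncRNAs survive), the five
positional categories are recovered exactly, the planted ~10% DE fraction
is called at 8.26% in liver, tissue dominates the variance decomposition
as planted, and the planted disease-gene set is strongly enriched among
liver DE genes. The same config and seed reproduce this report bit for bit.

Stage-level subcommands (`lncflux simulate / discover / classify / de /
pvca / pairs / orthologs / enrich / energy / run`) expose the same
functionality on files.

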