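# Methods

`lncflux` implements, as a reusable and fully seeded pipeline, the desk-scale
analysis stages of a force-feeding (foie-gras-style) goose fatty-liver
transcriptome study: lncRNA discovery from assembled transcripts, strand-aware
positional classification with cis-candidate annotation, differential
expression and variance decomposition of an FPKM matrix, correlation-based
lncRNA–mRNA function prediction, ortholog-family categorisation with
gene-set enrichment, and the feeding-energy model of the experimental design.
This note records the models, the numerical choices, and the limits of what
the synthetic fixtures can demonstrate.

## Study design being modelled

Two groups of geese (control, ad libitum, ~325 g feed/day; high-intake,
force fed on a fixed 18-day schedule) on the same 14.29 MJ/kg diet; three
tissues (liver, abdominal adipose, subcutaneous adipose) sampled from three
biological replicates per group, 18 RNA-seq libraries in total. Expression
is FPKM-like and all statistics operate on `log2(FPKM + 1)`.

## Discovery filter cascade

Candidates are removed by the first failing stage, in order:

1. **class** — structural match to the reference annotation. Implemented
   class codes: `=` (identical intron chain on the same strand; terminal
   exon ends free), `c` (exon chain contained in a same-strand reference
   transcript and intron-compatible), with `u`/`x`/`o` as context codes.
   Only `=` and `c` trigger removal; strand-unknown transcripts are also
   removed here under a separate `unstranded` counter since none of the
   downstream strand-aware logic is defined for them.
2. **length** — spliced (summed-exon) length < 200 bp. Spliced length, not
   genomic span, is the conventional lncRNA length measure.
3. **coding** — coding-potential score > 1. The built-in score is
   `longest ORF (codons, 3 forward frames) / 100`, so the threshold of 1
   corresponds to a ~100-codon ORF; an ORF runs from ATG to the first
   in-frame stop (start counted, stop not), or to the last full codon when
   no stop occurs. Externally computed scores (e.g. from an SVM-based
   classifier run against a protein database) can be supplied as a TSV and
   override the built-in score per transcript id (duplicates: last wins,
   logged). The built-in score is a deliberately transparent heuristic; the
   score-table interface is the high-fidelity path.
4. **monoexonic** — single-exon transcripts, which are unreliable at
   assembly level and conventionally excluded from lncRNA sets.

The filter report satisfies the accounting identity
`input = Σ removed + survivors` by construction and is checked at run time.

## Positional classification

Each lncRNA is classified against its nearest protein-coding gene (gap
between genomic spans, exon structure ignored; ties broken to the smaller
gene id). Distances are signed relative to the *gene's* strand: negative
downstream of its 3′ end, positive upstream of its 5′ end, zero when
overlapping.

Categories: same-strand overlap → `sense_genic`; same strand, no overlap →
`sense_intergenic`; opposite strand, no overlap → `convergent` when the 3′
ends face, `divergent` when the 5′ ends face, provided the gap is within a
proximal window (default 10 kb, the same span as the cis window), and
`antisense_intergenic` beyond it. Two opposite-strand transcripts on a line
always face 3′–3′ or 5′–5′, so without a distance bound a generic antisense
class would be empty; reserving convergent/divergent for
terminator/promoter-proximal configurations keeps all five categories
well-defined and matches the worked example in the source study design (an
opposite-strand lncRNA 5.7 kb downstream of its gene is convergent).
Opposite-strand *overlapping* lncRNAs — a configuration the five-class
taxonomy does not name — are resolved by the same facing rule on span
midpoints (ties → convergent) and logged. A lncRNA on a gene-less
chromosome gets a no-neighbor sentinel and falls back to
`sense_intergenic` (logged).

Cis candidates are all (lncRNA, gene) pairs — not only nearest pairs —
with span gap ≤ 10 kb, boundary inclusive. Span-to-span distance (not
TSS-to-TSS) is used throughout.

Coordinates are 0-based half-open internally; GTF I/O converts to/from the
1-based closed convention.

## Expression statistics

- **Expressed**: maximum FPKM across samples strictly greater than 0.1
  (the most permissive deterministic reading; mean aggregation available).
- **Differential expression**: Welch t-test on `log2(FPKM+1)` per feature
  between treatments within one tissue, Benjamini–Hochberg q-values,
  `is_de ⇔ q < 0.05`. This replaces read-level count models (which need
  fragment-level abundance estimates unavailable at desk scale); the
  pipeline's downstream logic depends only on the DE calls. Both-groups
  constant with equal means gives p = 1; constant with different means
  gives p = 0. Fold change uses a 1e-6 pseudo-abundance.
- **Percentages** are rounded half-up to two decimals to match printed
  two-decimal percentages.
- **Venn regions** are exact disjoint membership counts over all
  2^k − 1 set combinations.
- **Correlation overview**: sample–sample Pearson on `log2(FPKM+1)`;
  within-group tissue-pair means average all cross-tissue sample pairs of
  one treatment group; constant samples give undefined correlations that
  are excluded and logged.

### PVCA

PCA is run on the sample–sample covariance of standardised features; the
smallest set of leading PCs explaining ≥ `min_var_explained` (default 0.6)
of total variance is retained. Each PC's score vector is decomposed by a
balanced two-way crossed random-effects ANOVA (tissue, treatment,
interaction, residual) using method-of-moments:
`σ²_e = MSE`, `σ²_ab = (MSAB − MSE)/n`, `σ²_a = (MSA − MSAB)/(bn)`,
`σ²_b = (MSB − MSAB)/(an)`. Negative estimates truncate to zero. Because
positive-part truncation leaves chance mean-square excesses on the factors
under a null design, a factor is additionally pooled into the residual
unless its mean square significantly exceeds the error mean square
(F-test, α = 0.001 Bonferroni-corrected over the retained PCs); the
method-of-moments subtraction then attributes any passing signal between
the factor and its interaction. Per-PC proportions are normalised, averaged with eigenvalue
weights, and re-normalised. The screening is deliberately conservative:
genuinely weak factors (F p-values above ~1e-4/PC) are reported as zero.
Unbalanced designs raise an error pointing to the means-based fallback
(`method="means"`), which applies the same sums with the average cell
size. Note that with the default 0.6 variance threshold a weak factor
whose PC lies outside the retained set contributes nothing; analyses that
need minor factors (e.g. recovering a 3:1 tissue:treatment variance ratio)
should raise `min_var_explained` to ~0.9.

This estimator family differs from the mixed-model (REML) estimator of the
established PVCA package, so published weighted proportions from that
package are not reproduction targets here.

## Co-expression pairs

Pearson r between every lncRNA and every mRNA on `log2(FPKM+1)` across all
18 pooled samples; two-sided p from `t = r√((n−2)/(1−r²))` on n−2 df.
Retention requires signed `r > 0.80` (strict; an absolute-value variant is
a flag) and raw `p < 0.05` (strict; no multiple-testing correction by
default, BH by flag) — the permissive screening convention of co-expression
function prediction. Correlated pairs intersected with the cis list are
ranked by descending r, ties by smaller |distance| then lexicographic ids,
and reported as top-10 cis-regulatory candidates.

## Enrichment and ortholog families

Gene-set enrichment is a 2×2 Pearson chi-square (no Yates correction by
default; both variants exposed) on (in-set) × (DE) over an explicit
universe, which must be supplied — typically the expressed protein-coding
genes. The odds ratio gets a 0.5 continuity increment only when a zero
cell exists (flagged); expected cells < 5 raise a warning recommending an
exact test.

Family categorisation from (focal, reference) copy counts:
(1,1) one-to-one; f>r expansion; f<r contraction; f=r>1 many-to-many;
r=0 focal-specific; f=0 reference-specific (the species-specific class is
split for auditability). Proportions are over families containing the
focal species. Transcript selection upstream keeps the longest CDS per
gene (ties to the lexicographically smaller transcript id) and drops
peptides shorter than 50 aa (strictly fewer; 50 is kept). Sequence
clustering itself (BLAST/hcluster/alignment ranking) is out of scope; the
module consumes a family membership table.

## Feeding-energy model

Meal size grows linearly per calendar day (not per meal):
`meal(d) = base + increment·(d−1)`; meals per day are piecewise constant
over contiguous phases. Total intake has a closed form (arithmetic series
per phase) and a day-loop oracle that must agree exactly. The energy
difference is `(grams_treated − grams_control)/1000 × MJ/kg`, rounded
half-up to 2 decimals; the per-day-increment interpretation is fixed
because it reproduces the published 72.81 MJ difference exactly. The
control's final day is counted for both groups symmetrically (the
overnight feed deprivation before sacrifice cancels).

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions. A fixed `SimulationConfig` (single seed; one independent
`numpy` substream per generation step, labelled by a CRC of the step name)
yields byte-identical files.

- **Annotation**: 200 multi-exon (2–5 exons) protein-coding genes over two
  4-Mb chromosomes, spaced by ≥ 25 kb so every planted lncRNA's nearest
  gene is unambiguously its dedicated host; 6 lncRNAs per positional
  category constructed geometrically (proximal categories at 1–8 kb,
  antisense-intergenic at ~10.25–11.5 kb so it is beyond the 10-kb window
  but still closer to its host than to any other gene).
- **Candidates**: the planted lncRNAs (rejection-sampled sequences with no
  ≥100-codon ORF, so they pass the coding filter) plus decoys removed at
  each cascade stage: reference copies (`=`), exon-contained fragments
  (`c`), sub-200-bp transcripts, transcripts carrying a planted 150-codon
  ORF, and mono-exonic transcripts.
- **Expression**: log-normal FPKM. Per feature: baseline N(4, 1.5²) on
  log2 scale, per-tissue offsets N(0, 1.5²), replicate noise N(0,
  `noise_sd`²) with `noise_sd = 0.15`, treatment shift ±`de_log2fc`
  (default 3, sign random) on a 10% planted DE set per tissue. The default
  replicate noise is deliberately low — the tight-replicate regime in
  which a Welch test at n = 3 has near-complete power — so that planted-
  truth recovery is informative; real biological replicates are noisier
  and would need larger n or a count-based test for comparable
  sensitivity. Planted correlated pairs (10 lncRNA–mRNA pairs) share a
  per-sample latent Gaussian factor with loading √ρ (ρ = 0.95), scaled by
  `noise_sd`, and carry no tissue/DE effects so the planted correlation is
  unconfounded; at `noise_sd = 0` replicates are exactly identical.
- **Families**: 100 families at planted proportions 60% one-to-one, 10%
  expansion, 10% contraction, 5% many-to-many, 10% focal-specific, 5%
  reference-specific, with copy counts drawn within each category's
  defining region.
- **Gene set**: ~30 genes, half drawn from the planted liver DE genes,
  emulating a curated disease-ortholog list that is genuinely enriched.

What the fixtures do *not* emulate: count-level sampling noise and
mean–variance dependence, library-size variation, unannotated strand
errors, overlapping gene models, isoform mixtures, and correlation
structure induced by shared pathways. Passing the planted-recovery tests
therefore demonstrates the correctness of the pipeline's logic and
statistics, not the power of the tests on real data.

## Problem sizes and determinism

Default analyses run on 230 features × 18 samples; oracle-equivalence
checks use ≥1000 randomised placements; Monte-Carlo properties
(pair retention, null PVCA) use 25 and 5 replicate simulations
respectively — sizes at which every check completes in seconds while the
Monte-Carlo error is far smaller than the tested margins. All randomness
descends from a single integer seed.

## Known limitations

- The class-code vocabulary covers only the codes the cascade acts on plus
  minimal context codes; it is not a full transcript-comparison taxonomy.
- The built-in coding score ignores codon usage, conservation and peptide
  homology; it is a screening heuristic with the external-score table as
  the fidelity path.
- The Welch/BH DE caller is anti-conservative for very low counts and
  n = 2; it is intended for FPKM-scale screening, not count inference.
- PVCA's significance-gated method-of-moments reports conservative zeros
  for weak factors and is not an REML mixed-model fit.
- The published study's headline data-dependent numbers (1702 lncRNAs,
  1930 liver DEGs, etc.) depend on sequencing data that is not deposited
  and are out of reach by design; the package validates the machinery on
  planted ground truth instead.
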