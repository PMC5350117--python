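# panelval

Validation analytics for clinical targeted NGS gene panels.

When a diagnostic laboratory brings a disease-specific sequencing panel into
clinical service, it must demonstrate — before the first patient report —
that the assay calls genotypes concordantly with genotype-known reference
samples, that every reportable base reaches a depth floor (with an orthogonal
Sanger "backfill" plan for the bases that do not), that discordant calls
resolve correctly under orthogonal confirmation, and that results are
reproducible across runs, operators, reagent lots and days.  `panelval`
implements that entire post-bioinformatics validation workflow for a
cardiovascular panel family (comprehensive cardiomyopathy and its HCM,
DCM/LVNC, ARVC, MFS/LDS and TAAD sub-panels), plus the clinical triage stage
that turns annotated variants into per-case positive / VUS-only / negative
results.  It consumes the VCF/BED/TSV outputs of an upstream read pipeline;
it does not align reads or call variants.

## The metric suite

Truth and evaluation callsets are harmonized site-by-site over the panel
targets (absence of a record inside a callset's assessed regions means
homozygous reference; matching requires identical chrom, pos, ref, alt) and
tallied into a 4×4 genotype confusion table *C*[e][t] over
{hom-ref, het, hom-alt, missing}.  With non-reference genotypes
NR = {het, hom-alt}:

- **OGC** (overall genotype concordance) = concordant co-called sites / co-called sites
- **NRS** (non-reference sensitivity) = truth-NR sites called NR / truth-NR sites
- **NRD** (non-reference discrepancy) = discordant co-called sites / (co-called sites − concordant hom-ref pairs)
- **NRGC** (non-reference genotype concordance) = truth-NR sites with the exact genotype / truth-NR sites
- **TP** = NR in both; **FP** = evaluation NR, truth hom-ref; **FN** = truth NR, evaluation hom-ref or missing
- precision = specificity = TP/(TP+FP) = 1 − FP rate; sensitivity = TP/(TP+FN) = 1 − FN rate

Zero denominators yield `NA`, never 0 or an exception.  Metrics are
SNV-only by default; indel capability is summarized separately as the
maximum properly detected indel length per genotype state.

Downstream stages: sub-threshold depth runs (strictly below 15×, or 10× as
needed) become Sanger backfill loci, masked as non-reportable when they fall
in unvalidated segmental duplications; Sanger adjudication of provisional
FP/FN calls yields corrected metrics over adequately covered bases;
pairwise replicate comparisons give per-grouping min–max ranges; and a
configurable ordered-rule engine classifies annotated variants into the six
clinical categories.

## Worked example

The analysis drivers under `analysis/` run the whole workflow on a
synthetic comprehensive-panel validation (61 genes, 5,000 truth variants,
planted 7% FP / 4% FN / 1% genotype-error structure, ~301× single-sample
depth with depressed first exons):

```sh
python analysis/01_simulate_inputs.py
python analysis/02_concordance_metrics.py
```

prints

```
joined SNV sites: 5326 (tp 4804, fp 326, fn 196)
sensitivity 0.9608  specificity 0.9365
fp_rate 0.0635 (planted 0.07)  fn_rate 0.0392 (planted 0.04)
OGC 0.8943  NRS 0.9608  NRD 0.1057  NRGC 0.9526
max detected indel: 22 nt homozygous, 30 nt heterozygous
```

— the provisional (pre-confirmation) performance: the planted error rates
are recovered, sensitivity is the complement of the FN rate, and
specificity of the FP rate.  `analysis/04_confirmation_correction.py`
then adjudicates every discrepancy in the evaluation set's favor and
reports the corrected performance over ≥15× bases
(`sensitivity 0.9608 -> 1.0000`, `fp_rate 0.0635 -> 0.0000`), the pattern a
successful confirmation campaign establishes.  Stages 03, 05 and 06 cover
coverage QC/backfill, replicate variability ranges, and the clinical cohort
summary (35 panel requests: 51% CMP, 29% TAAD; 20% positive overall, 28%
for CMP; 43% VUS-only; 37% negative).

A `panelval` console script exposes the same stages
(`simulate`, `concord`, `coverage`, `correct`, `variability`, `case`,
`cohort`, `validate`) for file-based use.

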