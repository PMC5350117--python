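# Methods

## Scope and model

`panelval` models the post-bioinformatics half of a clinical targeted-panel
validation.  The unit of comparison is the *variant site*: a biallelic
(chrom, 1-based pos, ref, alt) key.  Multi-allelic records are decomposed
into one key per alternate allele on ingest, and alleles are trimmed of
shared context (common suffix, then common prefix with position
adjustment).  No realignment or haplotype-aware re-representation is
attempted: two pipelines that encode the same indel differently will count
it as a discordance.  This is acceptable for the SNV-dominated metric suite
(metrics are SNV-only by default) and is the reason indel capability is
reported separately as a detection-limit summary rather than folded into
the rates.

### Absent-call semantics

A genotype-known truth set and a panel evaluation callset are both treated
as *complete over their assessed regions*: a site recorded in one set but
absent from the other is homozygous reference on the absent side if it lies
inside that side's assessed regions, and missing otherwise.  The joined
table is the union of *recorded* sites restricted to the panel targets —
positions never recorded by either side do not enter any denominator.  This
makes OGC and NRD denominators depend on what was recorded, which is the
behaviour validation laboratories actually face when comparing VCFs rather
than gVCFs.

### Metric definitions

From the 4×4 confusion table (evaluation rows × truth columns over hom-ref,
het, hom-alt, missing): OGC = concordant co-called / co-called;
NRS = truth-non-ref with any non-ref evaluation call / truth-non-ref;
NRD = discordant co-called / (co-called − concordant hom-ref);
NRGC = truth-non-ref with exact genotype match / truth-non-ref;
TP/FP/FN are variant-level as defined in the README.  Two specificity
variants are emitted: the call-level `specificity` = 1 − FP/(TP+FP), which
is what panel-validation summary tables report (and which equals
precision), and a site-level true-negative-based `specificity_tn` =
TN/(TN+FP) over the joined table, kept separate because a TN-based rate
over all assessed reference bases would be indistinguishable from 1 for any
realistic panel.  All ratios are computed with exact rational arithmetic
before conversion to float, so equality tests against an enumeration oracle
are exact; undefined (0/0) metrics are `None`/`"NA"`, never 0.  Displayed
metrics round half-up to 2 decimals; full precision is retained internally.

## Coverage QC and backfill

Targets are BED-style 0-based half-open internally; depth files and VCF
positions are 1-based, with conversion isolated in `regions.py` and tested
at both region edges.  Exon targets carry ±2 nt splice padding.  A base is
*deficient* when its depth is strictly below the threshold (default 15×;
10× supported), and maximal runs of deficient bases within a region become
Sanger backfill loci; runs never merge across a base at/above threshold or
across region boundaries, so the partition "deficient bp + bases ≥ t =
targeted bp" holds exactly at every threshold.  Both a per-base and a
per-region "fraction ≥ t" are computed, because published summary tables
are ambiguous between the two; the per-base figure is the headline.  Loci
overlapping a segmental-duplication interval not validated to amplify
unambiguously are flagged non-reportable — Sanger cannot resolve a unique
locus there — while validated SegDup loci pass through normally.

## Confirmation correction

Orthogonal (BigDye/Sanger) outcomes reclassify provisional discordances:
FP + confirmed-present → TP (the reference set was incomplete);
FP + confirmed-absent → the call is removed from the reportable set, with
the raw count preserved in an audit block (the clinical workflow confirms
before reporting, so an artifactual call never reaches a report — keeping
it as an FP would misstate reportable performance); FN + confirmed-absent
→ the truth record dissolves to concordant hom-ref; FN + confirmed-present
remains a genuine miss.  Failed reactions exclude the site with a warning
(how failed reactions were handled historically is not documented anywhere
we know of; exclusion-with-audit is the conservative choice).  Corrected
metrics are then recomputed over sites at bases with depth ≥ threshold,
since sub-threshold bases are the backfill's responsibility.  SegDup
exclusion from corrected denominators is off by default and
flag-controlled.  Conservation (corrected TP+FP+FN + removed + failed +
depth-excluded = provisional TP+FP+FN) is asserted in tests.

## Replicate variability

Every ordered pair of same-sample replicates is compared with the full
metric suite — each replicate serving alternately as comparison and
evaluation set, because NRS and NRGC are directional.  Pairs are grouped
intra-run (same run) or inter-run, with additional inter-operator /
inter-lot / inter-day tags per differing factor; comparisons against an
external genotype-known callset reuse the engine under `vs_secondary`.
Summaries report min–max per metric per grouping.  A pair with fewer than
10 truth-side non-reference sites (configurable) is excluded as
under-powered, and a grouping with no powered pairs reports NA — a
handful of variants cannot support a stable concordance range.  No
variance-component modelling is attempted; ranges are what validation
tables report.

## Variant triage

Classification into pathogenic / likely pathogenic / gene modifier / VUS /
likely benign / benign is a deterministic ordered-rule engine: first
matching rule wins, no match defaults to VUS.  Conditions cover database
presence, consequence class, population-frequency ceilings (an unobserved
frequency satisfies any rarity ceiling), an in-silico deleterious-consensus
count (string calls like "D"/"damaging" or numeric values ≥ 0.5 count as
deleterious), and a configured gene-modifier list.  The default ceilings
(benign ≥ 5%, likely benign ≥ 1%, "rare" < 0.1%) are deliberately relaxed
relative to strict monogenic assumptions, fitting cardiac disorders where a
non-trivial fraction of cases carry two or more deleterious variants; every
threshold is exposed in YAML config, and the defaults are declared choices,
not assertions about any historical laboratory's exact procedure.  A case
is positive with ≥1 pathogenic/likely-pathogenic reportable variant,
VUS-only with ≥1 VUS and no P/LP, else negative; variants in unvalidated
SegDup loci are excluded from the reportable set.  Reflexed panels produce
a second report for the same patient rather than a merged one.

## Synthetic data generator

The generator emulates the validation design so every stage runs with no
external data: 61 genes (comprehensive-panel scale) of 3–8 exons of 90–240
bp laid out collision-free on one synthetic chromosome; truth variants
uniform over target bases without collision, het with probability 0.6;
evaluation callsets built by dropping truth variants at the FN rate,
flipping het↔hom-alt at the genotype-error rate, and adding
Binomial(n, FP rate) spurious calls at distinct non-variant target
positions (alt allele uniform over the three non-reference bases —
off-target calls are never produced, matching a targeted pipeline).
Depth is negative-binomial per base (variance μ + μ²/k, dispersion k = 60)
with mean 301.25× for single-sample runs and 117.48× for three-sample
pools — the two observed plexing regimes — scaled by a first-exon
multiplier that models GC-driven capture loss.  Replicates share the truth
and receive independent error draws at a 1% noise scale, with labels
cycling runs, operators, lots and days so every variability grouping
occurs.  Every artifact is a deterministic function of the seed (string
streams are digested stably, not via the salted built-in `hash`), and
generated files are byte-identical across runs.

What the generator does *not* model — and what passing tests therefore do
not show about real data: positional correlation of depth (bases are
independent given the regional mean, so deficient runs are single bases to
a few bp rather than probe-scale gaps; counts of backfill loci are
structurally, not numerically, comparable to a real panel's), error
clustering in homopolymers or at GC extremes, mapping artifacts inside
segmental duplications (SegDup status is geometric, not sequence-derived),
indel representation ambiguity, and contamination or sample swaps.

## Problem sizes and numerical choices

The analysis drivers and the acceptance script use the comprehensive-panel
scale the package was designed around: 61 genes (~55 kb of targets), 5,000
truth variants, 20 seeds for the rate-recovery check — sizes at which
binomial standard errors on the planted 7%/4% rates are ~0.4%/0.3% and the
whole pipeline runs in seconds.  Recovery is asserted within 3 binomial
SEs per seed.  Note the measured FP rate is FP/(TP+FP) while the generator
plants spurious calls per truth variant, so its expectation is
0.07/(0.96+0.07) ≈ 0.068 rather than 0.070 — well inside the assertion
band, and a reminder that "FP rate" definitions matter.  Ties in display
rounding go half-up (clinical-table convention, e.g. 28.57% → 29%).
Degenerate inputs (empty joined tables, all-missing callsets, zero-variant
truth sets, empty backfill manifests) return well-typed empty results or
`NA`, not exceptions; genuinely invalid inputs (ref-allele conflicts,
contradictory confirmations, malformed rules, cross-sample replicate
pairs) raise typed errors.

## Known limitations

No CNV or structural-variant awareness (deletions up to tens of nt only),
no phasing, no haplotype comparison, no mosaicism modelling, no
annotation computation (consequences, frequencies and in-silico scores are
consumed as given), and no chromatogram analysis (confirmation outcomes
are consumed as adjudicated labels).  The rule engine is a configurable
approximation of ACMG-style evidence combination, not a reimplementation
of it.
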