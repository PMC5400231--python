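# Methods

## Model and procedure

The package implements a candidate gene-set burden design for very small
case/control cohorts of CNV carriers. Its stages, in order:

1. **Variant triage.** A subject-level call enters the analysis iff it
   (a) passes upstream quality (`FILTER` pass; the upstream caller's score
   logic is consumed as a boolean, not reimplemented), (b) is rare —
   alternate allele frequency strictly below `rarity.threshold` (default
   0.01) in *every* reference panel present in the annotation table,
   ethnic subgroup panels included, and (c) lies in a diploid region:
   autosomal (chromosomes 1–22, `chr` prefix normalized) and not
   hemizygous — except inside the subject's declared deletion interval,
   where hemizygous calls are retained because a deletion carrier's single
   copy is the entire genotype there. A variant absent from a panel is
   treated as satisfying the rarity bound (unobserved ⇒ rare); this is
   configurable (`missing_is_rare`).
2. **Impact classification.** Stop-gain, frameshift and core splice-site
   changes are loss-of-function and count regardless of predictor scores.
   Missense variants are damaging when ≥ `criteria_required` (default 4)
   of seven criteria hold, with the boundary semantics exactly as stated:
   PhyloP placental ≥ 2.3, PhyloP 100-vertebrate ≥ 4.0 (two independent
   criteria), SIFT ≤ 0.05, PolyPhen2 ≥ 0.90, Mutation Assessor ≥ 1.9,
   CADD Phred ≥ 15, MutationTaster **strictly** > 0.5. A missing score
   fails its criterion (conservative default). A sensitivity mode
   (`missing_policy="exclude"`) instead drops missing predictors from the
   denominator and requires the same 4/7 proportion among those present
   (no scores present ⇒ not damaging); the proportional form was chosen
   because it reduces to the default rule when all seven are present.
   Multi-transcript annotations collapse to the most severe effect
   (LOF > missense > other).
3. **Burden and tests.** Per-subject set burden counts each qualifying
   heterozygous/hemizygous variant once (homozygous variants are tabulated
   separately, not added to the burden). Group comparison is the
   unequal-variance Welch *t* with Welch–Satterthwaite df — not the pooled
   test, which does not reproduce the reference cohort's printed p-values
   from its printed counts. The one-sided tail is an explicit parameter:
   `cases_greater`, `controls_greater`, or `observed` (the tail of the
   observed mean difference, i.e. half the two-sided p) — explicit because
   the reference analysis itself mixes conventions (its schizophrenia
   negative control is a fixed case-greater tail, its other tests follow
   the observed direction). The non-parametric check is a rank-sum test
   that enumerates all C(nx+ny, nx) assignments of pooled midranks when
   nx+ny ≤ 12 (exact and tie-aware; all-tied input returns 0.5 by symmetry
   convention), falling back to the normal approximation above that.
   BH-FDR (statsmodels step-up) is applied across the gene-set × class
   family of one run. The total-burden adjustment converts each subject's
   set count to the proportion of their genome-wide qualifying variants
   and Welch-tests the proportions; the method tag is recorded in the
   result so alternatives (e.g. residualization) can be plugged in — the
   reference analysis does not state its adjustment, and the proportion
   form was chosen for its scale invariance.
4. **Empirical specificity.** Random gene-sets of the hypothesis set's
   size are drawn uniformly without replacement (independent across
   draws) from the eligibility pool: genes with ≥ 1 GO annotation of
   ≤ 500 genes (term sizes taken as given; no ontology traversal) outside
   every hypothesis set. The reported specificity is the fraction of
   random-set p-values *strictly* below the observed p. Degenerate random
   sets (zero pooled variance) are dropped from the null rather than
   assigned a p.
5. **Polygenic score.** Natural-log odds ratios (the ISC-style scoring);
   a GWAS SNP is used only if every subject has a callable genotype with
   alleles inside the SNP's allele pair — no strand flipping or
   ambiguous-site rescue, skips are counted and logged. Effect-allele
   orientation is the data supplier's contract.

## Coordinates and formats

Internal coordinates are 0-based half-open; VCF, the annotation sidecar,
GWAS and genotype tables are 1-based at the file boundary, BED is 0-based.
The annotation sidecar is the canonical transport (ANNOVAR-multianno
shape, keyed by chrom/pos/ref/alt; every non-reserved column is an
allele-frequency panel); VCF `INFO` ingestion is deliberately not relied
on. Gene symbols are compared case-sensitively after whitespace trimming;
alias resolution is upstream's job. Multi-allelic records must be split
upstream (one ALT per record).

## Synthetic cohort generator

`simulate_cohort` emulates the reference study conditions by default:
3 cases vs 6 controls; a 1000-gene target set inside a 1561-gene ranked
candidate list over 5000 genes; control target-set damaging-missense mean
4.8 per subject with case enrichment 10/4.8 (the reference group means);
genome-wide background damaging-missense mean 85 outside the target set
(total ≈ 90–105 per subject) and LOF mean 14; a ~2.6 Mb hemizygous
deletion on chromosome 22 carrying its own gene complement; GWAS summary
statistics with cohort genotypes. Counts are independent Poisson per
subject × gene — benign missense variants are an independent stream, so
damaging counts stay exactly Poisson after classification. Scores for
intended-damaging variants are drawn past 4–7 randomly chosen thresholds
with margin and intended-benign ones past at most 3 (boundary cases are
exercised directly in tests, not generated); failing predictors go
missing with probability 0.2, which cannot change the classification
under the default missing policy. Common (≥ threshold in one panel),
low-quality, non-autosomal and synonymous streams exist solely to give
the filters work. Seeds are split per component (`SeedSequence.spawn`) so
resources regenerate independently.

What the generator does **not** emulate: linkage disequilibrium,
haplotypes, mutation spectra, per-gene length/mutability variation,
relatedness, batch effects, or annotation errors. Passing tests therefore
show the *pipeline machinery and its statistics* behave as specified
under the stated count model — not that the biological conclusions would
replicate on real genomes.

## Numerical choices and degenerate inputs

- Welch with zero pooled variance raises a flagged
  `DegenerateStatisticsError`; the pipeline records such tests as NaN
  rows (e.g. an all-zero candidate set) and excludes them from the BH
  family rather than inventing a p.
- Exact Wilcoxon uses midranks with a 1e-9 tie tolerance on rank sums;
  the `observed` tail picks the side of the statistic relative to its
  permutation mean.
- Random-set draws use a PCG64 generator over the *sorted* pool for
  determinism; the vectorized index sampler (argpartition of uniform
  keys) realizes the same uniform without-replacement law and is used on
  the gene-level count-matrix fast path.
- p-values are kept at full precision; comparisons against the reference
  tables round to their printed two decimals.

## Replicate-study problem sizes

Calibration and recovery studies run at sizes chosen to make their
Monte-Carlo error small relative to the asserted margins: 2,000 replicate
cohorts for direction-recovery (observed ≈ 99.7% vs the ≥ 95% claim) and
for type-I error at unit enrichment; 1,000 replicate cohorts × 150 random
sets × 400 genes for the uniformity of the empirical specificity under
the null (Kolmogorov–Smirnov). The type-I acceptance band is
[0.025, 0.085] around the nominal 0.05, fixed a priori: Welch on Poisson
counts at n = 3 vs 6 is an approximate test, so calibration error beyond
pure Monte-Carlo noise is expected. The full file-level pipeline
(VCF → results) runs end-to-end at a 600-gene scale in the tests; the
statistics are invariant to that scale by construction of the count
model.

## Known limitations

- The reference count table's top-1000 LOF row is internally inconsistent
  (its printed control mean does not match its printed counts), and the
  faithful Welch p from the printed counts is 0.2847, one rounding unit
  below the printed 0.29; the package reports the computed value.
- Under exact tie-aware enumeration the genome-wide missense rank-sum
  check (p = 0.048) crosses α = 0.05 while the Welch test (p = 0.069)
  does not; the Welch/Wilcoxon agreement claim is checked on the
  candidate gene-sets.
- The variant-gene rank comparison (`rank_comparison`) defines the case
  vs control mean priority rank with a one-sided Welch test on ranks;
  pooled case ranks of the bundled variant list average ≈ 453, so
  alternative published summaries based on undeposited rank definitions
  are not asserted.
- PRS values on real cohorts depend on external GWAS tables and genomes;
  the package validates the scoring algebra and matching rules, not any
  particular published score.
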