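# Methods

This note documents the statistical procedures, the synthetic-data
generators that stand in for sequencing-derived inputs, and the numerical
and design choices a maintainer would want to know.

## Paired cohort design

Every expression analysis assumes a paired design: each patient contributes
one tumor and one matched adjacent-normal sample, and the per-patient log2
fold change `tumor − normal` (on log2 normalized expression) is the basic
observation. Cohort comparisons are therefore comparisons of
within-patient changes, which removes between-patient baseline variation.
Default cohort sizes are 21 early-onset and 22 later-onset patients, the
study conditions the package emulates.

## Normalization stand-in

Upstream differential-expression tables are treated as *inputs*: the
package does not reimplement any published DE model's dispersion shrinkage
or Wald testing. Where a normalized matrix is needed and only counts are
available, the stand-in is `log2(c/s + 1)` with median-of-ratios size
factors `s` (each sample's median ratio to the per-gene geometric mean over
genes detected in all samples). All downstream rules operate on whatever
normalized matrix they are given; no equivalence with a variance-
stabilizing transformation is claimed. `de_table_from_counts` likewise
exists only so the filter cascade can be exercised end-to-end on synthetic
counts: `base_mean` is the mean size-factor-normalized count, `lfc` the
mean per-patient difference of log2 values, `padj` a Benjamini–Hochberg-
adjusted per-gene paired t-test.

## The uniqueness cascade and refinement

Thresholds (all strict, as the rules are stated): cohort significance at
padj < 0.05, |LFC| > 1, mean counts > 50; late-cohort non-significance at
padj > 0.2, |LFC| < 0.7, mean counts > 50; LFC divergence at
|LFC_eo − LFC_lo| > 1.5 requiring either |LFC_eo| > |LFC_lo| or
opposite significant directions. Missing adjusted p-values are
non-significant, never zero. When both the non-significance rule and the
divergence rule hold, provenance records the non-significance rule. The
signed difference of fold changes is used; a difference-of-absolute-values
reading is available behind `PipelineConfig.lfc_difference_on_abs`.

The refinement applies the Wilcoxon signed-rank test to per-patient LFCs
within each cohort, dropping zero differences, using the exact null
distribution for up to 25 nonzero tie-free pairs and a continuity-corrected
normal approximation otherwise (the defaults of the R environment, so
results line up with common practice). A candidate is kept when the early
test is significant (p < 0.05) and the late cohort is clearly null
(p > 0.25), or both are significant with opposite median-LFC signs or a
median-LFC gap above 1.5. Cohorts with fewer than five pairs are rejected
as underpowered. Genes with a late p between 0.05 and 0.25 fall in a
deliberate gray zone and are excluded.

## Contingency statistics

The Fisher odds ratio is the conditional MLE under the noncentral
hypergeometric likelihood with margins fixed, with a 95% CI from inverting
the one-sided tail probabilities at 0.025 per side; this (not the sample
odds ratio ad/bc, which is reported alongside) is the convention that
matches the reproduced worked example. The two-sided p sums hypergeometric
probabilities no larger than the observed table's (the minimum-likelihood
convention). The 2×2 chi-square always applies the Yates correction,
clamped at zero; an uncorrected mode exists (`correction=False`). The
correction is adopted because it reproduces the reference clinical-table
p-values to four decimals; tests verify the CI inversion to 1e-6 and
compare the exact p to an enumeration oracle. One property worth noting:
the Yates p tracks the *central* two-sided exact p (twice the smaller
hypergeometric tail) within 0.01 once all cells reach 20, but can differ
from the minimum-likelihood two-sided p by considerably more at moderate
p; the test suite checks the form that actually holds.

## Survival risk model

The Cox partial likelihood with Breslow tie handling is maximized by
Newton iterations on standardized covariates (coefficients are returned on
the original scale), with step-halving, a gradient-norm stop at 1e-6, a
100-iteration cap, and errors on singular information (collinear genes),
separation (|standardized β| > 50), fewer than 10 events, or constant
genes. Breslow ties were chosen because day-resolution synthetic times
rarely tie, making it the simplest consistent choice; on tie-free data the
fit matches an independent implementation to 4+ decimals (verified in
tests). The risk score is the plain linear predictor; the median split
assigns scores equal to the median to the high-risk group (for an even
number of samples the median is the midpoint of the central order
statistics). The log-rank statistic sums observed-minus-expected events
over distinct event times with the hypergeometric risk-set variance;
Kaplan–Meier estimation beyond what the test needs, and plotting, are out
of scope.

## Cell-score summaries

Only the 64 individual cell types enter the proportion denominator;
composite immune/stroma aggregates would double-count their members and
are excluded. The lymphoid/myeloid/other membership of the 64 types ships
as a package data file following the deconvolution tool's published
lineage annotations (lymphoid and myeloid progenitors with their lineages;
stem, stromal and epithelial types under "other"); this assignment is not
fully derivable from the source material, so it is isolated in a
user-overridable two-column TSV. PCA selects the top-variance features,
centers each feature and projects samples via SVD; PSI matrices reuse it
unchanged after per-event mean imputation of missing values (the imputed
fraction is warned about). Top differential types are ranked by unpaired
test p with |median difference| as tie-break; an all-null table still
yields a ranking, flagged non-significant.

## Splicing reconciliation

Internally every interval is 0-based half-open; the two caller dialects
are converted at the I/O boundary and the harmonized match key is
`(chromosome, 1-based coordinate)` — variable-region start + 1 for
junction-count events, the 1-based start for node-level events, and the
end coordinate for alternative 3′ splice sites, which the two callers
describe from opposite ends. Matching is by coordinate key only, not by
event-type label or ΔPSI sign (an optional strict mode adds sign
agreement). Mutually-exclusive-exon events are keyed by the 5′-most
alternative exon's start, a choice the source conventions leave open, and
it is logged per event. Minus-strand events keep their genomic coordinates
with no strand-dependent reinterpretation of "start". Duplicate keys
within one caller collapse to the smallest-FDR (largest-probability)
record before matching. Cohort-unique events are a set difference on match
keys: with 82 early, 191 late and 49 shared events this yields 33, the
arithmetic the reconciliation is expected to reproduce. ΔPSI is always
tumor − normal; readers take a sample-order argument rather than guessing
which group was first.

## Neoantigen candidates

Flanks are exon-adjacent (the last/first 27 nt of the annotated flanking
exons), not genome-adjacent, so extracted sequences contain no intronic
bases; 27 nt = 9 codons makes junction-spanning 9-mers possible. Flanks
clamp to short exons with a warning; a missing flanking exon degrades to
fewer blocks. A translation frame containing any stop codon is discarded
whole (a truncation mode exists behind `PipelineConfig.truncate_at_stop`
for callers that want it; the default matches the construction being
emulated). The binding predictor is pluggable — any
`(peptide, allele) → percent rank` callable — and the package ships a
deterministic MD5-hash mock whose unplanted ranks always exceed 0.5, plus
a peptide FASTA writer for external predictors. Duplicate peptides from
different frames or events keep separate provenance.

## Synthetic-data generators

Every generator is a pure function of its spec (seed included); identical
specs give bit-identical outputs.

* **Counts**: negative binomial with dispersion 0.1 (typical bulk RNA-seq
  scale), per-gene log-normal baselines, library sizes log-uniform over a
  4× range with a mild log-normal patient effect. Planted genes carry a
  |log2 fold change| of 3 in early-onset tumors only and have baselines
  forced high enough to clear the mean-count filter, so cascade recovery
  measures the filter logic rather than detection power.
* **Signature refinement fixture**: expression matrices are constructed
  directly with controlled per-patient differences — planted signature
  genes have exactly zero late-cohort differences (signed-rank p = 1),
  non-signature candidates carry a tie-free difference pattern whose exact
  signed-rank p falls in the excluded (0.05, 0.25] band. This makes the
  planted signature deterministically recoverable, which count-level noise
  cannot guarantee.
* **Splice tables**: planted significance is written directly into the
  dialect columns (FDR/probability/ΔPSI/counts) rather than re-derived
  from simulated reads, because the reconciliation logic starts at caller
  outputs. The universe contains early-only/shared/late-only events,
  single-caller events (so concordance sits near 80%, not 1), and decoys
  failing exactly one filter each.
* **Toy genome**: random uniform ACGT, cassette events on both strands;
  ground-truth peptides come from direct string slicing and a codon table
  local to the generator, independent of the BED12 extraction path they
  validate.
* **Survival**: exponential times with hazard `h0·exp(score)`
  (h0 = 1/1000 per day), censoring by an independent uniform time whose
  window is calibrated to ~30% censoring at baseline — uniform censoring
  keeps the log-rank calibration tests stable.
* **Cell scores**: gamma-distributed around per-type log-normal baselines
  with planted multiplicative shifts per (type, cohort, tissue) stratum.

What the generators do **not** emulate: read-level noise, alignment and
counting artifacts, correlated gene modules, batch effects, covariate
structure between cohorts, or informative censoring. Passing tests
therefore certify the decision logic, coordinate handling and statistical
calibration of the pipeline — not its behavior under real-data pathologies
upstream of its inputs.

## Problem sizes used in tests

The suite runs the cascade on 2,000 genes × 43 patients, reconciliation on
the 82/191/49 planted configuration, peptide validation on 100 fuzzed
events, Cox recovery at n = 500, and calibration checks at 200–500
replicates; these sizes give stable assertions while keeping the whole
suite around ten seconds.

## Known limitations

* The eight-coefficient risk model's published coefficients are not
  available, so exact score reproduction is impossible; correctness is
  established by parameter recovery on synthetic survival data instead.
* The uniqueness cascade and refinement share the 1.5 LFC-difference
  threshold, so on clean planted effects refinement rarely removes
  divergence-rule genes; the distinction only matters on noisy data where
  table statistics and rank tests disagree.
* Exact r×c tests (beyond 2×2) and multiple-testing correction across
  clinical tables are out of scope, as are the upstream DE model,
  deconvolution scoring, subtype calling, enrichment engines and the
  neural binding predictor.
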