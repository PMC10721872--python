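# Methods

## The scoring model

The OE score treats a gene signature's activity in a sample as the mean
*centered* expression of its genes, referenced against random gene sets of
the same expression profile. Centering (per-gene mean subtraction across
samples) stops highly expressed genes from dominating the mean; the
bin-matched null subtracts what a signature of equally expressed genes
would have scored, which removes per-sample technical effects (library
depth, capture efficiency) that move all genes together. The method assumes
the matrix is on a log-like or otherwise variance-comparable scale and
that samples are exchangeable within a cohort; it does not model batch
structure.

Expression bins are **equal-frequency** (rank-quantile) bins of the
per-gene average expression, not equal-width: frequency matching in the
null only controls expression level if every bin holds comparably many
genes, and equal-width bins on log expression would leave extreme bins
nearly empty. Ties in average expression are broken by stable input order,
and when the gene count is not divisible by the bin count the earlier bins
take the extra genes (sizes differ by at most one). Binning is computed
once from the full matrix and reused for all null draws, since the average
expression is defined across all samples.

Null draws are uniform **without replacement within each bin**, and the
signature's own genes are eligible: excluding them would bias the null low
and break the useful identity that a signature occupying complete bins has
OE exactly zero (every draw is then forced to the same gene set).

For single-cell matrices the stored values are log2(TPM/10 + 1); the
average expression branch un-logs to TPM space before averaging so that
the per-gene mean reflects abundance rather than the mean of logs. A
helper (`tpm_to_log2tpm10p1`) produces the storage scale from raw TPM.
Bulk matrices are scored on whatever normalized scale the caller declares;
the package records the declaration rather than guessing a normalization.

### RNG contract

Each gene list's null uses its own `numpy` generator seeded from
`SeedSequence([seed, key])`, where `key` is a SHA-256 digest of the sorted
gene list. Draws iterate bins in ascending order; each bin contributes
exactly the signature's count of its members, drawn with
`Generator.choice(members, size=count, replace=False)`, members in matrix
gene order. Consequences, all covered by tests:

- results are deterministic given `(seed, matrix, signature)` and
  independent of the order genes are listed in a signature;
- the up- and down-arm nulls are independent (different lists give
  different streams), which resolves the open question of whether the two
  arms share draws;
- swapping the up and down lists exactly negates the score, because each
  list's null is identical in both roles. A single sequentially consumed
  stream could not provide this exact antisymmetry, which is why the
  per-list keying was chosen.

### Numerical choices

- `signature_score` sorts gene indices before averaging, so scores are
  bit-identical under signature permutation and the forced-draw identity
  holds exactly.
- The null mean is accumulated as differences from the signature score
  (`S_K + mean(S_K' − S_K)`), making the forced-null OE exactly 0.0 rather
  than 0 ± accumulation error.
- The score/OE tables are written at 12 significant digits, which
  round-trips through TSV at the precision the tests assert.

## Stratification

Fixed-cutoff labeling calls a sample mutation-like iff its score is
*strictly* above the cutoff; median splitting calls it high iff strictly
above the median. Boundary ties therefore go to the lower group — a
convention, recorded in the output metadata, chosen so the two rules share
one comparison. The single-cell default cutoff −0.0025 is a user parameter
(it reflects the valley of one particular bimodal score distribution);
`find_bimodal_cutoff` locates such a valley on new data via a
two-component Gaussian mixture and is what the synthetic recovery
experiments use. Two-group comparisons use the exact Wilcoxon rank-sum
distribution when the pooled sample is ≤ 20 and tie-free (reproducible at
toy scale), the tie-corrected normal approximation otherwise;
three or more groups use Kruskal–Wallis. Completely constant data returns
statistic 0, p = 1 instead of failing.

## The two-stage screen

Differential expression uses Welch's t per gene on log-scale values. The
original analysis of this kind is typically run through limma's moderated
t; empirical-Bayes variance moderation mainly matters at very small n, and
re-implementing it is out of scope here, so Welch is used and this stands
as a deliberate, documented deviation. Zero-variance genes get p = 1 when
the group means agree and p = 0 when they differ.

The survival filter is computed only for genes that pass the DE filter
(the screen is a two-step procedure), and the BH adjustment for the KM and
Cox families is correspondingly over that gene set; `survival_on="all"`
computes survival statistics for every gene instead. The KM arm splits
each gene at its median expression (the split rule is otherwise
unspecified; median is the convention used for every other split in this
pipeline); the Cox arm uses continuous per-gene standardized expression
with Efron tie handling. Retention requires both arms significant
(`require_both=False` relaxes to either). BH is implemented in-package
with the canonical step-up scaling `p·m/rank` so it agrees exactly with a
literal application of the rule; statsmodels' implementation serves as an
independent cross-check in the tests.

## The risk model

Candidate-gene expression is standardized per gene before the penalized
fit — L1 paths are scale-sensitive and the candidate genes arrive on
heterogeneous scales — and the coefficients are reported on the
standardized scale with the training means/SDs stored in the model, so a
validation cohort is placed on the training scale via
`RiskModel.standardize`. The L1 path comes from scikit-survival's Coxnet;
the penalty is selected at minimum mean 10-fold cross-validated
partial-likelihood deviance, each fold's deviance computed as
−2·(ℓ(all) − ℓ(train)) with a Breslow partial log-likelihood implemented
here (the subtraction form is stable when per-fold event counts are
small; scikit-survival ships no deviance-based CV). Fold assignment is
drawn from the run seed. Genes with zero coefficients at the selected
penalty are dropped; constant genes are dropped before fitting with a
warning.

`krd_score` is the exact linear combination Σ Exp·Coef on the matrix it is
given — deliberately not affine — so it is exactly linear in the
expression profile; standardization is a separate, explicit step. Median
splitting of the score reuses the stratification module. Evaluation
reports the high-vs-low log-rank p, the Cox hazard ratio of the
high-group indicator, and the cumulative/dynamic time-dependent AUC with
inverse-probability-of-censoring weights (the estimator is otherwise
unspecified; this is the standard right-censoring-aware choice). Horizons
outside the observed follow-up are dropped with a warning; a cohort whose
scores are all identical is reported as degenerate rather than producing
an arbitrary hazard ratio. A seeded 60/40 train/validation split,
stratified by event status, is provided as a utility.

## Synthetic data

The generator produces the structure the pipeline assumes and nothing
more: two sample groups; a planted signed signature (defaults 50 up + 30
down, matching an 80-gene signature) shifted ±δ (default 1.5 log2 units)
in the mutation-like group (default fraction 0.4); Gaussian log-scale
noise (σ = 0.5) around per-gene baselines spanning a wide log2 range so
the expression bins are non-trivial; exponential survival with hazard
5·10⁻⁴ · exp(β·z) per day, where z is the standardized planted score and
β defaults to 1 per SD; and uniform censoring whose window is bisected to
hit the target censored fraction (default 0.3) on the realized event
times, warning if the achieved fraction misses by more than 0.05. The
single-cell generator adds a per-cell log2 library factor (SD 0.2) and
mean-dependent dropout (logistic in log2 mean expression, midpoint 3,
slope 1), then stores log2(TPM/10 + 1). Values are generated directly on
the log scale rather than as negative-binomial counts: every in-scope
operation consumes normalized/log values, so count-level realism would be
invisible to the pipeline.

All randomness flows from one seed through documented sub-streams
(expression, survival, censoring), so outputs are bit-reproducible, and
the truth records carry every planted quantity (genes, per-sample scores,
group membership, achieved censoring) so tests can recompute them
independently.

What passing tests on this data do **not** show: robustness to batch
effects, cell-type mixtures, count-level overdispersion, non-proportional
hazards, informative censoring, or gene universes that only partially
overlap a signature — real cohorts have all of these, and results there
depend on preprocessing choices this package deliberately leaves to the
caller.

## Problem sizes

The test and acceptance runs use desk-scale cohorts chosen to exercise
every code path with clear planted signal: random matrices up to 50 × 20
for oracle equivalence, 1000-gene matrices for null calibration, 2000
genes × 500 cells for single-cell recovery, 400 samples × 80 candidate
genes for risk-model recovery, and a 1200-gene × 300-sample cohort for
the end-to-end acceptance analysis.

## Known limitations

- The DE stage is Welch's t, not a moderated linear model; at n < ~10 per
  group its variance estimates are noisy.
- The Cox screen fits one gene at a time; correlated genes will co-pass.
- Penalty selection refits the Coxnet path per fold at the full-data alpha
  grid; with very few events per fold the deviance curve can be flat, and
  the selected model may then be unstable across seeds (the null-selection
  test quantifies this).
- The bin-matched null corrects expression level only; it does not match
  gene-gene correlation, so OE variance is signature-dependent.
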