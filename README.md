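# krdsig

Gene-signature scoring and prognostic risk modeling for KRAS-driven colon
cancer transcriptomics, for computational biologists who want the full
analysis chain — signature quantification, sample stratification, signature
derivation, and survival-based risk scoring — as reusable, tested library
code that runs on bulk or single-cell expression matrices.

## What it computes

**Overall-expression (OE) score.** For an expression matrix *C* (genes ×
samples, *N* samples), the per-gene average expression is

- bulk: *E<sub>i</sub>* = Σ<sub>j</sub> *C<sub>i,j</sub>* / *N*
- scRNA-seq (values stored as log₂(TPM/10 + 1)):
  *E<sub>i</sub>* = log₂( Σ<sub>j</sub> 10·(2^*C<sub>i,j</sub>* − 1) / *N* + 1 )

Genes are ranked by *E<sub>i</sub>* into 50 equal-frequency expression bins,
and the matrix is row-centered, *Z<sub>i,j</sub>* = *C<sub>i,j</sub>* −
Σ<sub>j</sub> *C<sub>i,j</sub>*/*N*. The raw score of a gene set *K* for
sample *j* is the mean of *Z<sub>i,j</sub>* over *i* ∈ *K*. The OE score
subtracts the mean raw score of 1000 random signatures *K′* that match *K*'s
per-bin gene frequency:

&nbsp;&nbsp;&nbsp;&nbsp;OE = *S<sub>K</sub>* − Σ<sub>n</sub> *S<sub>K′ₙ</sub>* / 1000

which corrects for expression-level-dependent signal-to-noise. A signed
signature (up- and down-regulated arms) scores as OE = OE<sub>up</sub> −
OE<sub>down</sub>.

**Stratification.** Cells are labeled *mutation-like* above a fixed OE
cutoff (default −0.0025, the valley of the bimodal single-cell score
distribution); bulk samples and risk scores are split at the median.
Group score distributions are compared with Wilcoxon rank-sum /
Kruskal–Wallis tests.

**Two-stage signature screen.** Differential expression between the groups
(Welch's t on log-scale values; keep BH-adjusted *p* < 0.01 and |log₂FC| >
1), then a survival filter on the surviving genes: Kaplan–Meier log-rank at
the per-gene median split *and* univariate Cox on standardized expression,
both at BH-adjusted *p* < 0.05. Retained genes form a signed signature by
fold-change sign.

**KRD risk score.** A LASSO-penalized Cox model over the signature genes,
with the penalty λ chosen at the minimum cross-validated partial-likelihood
deviance. The risk score is the linear combination
score = Σ *Exp<sub>i</sub>* × *Coef<sub>i</sub>*; cohorts are split at the
median score and evaluated by log-rank test, hazard ratio, and
inverse-censoring-weighted time-dependent AUC.

A synthetic-data module generates bulk and single-cell cohorts with planted
signed signatures, log-scale noise, dropout (scRNA), and right-censored
survival whose hazard tracks the planted signature activity — so every
stage is testable offline against known ground truth.

## Worked example

```python
from krdsig import (SimConfig, generate_bulk, oe_score, compare_groups,
                    run_screen, fit_penalized_cox, krd_score, evaluate_model)

cfg = SimConfig(n_genes=1200, n_samples=300, seed=17)   # 50 up + 30 down planted
data = generate_bulk(cfg)

oe = oe_score(data.matrix, data.signature, n_random=1000, seed=17)
test = compare_groups(oe["oe"], data.labels["label"])
print(f"OE separation (rank-sum): p = {test.pvalue:.3g}")

table, signature = run_screen(data.matrix, data.labels, data.survival,
                              group1="mutation_like")
print(f"screen retained {table['retained'].sum()} genes "
      f"({len(signature.up)} up, {len(signature.down)} down)")

model = fit_penalized_cox(data.matrix.subset_genes(signature.genes),
                          data.survival, seed=17)
print(f"penalized Cox model: {model.n_genes} genes, lambda = {model.penalty:.4f}")

scores = krd_score(model.standardize(data.matrix), model)
ev = evaluate_model(scores, data.survival, horizons=(365, 1095, 1825))
print(f"high vs low risk: HR = {ev.hazard_ratio:.2f} "
      f"(95% CI {ev.hr_ci[0]:.2f}-{ev.hr_ci[1]:.2f}), log-rank p = {ev.logrank_p:.3g}")
print("time-dependent AUC:",
      ", ".join(f"{int(h)//365}y = {a:.3f}" for h, a in ev.auc.items()))
```

prints

```
OE separation (rank-sum): p = 9.77e-49
screen retained 80 genes (50 up, 30 down)
penalized Cox model: 16 genes, lambda = 0.0603
high vs low risk: HR = 6.01 (95% CI 4.37-8.26), log-rank p = 2.15e-33
time-dependent AUC: 1y = 0.815, 3y = 0.874, 5y = 0.866
```

The mutation-like group's OE scores separate cleanly from the wildtype-like
group; the screen recovers exactly the 80 planted signature genes; the
penalized fit compresses them to a 16-gene risk model whose high-scoring
half of the cohort dies markedly faster (HR ≈ 6), with good discrimination
at 1–5-year horizons.

The same chain is available from the shell via the `krdsig` CLI
(`krdsig simulate|oe-score|stratify|deg-screen|fit-model|score`); see
`krdsig --help`.

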