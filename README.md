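# tamscreen

Differential ligand–receptor screening for tumor-associated macrophage
(TAM) states, with synthetic single-cell experiments and patient-cohort
outcome statistics.

## The problem

PARP-inhibitor response in breast tumor models tracks the polarization of
tumor-associated macrophages: a pro-inflammatory state (TAM_C1-like) in
sensitive tumors versus an anti-inflammatory, pro-tumor state
(TAM_C3-like, CD206-high/MHCII-low) in resistant ones. Finding which
tumor→macrophage signal drives that switch requires comparing
cell–cell communication *between replicated conditions* — a setting
off-the-shelf communication tools do not address, because they score one
sample at a time.

`tamscreen` implements the full chain for this question, and is aimed at
computational biologists who want each stage as a tested, composable
library function:

* marker-rule annotation of single-cell data (lineages, TAM/monocyte
  subtypes, the C5ar1-high/low split of TAM_C3);
* permutation-based ligand–receptor interaction calling per sample;
* the **interaction count estimate**: with `a` replicates of condition A
  and `b` of condition B, every cross-condition sample pair is compared
  and, per interaction unit,

  `N = n_up − n_dn` over all `a×b` pairs (and `N = Σ_ligands N` per receptor),

  where an interaction is "up" in a pair when it is called significant in
  the A sample but not the B sample;
* the **discordance screen**: units with `N ≥ +m` in the resistant
  model's treated-vs-vehicle contrast and `N ≤ −m` in the sensitive
  model's — the signature of a program that treatment induces only where
  it fails;
* rank-based (UCell-style) signature scoring, within-sample Z-ranks,
  binned-control pathway scores, pseudobulk Pearson correlation with the
  strict r > 0.3, p < 0.05 rule;
* patient-level outcome statistics on the **C5aR1hi/CD86hi myeloid
  ratio**: upper-quartile stratification, Mann–Whitney ROC for
  non-response, Kaplan–Meier + log-rank, univariate Cox regression.

A synthetic-data module generates replicated experiments (negative
binomial counts, marker structure matching the annotation rules, a
planted condition-dependent malignant Rps19 → TAM_C3 C5ar1 program,
doublets, low-quality cells, hashtag oligo matrices) and patient cohorts
whose hazard and response depend on the myeloid ratio — so every stage is
testable end-to-end with known ground truth and no downloads.

## Worked example

```python
import numpy as np
from tamscreen import simulate, pipeline, cohort

# a reduced replicated design: 2 models x 2 treatments x 2 samples x 500 cells
cfg = simulate.default_config(seed=0, cells_per_sample=500, n_samples_per_arm={
    "sensitive:vehicle": 2, "sensitive:treated": 2,
    "resistant:vehicle": 2, "resistant:treated": 2})
exp = simulate.generate_experiment(cfg)

result = pipeline.run_discordance_screen(
    exp, pipeline.PipelineOptions(n_perm=300), seed=0)
print(result.screen)

table = simulate.generate_cohort(20, seed=0).table
auc, p = cohort.roc_auc(table["ratio"], table["response"], positive="NE")
print(f"AUC for non-response: {auc:.3f} (p = {p:.4f})")
groups = cohort.stratify_quartile(table["ratio"])
_, chi2, logrank_p = cohort.km_logrank(table["time_days"], table["event"], groups)
print(f"log-rank high vs rest: chi2 = {chi2:.2f}, p = {logrank_p:.4f}")
fit = cohort.cox_univariate(table["time_days"], table["event"],
                            table["standardized_ratio"])
print(fit.summary().round(3).to_string())
```

prints

```
                                N_sensitive  N_resistant  score
pair_id     sender    receiver
Rps19_C5ar1 malignant TAM_C3             -4            4      8
AUC for non-response: 0.859 (p = 0.0078)
log-rank high vs rest: chi2 = 7.04, p = 0.0080
            coef  se(coef)     HR  HR 95% CI low  HR 95% CI high   n  events
covariate  1.283     0.416  3.608          1.598            8.15  20      17
```

Reading the screen table: the planted malignant→TAM_C3 program was called
significant in both treated resistant samples and neither vehicle one
(`N_resistant = +4 = a×b`), and the mirror image in the sensitive model
(`N_sensitive = −4`) — it is the only unit passing the discordance screen,
exactly as planted. In the cohort, a high C5aR1hi/CD86hi ratio predicts
non-response (AUC 0.86) and shorter survival (hazard ratio 3.6 per SD of
the ratio), as generated.

A thin CLI wraps the same functions
(`tamscreen simulate experiment`, `tamscreen screen`,
`tamscreen cohort roc|km|cox`); see `tamscreen --help`.

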