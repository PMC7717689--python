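# hierde — hierarchical differential expression for repeated-measures transcriptomics

`hierde` is a Python package for differential-expression analysis of bulk
RNA-seq cohorts in which each subject contributes several correlated
samples — for example postmortem brain expression measured in multiple
regions (hippocampus, temporal cortex, parietal cortex, forebrain white
matter) of the same donors in a case/control dementia study. Treating such
samples as independent replicates understates the standard error of the
disease contrast and inflates the type-I error; `hierde` models the
within-subject correlation explicitly and demonstrates, on synthetic
cohorts with known ground truth, that it controls the error rate where the
naive pooled analysis does not.

The pipeline is aimed at statisticians and computational biologists who
need a tested, reproducible implementation of:

* **voom-style precision weights** — a robust LOWESS fit of the
  mean–variance trend on the √sd scale; each observation's weight is the
  inverse of its predicted variance, `w_gi = trend(fitted_gi)^-4`;
* **per-gene weighted linear mixed models** — for gene *g*,

  `y = Xβ + Z u + ε`, `u ~ N(0, τ² I)`, `ε ~ N(0, σ² W⁻¹)`,

  with a random intercept per subject and the diagnosis coefficient
  `β₁ = logFC` (log2, case − control) as the contrast of interest. REML
  estimation profiles λ = τ²/σ² with closed-form block inversion, so tens
  of thousands of genes fit in seconds;
* **empirical-Bayes moderation** — gene-wise variances `s²_g` (df `d_g`)
  are squeezed toward a prior `s₀²` with df `d₀` fitted by marginal method
  of moments: `s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g)`; the moderated
  `t̃_g = β̂₁/(s̃_g·se_unit)` is referred to a t with `d₀ + d_g` df, and the
  B-statistic is the posterior log-odds of differential expression;
* **enrichment** — hypergeometric over-representation analysis with
  Bonferroni correction, and pre-ranked GSEA (weighted running-sum ES,
  gene-set permutation NES/p/FDR) on genes ranked by moderated t;
* **gene-panel classification** — exhaustive search over all C(10, N)
  combinations of the top 10 genes (2 ≤ N ≤ 10, 1013 panels) with linear
  and RBF SVMs, a random forest and quadratic discriminant analysis, on a
  subject-disjoint 70/30 split, reporting test accuracy/precision/recall/F1
  and a distribution-free Hoeffding bound `ε = √(ln(2/δ)/(2n_test))`;
* **a synthetic cohort generator** with subject random intercepts, a
  configurable mean–variance trend, covariate effects and planted DE genes,
  so every stage is testable end-to-end without any data download.

See `docs/methods.md` for the model details, defaults and limitations.

## Worked example

```python
import numpy as np
from hierde import (CohortDesign, SimulationParams, generate_metadata,
                    simulate_expression, MixedDE, VoomWeights)
from hierde.preprocess import run_preprocess

design = CohortDesign(seed=7)                  # 15 AD / 30 control, 4 regions
meta = generate_metadata(design)
params = SimulationParams(n_genes=2000, de_fraction=0.025,
                          effect_size=1.0, up_fraction=1.0)
matrix, truth = simulate_expression(meta, params, seed=8)

E_adj = run_preprocess(matrix, meta)           # log2(FPKM+1), adjust age+sex
weights = VoomWeights().fit_transform(E_adj, meta)
de = MixedDE().fit(E_adj, meta, weights=weights)

top = de.significant(alpha=0.05)
print(f"samples: {len(meta)}  genes: {len(de.results_)}")
print(f"Bonferroni-significant at 0.05: {len(top)}")
planted = set(np.asarray(truth.gene_ids)[truth.de_flags])
print(f"of which planted: {len(set(top['gene_id']) & planted)}")
print(top.head(5)[["gene_id", "logFC", "AvExp", "t", "adj.P.Val", "B"]]
      .to_string(index=False, float_format=lambda x: f"{x:.3g}"))
```

Output:

```
samples: 169  genes: 2000
Bonferroni-significant at 0.05: 39
of which planted: 39
gene_id  logFC  AvExp    t  adj.P.Val    B
 G01636   1.29   2.14 8.21   1.98e-07 14.2
 G00939   1.19   7.48 7.93   5.22e-07 13.3
 G01181   1.19   4.93 7.83   7.44e-07   13
 G01368  0.972   4.81 7.75   1.01e-06 12.8
 G01040   1.29    4.2 7.59   1.74e-06 12.2
```

The cohort has 169 samples from 45 subjects; 50 genes carry a planted
+1 log2-fold-change. The hierarchical model recovers 39 of them at the
Bonferroni-corrected 0.05 level with zero false positives: every reported
gene is planted, the estimated `logFC` values cluster around the planted
effect, and the B-statistic (posterior log-odds of differential
expression) decreases with the corrected p-value.

## Command line

The same stages are available as subcommands:

```bash
hierde --seed 1 simulate --out fixture/
hierde --seed 1 de --expression fixture/expression.tsv \
       --metadata fixture/metadata.csv --regions HIP,TCx,PCx,FWM --out de/
hierde --seed 1 enrich --de-results de/de_results.csv --gmt sets.gmt --out enrich/
hierde --seed 1 classify --de-results de/de_results.csv \
       --expression fixture/expression.tsv --metadata fixture/metadata.csv --out cls/
```

Every output carries the package version, a configuration hash and the
seed, and reruns are byte-identical. Exit codes: 0 ok, 2 validation error,
3 stage failure.

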