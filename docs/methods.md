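# Methods

This note records the statistical model behind `hierde`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions a maintainer should know about.

## The hierarchical model

Expression arrives as a genes × samples matrix of non-negative FPKM values
together with per-sample metadata (subject, brain region, diagnosis, age,
sex, APOE ε4, Braak stage). Samples are nested in subjects: each subject
contributes up to one sample per region, so observations within a subject
are correlated. The pipeline is

1. **log transform** — `y = log2(FPKM + offset)`, offset 1.0. The offset
   keeps zero FPKM at zero and stabilises the variance of small values.
2. **covariate adjustment** — per gene, OLS of `y` on age and sex (with
   intercept); the adjusted value is residual + gene grand mean, so average
   expression is preserved and residuals are exactly orthogonal to the
   covariates. The default order is log-then-adjust. A literal
   adjust-then-log mode exists for parity with protocols that adjust raw
   values first, but OLS residuals of raw FPKM can be negative and have no
   logarithm; that mode restores the gene mean and floors at 1e-3 before
   the log, with a warning. Diagnosis is rejected as an adjustment
   covariate — adjusting out the effect of interest is a detectable misuse.
   Sex is coded female = 1, male = 0; any consistent binary coding yields
   identical residuals.
3. **precision weights** — an unweighted first-pass OLS with the same fixed
   effects as the mixed model (subjects pooled) gives per-gene residual
   standard deviations and per-observation fitted values. A robust LOWESS
   smoother (span 0.5, 3 robustness iterations) of √sd on mean log2
   expression defines the trend; the predicted sd^(1/2) at an observation's
   fitted value implies predicted variance trend⁴ and weight
   `w = trend(fitted)^-4`. The quarter-power parameterisation tames the
   heavy right tail of gene-wise variances before smoothing. The trend is
   fitted on covariate-adjusted log-scale data so the weights reflect the
   residual variance of the model actually fitted. Genes with numerically
   zero residual variance are flagged and given weight 1 everywhere.
4. **per-gene weighted LMM** — `y = Xβ + Zu + ε` with `u ~ N(0, τ²I)` per
   subject and `ε ~ N(0, σ²W⁻¹)`. The default fixed effects are intercept
   and diagnosis (AD = 1), so `β₁` is the log2 fold change AD − control;
   region can be added as a fixed effect but is off by default because the
   disease contrast is the sole quantity of interest. REML estimation
   profiles β and σ², leaving a one-dimensional criterion in λ = τ²/σ²:

   `f(λ) = (n−p)·log RSS(λ) + log|Ṽ(λ)| + log|XᵀṼ(λ)⁻¹X|`, `Ṽ = W⁻¹ + λZZᵀ`.

   Because subjects are independent blocks, `Ṽ⁻¹` follows from per-subject
   Sherman–Morrison updates, and the per-subject sufficient statistics do
   not depend on λ — so the criterion evaluates for *all genes at once* in
   O(G·S) numpy work. Optimisation is a λ grid (0 plus 40 geometric points
   up to 50) followed by vectorised golden-section refinement; if the
   refined point does not beat λ = 0 the gene is set exactly to the
   boundary, making the τ̂² = 0 ⇒ weighted-least-squares identity exact.
   Weights are normalised to mean 1 within each gene, so they are defined
   up to scale (doubling all weights changes nothing). Degenerate genes
   (zero residual variance, singular fits) are flagged `converged = False`,
   kept in the table, and still count toward the multiple-testing family.
5. **empirical-Bayes moderation** — marginally `s²_g ~ s₀²·F(d_g, d₀)`;
   matching mean and variance of `log s²_g` through digamma/trigamma
   identities gives closed-form moment estimators (a Newton trigamma
   inverse for d₀). Non-positive excess spread means the gene-wise
   variances vary no more than sampling noise predicts: then d₀ = +∞, the
   prior variance is the arithmetic mean of the `s²_g` (so equal variances
   are an exact fixed point), and every posterior variance equals s₀².
   The moderated `t̃ = β̂₁/(s̃·se_unit)` is referred to a t distribution
   with `d₀ + d_g` df, two-sided.
6. **multiplicity** — Bonferroni, `min(1, m·p)`, with m the full gene count
   including non-converged genes (conservative, consistent with analysing
   all genes without filtering).
7. **B-statistic** — posterior log-odds of differential expression under a
   two-component prior: a fraction `p₁` (default 0.01) of genes carries
   extra prior variance `v₀σ²` on the contrast;

   `B = log(p₁/(1−p₁)) − ½·log r + ((d+1)/2)·log((t̃²+d)/(t̃²/r+d))`,
   `r = (v+v₀)/v`, `v = se_unit²`.

   `v₀` defaults to an estimate from the upper tail of the |t̃|
   distribution (equating empirical and mixture tail probabilities for the
   top `p₁/2` fraction); it can be set explicitly. B is strictly
   increasing in |t̃| at fixed df and se_unit.

### Degrees of freedom for the contrast

The diagnosis contrast compares *subjects*, not observations: all of a
subject's samples share one random intercept, so the contrast carries
subject-level information only. `hierde` therefore uses the between–within
convention `d_g = n_subjects − p`. Using observation-level df (n − p) looks
harmless at the 0.05 level but overstates precision exactly where
Bonferroni operates (p ≈ α/m): in null-cohort simulation it inflated the
family-wise error several-fold, while the between-within df restores the
nominal level. Per-gene Satterthwaite approximation would interpolate
between the two and is a possible extension; it is not implemented.

### The naive comparator

`ols_pvalues` fits the same fixed effects by per-observation OLS, ignoring
subjects. It exists to quantify the cost of the anti-pattern: on null
cohorts with τ = σ = 0.5 it rejects at ≈ 0.16–0.18 instead of 0.05. It is
not part of the analysis path.

### Within-region rank-sum check

`wilcoxon_region` runs a two-sided Wilcoxon rank-sum test AD vs control
within one region (exact null when the combined n ≤ 20 and tie-free,
normal approximation with tie correction otherwise). At ~10–40 samples per
region and Bonferroni over all genes it is expected to find nothing — a
deliberate illustration that per-region marginal testing is underpowered
compared to the hierarchical model that pools regions.

## Enrichment

* **ORA** — hypergeometric upper tail `P(X ≥ k)` of the overlap between the
  Bonferroni-significant list and each gene set, within the universe of
  all genes in the expression matrix (not the annotation's universe);
  Bonferroni over the number of sets tested. Gene-ID matching everywhere
  is exact-string and case-sensitive; the package never translates IDs.
* **pre-ranked GSEA** — genes ranked by decreasing moderated t (ties broken
  by gene ID for determinism). Weighted running sum with exponent p = 1 by
  default (p = 0 is the classic KS statistic and is used in unit tests).
  ES is the running-sum value of maximal |deviation|; an exact tie between
  the positive and negative extremum (possible at p = 0 where the running
  sum is rational) resolves to the positive value, with 1e-12 tolerance so
  the convention is stable under floating-point noise. Significance uses
  size-matched random gene sets (gene-set permutation — phenotype
  permutation does not exist for a pre-ranked list): NES divides ES by the
  mean |null ES| of matching sign, the p-value is the add-one-smoothed
  same-sign tail fraction, and FDR compares each observed NES with the
  pooled normalised null NES distribution. Null ES distributions are
  computed vectorised and cached per set size.
* **set similarity** — Jaccard, overlap coefficient and their mean
  ("combined"), the usual enrichment-map edge weights. Only the numeric
  coefficients are computed; graph layout is left to external tools.

## Panel classification

The top 10 genes by corrected p-value (or an explicit list) feed an
exhaustive search: for each N in 2..10 every C(10, N) combination is
trained and scored on the training split only; the maximiser — ties broken
by lexicographically smallest combination — is then evaluated once on the
test split. Test data cannot influence selection, which the test suite
verifies by shuffling test labels and asserting identical selections.

Splits are subject-disjoint: subjects are shuffled within each diagnosis
group and per-group train counts are chosen so the train-sample count is
closest to 70% of all samples (stratification by group fraction breaks
ties), with at least one subject per group on each side. Subject-level
granularity means the achieved fraction quantises; on ~165-sample cohorts
it lands within a few samples of the target.

Classifiers: linear SVM (C = 1), RBF SVM (C = 1, γ = 1/(N·Var)), random
forest (500 trees, seeded), and quadratic Bayes implemented as quadratic
discriminant analysis with covariance regularisation 1e-3 (Gaussian
class-conditionals with unequal covariances). Features are standardised
with training-set mean/sd only. No resampling, cross-validation or
hyperparameter tuning — the protocol is deliberately plain so the
subject-disjoint split and the Hoeffding bound carry the generalization
claim: `ε = √(ln(2/δ)/(2n_test))` with δ = 0.5 by default, and the
out-of-sample error is ≤ test error + ε with probability ≥ 1 − δ.

## The synthetic cohort generator

`generate_metadata` draws a cohort of 15 case and 30 control subjects
(configurable) over four regions, with per-(subject, region) missingness
at rate 1/12 — chosen so the expected sample count is 165 of 180, matching
the design it emulates; a subject who would lose all regions is resampled.
Ages are Normal(88, 6) truncated at 60; sex is Bernoulli(0.44 female);
APOE ε4 carrier rates default to 1/3 (case) and 0.10 (control); Braak
stages are rounded normals centred at 4.1 / 2.7. Missingness is uniform at
random — the emulated study reports no mechanism, so uniformity is an
assumption of the generator, not a statement about the data.

`simulate_expression` builds log2 signal as

`baseline_g + δ_g·[case] + region_{g,r} + a·(age − mean) + s·[female] + u_{g,subj} + ε`

with `u ~ N(0, τ²)`, `ε ~ N(0, trend(baseline_g)²)` and emits
`max(2^signal − 1, 0)` on the FPKM scale. Defaults: 2000 genes (desk
scale; the gene count is a parameter, not a limit), DE fraction 1.2%
(mirroring ~600 of 50k genes), effect magnitude δ = 0.653 (the top
reported fold change in the study design emulated), 80% of DE genes
upregulated, τ = 0.5, trend `sd(μ) = 0.2 + 1.5·e^(−0.4μ)` (decreasing,
strictly positive), region-effect sd 0.25, age slope 0.01 log2/yr, sex
shift 0.1, baselines Normal(4, 2). Planted effects are exactly ±δ so
recovery bias is measurable without Monte-Carlo ambiguity.

What it does **not** emulate: count-level sampling noise and library-size
effects (values are FPKM-scale by construction), batch and RNA-quality
artefacts, gene–gene correlation beyond the shared subject effect,
Braak-stage progression, and region-specific disease effects (the planted
δ is common to all regions). Passing tests therefore demonstrate the
statistical machinery under the assumed covariance structure, not
robustness to those real-data complications.

One consequence worth knowing: the FPKM floor `max(2^y − 1, 0)` followed by
`log2(x + 1)` is not exactly the identity for low-expressed genes, so
planted effects are slightly attenuated after the round trip (a few
percent at the default baseline distribution, more for genes near zero).
Recovery of planted logFC at desk scale is within 10% of δ; power at
Bonferroni stringency is modest (roughly half to three-quarters of planted
δ = 1 effects at 2000 genes), dominated by low-baseline genes whose trend
sd is large.

## Numerical conventions and edge cases

* λ search range [0, 50] (ICC up to ≈ 0.98); grid + golden section to
  relative width ~1e-7; exact boundary handling at λ = 0.
* RSS is floored at 1e-300 inside logs; fits with RSS below 1e-12 of the
  weighted response norm are flagged non-converged.
* LOWESS knots with duplicate abscissae are averaged so interpolation is
  well defined; trend values are floored at 1e-6 to keep weights finite;
  evaluation clamps outside the knot range.
* The trigamma inverse uses Newton iteration with the standard asymptotic
  starting point; d₀ estimates use only genes with positive finite
  variance and df.
* Wilcoxon: all-identical pooled values return p = 1; ties force the
  asymptotic path with tie correction.
* `evaluate` defines precision/recall/F1 as 0 when their denominators
  vanish.
* All randomness flows through `numpy.random.default_rng` seeds carried in
  the design/params/CLI config; identical seeds give byte-identical
  outputs.

## Known limitations

* Single random intercept only — no random slopes, no crossed random
  effects, no Satterthwaite df.
* The moderated-t reference distribution treats `d_g` as fixed at the
  between-within value; for very unbalanced cohorts a per-gene df
  approximation would be tighter.
* GSEA FDR follows the pooled-null convention and can be conservative for
  collections with few sets.
* ORA treats annotation sets as flat; no ontology propagation.
* The classification protocol maximises training accuracy per panel size;
  with small test sets the reported test metrics have wide Hoeffding
  intervals by construction — that is the point of reporting the bound.
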