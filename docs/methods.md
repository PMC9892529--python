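# Methods

## Statistical model

### Association stage

For each gene in each cohort the model is ordinary least squares on
inverse-normal-transformed (INT) expression:

    INT(expr_g) = β₀ + β₁·exposure + β₂·age + β₃·sex + β₄·WBC + β₅·RBC
                + β₆·%mono + β₇·%lymph + β₈·%neutro + β₉·%eos
                + Σₖ βₖ·hiddenₖ + ε

where the exposure is an INT lipid level, a standardized genetic
instrument score, or a single variant dosage (the single-variant model
omits the hidden factors). Basophils, the fifth differential fraction, are
excluded: the five fractions sum to 100%, so the fifth column would be
collinear with the intercept, which absorbs its effect. The dropped
fraction is configurable.

Hidden factors are estimated per cohort by residualizing the
sample × gene expression matrix on the known covariates, taking the top-k
left singular vectors of the residual, and residualizing those on the
exposure so the exposure's own transcriptome-wide signal is not absorbed.
k = 5 by default. This is an SVD surrogate for factor-analytic confounder
estimators; it recovers a planted batch factor with |r| > 0.9 at
n = 1,000 (see the test suite) but is not identical to shrinkage-based
estimators.

Per-cohort z-scores are recalibrated against an empirical null before
meta-analysis: bias = median, inflation = median absolute deviation on the
central 90% of the z distribution, scaled by the consistency constant of a
normal sample truncated to its central 90% (Φ⁻¹(0.725) ≈ 0.598, reducing
to the familiar 0.6745 MAD constant at 100%). Corrected
z = (z − bias)/inflation; betas and SEs are rescaled coherently. This is a
robust-location/scale surrogate for Gibbs-sampler mixture deconvolution of
the null; it assumes the majority of genes are null and is skipped when
fewer than 100 genes are available. Correction is applied per cohort,
before pooling.

Cohorts are combined by fixed-effect inverse-variance meta-analysis
(wᵢ = 1/seᵢ², pooled se = (Σwᵢ)^(-1/2)); multiplicity is controlled by
Bonferroni over the number of expressed genes. Two-sided p-values use the
normal, not t, distribution: the smallest cohort has n = 169 and the meta
operates on z-scores.

### Instruments

The genetic instrument for a lipid is the weighted dosage sum with
external discovery-GWAS betas as weights, restricted to variants more
than 1 Mb apart with pairwise r² < 0.10 (greedy pruning by ascending
discovery p; ties break by |weight|, then position), then standardized to
mean 0, SD 1. Validity reporting: first-stage F = (n−2)R²/(1−R²), R², and
per-confounder association p-values. Pairwise r² is an input (identity for
the synthetic data, whose variants are simulated independent); computing
LD from a reference panel is out of scope.

### MR stage

The causal estimate for a gene is the Wald ratio of the two
instrument-score regressions, each meta-analyzed across cohorts before the
single division. The confidence interval inverts the test of
`β_zy − ρ·β_zx = 0` (Fieller), i.e. the real roots of

    (β_zx² − z²se_zx²)ρ² − 2(β_zy β_zx − z²c)ρ + (β_zy² − z²se_zy²) = 0.

When the leading coefficient is non-positive the instrument-exposure
association is itself compatible with zero; the interval is unbounded, the
estimate is flagged rather than dropped, and the delta-method SE is
reported. The robust SE is otherwise the interval width over 2z, and the
p-value is a normal test on estimate/robust-SE. The numerator–denominator
covariance is taken as 0 by default (one-sample sharing is a documented
limitation; the `cov_zxzy` argument accepts an external estimate).

Pleiotropy: per-variant Wald ratios β̂ⱼ = Γⱼ/γⱼ get modified Cochran
weights evaluated at the pooled estimate,
wⱼ = (SE_Γⱼ²/γⱼ² + β̂_pooled²·SE_γⱼ²/γⱼ²)⁻¹, iterating pooled estimate and
weights to 1e-8 (first-order weights; a second-order option adds the
cross term). Q = Σ wⱼ(β̂ⱼ − β̂_pooled)² is referred to χ²_{J−1}. While
p_Q is at or below the threshold and more than two variants remain, the
single variant with the largest contribution qⱼ is removed and the
statistic recomputed; the removal order is recorded and the final Wald
ratio uses an instrument rebuilt from the surviving variants. The default
threshold is 0.05; a stricter 0.5 screen is exposed as configuration
because both conventions are in circulation, and the two are not silently
interchangeable.

Egger regression (sensitivity only): variants oriented to positive
exposure effects, outcome betas regressed on exposure betas with 1/SE²
weights; the intercept estimates average directional pleiotropy. SEs use
multiplicative overdispersion scaling floored at 1 and the intercept test
is t with J−2 df, which keeps the test calibrated under balanced (mean
zero) pleiotropy.

Multivariable MR refits both stages with an extra covariate — the dosage
of a cis-eQTL variant inside the instrument (direct pleiotropy) or a
second instrument score (parallel path) — and rejects covariates with
r² ≥ 0.95 against the instrument. Reverse-direction MR instruments a
gene's expression with its strongest cis-eQTL and forms the ratio
(variant→lipid)/(variant→expression); two-sample MR applies the same
single-variant ratio to external outcome summary statistics after allele
harmonization. BH-FDR (step-up) controls each tested set.

### Power

With standardized variables the Wald test has non-centrality
NCP = n·R²_gx·β_xy²; power is the non-central χ²₁ upper tail beyond the
central critical value. The general error-variance terms of the standard
continuous-outcome calculator collapse under standardization, which is
how all pipeline variables enter. Required sample size inverts this by
bisection.

### Enrichment

One-sided over-representation p-values are exact hypergeometric tails on
the 2×2 table of query × gene set over a fixed expressed background, with
genes absent from the background excluded from both query and sets
(case-insensitive symbol matching), and BH applied jointly across all sets
of all GMT libraries. Odds ratios are displayed with a Haldane 0.5
continuity correction; p-values never use it. The replication-overlap test
is the same upper tail applied to two gene lists in a common universe.

## Synthetic-study generator

The generator emulates a six-cohort whole-blood consortium; its defaults
are the study conditions the pipeline targets.

- **Cohorts.** Six cohorts of 183, 741, 642, 797, 169 and 697 samples
  (total 3,229), each with its own age, sex, lipid, cell-count and
  cell-fraction means/SDs. Cell fractions are drawn per type and
  renormalized to sum to exactly 100.
- **Genotypes.** Hardy-Weinberg dosages (binomial(2, MAF)); MAFs drawn
  U(0.05, 0.5) unless specified. Variants are independent (no LD); the
  pairwise r² matrix is the identity.
- **Lipids.** The exposure lipid is
  `Σ bⱼ(dosⱼ − 2MAFⱼ) + λ_C·C + Σ reverse effects + ε`, with per-variant
  effects sized so the instrument explains 5% of variance by default (the
  observed instruments explained 4.0–6.4%) and a standard-normal shared
  confounder C with loading 0.3. Non-genetic residuals of (TG, HDL, LDL)
  are drawn from a correlated Gaussian calibrated so the realized
  correlations match the observed values (TG–HDL −0.48, TG–LDL 0.45,
  HDL–LDL −0.12); total cholesterol is assembled as LDL + HDL + TG/2.2 so
  the Friedewald derivation is exactly consistent. Lipids are mapped to
  mmol/L with cohort-specific means/SDs and floored at 0.05.
- **Expression.** Negative-binomial counts (dispersion 0.05) whose
  log-mean is baseline (log-normal around 500 counts) plus a unit-variance
  biological latent combining: the causal lipid effect (for a configured
  gene subset), direct pleiotropic variant effects, a cis-eQTL effect of
  0.4 log-SD per allele for causal/reverse genes, five hidden factors
  (loadings N(0, 0.15²)), the confounder (loadings N(0, 0.10²)), loadings
  on the measured cell fractions, and residual noise; plus a per-sample
  sequencing-depth offset (log-SD 0.2). Counting noise attenuates planted
  standardized slopes by about 2.5% at these settings; this is accepted
  rather than deconvolved, and lies within every stated tolerance.
- **External summary statistics.** Discovery-GWAS instrument weights are
  the true variant effects plus noise at SE = (2·MAF(1−MAF)·N)^(-1/2) with
  N = 188,577, drawn from an independent stream (two-sample weights, no
  sample overlap). Outcome summary statistics for two-sample MR are built
  the same way from a configured gene→outcome effect through each gene's
  cis-eQTL.
- **Seeding.** One master seed; global gene/variant parameters, each
  cohort, the discovery GWAS, and each pleiotropy injection use
  independent deterministic substreams, so identical seed and
  configuration give bitwise-identical output.

What the generator does **not** emulate: linkage disequilibrium, realistic
gene-gene correlation beyond shared factors, winner's-curse in discovery
weights, fine-grained count properties (zero inflation, GC/length bias),
population structure, or relatedness. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated generative
assumptions, not robustness to everything real cohort data can do.

## Numerical and design choices

- INT uses the Blom offset c = 3/8 with average ranks for ties; missing
  values propagate; constant vectors are an error. INT is idempotent to
  1e-12.
- TMM uses the canonical 30% M-trim / 5% A-trim with delta-method binomial
  weights and geometric-mean-1 rescaling; the reference sample is the one
  with the most typical upper-quartile fraction. The implementation is
  cross-checked against edgeR in the test suite.
- Friedewald LDL is invalid above TG = 4.52 mmol/L (400 mg/dL); such
  samples get missing LDL with a warning.
- Genotype QC removes variants with info < 0.5, HWE p < 1e-4, call rate
  < 0.95 or MAF < 0.05 (all strict), and any variant with a missing
  metric.
- Degenerate inputs raise typed errors rather than returning silently:
  collinear designs (e.g. all five cell fractions), zero-variance
  instruments, zero denominators in ratios, sub-minimal variant counts.
- The Q-pruning loop removes one variant per iteration (most conservative
  ordering, order recorded) rather than all nominally heterogeneous
  variants at once.
- Per-cohort stage estimates are meta-analyzed before the Wald division;
  dividing first and pooling ratios is noisier when cohort instruments are
  weak.

## Benchmark problem sizes

The Monte-Carlo acceptance benchmarks use: 10,000 parametric draws for
Fieller coverage at F ≈ 30; 200 single-cohort replicates (n = 5,000,
20 variants, 2 planted pleiotropic) for Q-pruning recovery; one full
six-cohort study with 1,000 confounded null genes for pipeline type-I
error; 50 six-cohort replicates (40 genes each, planted effect 0.4) for
bidirectional direction identification; and 2,000/1,000 summary-level
replicates for Q and Egger null calibration. The forward effect of 0.4 SD
per SD with a 0.4-per-allele cis-eQTL was fixed by a priori power analysis
at the consortium total n = 3,229 (forward Wald z ≈ 5) so the direction
benchmark measures direction identification rather than raw power.

## Known limitations

- The latent-factor and empirical-null components are deliberate
  surrogates for factor-analytic and Bayesian-mixture estimators; results
  are labelled accordingly in logs and should not be read as exact
  re-implementations of those methods.
- One-sample numerator/denominator covariance is ignored by default;
  with strong instruments (F > 100) the effect on the Fieller interval is
  negligible, but weak-instrument one-sample intervals may be optimistic.
- Reverse-direction MR is only as good as the supplied cis-eQTL; the
  generator plants one eQTL per causal/reverse gene, which is idealized.
- Power analysis covers continuous outcomes only.
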