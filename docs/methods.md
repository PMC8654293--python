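# Methods

This note documents the statistical model behind `cismr`, the choices made
where the design was genuinely open, and what the synthetic validation does
and does not establish.

## The two-sample design

Exposure-SNP effects (b_zx, per SD of rank-inverse-normal protein level) and
outcome-SNP effects (b_zy, log-odds of disease) are estimated in disjoint
cohorts, so their sampling errors are independent. Under the three
instrumental-variable assumptions (association with the exposure; no
association with confounders; no effect on the outcome except through the
exposure), each instrument's Wald ratio b_zy/b_zx estimates the same causal
effect b, and departures between ratios indicate horizontal pleiotropy.
With same-cohort instrument discovery and effect estimation, both
weak-instrument and winner's-curse biases point toward the null in this
design — estimates are conservative, never anti-conservative.

## Association scans

- **Exposure**: the protein is transformed by the rank-based inverse normal
  transformation, Φ⁻¹((rank − ½)/n) within groups, with average ranks for
  ties. The ½ offset is chosen for symmetry (the exact offset is a
  convention). Per SNP, OLS of the INT value on dosage plus covariates (sex,
  age, PC analogues); the per-SNP slope, SE and t-based p come from
  residualizing both sides against the covariates (Frisch–Waugh–Lovell),
  which equals the full joint fit exactly. Synthetic individuals are
  unrelated, so no kinship/mixed-model adjustment is needed or performed.
- **Outcome**: per SNP, maximum-likelihood logistic regression of case
  status on dosage plus covariates; Wald SE and normal p. Non-converged or
  separated fits are flagged with `se = inf`, `p = 1` rather than dropped.
- **Variant QC** removes variants by MAF (< 0.01), Hardy–Weinberg
  chi-square p (< 1e-20), missingness (> 0.05) and imputation info (< 0.8),
  logging the first failing rule in that fixed order. HWE uses the 1-df
  chi-square test; at these deep-tail thresholds the exact test adds
  nothing.
- Summary tables are validated on read: unique SNP ids, positive SEs, and
  p consistent with the normal tail of beta/se within 10% — applied only in
  the bulk (p > 1e-3), because a t-based p legitimately departs from the
  normal tail beyond that at cohort sizes in the hundreds.

## Instrument selection

Candidates are cis SNPs (gene end points ± 2 Mb, 1-based inclusive; BED
input converted on read) present in both cohorts, harmonized to a common
effect allele (swapped alleles flip the outcome beta and EAF; palindromic
A/T and C/G SNPs are excluded by default because strand cannot be verified
— configurable), passing P < 1e-6 in the exposure scan. The greedy loop
then repeatedly selects the smallest remaining exposure p (ties: smaller
position, then lexicographic id) and removes everything with r² > threshold
(default 0.6) against it in either cohort's LD. Proteins with fewer than
four survivors are rejected; with exactly four, estimation proceeds but the
outlier step is disabled (below). The relatively liberal default r²
maintains instrument counts for near-monogenic protein architectures; the
estimators absorb the resulting correlation through the covariance model.

## Causal estimation

With ratios β̂_i and delta-method variances v_i, the ratio covariance is
modelled as V_ij = r_ij √(v_i v_j), with signed LD r estimated in the
outcome cohort. The formula is applied in the canonical orientation
b_zx ≥ 0 (equivalently, the LD signs are re-expressed for that
orientation); without this the √ would discard the sign of b_zx,i·b_zx,j
and the estimate would depend on arbitrary allele coding. GLS then gives
b̂ = (1ᵀV⁻¹β̂)/(1ᵀV⁻¹1), se = (1ᵀV⁻¹1)^(−1/2) (fixed-effect convention),
p from χ²₁. The first-order (no second-order term) ratio variance is
adequate because the selection rule guarantees strong instruments.

All solves factorize the correlation-scaled system (V = D R D with diagonal
D): Cholesky on R, never an explicit inverse, with a hard
condition-number guard at 1e12 on R. Guarding R rather than V matters:
a weak instrument inflates its ratio variance by orders of magnitude, which
is benign scaling, not singularity. No silent regularization is applied;
the error advises a stricter r² threshold.

**HEIDI-outlier.** The reference is the instrument with the smallest
exposure p; each other SNP's deviation d_i = β̂_i − β̂_ref has variance
v_i + v_ref − 2 r_{i,ref}√(v_i v_ref) (same orientation convention), and
SNPs with χ²₁ p < α = 0.01 are removed in a single pass before
re-estimation. With fewer than five instruments the procedure is disabled
and flagged, since a meaningful consensus cannot be formed. The released
method's exact iteration schedule is not publicly specified; a single pass
against the top instrument is the defensible core, and the pass is
implemented as one shot by design.

**Sensitivity estimators** run on the unfiltered instrument set:

- *IVW (correlated)*: GLS of b_zy on b_zx through the origin with
  Ω_ij = r_ij se_zy,i se_zy,j — outcome-side errors only, matching the
  convention of the correlated-instrument sensitivity methods; exposure
  uncertainty enters the main estimator through the ratio variances
  instead. SE inflated by φ = max(1, √(RSS_GLS/(L−1))) — a random-effect
  model whose residual SE cannot fall below one.
- *MR-Egger*: the same GLS with a free intercept after orienting all
  b_zx ≥ 0; the slope is the causal estimate (L−2 df for φ) and the
  intercept with its p is the directional-pleiotropy test.
- *Weighted median*: inverse-variance-weighted median of ratios with
  linear interpolation at cumulative weight ½; consistent while valid
  instruments carry > 50% of weight. Its SE is a parametric bootstrap
  (default 1000 draws, seeded) that resamples per-SNP effects
  independently — LD is ignored in the bootstrap, a simplification that
  makes the weighted-median SE approximate when instruments are strongly
  correlated.

ORs per SD are exp(b) with 95% CI exp(b ± 1.959964·se). p-values are
two-sided; χ²₁ and squared-normal formulations are identical.

## Grid reporting

Each protein × disease cell re-harmonizes the instruments to that disease's
outcome scan, applies HEIDI where feasible, and estimates with the
requested methods. Main-analysis (GSMR) p-values are BH-adjusted with the
family size m equal to *all attempted cells* (failed cells count — the grid
is the hypothesis family), and FDR < 0.05 declares significance;
sensitivity p-values are reported raw. Cells are coded machine-readably:
direction (protective OR < 1 / harmful), four raw-p shade bins
(10⁻⁴/10⁻³/10⁻²/0.05), white at p ≥ 0.05, a star for FDR significance,
plus flags for fewer than four post-removal instruments and for disabled
outlier removal. BH is the step-up running-minimum form, capped at 1, ties
sharing the better value; m may exceed the vector length when a subset of a
wider family is adjusted.

## Synthetic cohorts

The generator produces what the analysis assumes, with known ground truth:

- **Genotypes**: Gaussian copula — two latent MVN(0, R) draws per
  individual thresholded at Φ⁻¹(EAF) and summed — giving Hardy–Weinberg
  dosages, controllable block-AR(1) LD and exact marginals without a
  coalescent simulator. The realized dosage correlation is slightly
  attenuated relative to the latent r (a known property of dichotomized
  Gaussians); estimators consume LD re-estimated from the genotypes, so
  this is internally consistent.
- **Protein**: genetic value Σβ_j·g_j plus small covariate effects plus
  Gaussian noise scaled so the genetic fraction of variance equals
  `h2_target` (default 0.3, mid-range for strongly cis-regulated
  proteins). Effect sizes follow a dominant-lead cis architecture: the lead
  SNP carries 40% of the genetic variance (~12% of protein variance at the
  default), secondaries split the rest (~2% each) — so per-instrument
  variance explained spans a few to ~12%, within the single-digit-to-tens
  range typical of cis-pQTLs, and every planted instrument is strong
  enough to pass the P < 1e-6 selection rule at n = 872.
- **Disease**: logistic (not liability-threshold), matching the outcome
  model actually fitted: logit P = α + b·(G/σ_protein) + Σδ_j·g_j +
  covariates, with α root-solved so the expected case count hits
  `n_cases`. Scaling the genetic value by the protein SD makes the
  configured `true_b` exactly the log-odds per protein SD — the estimand
  of every estimator. Planted pleiotropy gives direct effects δ_j to a
  configurable fraction of the causal SNPs.
- The two panels share SNPs and LD but contain disjoint, independently
  drawn individuals; defaults mirror the motivating study's scale
  (exposure n = 872; biobank-scale outcome with a free case count).

The summary-level simulator (`simulate_summary_mr`) skips individual-level
data for estimator-focused experiments: exposure effect magnitudes uniform
on [0.15, 0.65] per SD with random signs, LD-correlated estimation errors
on both sides. Two deliberate conventions: planted direct effects are
directional *on the oriented scale* (sign-linked to b_zx — sign-free draws
would cancel after Egger orientation and no intercept test could ever
detect them), and they land on the weakest instruments, so the top
instrument — HEIDI's reference — is valid, which is exactly the assumption
the reference-based test needs.

**What passing tests do not show.** Synthetic cohorts have no relatedness,
no imputation error, rectangular LD blocks rather than human LD maps, no
assay artifacts beyond what INT removes, and pleiotropy of a single planted
form. Recovery and power results validate the estimators and the pipeline's
plumbing under the stated model; they do not certify performance on real
biobank data, where instrument validity is an assumption, not a
construction.

## Validation experiments and problem sizes

The validation suite and reproduction script use: 200 replicates per
recovery arm (full pipeline, exposure n = 872, outcome n = 20,000 / 2,000
cases, 10 instruments, planted OR 0.84 per SD and a null arm); 200
summary-level replicates each for HEIDI power (3 of 10 instruments with
direct effects of mean 0.15), Egger intercept power (20 instruments, mean
direct effect 0.05, outcome SE 0.015 — biobank scale), and 150 for the
weighted-median-vs-IVW comparison (30% balanced contamination). Oracle
checks compare the greedy pruner against a brute-force re-implementation on
500 random instances, the GLS estimators against explicit-inverse algebra
at 1e-10, and BH against its O(m²) definition.

## Known limitations

- Single-pass HEIDI with a top-SNP reference fails when the strongest
  instrument is itself pleiotropic (inherent to reference-based outlier
  tests).
- The weighted-median bootstrap ignores LD (flagged above).
- No MR-PRESSO/mode-based/multivariable/bidirectional estimators; trans
  instruments and proxy-SNP lookup are out of scope.
- The BH family size is recomputed per run from attempted cells; analyses
  with different thresholds form different families.
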