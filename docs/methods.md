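# Methods

## Model and estimand

Two traits X and Y are modeled linearly with a hidden confounder U and m
genetic instruments g (dosages 0/1/2):

    X = β_X0 + β_Xg·g + β_XU·U + ε_X
    Y = β_Y0 + β_YX·X + α·g + β_YU·U + ε_Y

α holds per-SNP direct (horizontally pleiotropic) effects on Y; α = 0 is
the valid-instrument case. The estimand is the correlation ratio
K_YX = β_YX·sqrt(var X / var Y), the common value of ρ_Yg/ρ_Xg across valid
instruments. K_YX = 0 iff β_YX = 0, and |K_YX| < 1 under the key condition
var(Y) > β²_YX var(X), which holds automatically without confounding and can
fail only when β_YX·β_YU·cov(X,U) is strongly negative. A summary-data
diagnostic reconstructs per-SNP trait variances as
β̂²·var(g) + (n−2)·se²·var(g) with var(g) = 2·MAF·(1−MAF) and compares the
spread of var(Y)/var(X) against an external β̂²_YX. The variance reported is
never enforced; an R²_YX heuristic (< 0.2 makes the condition hold in
practice) is echoed when supplied.

## From summary statistics to correlations

r = β̂ / sqrt(β̂² + (n−2)·se²) inverts simple-OLS algebra exactly (tested to
1e−12 against direct Pearson correlations). The asymptotic covariance of
√n(r − ρ) uses the classical expression for two sample correlations sharing
one variable (Pearson–Filon / Olkin–Siegel family): diagonal (1−r_i²)², and

    V_ij = ρ_ij(1 − r_i² − r_j²) − ½ r_i r_j (1 − r_i² − r_j² − ρ_ij²)

with plug-in sample values: r for SNP–trait, reference-panel LD for
SNP–SNP. The reconstruction is validated against a 20,000-replicate
Monte-Carlo covariance (agreement within 3 MC standard errors entrywise).
The two cohorts are independent, so the ratio vector r_Yg/r_Xg has
block-diagonal input covariance and a delta-method normal law with Jacobian
entries 1/r_Xi and −r_Yi/r_Xi². Denominator correlations with
|r_Xg| < 1e−4 (τ_den) are rejected: the ratio has no useful normal
approximation near a zero denominator, and instruments are required to be
associated with both traits anyway.

## Estimators

**CD-Ratio.** K̂ = (1ᵀV⁻¹ρ̂)/(1ᵀV⁻¹1), var = 1/(1ᵀV⁻¹1): exact GLS on the
ratio vector; closed form, no iteration. Covariance matrices are
symmetrized and eigenvalues in [−1e−10, 0) clipped to 0 before solving;
anything more negative raises rather than being silently repaired.

**CD-Egger.** Mean model r_Yg = b₀·v + K·r_Xg with v = Σ1 (LD row sums) and
covariance W = V_Yg/n_Y + σ₀²Σ² (Σ² the matrix square — the direct-effect
contribution to a SNP's correlation is spread over its LD neighbors, so
b ∝ Σα with α i.i.d.). Fitting alternates (i) GLS for (b₀, K) given σ₀²
and (ii) a bounded 1-D maximization of the Gaussian log-likelihood over
σ₀² ∈ [0, 10], initialized at σ₀² = 0, until the largest parameter change
is below 1e−8 (cap 200 iterations; non-convergence returns the last iterate
flagged `converged=False`). This coordinate scheme ascends the joint
Gaussian likelihood, and its fixed point matches a generic joint optimizer
to ~1e−9 on toy instances. Standard errors come from (XᵀW⁻¹X)⁻¹ at the
final W, matching normal-based confidence intervals; no degrees-of-freedom
inflation is applied.

**CD-GLS.** Identical mean model with working covariance
W(K) = V_Yg/n_Y + σ₀²Σ² + K²·V_Xg/n_X, so the denominator correlations'
sampling noise is propagated instead of ignored. The update evaluates W at
the previous K (an iteratively-reweighted estimating equation). Its fixed
point is not exactly the joint-likelihood maximizer — the GLS step drops
the ∂log det W/∂K term — but the difference is O(1/n_X) (≈2e−5 on a toy at
n = 1e5, ≈3e−7 at n = 5e6) and vanishes in the GWAS regime, where CD-GLS
and CD-Egger agree to 1e−8 as V_Xg/n_X → 0. This working-covariance form is
a design choice of this package and is flagged as such.

**MV-CD-Egger.** Adds a third trait's correlations as a regressor,
X = [v, r_Xg, r_Ag]; the companion GOF test then has m−3 df. Collinear
designs (condition number > 1e10 of the information matrix) raise.

**bi-CD-Ratio.** CD-Ratio on two disjoint instrument sets: instruments for
X estimate K₁ (X→Y arm), instruments for Y estimate K₂ (Y→X arm). An arm
concludes an effect iff its CI lies completely inside [−1, 0) or (0, 1];
covering 0 concludes none; the four verdict combinations give
none / x_to_y / y_to_x / bidirectional.

**Allele orientation.** CD-Ratio is invariant to recoding any single SNP's
alleles. The Egger family is not: the directional intercept b₀ refers to a
specific orientation (the same orientation dependence as MR-Egger
regression); recoding all SNPs simultaneously leaves K unchanged and
negates b₀. Harmonization therefore fixes one consistent orientation before
estimation.

## Decision rules and GOF tests

With est_xy the fit of the X→Y parameter and est_yx of the Y→X parameter,
X→Y is concluded iff CI(est_xy) ⊂ [−1,0)∪(0,1] and CI(est_yx) is entirely
outside [−1,1]; symmetrically for Y→X; otherwise no conclusion. Interval
endpoints exactly at 0 or ±1 count as covered (conservative; boundaries are
measure-zero so the choice matters only for printed CIs). A separate
existence flag reports whether both, neither, or one of the CIs covers 0,
so the three-outcome rule itself stays exactly as stated.

Q_Ratio = (ρ̂ − K̂1)ᵀV⁻¹(ρ̂ − K̂1) ~ χ²(m−1) under valid instruments; its
null distribution passes a Kolmogorov–Smirnov check at the 1% level in
2,000-replicate calibrations once cohort sizes reach ~2e4 (plug-in error
dominates below that). Q_Egger is the analogous residual form at the fitted
(b₀, K, σ̂₀²). Because σ̂₀² is estimated from the same residuals, Q_Egger is
*not* exactly χ²(m−2): it is conservative when the true dispersion is ~0,
and when the σ₀²Σ² term dominates the weighted residual sum is pinned near
m by the ML stationarity condition, making the statistic nearly degenerate
(its χ²(m−2) upper tail is then ≈ the tail at Q = m regardless of the
data). Its type-I error is controlled (at or below nominal, verified by
simulation); users should read large Q_Egger p-values as "not rejected"
rather than as calibrated tail probabilities. Rejection power against
mean-model misspecification (e.g. instruments correlated with confounders)
is retained.

## Instrument selection

SNPs must be genome-wide significant (default p < 5e−8) for *both* traits.
Significant SNPs are assigned to predefined LD-independent loci (consumed
as BED; never computed here). Within each locus the p-values are ranked
ascending per trait, rank sums I_i = I_Xi + I_Yi sorted ascending, then a
greedy pass keeps a SNP iff its absolute LD correlation with every
already-kept SNP is < 0.8. Rank ties break by smaller min(p_X, p_Y), then
genomic position — the procedure must be deterministic. Within-locus
ranking is the default; a genome-wide ranking mode exists. Keep-iff-strictly
-below-cutoff is used (the alternative ≤ convention differs only at exactly
the cutoff, which is exposed as a parameter).

## Synthetic-data generator

The generator emulates the two-sample design the estimators assume: two
independent cohorts drawn from the same population, each scanned marginally
(per-SNP simple OLS with n−2-df residual variance, t-based two-sided
p-values, empirical allele frequencies; exact fits get a floored residual
variance). Defaults are the main study conditions: m = 22 SNPs, cohorts of
n = 97,800, instrument effects β_Xg from a standard normal truncated to
|β| ≥ 0.5 (rejection sampling), U ~ N(0,1) with unit loadings on both
traits, error variances 4, direct effects α_i ~ N(μ_α, σ_α²) — regimes:
none (μ=σ=0), balanced (μ=0, σ=0.1), directional (μ≠0). Structural
parameters (β_Xg, α) are drawn once per replicate and shared by both
cohorts; a `fix_beta_xg` mode freezes β_Xg across replicates so a single
true K applies to a whole study.

Genotypes come either from tiling a provided reference panel or from a
synthetic panel: latent Gaussians with equicorrelation 0.3 inside 4 LD
blocks, thresholded at each SNP's Hardy–Weinberg genotype frequencies with
MAF ~ U(0.05, 0.5). The genotype matrix is drawn once per study and held
fixed across replicates, mirroring a fixed reference-panel design. The true
MAF/LD of the emulated 22 variants are not published, so dispersion
magnitudes (sd and SE columns of the harness output) are
configuration-specific; only bias-type quantities (means against analytic
true K, computed from the drawn structural parameters and the genotype
covariance) are treated as reproducible. The latent-threshold construction
also means realized dosage correlations sit somewhat below the latent 0.3.

What the generator does not emulate: binary traits (all models are linear),
overlapping cohorts, genotyping error or imputation noise, weak-instrument
selection from genome-wide scans (instruments are the simulated SNPs
themselves), or instruments correlated with the confounder — the last is a
known unsolved case for this framework, and passing simulations say nothing
about it. Real summary data additionally carry allele-frequency and
harmonization ambiguities (palindromic SNPs are dropped by default, without
frequency-based strand inference).

With LD and sign-random instrument effects, (Cβ)_i can cancel near zero for
some SNP, putting that replicate's reverse-direction (or rarely forward)
ratio under the weak-denominator guard; the harness records the failure,
excludes the replicate from that method's averages, and counts it.

## Numerical choices

* PSD repair: symmetrize, clip eigenvalues in [−1e−10, 0) to 0.
* σ₀² search: scipy bounded Brent on [0, 10], xatol 1e−12, with an explicit
  boundary comparison at 0 (the bounded optimizer cannot land exactly on a
  bound).
* Convergence: max |parameter change| < 1e−8, ≤ 200 iterations.
* Weak-denominator guard τ_den = 1e−4 on |r_Xg|.
* Missing panel dosages are mean-imputed per SNP; LD shrinkage toward the
  identity is available (weight λ, default 0) for near-singular loci.
* p-values are clipped to [1e−300, 1] to keep them strictly positive.
* Steiger majority votes tie to "inconclusive"; Steiger p-values are
  two-sided; decisions use the same α as the CD confidence intervals
  (default 0.05).

## Known limitations

Asymptotic theory only (large n, small m): no finite-sample correction for
the Fisher transform of |r|, no exact distributions. No overlapping-sample
correction between the two GWAS. No handling of instruments associated with
the hidden confounder. The m² × m² covariance construction makes hundreds
of instruments impractical by design; prune correlated SNPs instead. The
Q_Egger caveat above applies to all dispersion-refitted residual tests in
this family.
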