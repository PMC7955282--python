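# Methods

Statistical model, estimator conventions and numerical design choices for
`mrmed`.  Notation: J instruments, per-variant exposure association
β̂_Xj ± σ_Xj (SD units of the exposure), outcome association β̂_Yj ± σ_Yj
(log odds ratio), causal effect θ.

## 1. Summary statistics and harmonization

`VariantAssociation` is a frozen record (variant id, effect/other allele,
beta, SE, optional EAF, p, N).  A stated p-value is validated against the
beta/SE-implied two-sided normal p on the z scale (ratio within
0.80–1.25) or by agreement to one significant figure; missing p-values are
recomputed.  This tolerates the rounding found in published summary files
while rejecting gross inconsistencies.

Harmonization intersects variant ids across all traits, takes the first
exposure's effect allele as the reference orientation, sign-flips rows
stored on swapped alleles, drops (and logs) allele mismatches, and by
default drops palindromic variants (A/T, C/G), whose strand cannot be
resolved without allele frequencies.  Instrument selection is strict
(p < 5×10⁻⁸).  LD clumping is greedy: rank by ascending p (ties broken
lexicographically by variant id for determinism), keep a variant iff its
r² with every previously kept variant is below the threshold (default
0.001).  For MVMR the pool of variants significant for *any* trait is
clumped on the minimum p across traits.  Associations reported in natural
units can be rescaled per SD of the phenotype (`rescale_to_sd`).

## 2. Univariable estimators

All four operate on the harmonized set; rows are weighted by
w_j = 1/σ_Yj² (second-order weights are not used).

**IVW** is zero-intercept weighted least squares of β̂_Y on β̂_X.  The SE
uses a multiplicative random-effects model: the fixed-effect SE times
max(1, √(Q/(J−1))), where Q is Cochran's statistic (the weighted residual
sum of squares).  The floor at 1 prevents under-dispersion from shrinking
the SE below fixed-effects.

**MR-Egger** adds a free intercept after orienting all rows to β̂_X ≥ 0.
The intercept estimates directional pleiotropy; its test uses a t
distribution with J−2 degrees of freedom.  The random-effects scale is
max(1, √(Q/(J−2))).

**Weighted median**: the ratio estimates θ̂_j = β̂_Yj/β̂_Xj are sorted and
the weighted empirical CDF (weights 1/se(θ̂_j)²) is interpolated at 0.5.
The SE comes from a seeded parametric bootstrap (default 1000 draws of
β̂_X and β̂_Y from their sampling distributions); `n_boot=0` returns the
point estimate alone.  The estimator is consistent while valid instruments
carry more than half the weight.

**Contamination mixture**: for a candidate θ on a grid, each variant
contributes the larger of a valid component N(θ̂_j; θ, se_j²) and an
invalid component N(θ̂_j; 0, se_j² + ψ²); the profile log-likelihood is
the sum of the per-variant maxima.  ψ defaults to 1.5·SD(θ̂_j).  The
default grid is IVW ± 5 SE with 2001 points.  The 95% confidence set is
{θ : ℓ(θ) ≥ ℓ_max − 1.92}; `ci_status` reports `ok` for a contiguous
interior interval, `non_contiguous` when the set splits (conflicting
ratio clusters), and `failed` when it touches the grid boundary.  The
acceptance suite checks the grid maximum against exhaustive enumeration
of all 2^J valid/invalid assignments.

## 3. MVMR and proportion mediated

MVMR regresses β̂_Y jointly on the K exposure-beta columns with zero
intercept and weights w_j, giving each exposure's direct effect
conditional on the others.  The random-effects scale is
max(1, √(Q/(J−K))).  A condition number above 10¹⁰ on X′WX raises
`DegenerateDesignError` naming the most correlated column pair.  MVMR
needs at least K+1 variants.

The proportion mediated is PM = 1 − direct/total on the log-OR scale,
with total the univariable IVW estimate on the exposure's own clumped
instruments.  The delta-method variance of R = direct/total is

    Var(R) = R² (se_d²/d² + se_t²/t² − 2·Cov(d,t)/(d·t)),

implemented in the algebraically equivalent form
(se_d² + R²·se_t² − 2R·Cov)/t², which stays finite as d → 0.

**Covariance between direct and total.**  When both estimates come from
the same outcome summary statistics they share sampling noise, and
treating them as independent materially overstates the PM standard error:
on the generator's default mediation scenario the zero-covariance SE is
0.050 against an empirical SD of 0.040, and 95% intervals cover the truth
98.7% of the time.  Both estimators are linear in the outcome betas, so
conditional on the exposure matrices

    Cov(direct, total) = [ (X′WX)⁻¹ X_A′ W_A x_A ]_e / (x_A′ W_A x_A),

where A is the total-effect instrument subset of the pooled MVMR set, x_A
the primary-exposure column on that subset, and e the primary-exposure
coordinate.  No random-effects scaling enters this term: the total
effect's overdispersion comes from mediated heterogeneity that the
mediator columns absorb in MVMR, so it is not shared.  With this
covariance the delta SE is 0.0395 against an empirical SD of 0.0404 and
coverage is 95.0% over 300 replicates (the acceptance suite re-verifies
coverage within 95% ± 3%).  `mediation_pipeline` applies the covariance
automatically; `proportion_mediated` defaults to zero covariance, which
is the correct choice when the two estimates come from independent data
or when only published marginal intervals are available (the worked
example reproduces a published 13–57% interval under exactly that
convention).

`mediation_pipeline` reports, for each mediator subset (each mediator
singly, then all jointly), the MVMR direct effect on a pooled-and-clumped
instrument set and the corresponding PM with its interval.  PM intervals
are deliberately not clipped to [0, 1]: sampling noise can push the
bounds outside.

## 4. Power and sample overlap

Instrument strength: F_j = (β̂_Xj/σ_Xj)².  Summed instrument r² uses
β²·2·EAF·(1−EAF) when frequencies are available, else z²/N.

Minimum detectable OR for a binary outcome with case fraction p:
se(θ̂) ≈ 1/√(N·r²·p·(1−p)) and the detectable log-OR is
(z_{1−α/2} + z_power)·se, defaults α = 0.05, power = 0.80.

Participant overlap: with overlap fraction ω, confounded observational
association b_obs (log-OR per unit exposure) and mean instrument strength
F̄, the expected null bias of the MR estimate is ω·b_obs/F̄, and the
two-sided z-test's type-I error is Φ(−z + b/se) + Φ(−z − b/se) with
b the bias and se the MR standard error.  Both closed forms are validated
against the individual-level simulator (below): over 150–200 replicates
of a fully overlapped, confounded null scenario the mean IVW estimate
matches ω·b_obs/F̄ and the empirical rejection rate matches the analytic
type-I error within Monte-Carlo error.

## 5. Synthetic-data generator

**Summary-level path.**  Each variant j gets an independent RNG substream
(`SeedSequence(seed, spawn_key=(j,))`), so enlarging a scenario preserves
earlier draws and all results are reproducible from one integer seed.
Per variant: MAF ~ U(0.05, 0.5); instrument effect γ_j ~ N(0, 0.05²)
truncated to |γ_j| ≥ 0.01 (or supplied explicitly); exposure SE
1/√(N_X·2·maf·(1−maf)); outcome SE
1/√(N_Y·p·(1−p)·2·maf·(1−maf)).  β̂_X ~ N(γ_j, σ_X²) and
β̂_Y ~ N(θ·γ_j + α_j + Σ_m θ_m·(ρ_m γ_j + δ_j), σ_Y²), where α_j is
horizontal pleiotropy (none / balanced / directional / InSIDE-violating,
plus an invalid fraction with a ratio offset) and each mediator m has
genetic correlation path ρ_m, causal effect θ_m and per-variant
heterogeneity δ_j ~ N(0, 0.02²).  Truth records (θ_total, θ_direct,
PM by subset) accompany every study.

Defaults (J = 50, N_X = 200 000, N_Y = 400 000, case fraction 0.15)
emulate large GWAS consortia: mean instrument F ≈ 150 and most variants
pass genome-wide significance, matching the strong-instrument regime of
published MR mediation analyses.

**Individual-level path** (for overlap experiments): genotypes
Binomial(2, maf); exposure X = Σ γ_j g_j + 0.7·U + ε with shared
confounder U ~ N(0,1); binary outcome by a logistic model with the
confounder path chosen to give observational slope b_obs; overlapping
individuals are literally shared between the two association analyses.
Per-variant logistic regressions are fitted by a vectorized Newton solver.
Guard rails (J ≤ 500, N ≤ 200 000) keep desk-scale runtimes; this path is
for calibration studies, not production data.

**Realism limits.**  Variants are simulated independent (LD enters only
through user-supplied r² matrices), allele frequencies are uniform rather
than ascertainment-skewed, winner's curse is not modelled (instrument
effects are known, not discovered in-sample), and the summary-level path
draws betas directly from their asymptotic sampling distributions.

## 6. Numerical choices

- All inference is normal-theory except the Egger intercept (t, J−2 df)
  and the weighted-median bootstrap.
- Random-effects scales are floored at 1 everywhere.
- The contamination-mixture grid resolution (2001 points over ±5 IVW SE)
  bounds discretization error at ~0.5% of an SE; the acceptance oracle
  tolerance is 2 grid steps.
- Replicate counts (500 recovery, 1000 null, 300 coverage, 150–200
  individual-level) balance Monte-Carlo error against a single-CPU,
  minutes-scale budget; binomial/SEM tolerances in the tests are set from
  those counts, not tuned to outcomes.
- Determinism: every stochastic routine takes an explicit seed; pipeline
  manifests record the config hash, and repeated runs are byte-identical.
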