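# Methods

## The two-sample MR model

Each SNP i provides a pair of marginal association estimates from two
non-overlapping GWAS: β̂_Xi ~ N(γ_i, σ²_Xi) for the exposure and
β̂_Yi ~ N(θγ_i + α_i, σ²_Yi) for the outcome, where θ is the causal effect
of interest and α_i is a direct (pleiotropic) SNP→outcome effect, zero for a
valid instrument. All estimators operate on a harmonized instrument table —
the per-SNP (β̂_X, σ_X, β̂_Y, σ_Y) pairs with the outcome effect expressed
per copy of the exposure's effect allele. For binary outcomes β̂_Y is a
log odds ratio and every causal estimate is reported both on the log-odds
scale and as exp(β).

### Harmonization

Tables are joined on variant id (rsID-style identifiers; chromosome and
position are carried as annotation only). When the outcome's effect/other
alleles are swapped relative to the exposure, the outcome beta is negated
and its allele frequency replaced by 1 − f. Palindromic SNPs (A/T, C/G)
cannot be disambiguated by allele labels; they are kept only when both
allele frequencies fall outside 0.5 ± `palindrome_eaf_tol` (default 0.08)
and lie on the same side of 0.5 — otherwise they are dropped and counted.
Allele sets matching neither directly nor after swap are dropped. Both
sides are assumed to report the forward strand; duplicated variant ids
(possible multi-allelics) are removed with a warning.

### Instrument selection

Five criteria, in the order p-value → MAF → F → LD clumping →
(post-harmonization) Steiger:

| parameter | default | meaning |
|---|---|---|
| `p_primary` | 5e-8 | genome-wide significance threshold |
| `p_fallback` | 1e-5 | used when < `min_snps_for_primary` (3) primary hits |
| `maf_min` | 0.01 | minor allele frequency floor |
| `f_min` | 10 | per-SNP instrument strength, F = (β̂/σ)² |
| `clump_r2` / `clump_window_kb` | 0.001 / 10,000 | greedy LD clumping |
| `steiger_alpha` | 0.05 | reporting threshold for the Steiger z-test |

Clumping is greedy by ascending p (ties broken by variant id): each index
SNP removes remaining same-chromosome SNPs within the window whose r² with
it exceeds the threshold. The LD matrix is supplied by the caller (or the
simulator); there is no remote reference-panel lookup.

The per-SNP F statistic uses the ratio form (β/σ)² rather than the
r²-based (n−2)r²/(1−r²) form; the two agree closely at GWAS sample sizes.

Steiger filtering estimates the variance explained on each side as
r² = β̂²·2f(1−f) / (β̂²·2f(1−f) + σ²·2f(1−f)·n) — algebraically
β̂²/(β̂² + σ²n) — and removes SNPs with r²_outcome ≥ r²_exposure (likely
reverse causation). Removal is keyed on the direction; the z statistic
(atanh√r²_exp − atanh√r²_out) / √(1/(n_exp−3) + 1/(n_out−3)) and its
two-sided p are reported for transparency. For binary outcomes the same
formula is applied to log-odds betas with the reported case-control n; this
is an approximation, adequate for direction calls when both GWAS are well
powered but conservative when the outcome's effective sample size is small.

### Estimators

- **Wald ratio** (1 SNP): β̂_Y/β̂_X with first-order delta SE σ_Y/|β̂_X|.
- **IVW**: weighted regression of β̂_Y on β̂_X through the origin, weights
  1/σ²_Y — equivalently the inverse-variance-weighted mean of per-SNP Wald
  ratios. Default is multiplicative random effects (the fixed-effect SE
  scaled by max(1, √(Q/(k−1)))); a fixed-effect model is available by flag.
- **Maximum likelihood**: the per-SNP means ξ_i of the bivariate normal
  model are profiled out in closed form, leaving
  −2ℓ(b) = Σ (β̂_Yi − b·β̂_Xi)² / (σ²_Yi + b²σ²_Xi), maximised by Brent's
  method from the IVW start (tolerance 1e-10, ≤200 iterations); the SE comes
  from the numerical curvature of the profile log-likelihood. When σ_X → 0
  this reduces exactly to fixed-effect IVW (used as a test oracle).
- **MR-Egger**: instruments oriented so β̂_X ≥ 0 (required for
  identifiability of the intercept), then weighted least squares with
  intercept; SEs carry a multiplicative over-dispersion factor
  max(1, √(RSS_w/(k−2))) and inference uses t with k−2 df. The intercept,
  its SE and p form the pleiotropy test.
- **Weighted median**: per-SNP ratios with weights β̂²_X/σ²_Y (the inverse
  first-order ratio variance); the estimate interpolates the weighted
  cumulative distribution at 0.5 using midpoint positions
  p_j = (S_j − w_j/2)/S_total. SE by parametric bootstrap (default 5,000
  draws, explicit seed).
- **Mode estimators**: Gaussian kernel density over the ratios with
  bandwidth h = 0.9·min(SD, MAD/0.6745)·k^(−1/5) times a user factor
  (falling back to whichever spread measure is nonzero when one degenerates),
  evaluated on a 512-point grid spanning the ratio range ± 3h; simple mode
  uses uniform weights, weighted mode the IVW ratio weights. SE by
  parametric bootstrap (default 1,000 draws).

Dispatch: one instrument → Wald ratio; two → IVW + maximum likelihood;
three or more → all six multi-instrument methods, with IVW flagged primary.
All p-values are two-sided; CIs use Φ⁻¹(0.975) (t-quantiles for Egger) so
that p < 0.05 and a CI excluding the null coincide exactly.

### Sensitivity diagnostics

Cochran's Q uses the ratio weights β̂²_X/σ²_Y against the IVW fit, with
I² = max(0, (Q−df)/Q). Note Q conditions on the instrument effects being
known: when σ_X is non-negligible and θ ≠ 0, the extra term θ²σ²_X inflates
Q by a factor ≈ 1 + θ²σ²_X/σ²_Y even without pleiotropy. Its type-I error
is therefore calibrated in a scenario with the exposure GWAS much larger
than the outcome GWAS (n_exp = 500k vs n_out = 50k), where the statistic's
own null model holds.

MR-PRESSO uses leave-one-out residuals: RSS = Σ w_i (β̂_Yi − β̂_IVW,−i
β̂_Xi)², compared against a parametric null simulation (β̂*_Yi ~
N(β̂_IVW,−i·β̂_Xi, σ²_Yi), β̂*_Xi ~ N(β̂_Xi, σ²_Xi), residuals recomputed
with each simulated dataset's own leave-one-out fits). Empirical p-values
use (1+r)/(n_sim+1) so they are never zero; per-SNP outlier p-values are
Bonferroni-adjusted by k; the distortion test compares the raw-vs-corrected
IVW shift against random outlier sets of the same size and runs only when at
least one outlier is flagged. The default n_sim is 1,000 (configurable);
results are bit-reproducible for a given seed.

## Mediation

Two-step MR: β(A) (exposure→mediator) and β(B) (mediator→outcome) come from
separate MR fits, each defaulting to the primary (IVW or Wald) estimate.
Indirect = β(A)·β(B); direct = total − indirect (exact by construction);
proportion mediated = 100·indirect/total. The indirect-effect SE is the
first-order delta (Sobel) form √(β(B)²se(A)² + β(A)²se(B)²), with the
second-order exact-variance term available behind a flag. The proportion SE
applies the ratio delta method treating indirect and total as independent —
their covariance is unobtainable from summary data because both involve the
exposure GWAS; this is a documented limitation. Proportions outside
[0, 100]% (inconsistent mediation) are reported with a warning, never
truncated; a zero total leaves the proportion undefined while the indirect
effect is still returned.

`run_two_step` fits all three legs from raw summary statistics. Leg-B
(mediator→outcome) instruments exclude SNPs that are genome-wide significant
for the exposure: such SNPs reach the mediator only through the exposure and
carry the direct path c′, so including them structurally biases β(B). This
exclusion is computed from the exposure's observed p-values — no ground
truth is consulted.

## Screening and FDR

`run_screen` applies the full pipeline per exposure, emits one row per
(exposure, method), and reports every exposure: those yielding zero
instruments appear in a skipped table rather than vanishing. BH adjustment
is computed across the primary-method family within one invocation
(per-method families by flag); non-primary rows carry no FDR value. Rows
are flagged "nominal" at raw p < 0.05 and "fdr_significant" at FDR < 0.05.
Reverse MR is the same machinery with trait roles swapped.

## The synthetic-data generator

Simulation happens at the summary-statistic level — no individual genotypes.
Per replicate: MAFs uniform on `maf_range` (default 0.05–0.5); standardized
instrument effects |N(0, h²/k)| with h² = `exposure_h2`; observed effects add
N(0, 1/n) noise and are converted to the per-allele scale with SE
1/√(2f(1−f)n). Binary outcomes are generated directly on the log-odds scale
with SEs based on the effective sample size 4/(1/cases + 1/controls), a
standard approximation that sidesteps logistic simulation. LD is block-wise
AR(1) (r = ρ^|i−j| within blocks, zero across); marginal effects and
sampling noise are correlated with exactly the emitted matrix, so clumping
tests are self-consistent. Pleiotropic SNPs receive a per-allele direct
outcome effect N(mean, sd²); reverse-causal SNPs originate on the outcome
with an induced exposure effect `reverse_theta` times their outcome effect,
giving them larger outcome than exposure r² (the Steiger target structure).
Chains draw k exposure-specific and k mediator-specific instruments;
mediator effects are a·γ (+ δ on its own instruments) and outcome effects
b·mediator + c′·γ, so the true total is a·b + c′ exactly. Every output is a
pure function of the configuration including its seed.

Design choices worth noting:

- **Effect-allele orientation.** Instrument effects are drawn in the
  exposure-increasing orientation (γ ≥ 0), matching how published instrument
  lists are reported. This also makes directional pleiotropy well-defined:
  with random orientations, Egger's β̂_X ≥ 0 re-orientation would sign-flip
  half the pleiotropy effects and no simulation could exhibit a nonzero
  true intercept.
- **Instrument strength.** Defaults (h² = 0.25 over 50 instruments,
  n = 50k) give per-instrument F ≈ 250 — the generator emulates an
  *already-selected* instrument panel, and published panels for strongly
  heritable molecular traits are of this strength. The choice matters
  because IVW-type estimators carry a weak-instrument attenuation of order
  1/F̄: recovery experiments can only resolve the causal effect when that
  attenuation is well below Monte-Carlo resolution. For the mediation chain
  the product of two legs tightens the Monte-Carlo SE
  (|bias|/(3·MCSE) ≈ k/√(n·h²) per leg at 300 replicates), so chain
  experiments use 25 instruments per leg (per-instrument r² 1%, F ≈ 500,
  pQTL scale).
- **Outcome scale.** The default outcome is quantitative so that both GWAS
  of a pair are equally powered (the Steiger experiments presume symmetric
  power). The biobank-style binary configuration —
  case fraction 3,504/500,348 on the log-odds scale — is provided as
  `nafld_outcome_config()` and exercised in dedicated tests.

What the generator does *not* emulate: real LD panels (block AR(1) only),
winner's-curse inflation of the selected instruments' effect sizes, sample
overlap between GWAS, population stratification, or allele-frequency
differences between studies. Passing tests therefore demonstrate
correctness of the statistical machinery under its stated assumptions, not
robustness to those real-data complications.

## Validation experiments (tests/test_acceptance.py, scripts/acceptance.py)

- Estimator recovery: 500 replicates at θ = 0.2, 50 SNPs, n = 50k/50k; each
  multi-SNP estimator's mean must sit within 3 Monte-Carlo SEs of 0.2 and
  IVW 95% CI coverage within [0.93, 0.97].
- Oracle equivalence: IVW vs closed-form WLS (statsmodels) to 1e-10;
  weighted median vs a brute-force percentile oracle; maximum likelihood vs
  IVW in the σ_X → 0 limit to 1e-6.
- Worked arithmetic: the hand-computable fixtures (IVW 0.4/0.0707, Q = 2
  with p ≈ 0.157, Sobel ≈ 0.06403, the 0.2/0.6/25% decomposition, the BH
  step-up example, F = 25) reproduce exactly.
- Calibration: Cochran's Q and Egger-intercept type-I error inside the
  binomial 95% band of 5% over 2,000 replicates (scenarios above); MR-PRESSO
  global p uniform under the null (KS over 200 replicates) and ≥ 90%
  planted-outlier detection; Steiger removes ≥ 95% of reverse-causal
  instruments.
- Mediation: 300 chain replicates; mean indirect within 3 MCSE of 0.15,
  delta CI coverage in [0.92, 0.98], direct ≡ total − indirect bitwise.
- FDR: a 100-exposure all-null screen over 200 replicates keeps the mean
  fraction of FDR < 0.05 calls at or below 0.05.

The acceptance script reruns the same experiments at reduced replicate
counts (its problem sizes are recorded in the emitted JSON) so a complete
reproduction stays within a few minutes on one CPU.

## Numerical conventions

p-values are floored at the smallest positive double; empirical p-values
use (1+r)/(n+1); clumping ties break lexicographically by variant id;
bootstrap SEs always require an explicit seed; subnormal totals in the
mediation proportion are treated as zero (guarding the squared term);
identical-ratio tables short-circuit the mode estimator's bandwidth rule.
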