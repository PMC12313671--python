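# mrpath

Two-sample Mendelian randomization (MR) and two-step mediation analysis on
GWAS summary statistics, with a synthetic-data generator that makes every
stage of the pipeline testable against known ground truth.

The package is aimed at analysts studying causal chains of the form
*exposure → mediator → disease* from published GWAS — for example, gut
microbial taxa acting on a binary liver-disease outcome through plasma
protein-ratio phenotypes. Only summary-level data are required: one table of
per-SNP marginal associations per trait.

## What it computes

For instruments i = 1…k with harmonized exposure effects β̂<sub>Xi</sub>
(SE σ<sub>Xi</sub>) and outcome effects β̂<sub>Yi</sub> (SE σ<sub>Yi</sub>):

- **Instrument selection** — p < 5×10⁻⁸ (fallback 1×10⁻⁵ when fewer than 3
  hits), MAF > 0.01, per-SNP F = (β̂/σ)² > 10, greedy LD clumping at
  r² ≤ 0.001 within 10,000 kb, and Steiger filtering (drop SNPs with
  r²<sub>outcome</sub> ≥ r²<sub>exposure</sub>).
- **Estimators** — Wald ratio β̂<sub>Y</sub>/β̂<sub>X</sub> (single IV);
  IVW β̂ = Σw<sub>i</sub>β̂<sub>Xi</sub>β̂<sub>Yi</sub> / Σw<sub>i</sub>β̂²<sub>Xi</sub>,
  w<sub>i</sub> = σ<sub>Yi</sub>⁻² (primary method, fixed or multiplicative
  random effects); profile maximum likelihood; MR-Egger regression with a
  pleiotropy-absorbing intercept; weighted median; simple and weighted
  kernel-mode estimators.
- **Diagnostics** — Cochran's Q and I², the Egger intercept test, MR-PRESSO
  global / outlier / distortion tests, leave-one-out IVW.
- **Mediation** — two-step MR: indirect = β(A)·β(B), direct = total −
  indirect, proportion mediated = 100·indirect/total, with delta-method
  (Sobel) confidence intervals.
- **Screening** — many exposures against one outcome with
  Benjamini–Hochberg FDR across the primary-method family, forest and
  method-matrix table export, and an optional reverse-MR mode.
- **Simulation** — summary-statistic-level generation of exposure/outcome
  pairs and exposure→mediator→outcome chains with configurable causal
  effects, LD blocks, balanced/directional pleiotropy, reverse-causal SNPs
  and binary (log-odds) outcomes.

## Worked example

```python
import mrpath as mp

cfg = mp.SimConfig(n_snps=50, theta=0.2, seed=42)     # true causal effect 0.2
exposure, outcome, ld, truth = mp.simulate_pair(cfg)

table, report = mp.harmonize(exposure, outcome,
                             exposure_name="taxon_A", outcome_name="NAFLD")
table, steiger = mp.steiger_filter(table)
for est in mp.estimate_all(table, seed=7):
    print(f"{est.method:>15}  beta={est.beta:+.3f}  se={est.se:.3f}  "
          f"OR={est.odds_ratio:.3f} [{est.or_ci[0]:.3f}, {est.or_ci[1]:.3f}]  p={est.pval:.2e}")
q = mp.cochran_q(table)
print(f"Cochran Q = {q.Q:.1f} (df {q.df}, p = {q.pval:.2f}, I2 = {q.i2:.2f})")
```

prints

```
            ivw  beta=+0.212  se=0.013  OR=1.236 [1.206, 1.267]  p=8.99e-63
 max_likelihood  beta=+0.214  se=0.012  OR=1.238 [1.209, 1.268]  p=5.25e-69
          egger  beta=+0.191  se=0.021  OR=1.210 [1.160, 1.262]  p=7.17e-12
weighted_median  beta=+0.222  se=0.018  OR=1.249 [1.205, 1.294]  p=1.11e-34
    simple_mode  beta=+0.211  se=0.035  OR=1.235 [1.153, 1.324]  p=2.02e-09
  weighted_mode  beta=+0.211  se=0.128  OR=1.235 [0.961, 1.587]  p=9.85e-02
Cochran Q = 53.8 (df 47, p = 0.23, I2 = 0.13)
```

Every method recovers the generating slope 0.2 within sampling error
(reported also as an odds ratio, exp(β)), and Q shows no heterogeneity, as
expected with no pleiotropy simulated.

Two-step mediation on a simulated chain with a = 0.3, b = 0.5, c′ = 0.1
(true indirect 0.15, true proportion 60%):

```python
ch = mp.simulate_chain(mp.SimConfig(n_snps=25, seed=42))
res = mp.run_two_step(ch.exposure, ch.mediator, ch.outcome, seed=7)
m = res.mediation
```

```
beta(A) = 0.289 (se 0.017)   beta(B) = 0.520 (se 0.016)
total   = 0.248    indirect = 0.151 [0.131, 0.170], p = 2.59e-52
direct  = 0.097   proportion mediated = 60.7% [50.9%, 70.5%]
```

A command-line interface mirrors the library
(`mrpath harmonize|select|mr|presso|mediate|screen|simulate --help`).

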