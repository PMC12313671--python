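"""Heterogeneity and pleiotropy diagnostics.

Cochran's Q (with I-squared) across per-SNP ratio estimates, the MR-PRESSO
global / outlier / distortion tests built on leave-one-out IVW residuals and
a parametric null simulation, and a leave-one-out IVW sensitivity table.
The Egger intercept test lives with the Egger estimator in
:mod:`mrpath.estimators`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import EstimatorError, MREstimate, _ivw_point, ivw
from .sumstats import InstrumentTable


@dataclass(frozen=True)
class HeterogeneityResult:
    Q: float
    df: int
    pval: float
    i2: float


@dataclass(frozen=True)
class PressoResult:
    rss_obs: float
    global_p: float
    outlier_indices: list[int]
    outlier_p: np.ndarray  # Bonferroni-adjusted, one per SNP
    distortion_p: float | None
    beta_raw: float
    beta_corrected: float | None
    n_sim: int
    seed: int | None


def cochran_q(table: InstrumentTable) -> HeterogeneityResult:
    """Cochran's Q over per-SNP Wald ratios, weights beta_exp^2 / se_out^2.

    Q = sum_i w_i (ratio_i - beta_IVW)^2 on k - 1 degrees of freedom;
    I^2 = max(0, (Q - df) / Q) summarises the proportional excess.
    """
    k = table.n_snps
    if k < 2:
        raise EstimatorError("cochran_q needs >= 2 instruments")
    bx, _, by, sy = table.arrays()
    beta, _ = _ivw_point(bx, by, sy)
    w = 1.0 / sy**2
    q = float(np.sum(w * (by - beta * bx) ** 2))
    df = k - 1
    pval = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return HeterogeneityResult(Q=q, df=df, pval=max(pval, np.nextafter(0, 1)), i2=i2)


def _loo_ivw_betas(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """IVW slope excluding each SNP in turn, from running sums (vectorised)."""
    swxy = np.sum(w * bx * by)
    swxx = np.sum(w * bx * bx)
    return (swxy - w * bx * by) / (swxx - w * bx * bx)


def mr_presso(
    table: InstrumentTable,
    n_sim: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> PressoResult:
    """MR-PRESSO: residual-sum-of-squares test for pleiotropic outliers.

    The observed statistic is RSS = sum_i w_i (beta_out_i - beta_loo_i *
    beta_exp_i)^2 with w_i = 1/se_out_i^2 and beta_loo_i the IVW fit leaving
    SNP i out.  A null distribution is built from ``n_sim`` parametric
    simulations (beta_out_i* ~ N(beta_loo_i * beta_exp_i, se_out_i^2),
    beta_exp_i* ~ N(beta_exp_i, se_exp_i^2), residuals recomputed with the
    simulated data's own leave-one-out fits).  Per-SNP outlier p-values are
    Bonferroni-adjusted by k; when outliers are flagged, the distortion test
    compares the raw-vs-corrected IVW shift against random outlier sets of
    the same size.  Empirical p-values use (1 + r) / (n_sim + 1).
    """
    import warnings

    k = table.n_snps
    if k < 4:
        raise EstimatorError("mr_presso needs >= 4 instruments")
    if n_sim < 100:
        warnings.warn("n_sim < 100 gives very coarse empirical p-values", stacklevel=2)
    bx, sx, by, sy = table.arrays()
    w = 1.0 / sy**2
    beta_loo = _loo_ivw_betas(bx, by, w)
    res_obs = w * (by - beta_loo * bx) ** 2
    rss_obs = float(np.sum(res_obs))

    rng = np.random.default_rng(seed)
    bxs = rng.normal(bx, sx, size=(n_sim, k))
    bys = rng.normal(beta_loo * bx, sy, size=(n_sim, k))
    ws = w[None, :]
    swxy = np.sum(ws * bxs * bys, axis=1, keepdims=True)
    swxx = np.sum(ws * bxs * bxs, axis=1, keepdims=True)
    loo_star = (swxy - ws * bxs * bys) / (swxx - ws * bxs * bxs)
    res_star = ws * (bys - loo_star * bxs) ** 2
    rss_star = np.sum(res_star, axis=1)

    global_p = float((1 + np.sum(rss_star >= rss_obs)) / (n_sim + 1))
    raw_p = (1 + np.sum(res_star >= res_obs[None, :], axis=0)) / (n_sim + 1)
    outlier_p = np.minimum(1.0, raw_p * k)
    outlier_idx = [int(i) for i in np.flatnonzero(outlier_p < alpha)]

    beta_raw, _ = _ivw_point(bx, by, sy)
    beta_corrected: float | None = None
    distortion_p: float | None = None
    if outlier_idx:
        keep = np.ones(k, dtype=bool)
        keep[outlier_idx] = False
        if keep.sum() >= 2:
            beta_corrected, _ = _ivw_point(bx[keep], by[keep], sy[keep])
            d_obs = beta_raw - beta_corrected
            n_out = len(outlier_idx)
            diffs = np.empty(n_sim)
            for s in range(n_sim):
                drop = rng.choice(k, size=n_out, replace=False)
                m = np.ones(k, dtype=bool)
                m[drop] = False
                b_s, _ = _ivw_point(bx[m], by[m], sy[m])
                diffs[s] = beta_raw - b_s
            distortion_p = float((1 + np.sum(np.abs(diffs) >= abs(d_obs))) / (n_sim + 1))
    return PressoResult(
        rss_obs=rss_obs,
        global_p=global_p,
        outlier_indices=outlier_idx,
        outlier_p=outlier_p,
        distortion_p=distortion_p,
        beta_raw=float(beta_raw),
        beta_corrected=beta_corrected,
        n_sim=n_sim,
        seed=seed,
    )


def leave_one_out(table: InstrumentTable, ivw_model: str = "multiplicative_random") -> pd.DataFrame:
    """IVW re-estimated leaving each SNP out in turn.

    Returns one row per SNP with the reduced-table estimate and a flag for
    rows whose CI excludes the full-table estimate (influential SNPs).
    """
    k = table.n_snps
    if k < 3:
        raise EstimatorError("leave_one_out needs >= 3 instruments")
    full = ivw(table, model=ivw_model)
    rows = []
    for i in range(k):
        sub = table.drop_rows([i])
        est = ivw(sub, model=ivw_model)
        rows.append(
            {
                "left_out_variant": table.data["variant_id"].iloc[i],
                "beta": est.beta,
                "se": est.se,
                "pval": est.pval,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "excludes_full_estimate": not (est.ci_low <= full.beta <= est.ci_high),
            }
        )
    return pd.DataFrame(rows)
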