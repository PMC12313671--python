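"""Causal-effect estimators for two-sample MR on a harmonized instrument table.

Six estimators, each consuming per-SNP (beta_exp, se_exp, beta_out, se_out)
pairs: the Wald ratio (single instrument), inverse-variance-weighted
meta-analysis of ratio estimates (the primary method; fixed or multiplicative
random effects), profile maximum likelihood, MR-Egger regression (intercept
absorbs directional pleiotropy), the weighted median, and kernel-mode
estimators (simple and weighted).  :func:`estimate_all` applies the dispatch
rule: Wald ratio for one instrument, IVW + maximum likelihood for two, all
six multi-instrument methods for three or more.

Conventions: all p-values are two-sided; confidence intervals are 95% and
normal-based, except MR-Egger which uses a t reference with k - 2 degrees of
freedom; weighted-median and mode standard errors come from a parametric
bootstrap with an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import optimize, stats

from .sumstats import InstrumentTable

Z95 = float(stats.norm.ppf(0.975))

METHODS = (
    "wald_ratio",
    "ivw",
    "max_likelihood",
    "egger",
    "weighted_median",
    "simple_mode",
    "weighted_mode",
)


class EstimatorError(ValueError):
    """Table unsuitable for the requested estimator."""


class ConvergenceError(RuntimeError):
    """Iterative optimisation failed to converge."""


@dataclass(frozen=True)
class MREstimate:
    """One method's causal-effect estimate.

    ``beta`` is on the outcome scale per unit exposure (log odds ratio per
    unit for a binary outcome); ``extra`` carries method-specific values such
    as the Egger intercept.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    extra: dict[str, Any] = field(default_factory=dict)

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


def _normal_estimate(
    method: str, beta: float, se: float, k: int, extra: dict[str, Any] | None = None
) -> MREstimate:
    z = beta / se if se > 0 else 0.0
    pval = float(min(1.0, 2.0 * stats.norm.sf(abs(z)))) if se > 0 else 1.0
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        pval=max(pval, np.nextafter(0, 1)),
        n_snps=k,
        extra=extra or {},
    )


def _ratios_weights(table: InstrumentTable) -> tuple[np.ndarray, np.ndarray]:
    bx, _, by, sy = table.arrays()
    if np.any(bx == 0):
        raise EstimatorError("degenerate instrument: beta_exp = 0 (filter first)")
    return by / bx, bx**2 / sy**2


def wald_ratio(table: InstrumentTable) -> MREstimate:
    """Single-instrument ratio estimate with first-order delta SE."""
    if table.n_snps != 1:
        raise EstimatorError("wald_ratio requires exactly one instrument")
    bx, _, by, sy = (float(v[0]) for v in table.arrays())
    if bx == 0:
        raise EstimatorError("degenerate instrument: beta_exp = 0")
    return _normal_estimate("wald_ratio", by / bx, sy / abs(bx), 1)


def _ivw_point(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[float, float]:
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / denom
    return beta, denom**-0.5


def ivw(table: InstrumentTable, model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted meta-analysis of Wald ratios.

    Equivalent to weighted regression of beta_out on beta_exp through the
    origin with weights 1/se_out^2.  ``multiplicative_random`` (the default)
    inflates the fixed-effect SE by max(1, sqrt(Q / (k - 1))).
    """
    if model not in ("fixed", "multiplicative_random"):
        raise EstimatorError(f"unknown IVW model: {model}")
    if table.n_snps < 2:
        raise EstimatorError("ivw needs >= 2 instruments; use wald_ratio for one")
    bx, _, by, sy = table.arrays()
    beta, se = _ivw_point(bx, by, sy)
    k = table.n_snps
    w = 1.0 / sy**2
    q = float(np.sum(w * (by - beta * bx) ** 2))
    extra = {"model": model, "Q": q}
    if model == "multiplicative_random":
        se *= max(1.0, np.sqrt(q / (k - 1)))
    return _normal_estimate("ivw", beta, se, k, extra)


def _profile_nll(b: float, bx: np.ndarray, sx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> float:
    return 0.5 * float(np.sum((by - b * bx) ** 2 / (sy**2 + b**2 * sx**2)))


def max_likelihood(table: InstrumentTable) -> MREstimate:
    """Profile maximum likelihood allowing for exposure-side noise.

    Model: observed beta_exp_i ~ N(xi_i, se_exp_i^2) and beta_out_i ~
    N(b * xi_i, se_out_i^2); the per-SNP means xi_i are profiled out in
    closed form, leaving a one-dimensional likelihood in b that is maximised
    numerically from the IVW starting point.  SE from the observed-information
    curvature of the profile likelihood.
    """
    if table.n_snps < 2:
        raise EstimatorError("max_likelihood needs >= 2 instruments")
    bx, sx, by, sy = table.arrays()
    b0, _ = _ivw_point(bx, by, sy)
    nll = lambda b: _profile_nll(b, bx, sx, by, sy)  # noqa: E731
    res = optimize.minimize_scalar(
        nll,
        bracket=(b0 - 1.0, b0, b0 + 1.0) if nll(b0) < min(nll(b0 - 1.0), nll(b0 + 1.0)) else None,
        method="brent",
        options={"xtol": 1e-10, "maxiter": 200},
    )
    if not res.success or not np.isfinite(res.x):
        raise ConvergenceError(
            f"profile likelihood failed to converge after {res.nit} iterations (b = {res.x})"
        )
    b = float(res.x)
    h = 1e-4 * (1.0 + abs(b))
    d2 = (nll(b - h) - 2.0 * nll(b) + nll(b + h)) / h**2
    if d2 <= 0:
        raise ConvergenceError("non-positive curvature at the profile optimum")
    return _normal_estimate("max_likelihood", b, d2**-0.5, table.n_snps)


def egger(table: InstrumentTable) -> tuple[MREstimate, float, float, float]:
    """MR-Egger: weighted regression with a pleiotropy-absorbing intercept.

    Instruments are oriented so beta_exp >= 0 (both betas flipped otherwise),
    then beta_out is regressed on beta_exp with an intercept, weights
    1/se_out^2.  SEs carry a multiplicative over-dispersion factor
    max(1, sqrt(RSS_w / (k - 2))); inference uses t with k - 2 df.

    Returns (slope estimate, intercept, intercept SE, intercept p).
    """
    k = table.n_snps
    if k < 3:
        raise EstimatorError("egger needs >= 3 instruments")
    bx, _, by, sy = table.arrays()
    flip = bx < 0
    bx = np.where(flip, -bx, bx)
    by = np.where(flip, -by, by)
    w = 1.0 / sy**2
    s0, sx1 = float(np.sum(w)), float(np.sum(w * bx))
    sxx = float(np.sum(w * bx * bx))
    sy1, sxy = float(np.sum(w * by)), float(np.sum(w * bx * by))
    den = s0 * sxx - sx1**2
    if den <= 0:
        raise EstimatorError("degenerate design: no spread in beta_exp")
    slope = (s0 * sxy - sx1 * sy1) / den
    intercept = (sy1 * sxx - sx1 * sxy) / den
    rss = float(np.sum(w * (by - intercept - slope * bx) ** 2))
    phi = max(1.0, rss / (k - 2))
    se_slope = np.sqrt(phi * s0 / den)
    se_int = np.sqrt(phi * sxx / den)
    tdist = stats.t(df=k - 2)
    tcrit = float(tdist.ppf(0.975))
    p_slope = float(min(1.0, 2.0 * tdist.sf(abs(slope / se_slope))))
    p_int = float(min(1.0, 2.0 * tdist.sf(abs(intercept / se_int))))
    est = MREstimate(
        method="egger",
        beta=float(slope),
        se=float(se_slope),
        ci_low=float(slope - tcrit * se_slope),
        ci_high=float(slope + tcrit * se_slope),
        pval=max(p_slope, np.nextafter(0, 1)),
        n_snps=k,
        extra={
            "intercept": float(intercept),
            "intercept_se": float(se_int),
            "intercept_p": p_int,
            "overdispersion": phi,
        },
    )
    return est, float(intercept), float(se_int), p_int


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order]
    s = np.cumsum(w)
    p = (s - 0.5 * w) / s[-1]
    return float(np.interp(0.5, p, r))


def weighted_median(
    table: InstrumentTable, n_boot: int = 5000, seed: int | None = None
) -> MREstimate:
    """Weighted median of per-SNP ratio estimates.

    Consistent when valid instruments carry more than half the weight
    (weights beta_exp^2 / se_out^2, the inverse first-order variance of the
    ratio).  SE from a parametric bootstrap resampling beta_exp and beta_out
    from their sampling distributions.
    """
    if table.n_snps < 3:
        raise EstimatorError("weighted_median needs >= 3 instruments")
    ratios, weights = _ratios_weights(table)
    beta = _weighted_median(ratios, weights)
    bx, sx, by, sy = table.arrays()
    rng = np.random.default_rng(seed)
    bxs = rng.normal(bx, sx, size=(n_boot, table.n_snps))
    bys = rng.normal(by, sy, size=(n_boot, table.n_snps))
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bxi = bxs[i]
        bxi = np.where(bxi == 0, np.finfo(float).tiny, bxi)
        boots[i] = _weighted_median(bys[i] / bxi, bxi**2 / sy**2)
    se = float(np.std(boots, ddof=1))
    return _normal_estimate(
        "weighted_median", beta, se, table.n_snps, {"n_boot": n_boot, "seed": seed}
    )


def _kde_mode(ratios: np.ndarray, weights: np.ndarray, bandwidth_factor: float) -> float:
    k = ratios.size
    sd = float(np.std(ratios, ddof=1)) if k > 1 else 0.0
    mad = float(np.median(np.abs(ratios - np.median(ratios)))) / 0.6745
    spread = min(sd, mad) if (sd > 0 and mad > 0) else max(sd, mad)
    h = bandwidth_factor * 0.9 * spread * k ** (-1 / 5)
    if h <= 0:
        return float(ratios[0])  # all ratios identical
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512)
    dens = np.sum(
        weights[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2),
        axis=0,
    )
    return float(grid[np.argmax(dens)])


def mode_estimator(
    table: InstrumentTable,
    weighted: bool = True,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Mode of the kernel-smoothed ratio density (ZEMPA assumption).

    Gaussian kernel with bandwidth 0.9 * min(SD, MAD/0.6745) * k^(-1/5)
    scaled by ``bandwidth_factor``; density evaluated on a 512-point grid
    spanning the ratio range +/- 3 bandwidths.  ``weighted`` uses inverse
    ratio-variance weights; otherwise all instruments count equally.  SE from
    a seeded parametric bootstrap.
    """
    if table.n_snps < 3:
        raise EstimatorError("mode estimators need >= 3 instruments")
    ratios, ivw_weights = _ratios_weights(table)
    weights = ivw_weights if weighted else np.ones_like(ratios)
    beta = _kde_mode(ratios, weights, bandwidth_factor)
    bx, sx, by, sy = table.arrays()
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bxi = rng.normal(bx, sx)
        byi = rng.normal(by, sy)
        bxi = np.where(bxi == 0, np.finfo(float).tiny, bxi)
        wi = bxi**2 / sy**2 if weighted else weights
        boots[i] = _kde_mode(byi / bxi, wi, bandwidth_factor)
    se = float(np.std(boots, ddof=1))
    method = "weighted_mode" if weighted else "simple_mode"
    return _normal_estimate(
        method, beta, se, table.n_snps,
        {"n_boot": n_boot, "seed": seed, "bandwidth_factor": bandwidth_factor},
    )


def estimate_all(
    table: InstrumentTable,
    seed: int | None = None,
    *,
    ivw_model: str = "multiplicative_random",
    n_boot_median: int = 5000,
    n_boot_mode: int = 1000,
    methods: tuple[str, ...] | None = None,
) -> list[MREstimate]:
    """Dispatch: Wald ratio for 1 SNP, IVW + ML for 2, all six for >= 3.

    The primary method (IVW, or Wald ratio for a single instrument) is
    flagged via ``extra["primary"]``.  ``methods`` restricts the multi-SNP
    method set (the primary is always included).
    """
    if table.n_snps == 0:
        raise EstimatorError("empty instrument table")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    if table.n_snps == 1:
        est = wald_ratio(table)
        est.extra["primary"] = True
        return [est]
    wanted = set(methods) if methods is not None else set(METHODS)
    out: list[MREstimate] = []
    primary = ivw(table, model=ivw_model)
    primary.extra["primary"] = True
    out.append(primary)
    if "max_likelihood" in wanted:
        out.append(max_likelihood(table))
    if table.n_snps >= 3:
        if "egger" in wanted:
            out.append(egger(table)[0])
        if "weighted_median" in wanted:
            out.append(weighted_median(table, n_boot=n_boot_median, seed=seeds[0]))
        if "simple_mode" in wanted:
            out.append(mode_estimator(table, weighted=False, n_boot=n_boot_mode, seed=seeds[1]))
        if "weighted_mode" in wanted:
            out.append(mode_estimator(table, weighted=True, n_boot=n_boot_mode, seed=seeds[2]))
    return out
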