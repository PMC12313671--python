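"""Two-step MR mediation analysis.

The exposure -> mediator effect beta(A) and the mediator -> outcome effect
beta(B) come from two separate two-sample MR fits; their product is the
indirect (mediated) effect, the direct effect is total - indirect, and the
proportion mediated is 100 * indirect / total.  Confidence intervals for the
indirect effect use the first-order delta method (Sobel), treating the two
legs as independent because they are estimated from non-overlapping GWAS
pairs; the proportion CI applies the ratio delta method to indirect and
total.  :func:`run_two_step` orchestrates the three MR legs from raw summary
statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import Z95, MREstimate, estimate_all
from .selection import LDMatrix, SelectionConfig, instrument_pipeline
from .sumstats import SumStats


class MediationError(ValueError):
    pass


@dataclass(frozen=True)
class MediationResult:
    """Effect decomposition for one exposure -> mediator -> outcome triple."""

    beta_a: float
    se_a: float
    beta_b: float
    se_b: float
    total: float
    se_total: float
    indirect: float
    se_indirect: float
    ci_indirect: tuple[float, float]
    pval_indirect: float
    direct: float
    proportion: float          # percent; NaN when total == 0
    se_proportion: float       # NaN when indirect == 0 or total == 0
    ci_proportion: tuple[float, float]
    degenerate: bool = False   # both legs exactly zero

    @property
    def proportion_defined(self) -> bool:
        return np.isfinite(self.proportion)


def sobel_se(beta_a: float, se_a: float, beta_b: float, se_b: float) -> float:
    """First-order delta (Sobel) SE of the product beta_a * beta_b.

    sqrt(beta_b^2 se_a^2 + beta_a^2 se_b^2); the legs are assumed
    independent (they come from separate MR fits).  Exact-variance variant
    adds the se_a^2 * se_b^2 cross term, see :func:`product_se`.
    """
    if se_a <= 0 or se_b <= 0:
        raise MediationError("standard errors must be positive")
    return float(np.sqrt(beta_b**2 * se_a**2 + beta_a**2 * se_b**2))


def product_se(beta_a: float, se_a: float, beta_b: float, se_b: float, exact: bool = False) -> float:
    """Sobel SE, optionally with the second-order (exact-variance) term."""
    base = sobel_se(beta_a, se_a, beta_b, se_b) ** 2
    if exact:
        base += se_a**2 * se_b**2
    return float(np.sqrt(base))


def mediate(
    est_a: MREstimate,
    est_b: MREstimate,
    est_total: MREstimate,
    *,
    exact_variance: bool = False,
) -> MediationResult:
    """Combine the two mediation legs with the total effect.

    ``est_a``: exposure -> mediator; ``est_b``: mediator -> outcome;
    ``est_total``: exposure -> outcome (the primary MR fit).  The proportion
    mediated is reported even outside [0, 100]% (inconsistent mediation),
    with a warning.
    """
    a, b = est_a.beta, est_b.beta
    indirect = a * b
    degenerate = a == 0.0 and b == 0.0
    se_ind = (
        0.0
        if degenerate
        else product_se(a, est_a.se, b, est_b.se, exact=exact_variance)
    )
    ci_ind = (indirect - Z95 * se_ind, indirect + Z95 * se_ind)
    pval = (
        float(min(1.0, 2.0 * stats.norm.sf(abs(indirect / se_ind))))
        if se_ind > 0
        else float("nan")
    )
    total = est_total.beta
    direct = total - indirect
    if total * total > 0.0:  # squared guard: subnormal totals underflow
        proportion = 100.0 * indirect / total
        if indirect * indirect > 0.0:
            se_prop = abs(proportion) * np.sqrt(
                se_ind**2 / indirect**2 + est_total.se**2 / total**2
            )
            ci_prop = (proportion - Z95 * se_prop, proportion + Z95 * se_prop)
        else:
            se_prop = float("nan")
            ci_prop = (float("nan"), float("nan"))
        if not (0.0 <= proportion <= 100.0):
            warnings.warn(
                f"proportion mediated {proportion:.1f}% outside [0, 100]% "
                "(inconsistent mediation)",
                stacklevel=2,
            )
    else:
        proportion = float("nan")
        se_prop = float("nan")
        ci_prop = (float("nan"), float("nan"))
    return MediationResult(
        beta_a=float(a),
        se_a=float(est_a.se),
        beta_b=float(b),
        se_b=float(est_b.se),
        total=float(total),
        se_total=float(est_total.se),
        indirect=float(indirect),
        se_indirect=float(se_ind),
        ci_indirect=(float(ci_ind[0]), float(ci_ind[1])),
        pval_indirect=pval,
        direct=float(direct),
        proportion=float(proportion),
        se_proportion=float(se_prop),
        ci_proportion=(float(ci_prop[0]), float(ci_prop[1])),
        degenerate=degenerate,
    )


def mediation_screen(
    candidates: Sequence[tuple[tuple[str, str, str], MREstimate, MREstimate, MREstimate]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tabulate mediation results for labelled (exposure, mediator, outcome) triples.

    Rows sorted by the indirect-effect p-value, with a significance column at
    ``alpha``.
    """
    labels = [c[0] for c in candidates]
    if len(set(labels)) != len(labels):
        raise MediationError("duplicate (exposure, mediator, outcome) labels")
    rows = []
    for (exp_l, med_l, out_l), ea, eb, et in candidates:
        r = mediate(ea, eb, et)
        rows.append(
            {
                "exposure": exp_l,
                "mediator": med_l,
                "outcome": out_l,
                "beta_a": r.beta_a,
                "se_a": r.se_a,
                "beta_b": r.beta_b,
                "se_b": r.se_b,
                "indirect": r.indirect,
                "se_indirect": r.se_indirect,
                "ci_low": r.ci_indirect[0],
                "ci_high": r.ci_indirect[1],
                "pval": r.pval_indirect,
                "total": r.total,
                "direct": r.direct,
                "proportion_pct": r.proportion,
                "prop_ci_low": r.ci_proportion[0],
                "prop_ci_high": r.ci_proportion[1],
                "significant": r.pval_indirect < alpha if np.isfinite(r.pval_indirect) else False,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values("pval", kind="mergesort").reset_index(drop=True)
    return df


@dataclass
class TwoStepResult:
    mediation: MediationResult
    est_a: MREstimate
    est_b: MREstimate
    est_total: MREstimate


def _primary(estimates: list[MREstimate]) -> MREstimate:
    for e in estimates:
        if e.extra.get("primary"):
            return e
    return estimates[0]


def run_two_step(
    exposure: "SumStats | pd.DataFrame",
    mediator: "SumStats | pd.DataFrame",
    outcome: "SumStats | pd.DataFrame",
    ld: LDMatrix | None = None,
    config: SelectionConfig | None = None,
    seed: int | None = None,
    *,
    exclude_exposure_significant: bool = True,
) -> TwoStepResult:
    """Full two-step mediation from three summary-statistics tables.

    Three MR legs are fitted with the standard selection pipeline: total
    (exposure -> outcome) and leg A (exposure -> mediator) both use the
    exposure's instruments; leg B (mediator -> outcome) uses the mediator's
    instruments.  With ``exclude_exposure_significant`` (default), SNPs that
    reach the primary threshold for the exposure are excluded from leg B so
    that the mediator's instrument set is not contaminated by variants acting
    through the exposure's direct path.  Each leg's effect is the primary
    (IVW or Wald-ratio) estimate.
    """
    config = config or SelectionConfig()
    from .sumstats import _as_frame

    exp_f = _as_frame(exposure)
    med_f = _as_frame(mediator)
    out_f = _as_frame(outcome)

    t_total, _ = instrument_pipeline(exp_f, out_f, ld, config)
    t_a, _ = instrument_pipeline(exp_f, med_f, ld, config)
    excl = (
        exp_f.loc[exp_f["pval"] < config.p_primary, "variant_id"]
        if exclude_exposure_significant
        else None
    )
    t_b, _ = instrument_pipeline(med_f, out_f, ld, config, exclude_ids=excl)
    for name, t in (("total", t_total), ("A", t_a), ("B", t_b)):
        if t.n_snps == 0:
            raise MediationError(f"no instruments survived selection for leg {name}")
    kw = dict(methods=("ivw",), n_boot_median=0, n_boot_mode=0)
    est_total = _primary(estimate_all(t_total, seed=seed, **kw))
    est_a = _primary(estimate_all(t_a, seed=seed, **kw))
    est_b = _primary(estimate_all(t_b, seed=seed, **kw))
    return TwoStepResult(
        mediation=mediate(est_a, est_b, est_total),
        est_a=est_a,
        est_b=est_b,
        est_total=est_total,
    )
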