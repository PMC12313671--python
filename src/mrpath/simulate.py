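"""Synthetic GWAS summary statistics with known ground truth.

Generates per-SNP marginal effect estimates for an exposure/outcome pair or
an exposure -> mediator -> outcome chain, directly on the summary-statistic
level (no individual genotypes): true standardized instrument effects are
drawn once, optionally correlated in LD blocks, propagated through the
configured causal structure (causal effect ``theta``, or chain coefficients
``a``, ``b``, ``c_prime``), perturbed by a configurable fraction of
pleiotropic instruments (balanced or directional) and of reverse-causal
SNPs, and finally observed with sampling noise matching each GWAS's sample
size.  Binary outcomes are generated on the log-odds scale with
effective-sample-size standard errors.  Every output is a pure function of
the configuration, including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .selection import LDMatrix
from .sumstats import CANONICAL_COLUMNS, InstrumentTable


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters for one synthetic dataset.

    Effects are drawn for an already-selected instrument panel, so
    ``exposure_h2`` is the variance the panel explains jointly: the default
    0.25 over 50 instruments gives per-instrument r^2 of 0.5% (F ~ 250 at
    n = 50,000), typical of published instrument sets for strongly heritable
    molecular traits.  ``case_fraction`` defaults to the NAFLD case share in
    a large biobank-style case-control GWAS (3,504 / 500,348).
    """

    n_snps: int = 50
    n_exp: int = 50_000
    n_med: int = 50_000
    n_out: int = 50_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    exposure_h2: float = 0.25
    theta: float = 0.2
    a: float = 0.3
    b: float = 0.5
    c_prime: float = 0.1
    pleiotropy_frac: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    reverse_frac: float = 0.0
    reverse_theta: float = 0.3
    ld_block_size: int = 1
    ld_rho: float = 0.0
    outcome_type: str = "quantitative"
    case_fraction: float = 3504 / 500348
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise SimulationError("n_snps must be >= 1")
        for name in ("n_exp", "n_med", "n_out"):
            if getattr(self, name) <= 10:
                raise SimulationError(f"{name} must exceed 10")
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise SimulationError("maf_range must satisfy 0 < lo < hi <= 0.5")
        if not (0 < self.exposure_h2 < 1):
            raise SimulationError("exposure_h2 must be in (0, 1)")
        for name in ("pleiotropy_frac", "reverse_frac"):
            if not (0 <= getattr(self, name) <= 1):
                raise SimulationError(f"{name} must be in [0, 1]")
        if self.pleiotropy_sd < 0:
            raise SimulationError("pleiotropy_sd must be >= 0")
        if self.ld_block_size < 1:
            raise SimulationError("ld_block_size must be >= 1")
        if not (0 <= self.ld_rho < 1):
            raise SimulationError("ld_rho must be in [0, 1)")
        if self.outcome_type not in ("binary", "quantitative"):
            raise SimulationError("outcome_type must be 'binary' or 'quantitative'")
        if not (0 < self.case_fraction < 1):
            raise SimulationError("case_fraction must be in (0, 1)")


def nafld_outcome_config(**overrides) -> SimConfig:
    """A configuration shaped like a biobank NAFLD case-control outcome GWAS."""
    base = dict(outcome_type="binary", n_out=500_348, case_fraction=3504 / 500348)
    base.update(overrides)
    return SimConfig(**base)


@dataclass(frozen=True)
class SimTruth:
    """True generating quantities, for parameter-recovery tests."""

    beta_exp: np.ndarray          # per-allele true marginal effects on exposure
    beta_out: np.ndarray          # per-allele true marginal effects on outcome
    beta_med: np.ndarray | None   # per-allele true effects on mediator (chain only)
    pleiotropic: np.ndarray       # bool mask
    reverse: np.ndarray           # bool mask
    theta: float
    a: float | None
    b: float | None
    c_prime: float | None

    @property
    def total(self) -> float:
        if self.a is not None:
            return self.a * self.b + self.c_prime
        return self.theta


class PairBundle(NamedTuple):
    exposure: pd.DataFrame
    outcome: pd.DataFrame
    ld: LDMatrix
    truth: SimTruth


class ChainBundle(NamedTuple):
    exposure: pd.DataFrame
    mediator: pd.DataFrame
    outcome: pd.DataFrame
    ld: LDMatrix
    truth: SimTruth


def _block_correlation(k: int, block_size: int, rho: float, boundaries: list[int]) -> np.ndarray:
    """Within-block AR(1)-style correlation rho^|i-j|; blocks never straddle
    the indices in ``boundaries``."""
    c = np.eye(k)
    if rho == 0.0 or block_size == 1:
        return c
    starts = sorted(set([0] + boundaries))
    for s_i, start in enumerate(starts):
        end = starts[s_i + 1] if s_i + 1 < len(starts) else k
        for bstart in range(start, end, block_size):
            bend = min(bstart + block_size, end)
            idx = np.arange(bstart, bend)
            c[np.ix_(idx, idx)] = rho ** np.abs(idx[:, None] - idx[None, :])
    return c


def _ld_matrix(ids: list[str], chrom: np.ndarray, pos: np.ndarray, corr: np.ndarray) -> LDMatrix:
    pairs = {}
    k = len(ids)
    nz = np.argwhere(np.triu(corr, 1) != 0.0)
    for i, j in nz:
        pairs[(int(i), int(j))] = float(corr[i, j] ** 2)
    positions = pd.DataFrame({"variant_id": ids, "chrom": chrom, "pos": pos})
    return LDMatrix(ids, pairs, positions=positions)


def _correlated_noise(rng: np.random.Generator, corr: np.ndarray, scale: np.ndarray) -> np.ndarray:
    z = rng.standard_normal(corr.shape[0])
    if not np.allclose(corr, np.eye(corr.shape[0])):
        z = np.linalg.cholesky(corr) @ z
    return z * scale


def _variant_metadata(rng: np.random.Generator, k: int, prefix: str):
    ids = [f"{prefix}{i:05d}" for i in range(k)]
    chrom = np.array([str(1 + (i // 500) % 22) for i in range(k)])
    pos = 1 + np.arange(k, dtype=np.int64) * 1_000_000
    allele_pairs = [
        (a, b) for a in "ACGT" for b in "ACGT" if a != b
    ]
    pick = rng.integers(0, len(allele_pairs), size=k)
    ea = np.array([allele_pairs[i][0] for i in pick])
    oa = np.array([allele_pairs[i][1] for i in pick])
    return ids, chrom, pos, ea, oa


def _sumstats_frame(
    ids, chrom, pos, ea, oa, eaf, beta, se, n
) -> pd.DataFrame:
    z = beta / se
    pval = np.maximum(2.0 * stats.norm.sf(np.abs(z)), 1e-300)
    return pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": chrom,
            "pos": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": np.full(len(ids), n, dtype=np.int64),
        },
        columns=list(CANONICAL_COLUMNS),
    )


def _outcome_se(cfg: SimConfig, mafs: np.ndarray) -> tuple[np.ndarray, int]:
    """Per-allele outcome SE and the reported sample size."""
    v = 2.0 * mafs * (1.0 - mafs)
    if cfg.outcome_type == "binary":
        phi = cfg.case_fraction
        n_eff = 4.0 * cfg.n_out * phi * (1.0 - phi)  # = 4 / (1/cases + 1/controls)
        return 2.0 / np.sqrt(v * n_eff), cfg.n_out
    return 1.0 / np.sqrt(v * cfg.n_out), cfg.n_out


def simulate_pair(cfg: SimConfig, variant_prefix: str = "snp") -> PairBundle:
    """Simulate one exposure GWAS and one outcome GWAS over a shared panel.

    True standardized instrument effects gamma_i ~ |N(0, h2/k)| (effect
    alleles coded exposure-increasing); the outcome's true effect is
    theta * gamma_i plus, for the pleiotropic fraction, a per-allele direct
    effect alpha_i ~ N(pleiotropy_mean, pleiotropy_sd^2); reverse-causal SNPs
    originate on the outcome with induced exposure effect reverse_theta times
    their outcome effect.  Marginal effects within LD blocks mix via the
    block correlation, and sampling noise is correlated the same way.
    """
    rng = np.random.default_rng(cfg.seed)
    k = cfg.n_snps
    ids, chrom, pos, ea, oa = _variant_metadata(rng, k, variant_prefix)
    mafs = rng.uniform(*cfg.maf_range, size=k)
    scale = 1.0 / np.sqrt(2.0 * mafs * (1.0 - mafs))  # std -> per-allele

    per_snp_sd = np.sqrt(cfg.exposure_h2 / k)
    gamma = np.abs(rng.normal(0.0, per_snp_sd, size=k))  # standardized

    n_rev = int(round(cfg.reverse_frac * k))
    reverse = np.zeros(k, dtype=bool)
    if n_rev:
        reverse[rng.choice(k, size=n_rev, replace=False)] = True
    d_rev = np.abs(rng.normal(0.0, per_snp_sd, size=k))

    exp_joint = gamma.copy()
    exp_joint[reverse] = cfg.reverse_theta * d_rev[reverse]
    out_joint = cfg.theta * exp_joint
    out_joint[reverse] = d_rev[reverse]

    n_pleio = int(round(cfg.pleiotropy_frac * k))
    pleio = np.zeros(k, dtype=bool)
    candidates = np.flatnonzero(~reverse)
    if n_pleio and len(candidates):
        n_pleio = min(n_pleio, len(candidates))
        pleio[rng.choice(candidates, size=n_pleio, replace=False)] = True
    alpha_pa = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=k)
    out_joint = out_joint + np.where(pleio, alpha_pa / scale, 0.0)

    corr = _block_correlation(k, cfg.ld_block_size, cfg.ld_rho, [])
    exp_marg = corr @ exp_joint
    out_marg = corr @ out_joint

    se_exp = scale / np.sqrt(cfg.n_exp)
    se_out_pa, n_out_rep = _outcome_se(cfg, mafs)
    # noise on the standardized scale, correlated within LD blocks
    bx_pa = (exp_marg + _correlated_noise(rng, corr, np.full(k, 1.0 / np.sqrt(cfg.n_exp)))) * scale
    by_pa = out_marg * scale + _correlated_noise(rng, corr, se_out_pa)

    exposure = _sumstats_frame(ids, chrom, pos, ea, oa, mafs, bx_pa, se_exp, cfg.n_exp)
    outcome = _sumstats_frame(ids, chrom, pos, ea, oa, mafs, by_pa, se_out_pa, n_out_rep)
    ld = _ld_matrix(ids, chrom, pos, corr)
    truth = SimTruth(
        beta_exp=exp_marg * scale,
        beta_out=out_marg * scale,
        beta_med=None,
        pleiotropic=pleio,
        reverse=reverse,
        theta=cfg.theta,
        a=None,
        b=None,
        c_prime=None,
    )
    return PairBundle(exposure, outcome, ld, truth)


def simulate_chain(cfg: SimConfig, variant_prefix: str = "snp") -> ChainBundle:
    """Simulate the exposure -> mediator -> outcome chain over a 2k-SNP panel.

    The panel is split into k exposure-specific instruments (effects gamma)
    and k mediator-specific instruments (effects delta, same variance);
    mediator true effects are a * gamma (+ delta on its own instruments) and
    outcome true effects are b * mediator + c_prime * gamma, so the true
    total effect is a * b + c_prime.  Three independent noise draws honour
    the two-sample design of each leg.
    """
    if cfg.reverse_frac != 0.0:
        raise SimulationError("reverse_frac is only supported by simulate_pair")
    rng = np.random.default_rng(cfg.seed)
    k = cfg.n_snps
    total_k = 2 * k
    ids, chrom, pos, ea, oa = _variant_metadata(rng, total_k, variant_prefix)
    mafs = rng.uniform(*cfg.maf_range, size=total_k)
    scale = 1.0 / np.sqrt(2.0 * mafs * (1.0 - mafs))

    per_snp_sd = np.sqrt(cfg.exposure_h2 / k)
    gamma = np.zeros(total_k)
    delta = np.zeros(total_k)
    gamma[:k] = np.abs(rng.normal(0.0, per_snp_sd, size=k))
    delta[k:] = np.abs(rng.normal(0.0, per_snp_sd, size=k))

    n_pleio = int(round(cfg.pleiotropy_frac * k))
    pleio = np.zeros(total_k, dtype=bool)
    if n_pleio:
        pleio[rng.choice(k, size=n_pleio, replace=False)] = True
    alpha_pa = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=total_k)

    exp_joint = gamma
    med_joint = cfg.a * gamma + delta
    out_joint = cfg.b * med_joint + cfg.c_prime * gamma
    out_joint = out_joint + np.where(pleio, alpha_pa / scale, 0.0)

    corr = _block_correlation(total_k, cfg.ld_block_size, cfg.ld_rho, [k])
    exp_marg = corr @ exp_joint
    med_marg = corr @ med_joint
    out_marg = corr @ out_joint

    se_exp = scale / np.sqrt(cfg.n_exp)
    se_med = scale / np.sqrt(cfg.n_med)
    se_out_pa, n_out_rep = _outcome_se(cfg, mafs)
    bx = (exp_marg + _correlated_noise(rng, corr, np.full(total_k, 1.0 / np.sqrt(cfg.n_exp)))) * scale
    bm = (med_marg + _correlated_noise(rng, corr, np.full(total_k, 1.0 / np.sqrt(cfg.n_med)))) * scale
    by = out_marg * scale + _correlated_noise(rng, corr, se_out_pa)

    exposure = _sumstats_frame(ids, chrom, pos, ea, oa, mafs, bx, se_exp, cfg.n_exp)
    mediator = _sumstats_frame(ids, chrom, pos, ea, oa, mafs, bm, se_med, cfg.n_med)
    outcome = _sumstats_frame(ids, chrom, pos, ea, oa, mafs, by, se_out_pa, n_out_rep)
    ld = _ld_matrix(ids, chrom, pos, corr)
    truth = SimTruth(
        beta_exp=exp_marg * scale,
        beta_out=out_marg * scale,
        beta_med=med_marg * scale,
        pleiotropic=pleio,
        reverse=np.zeros(total_k, dtype=bool),
        theta=cfg.a * cfg.b + cfg.c_prime,
        a=cfg.a,
        b=cfg.b,
        c_prime=cfg.c_prime,
    )
    return ChainBundle(exposure, mediator, outcome, ld, truth)


def as_instrument_table(
    bundle: PairBundle,
    *,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> InstrumentTable:
    """Directly pair the simulated tables (already allele-aligned).

    Bypasses allele harmonization — useful when measuring estimator
    properties rather than pipeline behaviour.
    """
    e, o = bundle.exposure, bundle.outcome
    data = pd.DataFrame(
        {
            "variant_id": e["variant_id"],
            "chrom": e["chrom"],
            "pos": e["pos"],
            "beta_exp": e["beta"].to_numpy(),
            "se_exp": e["se"].to_numpy(),
            "beta_out": o["beta"].to_numpy(),
            "se_out": o["se"].to_numpy(),
            "eaf": e["eaf"].to_numpy(),
            "n_exp": e["n"].to_numpy(),
            "n_out": o["n"].to_numpy(),
            "pval_exp": e["pval"].to_numpy(),
            "pval_out": o["pval"].to_numpy(),
        }
    )
    return InstrumentTable(
        data, exposure_name=exposure_name, outcome_name=outcome_name, provenance="simulation"
    )


def write_fixture(bundle: "PairBundle | ChainBundle", out_dir: str | Path) -> dict[str, Path]:
    """Write a bundle to disk exactly as a user would supply it.

    Emits canonical sumstats TSVs, a square LD file, and a ``truth.txt``
    key = value file; bytes are deterministic for a given configuration.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    tables = {"exposure": bundle.exposure, "outcome": bundle.outcome}
    if isinstance(bundle, ChainBundle):
        tables["mediator"] = bundle.mediator
    for name, frame in tables.items():
        p = out / f"{name}.tsv"
        frame.to_csv(p, sep="\t", index=False)
        paths[name] = p
    ld_path = out / "ld.tsv"
    bundle.ld.write_square(ld_path)
    paths["ld"] = ld_path
    t = bundle.truth
    lines = [
        f"theta = {t.theta!r}",
        f"total = {t.total!r}",
        f"n_pleiotropic = {int(t.pleiotropic.sum())}",
        f"n_reverse = {int(t.reverse.sum())}",
    ]
    if t.a is not None:
        lines += [f"a = {t.a!r}", f"b = {t.b!r}", f"c_prime = {t.c_prime!r}"]
    truth_path = out / "truth.txt"
    truth_path.write_text("\n".join(lines) + "\n")
    paths["truth"] = truth_path
    return paths
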