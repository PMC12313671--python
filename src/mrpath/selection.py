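"""Instrument-variable selection for two-sample MR.

Five criteria, applied in a fixed order: genome-wide p-value threshold with a
relaxed fallback when too few hits survive, minor-allele-frequency filter,
instrument-strength (F-statistic) filter, greedy LD clumping against a
user-supplied r-squared matrix, and Steiger directionality filtering of the
harmonized table (drop SNPs explaining more variance in the outcome than in
the exposure — likely reverse causation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import (
    InstrumentTable,
    NoOverlappingInstrumentsError,
    SumStats,
    SumstatsError,
    _as_frame,
    harmonize,
)


class SelectionError(ValueError):
    """Invalid configuration or input to a selection step."""


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds of the instrument-selection pipeline.

    Defaults follow common MR practice: genome-wide significance 5e-8 with a
    1e-5 fallback when fewer than ``min_snps_for_primary`` hits survive,
    clumping at r^2 0.001 within a 10,000 kb window, MAF > 0.01 and F > 10.
    """

    p_primary: float = 5e-8
    p_fallback: float = 1e-5
    min_snps_for_primary: int = 3
    clump_r2: float = 0.001
    clump_window_kb: int = 10_000
    maf_min: float = 0.01
    f_min: float = 10.0
    steiger_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.p_primary <= self.p_fallback < 1):
            raise SelectionError("need 0 < p_primary <= p_fallback < 1")
        if not (0 < self.clump_r2 < 1):
            raise SelectionError("clump_r2 must be in (0, 1)")
        if self.clump_window_kb <= 0:
            raise SelectionError("clump_window_kb must be positive")
        if not (0 < self.maf_min < 0.5):
            raise SelectionError("maf_min must be in (0, 0.5)")
        if self.f_min <= 0:
            raise SelectionError("f_min must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "SelectionConfig":
        """Parse a plain-text ``key = value`` configuration file."""
        kwargs: dict[str, object] = {}
        types = {f.name: f.type for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key = key.strip()
            if key not in types:
                raise SelectionError(f"unknown configuration key: {key}")
            caster = int if "int" in str(types[key]) else float
            kwargs[key] = caster(val.strip())
        return cls(**kwargs)  # type: ignore[arg-type]


class LDMatrix:
    """Pairwise LD (r-squared) between variants, stored sparsely.

    Unstored pairs have r^2 = 0; the diagonal is 1 by construction.  Files
    are accepted either as sparse triplets (``variant_id_a, variant_id_b,
    r2``) or as a square matrix with variant ids as header row and first
    column.
    """

    def __init__(
        self,
        ids: Sequence[str],
        pairs: dict[tuple[int, int], float] | None = None,
        positions: pd.DataFrame | None = None,
    ) -> None:
        self.ids = list(ids)
        if len(set(self.ids)) != len(self.ids):
            raise SelectionError("duplicate variant ids in LD matrix")
        self._index = {v: i for i, v in enumerate(self.ids)}
        self._pairs: dict[tuple[int, int], float] = {}
        for (i, j), r2 in (pairs or {}).items():
            if not (0.0 <= r2 <= 1.0):
                raise SelectionError(f"r2 out of [0, 1] for pair ({self.ids[i]}, {self.ids[j]})")
            if i != j:
                self._pairs[(min(i, j), max(i, j))] = float(r2)
        self.positions = positions

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def __len__(self) -> int:
        return len(self.ids)

    def r2(self, a: str, b: str) -> float:
        ia, ib = self._index[a], self._index[b]
        if ia == ib:
            return 1.0
        return self._pairs.get((min(ia, ib), max(ia, ib)), 0.0)

    def to_dense(self) -> pd.DataFrame:
        k = len(self.ids)
        m = np.eye(k)
        for (i, j), r2 in self._pairs.items():
            m[i, j] = m[j, i] = r2
        return pd.DataFrame(m, index=self.ids, columns=self.ids)

    @classmethod
    def from_square(cls, df: pd.DataFrame) -> "LDMatrix":
        ids = [str(c) for c in df.columns]
        m = df.to_numpy(float)
        if m.shape[0] != m.shape[1]:
            raise SelectionError("square LD file is not square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise SelectionError("LD matrix is not symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-12):
            raise SelectionError("LD matrix diagonal must be 1")
        pairs = {
            (i, j): float(m[i, j])
            for i in range(len(ids))
            for j in range(i + 1, len(ids))
            if m[i, j] != 0.0
        }
        return cls(ids, pairs)

    @classmethod
    def from_pairs(cls, df: pd.DataFrame, ids: Sequence[str] | None = None) -> "LDMatrix":
        need = {"variant_id_a", "variant_id_b", "r2"}
        if not need.issubset(df.columns):
            raise SelectionError(f"sparse LD file needs columns {sorted(need)}")
        all_ids = list(ids) if ids is not None else sorted(
            set(df["variant_id_a"]) | set(df["variant_id_b"])
        )
        obj = cls(all_ids)
        for a, b, r2 in df[["variant_id_a", "variant_id_b", "r2"]].itertuples(index=False):
            ia, ib = obj._index[str(a)], obj._index[str(b)]
            if ia != ib:
                obj._pairs[(min(ia, ib), max(ia, ib))] = float(r2)
        return obj

    @classmethod
    def read(cls, path: str | Path, ids: Sequence[str] | None = None) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=None)
        if "variant_id_a" in df.columns:
            return cls.from_pairs(df, ids=ids)
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_square(df)

    def write_square(self, path: str | Path) -> None:
        dense = self.to_dense()
        dense.index.name = "variant_id"
        dense.to_csv(path, sep="\t")

    @classmethod
    def concat(cls, parts: Iterable["LDMatrix"]) -> "LDMatrix":
        """Block-diagonal concatenation (no LD across parts)."""
        ids: list[str] = []
        pairs: dict[tuple[int, int], float] = {}
        offset = 0
        for part in parts:
            ids.extend(part.ids)
            for (i, j), r2 in part._pairs.items():
                pairs[(i + offset, j + offset)] = r2
            offset += len(part.ids)
        return cls(ids, pairs)


@dataclass(frozen=True)
class SteigerRecord:
    variant_id: str
    r2_exp: float
    r2_out: float
    z: float
    p: float
    direction_ok: bool


def select_by_pvalue(
    records: "SumStats | pd.DataFrame", config: SelectionConfig | None = None
) -> tuple[pd.DataFrame, float]:
    """Genome-wide threshold, falling back to ``p_fallback`` when too few hits.

    Returns the selected rows (input order preserved) and the threshold that
    was actually applied.
    """
    config = config or SelectionConfig()
    df = _as_frame(records)
    primary = df[df["pval"] < config.p_primary]
    if len(primary) >= config.min_snps_for_primary:
        return primary.reset_index(drop=True), config.p_primary
    fallback = df[df["pval"] < config.p_fallback]
    return fallback.reset_index(drop=True), config.p_fallback


def filter_maf(
    records: "SumStats | pd.DataFrame", config: SelectionConfig | None = None
) -> pd.DataFrame:
    """Keep SNPs with minor allele frequency above ``maf_min``."""
    config = config or SelectionConfig()
    df = _as_frame(records)
    maf = np.minimum(df["eaf"], 1.0 - df["eaf"])
    return df[maf > config.maf_min].reset_index(drop=True)


def f_statistic(beta: float | np.ndarray, se: float | np.ndarray) -> float | np.ndarray:
    """Per-SNP instrument-strength F statistic, (beta/se)^2."""
    se = np.asarray(se, float)
    if np.any(se <= 0):
        raise SelectionError("se must be positive")
    out = (np.asarray(beta, float) / se) ** 2
    return float(out) if out.ndim == 0 else out


def filter_f(
    records: "SumStats | pd.DataFrame", config: SelectionConfig | None = None
) -> pd.DataFrame:
    """Drop weak instruments (F <= f_min)."""
    config = config or SelectionConfig()
    df = _as_frame(records)
    f = f_statistic(df["beta"].to_numpy(), df["se"].to_numpy())
    return df[f > config.f_min].reset_index(drop=True)


def ld_clump(
    records: "SumStats | pd.DataFrame",
    ld: LDMatrix,
    config: SelectionConfig | None = None,
) -> pd.DataFrame:
    """Greedy clumping: keep the most significant SNP per LD neighbourhood.

    SNPs are visited by ascending p-value (ties broken by variant id); each
    index SNP removes remaining same-chromosome SNPs within
    ``clump_window_kb`` whose r^2 with it exceeds ``clump_r2``.  The returned
    index SNPs keep their input row order.
    """
    config = config or SelectionConfig()
    df = _as_frame(records).reset_index(drop=True)
    for vid in df["variant_id"]:
        if vid not in ld:
            raise SelectionError(f"variant missing from LD matrix: {vid}")
    order = df.sort_values(["pval", "variant_id"], kind="mergesort").index
    alive = np.ones(len(df), dtype=bool)
    keep = np.zeros(len(df), dtype=bool)
    chrom = df["chrom"].astype(str).to_numpy()
    pos = df["pos"].to_numpy(float)
    vids = df["variant_id"].to_numpy()
    window = config.clump_window_kb * 1000.0
    for i in order:
        if not alive[i]:
            continue
        keep[i] = True
        alive[i] = False
        near = alive & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window)
        for j in np.flatnonzero(near):
            if ld.r2(vids[i], vids[j]) > config.clump_r2:
                alive[j] = False
    return df[keep].reset_index(drop=True)


def variance_explained(
    beta: float | np.ndarray,
    eaf: float | np.ndarray,
    se: float | np.ndarray,
    n: int | np.ndarray,
) -> float | np.ndarray:
    """Trait variance explained by one SNP, on the standardized scale.

    r^2 = beta^2 * 2f(1-f) / (beta^2 * 2f(1-f) + se^2 * 2f(1-f) * n), which
    algebraically reduces to beta^2 / (beta^2 + se^2 * n); clamped to [0, 1).
    """
    beta = np.asarray(beta, float)
    eaf = np.asarray(eaf, float)
    se = np.asarray(se, float)
    n = np.asarray(n, float)
    if np.any((eaf <= 0) | (eaf >= 1)):
        raise SelectionError("eaf must be in (0, 1)")
    if np.any(n <= 3):
        raise SelectionError("n must exceed 3")
    if np.any(se <= 0):
        raise SelectionError("se must be positive")
    v = 2.0 * eaf * (1.0 - eaf)
    r2 = (beta**2 * v) / (beta**2 * v + se**2 * v * n)
    r2 = np.clip(r2, 0.0, np.nextafter(1.0, 0.0))
    return float(r2) if r2.ndim == 0 else r2


def steiger_filter(
    table: InstrumentTable, config: SelectionConfig | None = None
) -> tuple[InstrumentTable, list[SteigerRecord]]:
    """Drop instruments more strongly correlated with the outcome.

    Per SNP, the variance explained on each side is compared; the z statistic
    contrasts Fisher-transformed correlations.  Removal is keyed on the
    direction (r2_out >= r2_exp), with the z-test p-value reported for
    transparency.
    """
    config = config or SelectionConfig()
    d = table.data
    n_exp = d["n_exp"].to_numpy(float)
    n_out = d["n_out"].to_numpy(float)
    if np.any(n_exp <= 3) or np.any(n_out <= 3):
        raise SelectionError("sample sizes must exceed 3 for Steiger filtering")
    r2_exp = variance_explained(d["beta_exp"], d["eaf"], d["se_exp"], n_exp)
    r2_out = variance_explained(d["beta_out"], d["eaf"], d["se_out"], n_out)
    r2_exp = np.atleast_1d(r2_exp)
    r2_out = np.atleast_1d(r2_out)
    z = (np.arctanh(np.sqrt(r2_exp)) - np.arctanh(np.sqrt(r2_out))) / np.sqrt(
        1.0 / (n_exp - 3.0) + 1.0 / (n_out - 3.0)
    )
    p = 2.0 * stats.norm.sf(np.abs(z))
    ok = r2_exp > r2_out
    records = [
        SteigerRecord(
            variant_id=str(v),
            r2_exp=float(re_),
            r2_out=float(ro),
            z=float(zi),
            p=float(pi),
            direction_ok=bool(oi),
        )
        for v, re_, ro, zi, pi, oi in zip(d["variant_id"], r2_exp, r2_out, z, p, ok)
    ]
    return table.subset(ok), records


@dataclass
class PipelineCounts:
    """Per-step instrument counts for one exposure/outcome pair."""

    n_input: int = 0
    n_after_pvalue: int = 0
    threshold_used: float = float("nan")
    n_after_maf: int = 0
    n_after_f: int = 0
    n_after_clump: int = 0
    n_after_harmonize: int = 0
    n_after_steiger: int = 0

    @property
    def steiger_removed(self) -> int:
        return self.n_after_harmonize - self.n_after_steiger


def instrument_pipeline(
    exposure: "SumStats | pd.DataFrame",
    outcome: "SumStats | pd.DataFrame",
    ld: LDMatrix | None,
    config: SelectionConfig | None = None,
    *,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    palindrome_eaf_tol: float = 0.08,
    apply_steiger: bool = True,
    exclude_ids: Iterable[str] | None = None,
) -> tuple[InstrumentTable, PipelineCounts]:
    """The full selection pipeline for one exposure against one outcome.

    Order: p-value selection -> MAF filter -> F filter -> LD clumping ->
    harmonization -> Steiger filter.  ``ld=None`` skips clumping (only
    appropriate when instruments are known independent).  ``exclude_ids``
    removes given variants before selection (used e.g. to keep
    exposure-significant SNPs out of a mediator's instrument set).
    """
    config = config or SelectionConfig()
    counts = PipelineCounts()
    df = _as_frame(exposure)
    counts.n_input = len(df)
    if exclude_ids is not None:
        df = df[~df["variant_id"].isin(set(exclude_ids))].reset_index(drop=True)
    df, counts.threshold_used = select_by_pvalue(df, config)
    counts.n_after_pvalue = len(df)
    df = filter_maf(df, config)
    counts.n_after_maf = len(df)
    df = filter_f(df, config)
    counts.n_after_f = len(df)
    if ld is not None and len(df):
        df = ld_clump(df, ld, config)
    counts.n_after_clump = len(df)
    if not len(df):
        empty = InstrumentTable(
            pd.DataFrame({c: [] for c in ("variant_id", "beta_exp", "se_exp", "beta_out", "se_out", "eaf", "n_exp", "n_out")}),
            exposure_name=exposure_name,
            outcome_name=outcome_name,
            provenance="harmonization",
        )
        return empty, counts
    try:
        table, _ = harmonize(
            df,
            _as_frame(outcome),
            palindrome_eaf_tol=palindrome_eaf_tol,
            exposure_name=exposure_name,
            outcome_name=outcome_name,
        )
    except NoOverlappingInstrumentsError:
        table = InstrumentTable(
            pd.DataFrame({c: [] for c in ("variant_id", "beta_exp", "se_exp", "beta_out", "se_out", "eaf", "n_exp", "n_out")}),
            exposure_name=exposure_name,
            outcome_name=outcome_name,
            provenance="harmonization",
        )
    counts.n_after_harmonize = table.n_snps
    if apply_steiger and table.n_snps:
        table, _ = steiger_filter(table, config)
    counts.n_after_steiger = table.n_snps
    return table, counts
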