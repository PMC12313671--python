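"""GWAS summary statistics: reading, validation, writing, and allele harmonization.

Summary statistics are carried as :class:`pandas.DataFrame` objects with the
canonical columns ``variant_id, chrom, pos, effect_allele, other_allele, eaf,
beta, se, pval, n`` (one row per SNP, betas on the per-effect-allele scale,
log-odds for binary traits).  :func:`harmonize` joins an exposure and an
outcome table on ``variant_id``, aligns the outcome effect to the exposure's
effect allele, and resolves palindromic (A/T, C/G) SNPs by allele-frequency
concordance, producing the :class:`InstrumentTable` consumed by every
estimator.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CANONICAL_COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)

INSTRUMENT_COLUMNS = (
    "variant_id",
    "beta_exp",
    "se_exp",
    "beta_out",
    "se_out",
    "eaf",
    "n_exp",
    "n_out",
)

_ALLELE_RE = re.compile(r"^[ACGT]+$")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class SumstatsError(ValueError):
    """Fatal problem with a summary-statistics table."""


class NoOverlappingInstrumentsError(SumstatsError):
    """Exposure and outcome tables share no variant identifier."""


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP's marginal association with one trait."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int


@dataclass(frozen=True)
class RowError:
    """A rejected input row, with its 1-based file line number."""

    line: int
    variant_id: str | None
    message: str


@dataclass
class SumStats:
    """A validated summary-statistics table plus any rejected rows."""

    frame: pd.DataFrame
    rejected: list[RowError] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def records(self) -> list[SummaryStatRecord]:
        return [SummaryStatRecord(**row) for row in self.frame.to_dict("records")]


@dataclass(frozen=True)
class HarmonizationReport:
    n_input: int
    n_matched: int
    n_flipped: int
    n_palindromic_dropped: int
    n_allele_mismatch_dropped: int


@dataclass
class InstrumentTable:
    """Harmonized per-SNP exposure/outcome effect pairs.

    ``data`` holds one row per SNP with columns ``variant_id, beta_exp,
    se_exp, beta_out, se_out, eaf, n_exp, n_out`` (plus optional ``chrom`` /
    ``pos`` annotation).  Construct via :func:`harmonize` or the simulator;
    ``provenance`` records which.
    """

    data: pd.DataFrame
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        missing = [c for c in INSTRUMENT_COLUMNS if c not in self.data.columns]
        if missing:
            raise SumstatsError(f"instrument table missing columns: {missing}")
        if self.data["variant_id"].duplicated().any():
            dup = self.data.loc[self.data["variant_id"].duplicated(), "variant_id"].iloc[0]
            raise SumstatsError(f"duplicate variant in instrument table: {dup}")
        if len(self.data):
            if not (self.data["se_exp"] > 0).all() or not (self.data["se_out"] > 0).all():
                raise SumstatsError("instrument table contains non-positive standard errors")
        self.data = self.data.reset_index(drop=True)

    @property
    def n_snps(self) -> int:
        return len(self.data)

    def subset(self, mask: Sequence[bool] | np.ndarray | pd.Series) -> "InstrumentTable":
        return InstrumentTable(
            self.data.loc[np.asarray(mask)].reset_index(drop=True),
            exposure_name=self.exposure_name,
            outcome_name=self.outcome_name,
            provenance=self.provenance,
        )

    def drop_rows(self, indices: Iterable[int]) -> "InstrumentTable":
        keep = np.ones(self.n_snps, dtype=bool)
        keep[list(indices)] = False
        return self.subset(keep)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return (beta_exp, se_exp, beta_out, se_out) as float arrays."""
        d = self.data
        return (
            d["beta_exp"].to_numpy(float),
            d["se_exp"].to_numpy(float),
            d["beta_out"].to_numpy(float),
            d["se_out"].to_numpy(float),
        )

    def write(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# exposure_name={self.exposure_name}\n")
            fh.write(f"# outcome_name={self.outcome_name}\n")
            fh.write(f"# provenance={self.provenance}\n")
            self.data.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "InstrumentTable":
        meta: dict[str, str] = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            data = pd.read_csv(fh, sep="\t")
        return cls(
            data,
            exposure_name=meta.get("exposure_name", "exposure"),
            outcome_name=meta.get("outcome_name", "outcome"),
            provenance=meta.get("provenance", "file"),
        )


def _as_frame(x: "SumStats | pd.DataFrame | Iterable[SummaryStatRecord]") -> pd.DataFrame:
    if isinstance(x, SumStats):
        return x.frame
    if isinstance(x, pd.DataFrame):
        return x
    rows = list(x)
    if rows and isinstance(rows[0], SummaryStatRecord):
        return pd.DataFrame([r.__dict__ for r in rows])
    return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


def validate_frame(df: pd.DataFrame, *, line_offset: int = 2) -> SumStats:
    """Validate a raw frame row-wise; invalid rows are collected, not fatal.

    ``line_offset`` is the file line number of the first data row (2 for a
    file with one header line), used in :class:`RowError` messages.
    """
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SumstatsError(f"missing mandatory column(s): {', '.join(missing)}")
    df = df.loc[:, list(CANONICAL_COLUMNS)].reset_index(drop=True)
    rejected: list[RowError] = []

    num = pd.DataFrame(index=df.index)
    for col in ("pos", "eaf", "beta", "se", "pval", "n"):
        num[col] = pd.to_numeric(df[col], errors="coerce")

    vid = df["variant_id"].astype(str)
    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()

    checks: list[tuple[pd.Series, str]] = [
        (num[["pos", "eaf", "beta", "se", "pval", "n"]].isna().any(axis=1), "unparsable numeric field"),
        (~ea.str.match(_ALLELE_RE), "invalid effect allele"),
        (~oa.str.match(_ALLELE_RE), "invalid other allele"),
        (ea == oa, "effect allele equals other allele"),
        (~(num["se"] > 0), "se must be > 0"),
        (~((num["eaf"] > 0) & (num["eaf"] < 1)), "eaf must be in (0, 1)"),
        (~((num["pval"] > 0) & (num["pval"] <= 1)), "pval must be in (0, 1]"),
        (~(num["n"] > 0), "n must be > 0"),
        (~(num["pos"] >= 1), "pos must be >= 1"),
    ]
    bad = pd.Series(False, index=df.index)
    for mask, msg in checks:
        mask = mask.fillna(True) & ~bad
        for i in df.index[mask]:
            rejected.append(RowError(line=i + line_offset, variant_id=vid[i], message=msg))
        bad |= mask

    # multi-allelic / duplicated ids: drop every copy, with a warning
    dup_ids = set(vid[~bad][vid[~bad].duplicated()])
    if dup_ids:
        warnings.warn(
            f"dropping {len(dup_ids)} duplicated variant id(s) (possible multi-allelics)",
            stacklevel=2,
        )
        dup_mask = vid.isin(dup_ids) & ~bad
        for i in df.index[dup_mask]:
            rejected.append(RowError(line=i + line_offset, variant_id=vid[i], message="duplicated variant_id"))
        bad |= dup_mask

    clean = pd.DataFrame(
        {
            "variant_id": vid,
            "chrom": df["chrom"].astype(str),
            "pos": num["pos"],
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": num["eaf"],
            "beta": num["beta"],
            "se": num["se"],
            "pval": num["pval"],
            "n": num["n"],
        }
    ).loc[~bad]
    clean = clean.astype({"pos": np.int64, "n": np.int64}).reset_index(drop=True)
    return SumStats(frame=clean, rejected=rejected)


def read_sumstats(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> SumStats:
    """Read a (optionally gzipped) TSV of summary statistics.

    ``column_map`` maps file column names to canonical ones, e.g.
    ``{"SNP": "variant_id", "EA": "effect_allele"}``.
    """
    path = Path(path)
    if not path.exists():
        raise SumstatsError(f"no such file: {path}")
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, compression="infer")
    except pd.errors.EmptyDataError:
        raise SumstatsError(f"empty summary-statistics file: {path}") from None
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    return validate_frame(raw)


def write_sumstats(
    records: "SumStats | pd.DataFrame | Iterable[SummaryStatRecord]", path: str | Path
) -> None:
    """Write records as a canonical TSV; numeric text round-trips exactly."""
    frame = _as_frame(records)
    cols = [c for c in CANONICAL_COLUMNS if c in frame.columns] or list(CANONICAL_COLUMNS)
    frame = frame.reindex(columns=cols)
    # pandas stringifies floats via repr (shortest round-trip), preserving
    # every significant digit
    frame.to_csv(path, sep="\t", index=False, compression="infer")


def _is_palindromic(ea: pd.Series, oa: pd.Series) -> pd.Series:
    single = (ea.str.len() == 1) & (oa.str.len() == 1)
    return single & (oa == ea.str.translate(_COMPLEMENT))


def harmonize(
    exposure: "SumStats | pd.DataFrame | Iterable[SummaryStatRecord]",
    outcome: "SumStats | pd.DataFrame | Iterable[SummaryStatRecord]",
    palindrome_eaf_tol: float = 0.08,
    *,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> tuple[InstrumentTable, HarmonizationReport]:
    """Align outcome effects to the exposure's effect allele per SNP.

    Outcome rows whose effect/other alleles are swapped relative to the
    exposure get their beta sign flipped and eaf replaced by ``1 - eaf``.
    Palindromic SNPs (A/T or C/G) are kept only when both allele frequencies
    fall outside ``0.5 +/- palindrome_eaf_tol`` and lie on the same side of
    0.5 after alignment; otherwise they are dropped (strand ambiguity).
    Allele sets matching neither directly nor after swap are dropped.
    """
    exp = _as_frame(exposure)
    out = _as_frame(outcome)
    merged = exp.merge(out, on="variant_id", suffixes=("_exp", "_out"), how="inner")
    if merged.empty:
        raise NoOverlappingInstrumentsError(
            "no overlapping instruments between exposure and outcome tables"
        )

    ea_e = merged["effect_allele_exp"]
    oa_e = merged["other_allele_exp"]
    ea_o = merged["effect_allele_out"]
    oa_o = merged["other_allele_out"]

    direct = (ea_o == ea_e) & (oa_o == oa_e)
    swap = (ea_o == oa_e) & (oa_o == ea_e) & ~direct
    matched = direct | swap

    beta_out = np.where(swap, -merged["beta_out"], merged["beta_out"])
    eaf_out = np.where(swap, 1.0 - merged["eaf_out"], merged["eaf_out"])

    pal = _is_palindromic(ea_e, oa_e)
    lo, hi = 0.5 - palindrome_eaf_tol, 0.5 + palindrome_eaf_tol
    eaf_exp = merged["eaf_exp"].to_numpy(float)
    in_zone = lambda f: (f >= lo) & (f <= hi)  # noqa: E731
    same_side = (eaf_exp - 0.5) * (eaf_out - 0.5) > 0
    pal_ok = ~in_zone(eaf_exp) & ~in_zone(eaf_out) & same_side
    pal_drop = pal.to_numpy() & matched.to_numpy() & ~pal_ok

    keep = matched.to_numpy() & ~pal_drop
    n_mismatch = int((~matched).sum())
    n_pal = int(pal_drop.sum())
    n_flipped = int((swap.to_numpy() & keep).sum())

    data = pd.DataFrame(
        {
            "variant_id": merged["variant_id"],
            "chrom": merged.get("chrom_exp", merged.get("chrom")),
            "pos": merged.get("pos_exp", merged.get("pos")),
            "beta_exp": merged["beta_exp"].to_numpy(float),
            "se_exp": merged["se_exp"].to_numpy(float),
            "beta_out": beta_out.astype(float),
            "se_out": merged["se_out"].to_numpy(float),
            "eaf": eaf_exp,
            "eaf_out": eaf_out.astype(float),
            "n_exp": merged["n_exp"].to_numpy(np.int64),
            "n_out": merged["n_out"].to_numpy(np.int64),
            "pval_exp": merged["pval_exp"].to_numpy(float),
            "pval_out": merged["pval_out"].to_numpy(float),
        }
    ).loc[keep]

    table = InstrumentTable(
        data,
        exposure_name=exposure_name,
        outcome_name=outcome_name,
        provenance="harmonization",
    )
    report = HarmonizationReport(
        n_input=len(exp),
        n_matched=int(keep.sum()),
        n_flipped=n_flipped,
        n_palindromic_dropped=n_pal,
        n_allele_mismatch_dropped=n_mismatch,
    )
    return table, report
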