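"""Batch screening of many exposures against one outcome.

Runs the full selection + harmonization + estimation pipeline per exposure,
collects one row per (exposure, method), applies Benjamini-Hochberg FDR
across the primary-method (IVW / Wald-ratio) family, and exports
publication-style tables (forest table of primary odds ratios; method-by-
exposure odds-ratio matrix).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .estimators import estimate_all
from .sensitivity import cochran_q, mr_presso
from .estimators import egger as egger_fit
from .selection import LDMatrix, SelectionConfig, instrument_pipeline
from .sumstats import SumStats, _as_frame, read_sumstats


class ScreenError(ValueError):
    pass


ROW_COLUMNS = (
    "exposure",
    "outcome",
    "method",
    "n_snps",
    "beta",
    "se",
    "or_value",
    "or_ci_low",
    "or_ci_high",
    "pval",
    "fdr",
    "primary",
    "nominal",
    "fdr_significant",
    "heterogeneity_p",
    "egger_intercept_p",
    "steiger_removed",
    "threshold_used",
)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ScreenError("empty p-value list")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ScreenError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ScreenResult:
    rows: pd.DataFrame
    skipped: pd.DataFrame  # exposures that yielded zero instruments

    def primary_rows(self) -> pd.DataFrame:
        return self.rows[self.rows["primary"]].reset_index(drop=True)


def _load(x) -> pd.DataFrame:
    if isinstance(x, (str, Path)):
        return read_sumstats(x).frame
    return _as_frame(x)


def run_screen(
    exposures: "Mapping[str, object] | Sequence[str | Path]",
    outcome: object,
    ld: LDMatrix | str | Path | None = None,
    config: SelectionConfig | None = None,
    seed: int | None = None,
    *,
    outcome_name: str = "outcome",
    methods: tuple[str, ...] | None = None,
    run_presso: bool = False,
    reverse: bool = False,
    alpha: float = 0.05,
    n_boot_median: int = 5000,
    n_boot_mode: int = 1000,
) -> ScreenResult:
    """Screen each exposure against the shared outcome.

    ``exposures`` is a mapping of label -> table (DataFrame / SumStats /
    path) or a sequence of paths (labelled by file stem).  ``reverse`` swaps
    the roles, instrumenting the outcome against each exposure (reverse MR).
    FDR is computed across the primary-method p-values of all exposures that
    yielded at least one instrument.
    """
    config = config or SelectionConfig()
    if not isinstance(exposures, Mapping):
        exposures = {Path(p).stem: p for p in exposures}
    if isinstance(ld, (str, Path)):
        ld = LDMatrix.read(ld)
    out_frame = _load(outcome)

    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(exposures))]

    rows: list[dict] = []
    skipped: list[dict] = []
    for (label, exp_obj), sub_seed in zip(exposures.items(), child_seeds):
        exp_frame = _load(exp_obj)
        left, right = (out_frame, exp_frame) if reverse else (exp_frame, out_frame)
        left_name = outcome_name if reverse else label
        right_name = label if reverse else outcome_name
        table, counts = instrument_pipeline(
            left, right, ld, config, exposure_name=left_name, outcome_name=right_name
        )
        if table.n_snps == 0:
            skipped.append(
                {
                    "exposure": label,
                    "reason": "no instruments survived selection",
                    "threshold_used": counts.threshold_used,
                }
            )
            continue
        estimates = estimate_all(
            table,
            seed=sub_seed,
            methods=methods,
            n_boot_median=n_boot_median,
            n_boot_mode=n_boot_mode,
        )
        het_p = cochran_q(table).pval if table.n_snps >= 2 else np.nan
        egger_int_p = egger_fit(table)[3] if table.n_snps >= 3 else np.nan
        presso_p = (
            mr_presso(table, seed=sub_seed).global_p
            if run_presso and table.n_snps >= 4
            else np.nan
        )
        for est in estimates:
            rows.append(
                {
                    "exposure": label,
                    "outcome": outcome_name,
                    "direction": "reverse" if reverse else "forward",
                    "method": est.method,
                    "n_snps": est.n_snps,
                    "beta": est.beta,
                    "se": est.se,
                    "or_value": est.odds_ratio,
                    "or_ci_low": est.or_ci[0],
                    "or_ci_high": est.or_ci[1],
                    "pval": est.pval,
                    "fdr": np.nan,
                    "primary": bool(est.extra.get("primary", False)),
                    "nominal": est.pval < alpha,
                    "fdr_significant": False,
                    "heterogeneity_p": het_p,
                    "egger_intercept_p": egger_int_p,
                    "presso_global_p": presso_p,
                    "steiger_removed": counts.steiger_removed,
                    "threshold_used": counts.threshold_used,
                }
            )
    frame = pd.DataFrame(rows, columns=list(ROW_COLUMNS) + ["direction", "presso_global_p"])
    if len(frame):
        mask = frame["primary"].to_numpy(bool)
        if mask.any():
            fdr = bh_adjust(frame.loc[mask, "pval"])
            frame.loc[mask, "fdr"] = fdr
            frame.loc[mask, "fdr_significant"] = fdr < alpha
    return ScreenResult(rows=frame, skipped=pd.DataFrame(skipped, columns=["exposure", "reason", "threshold_used"]))


def export_tables(rows: pd.DataFrame, out_dir: str | Path) -> dict[str, Path]:
    """Write forest and method-matrix TSVs with deterministic ordering.

    ``forest.tsv``: one row per exposure (primary method) with OR, CI, p and
    FDR, sorted by FDR then label.  ``methods_matrix.tsv``: exposures by
    methods, one OR column and one p column per method.
    """
    if not len(rows):
        raise ScreenError("no rows to export")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    forest = (
        rows[rows["primary"]]
        .loc[:, ["exposure", "outcome", "method", "n_snps", "or_value", "or_ci_low",
                 "or_ci_high", "pval", "fdr", "nominal", "fdr_significant"]]
        .sort_values(["fdr", "exposure"], kind="mergesort")
        .reset_index(drop=True)
    )
    forest_path = out / "forest.tsv"
    forest.to_csv(forest_path, sep="\t", index=False, float_format="%.6g")

    ors = rows.pivot_table(index="exposure", columns="method", values="or_value", sort=False)
    ps = rows.pivot_table(index="exposure", columns="method", values="pval", sort=False)
    ors.columns = [f"or_{m}" for m in ors.columns]
    ps.columns = [f"pval_{m}" for m in ps.columns]
    matrix = ors.join(ps)
    order = (
        rows[rows["primary"]]
        .sort_values(["fdr", "exposure"], kind="mergesort")["exposure"]
        .tolist()
    )
    matrix = matrix.reindex([e for e in order if e in matrix.index])
    matrix_path = out / "methods_matrix.tsv"
    matrix.to_csv(matrix_path, sep="\t", float_format="%.6g")
    return {"forest": forest_path, "methods_matrix": matrix_path}
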