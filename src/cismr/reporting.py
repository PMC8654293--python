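"""Protein-by-disease grid analysis with FDR control and category coding.

Runs the main estimator (and any requested sensitivity estimators) for every
(protein, disease) cell, adjusts the main-analysis p-values by
Benjamini-Hochberg over the full grid, and encodes each cell's direction and
raw-p shade bin for a machine-readable heatmap table. Sensitivity-method
p-values are reported raw, without FDR adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimators import (
    MRInput,
    egger_correlated,
    gsmr,
    ivw_correlated,
    weighted_median,
)
from .instruments import InstrumentSet, intersect_and_harmonize

__all__ = [
    "GridResult",
    "bh_adjust",
    "run_grid",
    "categorize_cell",
    "write_report",
    "read_report",
    "format_or_ci",
]

#: raw-p shade bins of the heatmap: (upper bound, name), darkest first
_SHADE_BINS = [
    (1e-4, "dark"),
    (1e-3, "medium_dark"),
    (1e-2, "medium_light"),
    (0.05, "light"),
]


def bh_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values.

    Sort ascending, form ``m * p_(k) / k`` and take the running minimum from
    the largest rank down, capping at 1; the original order is restored.
    ``m`` defaults to the number of p-values but may be larger when the
    vector is a subset of a wider family of tests (the grid passes the full
    cell count).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def categorize_cell(raw_p: float, or_: float, significant: bool) -> dict:
    """Direction/shade coding of one grid cell.

    Direction is protective (OR < 1) or harmful; the shade comes from the
    four raw-p bins (0.0001/0.001/0.01/0.05), with "white" for p >= 0.05;
    ``starred`` marks FDR-significant cells.
    """
    if raw_p >= 0.05:
        return {"direction": "none", "shade": "white",
                "starred": bool(significant)}
    shade = next(name for upper, name in _SHADE_BINS if raw_p < upper)
    direction = "protective" if or_ < 1.0 else "harmful"
    return {"direction": direction, "shade": shade,
            "starred": bool(significant)}


@dataclass(frozen=True)
class GridResult:
    """All cells of one protein-by-disease run plus the FDR family size."""

    rows: pd.DataFrame
    m_tests: int

    def __post_init__(self) -> None:
        r = self.rows
        if len(r):
            ok = r["fdr_p"].isna() | (r["fdr_p"] >= r["raw_p"] - 1e-15)
            if not ok.all():
                raise ValueError("adjusted p must not be smaller than raw p")


_SENSITIVITY = {
    "ivw": ivw_correlated,
    "egger": egger_correlated,
}


def run_grid(
    instrument_sets: list[InstrumentSet],
    outcome_stats: dict[str, pd.DataFrame],
    methods: tuple[str, ...] = ("gsmr",),
    heidi_alpha: float = 0.01,
    n_boot: int = 1000,
    seed: int = 0,
    fdr_alpha: float = 0.05,
) -> GridResult:
    """Estimate every (protein, disease) cell and control FDR over the grid.

    For each cell the protein's instruments are re-harmonized to that
    disease's outcome scan, HEIDI-outlier filtering is applied when at least
    five instruments are available, and each requested method is run. The
    main (GSMR) p-values are BH-adjusted with ``m`` equal to the total number
    of attempted cells; cells that fail (e.g. instruments missing from the
    outcome scan) still count toward ``m``.
    """
    records = []
    m_tests = len(instrument_sets) * len(outcome_stats)
    for iset in instrument_sets:
        exp_table = iset.table.rename(
            columns={
                "eaf_zx": "eaf", "b_zx": "beta", "se_zx": "se",
                "p_zx": "p", "n_zx": "n",
            }
        )[["snp_id", "chrom", "pos", "effect_allele", "other_allele",
           "eaf", "beta", "se", "p", "n"]]
        for disease_id, ostats in outcome_stats.items():
            rec = {"protein_id": iset.protein_id, "disease_id": disease_id}
            joined, _ = intersect_and_harmonize(exp_table, ostats,
                                                exclude_palindromic=False)
            if set(joined["snp_id"]) != set(iset.table["snp_id"]):
                missing = set(iset.table["snp_id"]) - set(joined["snp_id"])
                rec.update(status="failed",
                           reason=f"instruments missing from outcome scan: "
                                  f"{sorted(missing)[:5]}")
                records.append(rec)
                continue
            joined = joined.set_index("snp_id").loc[list(iset.table["snp_id"])]
            inp = MRInput(
                snp_ids=tuple(iset.table["snp_id"]),
                b_zx=joined["b_zx"].to_numpy(float),
                se_zx=joined["se_zx"].to_numpy(float),
                b_zy=joined["b_zy"].to_numpy(float),
                se_zy=joined["se_zy"].to_numpy(float),
                ld=iset.ld_outcome.values,
                p_zx=joined["p_zx"].to_numpy(float),
            )
            try:
                main = gsmr(inp, heidi=True, heidi_alpha=heidi_alpha)
            except Exception as exc:  # singular covariance etc.
                rec.update(status="failed", reason=str(exc))
                records.append(rec)
                continue
            rec.update(
                status="ok",
                reason="",
                n_iv_initial=main.n_iv_initial,
                n_iv_used=main.n_iv_used,
                removed_snp_ids=",".join(main.removed_snp_ids),
                heidi_disabled_flag=not main.heidi_applied,
                few_iv_flag=main.n_iv_used < 4,
                b=main.b, se=main.se, raw_p=main.p,
                or_=main.or_, ci_low=main.ci_low, ci_high=main.ci_high,
            )
            for meth in methods:
                if meth == "gsmr":
                    continue
                try:
                    if meth == "wmedian":
                        est = weighted_median(inp, n_boot=n_boot, seed=seed)
                    else:
                        est = _SENSITIVITY[meth](inp)
                    rec[f"{meth}_or"] = est.or_
                    rec[f"{meth}_ci_low"] = est.ci_low
                    rec[f"{meth}_ci_high"] = est.ci_high
                    rec[f"{meth}_p"] = est.p
                    if meth == "egger":
                        rec["egger_intercept"] = est.egger_intercept
                        rec["egger_intercept_p"] = est.egger_intercept_p
                except Exception:
                    rec[f"{meth}_p"] = np.nan
            records.append(rec)
    rows = pd.DataFrame(records)
    rows["fdr_p"] = np.nan
    ok = rows["status"] == "ok" if len(rows) else pd.Series(dtype=bool)
    if len(rows) and ok.any():
        rows.loc[ok, "fdr_p"] = bh_adjust(rows.loc[ok, "raw_p"].to_numpy(),
                                          m=m_tests)
        rows["significant"] = (rows["fdr_p"] < fdr_alpha).fillna(False)
        cats = [
            categorize_cell(r.raw_p, r.or_, r.significant)
            if r.status == "ok" else
            {"direction": "none", "shade": "white", "starred": False}
            for r in rows.itertuples()
        ]
        rows["direction"] = [c["direction"] for c in cats]
        rows["shade"] = [c["shade"] for c in cats]
    return GridResult(rows=rows, m_tests=m_tests)


def format_or_ci(or_: float, ci_low: float, ci_high: float) -> str:
    """Render an OR with CI in table style, e.g. ``0.84 (0.80-0.88)``."""
    return f"{or_:.2f} ({ci_low:.2f}–{ci_high:.2f})"


_PARAMS_FILE = "params.yaml"
_RESULTS_FILE = "results.tsv"
_CATEGORY_FILE = "figure1_categories.tsv"
_LOG_FILE = "run.log"


def write_report(grid: GridResult, out_dir, params: dict | None = None) -> dict:
    """Write results TSV, category TSV, run-parameter YAML and a log.

    ``read_report`` on the same directory reproduces the grid exactly.
    Returns the mapping of artifact names to paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results_path = out / _RESULTS_FILE
    grid.rows.to_csv(results_path, sep="\t", index=False)
    cat_cols = ["protein_id", "disease_id", "direction", "shade",
                "significant", "few_iv_flag", "heidi_disabled_flag"]
    cats = grid.rows[[c for c in cat_cols if c in grid.rows.columns]]
    cat_path = out / _CATEGORY_FILE
    cats.to_csv(cat_path, sep="\t", index=False)
    params_path = out / _PARAMS_FILE
    with open(params_path, "w") as fh:
        yaml.safe_dump({"m_tests": grid.m_tests, **(params or {})}, fh)
    log_path = out / _LOG_FILE
    n_ok = int((grid.rows["status"] == "ok").sum()) if len(grid.rows) else 0
    with open(log_path, "w") as fh:
        fh.write(f"cells attempted: {grid.m_tests}\n")
        fh.write(f"cells estimated: {n_ok}\n")
        if len(grid.rows) and "significant" in grid.rows:
            fh.write(f"FDR-significant cells: "
                     f"{int(grid.rows['significant'].sum())}\n")
    return {"results": results_path, "categories": cat_path,
            "params": params_path, "log": log_path}


def read_report(out_dir) -> GridResult:
    """Read a report directory back into a :class:`GridResult`."""
    out = Path(out_dir)
    rows = pd.read_csv(out / _RESULTS_FILE, sep="\t")
    if "removed_snp_ids" in rows.columns:
        rows["removed_snp_ids"] = rows["removed_snp_ids"].fillna("")
    if "reason" in rows.columns:
        rows["reason"] = rows["reason"].fillna("")
    with open(out / _PARAMS_FILE) as fh:
        params = yaml.safe_load(fh)
    return GridResult(rows=rows, m_tests=int(params["m_tests"]))
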