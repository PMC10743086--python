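"""Result-table writers.

Emits the assay's standard outputs as CSV: a wide IC50 table (rows =
culture/population, columns = drugs, censored entries rendered ">cmax" in
µM), a wide increase/no-change call matrix per marker, and long-format
per-cell, per-well, dose-response and induction tables that round-trip
numerically.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .doseresp import DoseResponseResult
from .induction import InductionResult, call_matrix
from .scoring import WellSummary

__all__ = ["write_results", "ic50_table", "dose_response_long"]


def ic50_table(results: Sequence[DoseResponseResult], scale: float = 1e6) -> pd.DataFrame:
    """Wide IC50 table (µM by default), censored entries as '>cmax'."""
    if not results:
        return pd.DataFrame()
    rows = [
        {
            "culture": r.culture,
            "population": r.population,
            "drug": r.drug,
            "ic50": r.ic50_display(scale=scale),
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    wide = df.pivot(index=["culture", "population"], columns="drug", values="ic50")
    wide.columns.name = None
    return wide


def dose_response_long(results: Sequence[DoseResponseResult]) -> pd.DataFrame:
    """Numeric long-format dose-response table (molar units, full precision)."""
    rows = [
        {
            "culture": r.culture,
            "population": r.population,
            "drug": r.drug,
            "ic50": r.ic50,
            "censored": r.censored,
            "cmax": r.cmax,
            "hill": r.hill,
            "top": r.top,
            "bottom": r.bottom,
            "rss": r.rss,
            "n_replicates": r.n_replicates,
            "degenerate": r.degenerate,
        }
        for r in results
    ]
    cols = [
        "culture", "population", "drug", "ic50", "censored", "cmax",
        "hill", "top", "bottom", "rss", "n_replicates", "degenerate",
    ]
    return pd.DataFrame(rows, columns=cols)


def induction_long(results: Sequence[InductionResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for _, t in r.table.iterrows():
            rows.append(
                {
                    "marker": r.marker,
                    "culture": r.culture,
                    "population": r.population,
                    "drug": r.drug,
                    **t.to_dict(),
                    "call": r.call,
                }
            )
    cols = [
        "marker", "culture", "population", "drug", "concentration", "n",
        "mean_pct", "sem", "p_adj", "increase", "significant", "relevant", "call",
    ]
    return pd.DataFrame(rows, columns=cols)


def write_results(
    outdir: Union[str, Path],
    dose_response: Sequence[DoseResponseResult] = (),
    induction: Sequence[InductionResult] = (),
    cells: Optional[pd.DataFrame] = None,
    wells: Sequence[WellSummary] = (),
) -> dict[str, Path]:
    """Write all result tables to ``outdir``; returns {name: path}.

    Empty collections produce headers-only files so downstream consumers
    always find the same set of outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame, index: bool = False) -> None:
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=index)
        paths[name] = p

    emit("ic50", ic50_table(dose_response), index=True)
    emit("dose_response", dose_response_long(dose_response))
    emit("calls", call_matrix(list(induction)), index=True)
    emit("induction", induction_long(induction))
    if cells is None:
        cells = pd.DataFrame(
            columns=[
                "well", "cell_id", "centroid_row", "centroid_col",
                "nucleus_area", "cell_area", "epithelial_positive", "marker_positive",
            ]
        )
    emit("cells", cells)
    wells_df = pd.DataFrame(
        [w.to_dict() for w in wells],
        columns=[
            "well", "n_total", "n_cancer_marker_pos", "n_cancer_marker_neg",
            "n_stromal_marker_pos", "n_stromal_marker_neg",
            "pct_marker_pos_cancer", "pct_marker_pos_stromal",
        ],
    )
    emit("wells", wells_df)
    return paths
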