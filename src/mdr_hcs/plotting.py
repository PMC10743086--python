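"""Dose-response and induction plots (matplotlib, Agg-safe)."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .doseresp import DoseResponseResult
from .induction import InductionResult

__all__ = ["plot_dose_response", "plot_induction"]


def plot_dose_response(
    result: DoseResponseResult, ax: Optional[plt.Axes] = None
) -> plt.Axes:
    """Replicate viability points, the fitted 4PL curve, and the IC50 mark."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    c = result.concentrations
    ax.semilogx(c, result.responses, "o", ms=4, alpha=0.6, label="replicates")
    if np.isfinite(result.hill):
        grid = np.geomspace(c.min() / 3, c.max() * 3, 200)
        ax.semilogx(grid, result.predict(grid), "-", color="C1", label="4PL fit")
    ax.axhline(50, color="grey", lw=0.8, ls="--")
    if not result.censored and np.isfinite(result.ic50):
        ax.axvline(result.ic50, color="C3", lw=0.8, ls=":",
                   label=f"IC50 = {result.ic50_display()} µM")
    ax.set_xlabel("concentration (M)")
    ax.set_ylabel("% of control")
    ax.set_title(f"{result.culture} {result.population} — {result.drug}"
                 + ("  (IC50 censored)" if result.censored else ""), fontsize=9)
    ax.legend(fontsize=7)
    return ax


def plot_induction(
    result: InductionResult, ax: Optional[plt.Axes] = None
) -> plt.Axes:
    """Mean ± SEM %-positive per concentration, stars where the series is
    both significant and above the relevance threshold."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    t = result.table
    x = np.arange(len(t) + 1)
    means = [result.control_mean] + list(t["mean_pct"])
    sems = [result.control_sem] + list(t["sem"])
    ax.bar(x, means, yerr=sems, capsize=3, color=["0.6"] + ["C0"] * len(t))
    for i, row in t.iterrows():
        if row["significant"] and row["relevant"]:
            ax.annotate("*", (i + 1, row["mean_pct"] + (row["sem"] or 0) + 1),
                        ha="center", fontsize=12)
    ax.set_xticks(x)
    ax.set_xticklabels(["ctrl"] + [f"{c:.3g}" for c in t["concentration"]],
                       rotation=45, fontsize=7)
    ax.set_ylabel(f"% {result.marker}-positive")
    ax.set_title(f"{result.culture} {result.population} — {result.drug} ({result.call})",
                 fontsize=9)
    return ax


def save_report_figures(
    outdir: Union[str, Path],
    dose_response: Sequence[DoseResponseResult] = (),
    induction: Sequence[InductionResult] = (),
) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for r in dose_response:
        ax = plot_dose_response(r)
        p = outdir / f"dr_{r.culture}_{r.drug}_{r.population}.png"
        ax.figure.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
        written.append(p)
    for r in induction:
        ax = plot_induction(r)
        p = outdir / f"induction_{r.marker}_{r.culture}_{r.drug}_{r.population}.png"
        ax.figure.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
        written.append(p)
    return written
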