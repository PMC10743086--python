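"""Marker-induction statistics: Dunnett-vs-control tests and the
biological-relevance call.

For each (marker, culture, population, drug) series the observable is the
percentage of marker-positive cells per replicate well, grouped by
concentration (0 = vehicle control). Each treated concentration is compared
to control with Dunnett's multiple-comparison test (family = the one drug
series, matching per-panel significance stars), and the final call is

    "increase"  iff  at >= 1 concentration:
        adjusted p < alpha  AND  the increase over control meets the
        relevance threshold (default: >= 20% relative increase),

otherwise "no change". Decreases never produce an "increase" call. The
relevance threshold is configurable as a relative fraction of the control
mean (default 0.20) or as absolute percentage points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .plate import AnalysisConfig, PlateLayout
from .scoring import WellSummary

__all__ = [
    "PercentGroups",
    "DunnettResult",
    "InductionResult",
    "group_percentages",
    "dunnett_vs_control",
    "induction_call",
    "call_matrix",
    "twoway_anova",
]


@dataclass
class PercentGroups:
    """Replicate %-positive observations grouped by concentration.

    ``control`` holds the concentration-0 wells; ``treated`` maps each
    positive concentration (molar, ascending) to its replicate values.
    """

    control: np.ndarray
    treated: dict[float, np.ndarray]

    def __post_init__(self):
        self.control = np.asarray(self.control, dtype=float)
        self.treated = {
            float(k): np.asarray(v, dtype=float)
            for k, v in sorted(self.treated.items())
        }

    @property
    def concentrations(self) -> list[float]:
        return list(self.treated)

    def mean(self, conc: Optional[float] = None) -> float:
        g = self.control if conc is None else self.treated[conc]
        return float(np.mean(g))

    def sem(self, conc: Optional[float] = None) -> float:
        g = self.control if conc is None else self.treated[conc]
        if g.size < 2:
            return float("nan")
        return float(np.std(g, ddof=1) / np.sqrt(g.size))


def _population_pct(summary: WellSummary, population: str) -> float:
    if population == "cancer":
        return summary.pct_marker_pos_cancer
    if population == "stromal":
        return summary.pct_marker_pos_stromal
    raise ValueError(f"population must be 'cancer' or 'stromal', got {population!r}")


def group_percentages(
    summaries: Mapping[str, WellSummary],
    layout: PlateLayout,
    culture: str,
    drug: str,
    population: str = "cancer",
) -> PercentGroups:
    """Collect per-replicate marker-positive percentages for one drug series.

    One observation per replicate well; wells where the population is absent
    (undefined percentage) are excluded with a warning. Requires at least
    one control and one treated group.
    """
    control_vals, treated_vals = [], {}
    for w in layout.wells:
        if w.culture != culture or w.well_id not in summaries:
            continue
        if w.role == "control":
            dest = control_vals
        elif w.role == "treated" and w.drug == drug:
            dest = treated_vals.setdefault(w.concentration, [])
        else:
            continue
        pct = _population_pct(summaries[w.well_id], population)
        if np.isnan(pct):
            warnings.warn(
                f"well {w.well_id}: no {population} cells; excluded from "
                f"{culture}/{drug} induction groups"
            )
            continue
        dest.append(pct)
    if not control_vals:
        raise ValueError(f"no usable control wells for culture {culture!r}")
    if not treated_vals:
        raise ValueError(f"no treated wells for {culture!r} / {drug!r}")
    return PercentGroups(
        control=np.array(control_vals),
        treated={k: np.array(v) for k, v in treated_vals.items()},
    )


@dataclass
class DunnettResult:
    """Dunnett many-to-one comparison of treated groups against control."""

    concentrations: list[float]
    statistics: np.ndarray  # pooled-variance t vs control, per treated group
    pvalues: np.ndarray  # family-wise adjusted, two-sided
    df: int
    degenerate: bool = False  # zero pooled variance


def dunnett_vs_control(
    groups: PercentGroups,
    rng: Union[int, np.random.Generator, None] = 0,
) -> DunnettResult:
    """Two-sided Dunnett test of every treated concentration against control.

    Pooled-variance t statistics; the family-wise adjusted p-value is the
    tail probability of the maximum |T| over the k comparisons under the
    equicorrelated multivariate t (exact unequal-n correlations), evaluated
    by randomized quasi-Monte-Carlo — pass ``rng`` for reproducibility.
    With a single comparison the adjusted p equals the ordinary pooled
    two-sample t p-value (computed exactly).
    """
    control = groups.control
    treated = [groups.treated[c] for c in groups.concentrations]
    for g in [control, *treated]:
        if g.size < 2:
            raise ValueError("every group needs n >= 2 for testing")
    k = len(treated)
    n_total = control.size + sum(g.size for g in treated)
    df = n_total - k - 1
    ss = sum(float(np.sum((g - g.mean()) ** 2)) for g in [control, *treated])
    s2 = ss / df
    tstats = np.empty(k)
    if s2 <= 0:
        # all groups internally constant: sign of the mean difference decides
        for i, g in enumerate(treated):
            tstats[i] = np.inf if g.mean() != control.mean() else 0.0
        pvals = np.where(np.isinf(tstats), 0.0, 1.0)
        return DunnettResult(groups.concentrations, tstats, pvals, df, degenerate=True)
    for i, g in enumerate(treated):
        se = np.sqrt(s2 * (1.0 / g.size + 1.0 / control.size))
        tstats[i] = (g.mean() - control.mean()) / se
    if k == 1:
        pvals = np.array([2.0 * stats.t.sf(abs(tstats[0]), df)])
    else:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        res = stats.dunnett(*treated, control=control, rng=rng)
        pvals = np.asarray(res.pvalue, dtype=float)
    return DunnettResult(groups.concentrations, tstats, pvals, df)


@dataclass
class InductionResult:
    """Per-concentration induction statistics and the increase/no-change call."""

    marker: str
    culture: str
    population: str
    drug: str
    table: pd.DataFrame  # columns: concentration, n, mean_pct, sem, p_adj, increase, significant, relevant
    call: str  # "increase" | "no change"
    control_mean: float
    control_sem: float
    n_control: int

    def summary(self) -> str:
        lines = [
            f"Induction: {self.marker} in {self.culture} {self.population} cells, {self.drug}",
            f"  control: {self.control_mean:.2f}% +/- {self.control_sem:.2f} (n={self.n_control})",
            self.table.to_string(index=False),
            f"  call: {self.call}",
        ]
        return "\n".join(lines)


def induction_call(
    groups: PercentGroups,
    dunnett: DunnettResult,
    config: AnalysisConfig,
    marker: str = "ABCB1",
    culture: str = "",
    population: str = "cancer",
    drug: str = "",
) -> InductionResult:
    """Apply the significance + biological-relevance rule to one drug series.

    With the relative metric the increase is ``(mean_i - mean_0)/mean_0``,
    compared against ``config.induction_threshold``; with absolute_points it
    is ``mean_i - mean_0`` in percentage points, compared against
    ``100 * induction_threshold``. "increase" requires both adjusted
    p < alpha and the relevance threshold at >= 1 concentration.
    """
    if list(groups.concentrations) != list(dunnett.concentrations):
        raise ValueError("groups and Dunnett result are not aligned")
    m0 = groups.mean()
    relative = config.induction_metric == "relative"
    if relative and m0 == 0:
        raise ValueError(
            "control mean is 0%: the relative induction metric is undefined; "
            "use induction_metric='absolute_points'"
        )
    rows = []
    any_hit = False
    for i, conc in enumerate(groups.concentrations):
        mi = groups.mean(conc)
        inc = (mi - m0) / m0 if relative else (mi - m0)
        thr = config.induction_threshold if relative else 100.0 * config.induction_threshold
        significant = bool(dunnett.pvalues[i] < config.alpha)
        relevant = bool(inc >= thr and mi > m0)
        any_hit = any_hit or (significant and relevant)
        rows.append(
            {
                "concentration": conc,
                "n": groups.treated[conc].size,
                "mean_pct": mi,
                "sem": groups.sem(conc),
                "p_adj": float(dunnett.pvalues[i]),
                "increase": inc,
                "significant": significant,
                "relevant": relevant,
            }
        )
    return InductionResult(
        marker=marker,
        culture=culture,
        population=population,
        drug=drug,
        table=pd.DataFrame(rows),
        call="increase" if any_hit else "no change",
        control_mean=m0,
        control_sem=groups.sem(),
        n_control=groups.control.size,
    )


def call_matrix(results: Sequence[InductionResult]) -> pd.DataFrame:
    """Wide increase/no-change matrix: rows (marker, culture, population),
    one column per drug — the shape of the published call tables."""
    if not results:
        return pd.DataFrame()
    seen = set()
    for r in results:
        key = (r.marker, r.culture, r.population, r.drug)
        if key in seen:
            raise ValueError(f"duplicate grid cell {key}")
        seen.add(key)
    df = pd.DataFrame(
        [
            {
                "marker": r.marker,
                "culture": r.culture,
                "population": r.population,
                "drug": r.drug,
                "call": r.call,
            }
            for r in results
        ]
    )
    wide = df.pivot(index=["marker", "culture", "population"], columns="drug", values="call")
    wide.columns.name = None
    return wide


def twoway_anova(
    summaries: Mapping[str, WellSummary],
    layout: PlateLayout,
    culture: str,
    drug: str,
) -> pd.DataFrame:
    """Diagnostic two-factor (population × concentration) ANOVA table.

    Complements the per-population Dunnett families with an overall test of
    concentration, population, and their interaction on %-positive.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    rows = []
    for w in layout.wells:
        if w.culture != culture or w.well_id not in summaries:
            continue
        if w.role == "treated" and w.drug != drug:
            continue
        if w.role == "empty":
            continue
        s = summaries[w.well_id]
        for pop in ("cancer", "stromal"):
            pct = _population_pct(s, pop)
            if not np.isnan(pct):
                rows.append(
                    {"pct": pct, "population": pop, "concentration": w.concentration}
                )
    df = pd.DataFrame(rows)
    if df.empty or df["population"].nunique() < 2:
        raise ValueError("two-way ANOVA needs both populations present")
    model = ols("pct ~ C(population) * C(concentration)", data=df).fit()
    return sm.stats.anova_lm(model, typ=2)
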