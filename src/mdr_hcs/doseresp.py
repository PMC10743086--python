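"""Viability, four-parameter-logistic dose-response fitting, and IC50 calls.

Viability of a population (total / cancer / stromal) in a treated well is
its cell count as a percentage of the mean count in same-culture control
wells. Dose-response is the standard 4PL on log10 concentration,

    R(c) = bottom + (top - bottom) / (1 + (c / x50)^h),

fitted jointly over all replicate points by bounded least squares. The
reported IC50 is where the *fitted* curve crosses 50% of control (not the
4PL inflection); when the curve never reaches 50% within the tested range,
the IC50 is censored and reported as ">cmax" — the convention used for
drugs ineffective across their whole panel. Fold-resistance and
selectivity calls are simple, censoring-aware ratio/order operations on
IC50 values.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import least_squares

from .scoring import WellSummary

__all__ = [
    "IC50",
    "DoseResponseResult",
    "FoldResistance",
    "SelectivityCall",
    "viability",
    "fit_curve",
    "fold_resistance",
    "selectivity_call",
]


@dataclass(frozen=True)
class IC50:
    """An IC50 value, possibly right-censored.

    ``censored=True`` means the true IC50 exceeds ``value`` (the highest
    tested concentration). Units are whatever the caller uses consistently
    (molar throughout this package).
    """

    value: float
    censored: bool = False

    @classmethod
    def parse(cls, x: Union["IC50", float, int, str, "DoseResponseResult"]) -> "IC50":
        if isinstance(x, IC50):
            return x
        if isinstance(x, DoseResponseResult):
            return x.ic50_value
        if isinstance(x, str):
            m = re.match(r"^\s*(>)?\s*([0-9.eE+-]+)\s*$", x)
            if not m:
                raise ValueError(f"cannot parse IC50 {x!r}")
            return cls(float(m.group(2)), censored=m.group(1) == ">")
        return cls(float(x))

    def display(self, scale: float = 1.0, digits: int = 4) -> str:
        v = self.value * scale
        s = f"{v:.{digits}g}"
        return f">{s}" if self.censored else s


def viability(
    treated: WellSummary, controls: Sequence[WellSummary], population: str = "total"
) -> float:
    """Percent-of-control cell count for one treated well.

    ``100 * count(treated) / mean(count(controls))`` for the requested
    population ('total', 'cancer', 'stromal').
    """
    if not controls:
        raise ValueError("at least one control well is required")
    mean_ctrl = float(np.mean([c.count(population) for c in controls]))
    if mean_ctrl <= 0:
        raise ValueError(
            f"mean control count for population {population!r} is zero; "
            "viability is undefined"
        )
    return 100.0 * treated.count(population) / mean_ctrl


def _4pl(c: np.ndarray, top: float, bottom: float, log_x50: float, h: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10 ** (h * (np.log10(c) - log_x50)))


@dataclass
class DoseResponseResult:
    """A fitted (or censored) dose-response curve for one population.

    ``concentrations``/``responses`` are the jointly fitted replicate points;
    ``ic50`` is molar (NaN when censored or degenerate), ``cmax`` the highest
    tested concentration. ``hill``, ``top``, ``bottom`` are the 4PL
    parameters and ``rss`` the residual sum of squares.
    """

    culture: str
    drug: str
    population: str
    concentrations: np.ndarray
    responses: np.ndarray
    ic50: float
    censored: bool
    cmax: float
    hill: float
    top: float
    bottom: float
    rss: float
    n_replicates: int
    degenerate: bool = False

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        uniq = np.unique(self.concentrations)
        if not np.all(np.diff(uniq) > 0):
            raise ValueError("concentrations must be strictly increasing")
        if np.any(self.responses < 0):
            raise ValueError("responses must be >= 0")

    @property
    def ic50_value(self) -> IC50:
        return IC50(self.cmax if self.censored else self.ic50, censored=self.censored)

    def ic50_display(self, scale: float = 1e6, digits: int = 4) -> str:
        """Formatted IC50, default in µM (e.g. '5.705' or '>100')."""
        if self.degenerate:
            return "degenerate"
        return self.ic50_value.display(scale=scale, digits=digits)

    def predict(self, concentrations: np.ndarray) -> np.ndarray:
        return _4pl(np.asarray(concentrations, float), self.top, self.bottom,
                    math.log10(self.ic50_inflection), self.hill)

    @property
    def ic50_inflection(self) -> float:
        """The 4PL midpoint parameter (curve half-way between top and bottom)."""
        return getattr(self, "_x50", float("nan"))

    def summary(self) -> str:
        lines = [
            f"Dose-response: {self.culture} / {self.drug} / {self.population}",
            f"  n points: {self.responses.size} ({self.n_replicates} replicates)",
            f"  IC50: {self.ic50_display()} uM"
            + (" (censored)" if self.censored else ""),
            f"  hill: {self.hill:.3g}  top: {self.top:.4g}  bottom: {self.bottom:.4g}",
            f"  rss: {self.rss:.4g}",
        ]
        if self.degenerate:
            lines.append("  WARNING: degenerate fit (IC50 unidentifiable)")
        return "\n".join(lines)


def fit_curve(
    concentrations: Sequence[float],
    responses: Sequence[float],
    culture: str = "",
    drug: str = "",
    population: str = "total",
    cmax: Optional[float] = None,
) -> DoseResponseResult:
    """Fit a 4PL viability curve and derive the (possibly censored) IC50.

    ``concentrations`` (molar) and ``responses`` (% of control) are paired
    per replicate point; replicate points share concentrations and are
    fitted jointly. Requires >= 4 distinct positive concentrations. The
    IC50 is censored (">cmax") when the fitted curve stays above 50% of
    control over the whole tested range.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if c.shape != r.shape:
        raise ValueError("concentrations and responses must be paired")
    if not np.all(np.isfinite(r)) or not np.all(np.isfinite(c)):
        raise ValueError("non-finite concentrations or responses")
    if np.any(c <= 0):
        raise ValueError("fit uses treated concentrations only (all > 0)")
    uniq = np.unique(c)
    if uniq.size < 4:
        raise ValueError(f"need >= 4 distinct concentrations, got {uniq.size}")
    if np.any(r < 0):
        raise ValueError("responses must be >= 0")
    cmax = float(cmax if cmax is not None else uniq.max())
    order = np.argsort(c, kind="stable")
    c, r = c[order], r[order]
    n_rep = int(np.max(np.bincount(np.searchsorted(uniq, c))))

    flat = float(np.ptp(r)) < 1e-9
    if flat:
        res = DoseResponseResult(
            culture, drug, population, c, r,
            ic50=float("nan"), censored=bool(r[0] > 50.0), cmax=cmax,
            hill=float("nan"), top=float(r[0]), bottom=float(r[0]),
            rss=0.0, n_replicates=n_rep,
            degenerate=bool(r[0] <= 50.0),
        )
        res._x50 = float("nan")
        return res

    # data-driven initialization
    means = np.array([r[c == u].mean() for u in uniq])
    top0 = min(float(r.max()), 120.0)
    bottom0 = max(float(r.min()), 0.0)
    x50_0 = math.log10(uniq[int(np.argmin(np.abs(means - 50.0)))])
    lo_x = math.log10(uniq.min()) - 4
    hi_x = math.log10(uniq.max()) + 4
    p0 = [top0, max(bottom0, 1e-6), np.clip(x50_0, lo_x, hi_x), 1.0]

    def resid(p):
        return _4pl(c, p[0], p[1], p[2], p[3]) - r

    sol = least_squares(
        resid,
        p0,
        bounds=([0.0, 0.0, lo_x, 1e-3], [120.0, 120.0, hi_x, 10.0]),
        method="trf",
    )
    top, bottom, x50_log, h = sol.x
    if bottom > top:  # enforce a decreasing curve parameterization
        top, bottom = bottom, top
    x50 = 10.0**x50_log
    rss = float(np.sum(sol.fun**2))

    censored = False
    degenerate = False
    ic50 = float("nan")
    if top > 50.0 > bottom:
        c50 = x50 * ((top - 50.0) / (50.0 - bottom)) ** (1.0 / h)
        if c50 > cmax:
            censored = True
        else:
            ic50 = float(c50)
    elif bottom >= 50.0:
        censored = True  # curve never drops to 50% of control
    else:  # top <= 50: below half-kill already at the lowest doses
        degenerate = True

    res = DoseResponseResult(
        culture, drug, population, c, r,
        ic50=ic50, censored=censored, cmax=cmax,
        hill=float(h), top=float(top), bottom=float(bottom),
        rss=rss, n_replicates=n_rep, degenerate=degenerate,
    )
    res._x50 = float(x50)
    return res


@dataclass(frozen=True)
class FoldResistance:
    """Ratio of a resistant IC50 to a sensitive IC50 (possibly a lower bound)."""

    fold: float
    lower_bound: bool = False  # True when the resistant IC50 was censored

    @property
    def n_fold(self) -> int:
        """Integer-rounded fold for 'n-fold' phrasing."""
        return int(round(self.fold))

    def __str__(self) -> str:
        s = f"{self.fold:.2f}-fold"
        return f"> {s}" if self.lower_bound else s


def fold_resistance(ic50_resistant, ic50_sensitive) -> FoldResistance:
    """Fold-resistance = resistant IC50 / sensitive IC50.

    Accepts numbers, ">x" strings, :class:`IC50`, or fitted results. A
    censored resistant IC50 gives a lower bound ("> cmax/sensitive"); a
    censored sensitive IC50 makes the ratio undefined and raises.
    """
    res = IC50.parse(ic50_resistant)
    sen = IC50.parse(ic50_sensitive)
    if sen.censored:
        raise ValueError("sensitive IC50 is censored; fold-resistance undefined")
    if sen.value <= 0:
        raise ValueError("sensitive IC50 must be > 0")
    return FoldResistance(fold=res.value / sen.value, lower_bound=res.censored)


@dataclass(frozen=True)
class SelectivityCall:
    """Which of two IC50s identifies the more drug-sensitive population."""

    selected: Optional[str]  # "a", "b", or None (no call)
    label_a: str = "a"
    label_b: str = "b"

    @property
    def selective_label(self) -> Optional[str]:
        if self.selected is None:
            return None
        return self.label_a if self.selected == "a" else self.label_b

    def __str__(self) -> str:
        if self.selected is None:
            return "no call"
        return f"selective toward {self.selective_label}"


def _as_ic50_with_meta(x) -> tuple[IC50, Optional[str], str]:
    if isinstance(x, DoseResponseResult):
        return x.ic50_value, (x.drug or None), f"{x.culture}/{x.population}".strip("/")
    return IC50.parse(x), None, ""


def selectivity_call(ic50_a, ic50_b, label_a: str = "a", label_b: str = "b") -> SelectivityCall:
    """Flag the more sensitive of two populations for the same drug.

    The call is made only when the ordering is unambiguous under censoring:
    an uncensored IC50 strictly below the other's value (or censoring
    bound) wins; censored-vs-censored never yields a call. Fitted results
    for different drugs raise.
    """
    a, drug_a, tag_a = _as_ic50_with_meta(ic50_a)
    b, drug_b, tag_b = _as_ic50_with_meta(ic50_b)
    if drug_a is not None and drug_b is not None and drug_a != drug_b:
        raise ValueError(f"selectivity compares one drug, got {drug_a!r} vs {drug_b!r}")
    label_a = tag_a or label_a
    label_b = tag_b or label_b
    selected: Optional[str] = None
    if not a.censored and not b.censored:
        if a.value < b.value:
            selected = "a"
        elif b.value < a.value:
            selected = "b"
    elif not a.censored and b.censored:
        if a.value <= b.value:  # b's true IC50 > bound >= a
            selected = "a"
    elif a.censored and not b.censored:
        if b.value <= a.value:
            selected = "b"
    # both censored: no call
    return SelectivityCall(selected=selected, label_a=label_a, label_b=label_b)
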