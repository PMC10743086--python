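"""Per-cell positivity scoring and four-population well summaries.

Each segmented cell is classified on two axes:

* epithelial (cancer) vs non-epithelial (stromal), from the cytokeratin
  channel — the axis that separates carcinoma cells from fibroblast-like
  stromal cells in a mixed culture;
* MDR-marker positive vs negative, from the marker channel (ABCB1/ABCC1/
  ABCG2 staining), when that channel is present.

Positivity compares the cytoplasmic intensity statistic (mean by default,
nucleus excluded; optionally integrated) against a per-channel threshold;
a value exactly at the threshold scores positive. Successful nuclear
segmentation is what defines "nuclear-stain positive": every scored cell
counts toward the well total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .plate import AnalysisConfig
from .simulate import CLASS_LABELS, SimulationTruth

__all__ = [
    "CellRecord",
    "WellSummary",
    "score_cells",
    "summarize_well",
    "records_to_frame",
    "score_against_truth",
    "TruthComparison",
]


@dataclass(frozen=True)
class CellRecord:
    """One segmented, scored cell."""

    cell_id: int
    well_id: str
    centroid: tuple[float, float]  # (row, col), 0-based px
    nucleus_area: float  # px²
    cell_area: float  # px²
    mean_intensity: dict[str, float]  # per channel name
    epithelial_positive: bool
    marker_positive: Optional[bool] = None

    def __post_init__(self):
        if self.nucleus_area > self.cell_area:
            raise ValueError("nucleus_area cannot exceed cell_area")

    @property
    def population(self) -> str:
        """Four-class population label (marker channel required)."""
        if self.marker_positive is None:
            raise ValueError("no marker channel was scored")
        a = "cancer" if self.epithelial_positive else "stromal"
        b = "marker_pos" if self.marker_positive else "marker_neg"
        return f"{a}_{b}"


@dataclass
class WellSummary:
    """Counts of the four scored populations in one well."""

    well_id: str
    n_total: int
    n_cancer_marker_pos: int
    n_cancer_marker_neg: int
    n_stromal_marker_pos: int
    n_stromal_marker_neg: int

    def __post_init__(self):
        s = (
            self.n_cancer_marker_pos
            + self.n_cancer_marker_neg
            + self.n_stromal_marker_pos
            + self.n_stromal_marker_neg
        )
        if s != self.n_total:
            raise ValueError(
                f"well {self.well_id}: population counts sum to {s}, total is {self.n_total}"
            )

    @property
    def n_cancer(self) -> int:
        return self.n_cancer_marker_pos + self.n_cancer_marker_neg

    @property
    def n_stromal(self) -> int:
        return self.n_stromal_marker_pos + self.n_stromal_marker_neg

    @property
    def pct_marker_pos_cancer(self) -> float:
        """% marker-positive among cancer cells; NaN when no cancer cells."""
        if self.n_cancer == 0:
            return float("nan")
        return 100.0 * self.n_cancer_marker_pos / self.n_cancer

    @property
    def pct_marker_pos_stromal(self) -> float:
        if self.n_stromal == 0:
            return float("nan")
        return 100.0 * self.n_stromal_marker_pos / self.n_stromal

    def count(self, population: str) -> int:
        """Population count: 'total', 'cancer', or 'stromal'."""
        if population == "total":
            return self.n_total
        if population == "cancer":
            return self.n_cancer
        if population == "stromal":
            return self.n_stromal
        raise ValueError(f"unknown population {population!r}")

    def to_dict(self) -> dict:
        return {
            "well": self.well_id,
            "n_total": self.n_total,
            "n_cancer_marker_pos": self.n_cancer_marker_pos,
            "n_cancer_marker_neg": self.n_cancer_marker_neg,
            "n_stromal_marker_pos": self.n_stromal_marker_pos,
            "n_stromal_marker_neg": self.n_stromal_marker_neg,
            "pct_marker_pos_cancer": self.pct_marker_pos_cancer,
            "pct_marker_pos_stromal": self.pct_marker_pos_stromal,
        }


def _per_label_stat(
    image: np.ndarray, labels: np.ndarray, index: np.ndarray, statistic: str
) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        if statistic == "mean":
            return np.asarray(ndi.mean(image, labels=labels, index=index))
        return np.asarray(ndi.sum_labels(image, labels=labels, index=index))


def score_cells(
    stack: np.ndarray,
    cells: np.ndarray,
    nuclei: np.ndarray,
    config: AnalysisConfig,
    well_id: str = "A1",
) -> list[CellRecord]:
    """Score every segmented cell for epithelial and marker positivity.

    ``stack`` is (C, H, W) with channels per ``config.channel_map``; ``cells``
    and ``nuclei`` are co-registered label masks sharing labels 1..K. The
    intensity statistic is computed over the cytoplasm (cell region minus
    nucleus); for degenerate cells with no cytoplasmic pixels the whole cell
    region is used instead.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (channels, H, W)")
    if stack.shape[1:] != cells.shape or cells.shape != nuclei.shape:
        raise ValueError("stack and masks have mismatched shapes")
    if "epithelial" not in config.channel_map:
        raise ValueError(
            "an epithelial (cytokeratin) channel is required to discriminate "
            "cancer from stromal cells"
        )
    for name, idx in config.channel_map.items():
        if not 0 <= idx < stack.shape[0]:
            raise ValueError(f"channel {name!r} index {idx} outside stack")

    n_labels = int(cells.max())
    if n_labels == 0:
        return []
    index = np.arange(1, n_labels + 1)
    cyto = np.where(nuclei > 0, 0, cells)
    has_cyto = np.isin(index, np.unique(cyto))

    nucleus_areas = ndi.sum_labels(np.ones_like(nuclei, float), labels=nuclei, index=index)
    cell_areas = ndi.sum_labels(np.ones_like(cells, float), labels=cells, index=index)
    centroids = ndi.center_of_mass(nuclei > 0, labels=nuclei, index=index)

    intensities: dict[str, np.ndarray] = {}
    for name, idx in config.channel_map.items():
        img = stack[idx].astype(float)
        vals_cyto = _per_label_stat(img, cyto, index, config.intensity_statistic)
        vals_cell = _per_label_stat(img, cells, index, config.intensity_statistic)
        intensities[name] = np.where(has_cyto, vals_cyto, vals_cell)

    thresholds = config.segmentation.cytoplasm_thresholds
    if "epithelial" not in thresholds:
        raise ValueError("no cytoplasm threshold configured for the epithelial channel")
    has_marker = "marker" in config.channel_map
    if has_marker and "marker" not in thresholds:
        raise ValueError("no cytoplasm threshold configured for the marker channel")

    records = []
    for i, lab in enumerate(index):
        mi = {name: float(vals[i]) for name, vals in intensities.items()}
        records.append(
            CellRecord(
                cell_id=int(lab),
                well_id=well_id,
                centroid=(float(centroids[i][0]), float(centroids[i][1])),
                nucleus_area=float(nucleus_areas[i]),
                cell_area=float(cell_areas[i]),
                mean_intensity=mi,
                epithelial_positive=bool(mi["epithelial"] >= thresholds["epithelial"]),
                marker_positive=(
                    bool(mi["marker"] >= thresholds["marker"]) if has_marker else None
                ),
            )
        )
    return records


def summarize_well(records: Sequence[CellRecord], well_id: str) -> WellSummary:
    """Cross-tabulate the four populations for one well.

    An empty record list yields zero counts (percentages are then NaN).
    """
    for r in records:
        if r.well_id != well_id:
            raise ValueError(f"record from well {r.well_id!r} passed to {well_id!r}")
    counts = dict.fromkeys(CLASS_LABELS, 0)
    for r in records:
        counts[r.population] += 1
    return WellSummary(
        well_id=well_id,
        n_total=len(records),
        n_cancer_marker_pos=counts["cancer_marker_pos"],
        n_cancer_marker_neg=counts["cancer_marker_neg"],
        n_stromal_marker_pos=counts["stromal_marker_pos"],
        n_stromal_marker_neg=counts["stromal_marker_neg"],
    )


def records_to_frame(records: Sequence[CellRecord]) -> pd.DataFrame:
    """Long-format per-cell table (one row per CellRecord)."""
    rows = []
    for r in records:
        row = {
            "well": r.well_id,
            "cell_id": r.cell_id,
            "centroid_row": r.centroid[0],
            "centroid_col": r.centroid[1],
            "nucleus_area": r.nucleus_area,
            "cell_area": r.cell_area,
            "epithelial_positive": r.epithelial_positive,
            "marker_positive": r.marker_positive,
        }
        for ch, v in r.mean_intensity.items():
            row[f"intensity_{ch}"] = v
        rows.append(row)
    cols = [
        "well",
        "cell_id",
        "centroid_row",
        "centroid_col",
        "nucleus_area",
        "cell_area",
        "epithelial_positive",
        "marker_positive",
    ]
    return pd.DataFrame(rows, columns=None if rows else cols)


@dataclass
class TruthComparison:
    """Detection + classification performance of scored cells vs ground truth."""

    confusion: pd.DataFrame  # rows: truth class, cols: predicted class (+ "missed")
    n_false_positive: int  # detections with no truth match
    detection_precision: float
    detection_recall: float

    def class_recall(self, label: str) -> float:
        row = self.confusion.loc[label]
        denom = row.sum()
        if denom == 0:
            return float("nan")
        return float(row[label] / denom)

    @property
    def classification_accuracy(self) -> float:
        matched = self.confusion.drop(columns="missed")
        total = matched.to_numpy().sum()
        if total == 0:
            return float("nan")
        return float(np.trace(matched.loc[list(CLASS_LABELS), list(CLASS_LABELS)].to_numpy()) / total)


def score_against_truth(
    records: Sequence[CellRecord], truth: SimulationTruth
) -> TruthComparison:
    """Match scored cells to simulator ground truth and tabulate confusion.

    A detection matches the nearest unmatched truth cell whose centroid lies
    within that truth cell's nucleus radius. Only meaningful on simulated
    wells (requires a truth table).
    """
    if truth.cells is None or not isinstance(truth.cells, pd.DataFrame):
        raise ValueError("score_against_truth requires simulated input with a truth table")
    t = truth.cells
    classes = list(CLASS_LABELS)
    confusion = pd.DataFrame(
        0, index=classes, columns=classes + ["missed"], dtype=int
    )
    n_false_pos = 0
    if len(t) == 0:
        n_false_pos = len(records)
        prec = float("nan") if not records else 0.0
        return TruthComparison(confusion, n_false_pos, prec, float("nan"))
    tree = cKDTree(t[["row", "col"]].to_numpy())
    matched_truth: dict[int, int] = {}  # truth idx -> record idx
    for ri, r in enumerate(records):
        dist, ti = tree.query(r.centroid)
        if dist <= t["nucleus_radius"].iloc[ti] and ti not in matched_truth:
            matched_truth[ti] = ri
        else:
            n_false_pos += 1
    for ti in range(len(t)):
        true_lab = t["population"].iloc[ti]
        if ti in matched_truth:
            rec = records[matched_truth[ti]]
            try:
                pred = rec.population
            except ValueError:
                pred = "missed"
            confusion.loc[true_lab, pred] += 1
        else:
            confusion.loc[true_lab, "missed"] += 1
    n_matched = len(matched_truth)
    n_det = len(records)
    precision = n_matched / n_det if n_det else float("nan")
    recall = n_matched / len(t)
    return TruthComparison(confusion, n_false_pos, precision, recall)
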