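"""Plate layout and analysis configuration model.

A 384-well plate (rows A–P, columns 1–24) is the unit of experiment: each
well holds one culture, optionally treated with one drug at one
concentration, with vehicle controls encoded as concentration 0.
Concentrations are stored in molar units internally; nM/µM is a display
concern handled at the table-formatting layer.
"""

from __future__ import annotations

import io
import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd
import yaml

__all__ = [
    "LayoutError",
    "WellAssignment",
    "PlateLayout",
    "SegmentationParams",
    "AnalysisConfig",
    "well_to_index",
    "index_to_well",
    "parse_layout",
    "write_layout",
    "load_config",
]

N_ROWS = 16
N_COLS = 24
_WELL_RE = re.compile(r"^([A-P])([1-9][0-9]?)$")

ROLES = ("control", "treated", "empty")


class LayoutError(ValueError):
    """Raised when a plate layout violates the 384-well conventions."""


def well_to_index(well_id: str) -> tuple[int, int]:
    """Map a well identifier like ``"A1"`` to 0-based ``(row, col)``.

    Row-major, 0-based: ``A1 -> (0, 0)``, ``P24 -> (15, 23)``.
    """
    m = _WELL_RE.match(well_id.strip())
    if not m:
        raise LayoutError(f"malformed well id {well_id!r}")
    row = ord(m.group(1)) - ord("A")
    col = int(m.group(2)) - 1
    if not (0 <= row < N_ROWS and 0 <= col < N_COLS):
        raise LayoutError(f"well id {well_id!r} outside 384-well range A1–P24")
    return row, col


def index_to_well(row: int, col: int) -> str:
    """Inverse of :func:`well_to_index`."""
    if not (0 <= row < N_ROWS and 0 <= col < N_COLS):
        raise LayoutError(f"(row, col) = ({row}, {col}) outside 384-well range")
    return f"{chr(ord('A') + row)}{col + 1}"


@dataclass(frozen=True)
class WellAssignment:
    """One well's experimental assignment."""

    well_id: str
    culture: str
    drug: Optional[str] = None
    concentration: float = 0.0  # molar; 0 = vehicle control
    replicate: int = 1
    role: str = "control"

    def __post_init__(self):
        well_to_index(self.well_id)  # validates the identifier
        if self.role not in ROLES:
            raise LayoutError(
                f"well {self.well_id}: role must be one of {ROLES}, got {self.role!r}"
            )
        if self.concentration < 0:
            raise LayoutError(f"well {self.well_id}: negative concentration")
        if self.replicate < 1:
            raise LayoutError(f"well {self.well_id}: replicate must be >= 1")
        if self.role == "treated":
            if not self.drug or not self.concentration > 0:
                raise LayoutError(
                    f"well {self.well_id}: treated well requires a drug and a "
                    f"concentration > 0"
                )
        if self.role == "control" and self.concentration != 0:
            raise LayoutError(
                f"well {self.well_id}: control well must have concentration 0"
            )


@dataclass
class PlateLayout:
    """A validated 384-well plate layout."""

    plate_id: str
    wells: list[WellAssignment] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.wells:
            raise LayoutError("no wells in layout")
        seen: set[str] = set()
        for w in self.wells:
            if w.well_id in seen:
                raise LayoutError(f"duplicate well id {w.well_id!r}")
            seen.add(w.well_id)
        # every treated (culture, drug) series needs a same-culture control
        controls = {w.culture for w in self.wells if w.role == "control"}
        for w in self.wells:
            if w.role == "treated" and w.culture not in controls:
                raise LayoutError(
                    f"treated wells for culture {w.culture!r} have no control well"
                )

    def __len__(self) -> int:
        return len(self.wells)

    def __iter__(self):
        return iter(self.wells)

    def well(self, well_id: str) -> WellAssignment:
        for w in self.wells:
            if w.well_id == well_id:
                return w
        raise KeyError(well_id)

    @property
    def cultures(self) -> list[str]:
        return sorted({w.culture for w in self.wells if w.role != "empty"})

    @property
    def drugs(self) -> list[str]:
        return sorted({w.drug for w in self.wells if w.drug})

    def treated(self, culture: str, drug: str) -> list[WellAssignment]:
        return [
            w
            for w in self.wells
            if w.role == "treated" and w.culture == culture and w.drug == drug
        ]

    def controls(self, culture: str) -> list[WellAssignment]:
        return [
            w for w in self.wells if w.role == "control" and w.culture == culture
        ]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([asdict(w) for w in self.wells])
        return df.rename(columns={"well_id": "well"})


_LAYOUT_COLUMNS = ["well", "culture", "drug", "concentration", "replicate", "role"]


def parse_layout(source: Union[str, Path, io.IOBase], plate_id: str = "plate") -> PlateLayout:
    """Read a layout table (CSV with header well,culture,drug,concentration,
    replicate,role) and return a validated :class:`PlateLayout`.

    Accepts a path, a CSV string, or an open text stream. Empty drug cells and
    empty concentrations are read as no-drug / 0 M.
    """
    if isinstance(source, (str, Path)):
        p = Path(source)
        if isinstance(source, str) and "\n" in source:
            buf: Union[io.StringIO, Path] = io.StringIO(source)
        elif p.exists():
            buf = p
        else:
            raise LayoutError(f"layout file {source!r} not found")
    else:
        buf = source  # type: ignore[assignment]
    try:
        df = pd.read_csv(buf, dtype={"well": str, "culture": str, "drug": str, "role": str})
    except Exception as exc:  # malformed CSV
        raise LayoutError(f"could not parse layout table: {exc}") from exc
    missing = [c for c in _LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise LayoutError(f"layout table missing columns: {missing}")
    if df.empty:
        raise LayoutError("no wells in layout (header only)")
    wells = []
    for _, r in df.iterrows():
        drug = r["drug"]
        drug = None if pd.isna(drug) or drug == "" else str(drug)
        conc = r["concentration"]
        conc = 0.0 if pd.isna(conc) else float(conc)
        rep = r["replicate"]
        rep = 1 if pd.isna(rep) else int(rep)
        wells.append(
            WellAssignment(
                well_id=str(r["well"]).strip(),
                culture=str(r["culture"]),
                drug=drug,
                concentration=conc,
                replicate=rep,
                role=str(r["role"]).strip(),
            )
        )
    return PlateLayout(plate_id=plate_id, wells=wells)


def write_layout(layout: PlateLayout, path: Union[str, Path]) -> Path:
    """Write a layout back to CSV such that ``parse_layout`` round-trips."""
    path = Path(path)
    layout.to_frame()[_LAYOUT_COLUMNS].to_csv(path, index=False)
    return path


@dataclass
class SegmentationParams:
    """Width-and-threshold segmentation parameters.

    Widths are physical (µm): a detected object is kept when its equivalent
    diameter (diameter of the equal-area circle) lies within
    ``[nucleus_min_width, nucleus_max_width]``; cell regions grow from nuclei
    up to ``cell_max_width``. Intensity thresholds are in raw image units;
    the nuclear threshold may be the string ``"auto"`` for a between-class
    variance (Otsu) threshold. These are assay-calibration parameters to be
    tuned per staining batch, not universal constants.
    """

    nucleus_min_width: float = 6.0
    nucleus_max_width: float = 25.0
    nuclear_intensity_threshold: Union[float, str] = "auto"
    cell_max_width: float = 30.0
    cytoplasm_thresholds: dict[str, float] = field(
        default_factory=lambda: {"epithelial": 400.0, "marker": 400.0}
    )
    split_touching: bool = True

    def __post_init__(self):
        if not (0 < self.nucleus_min_width < self.nucleus_max_width <= self.cell_max_width):
            raise ValueError(
                "require 0 < nucleus_min_width < nucleus_max_width <= cell_max_width"
            )
        if isinstance(self.nuclear_intensity_threshold, str):
            if self.nuclear_intensity_threshold != "auto":
                raise ValueError("nuclear_intensity_threshold must be a number or 'auto'")
        elif self.nuclear_intensity_threshold < 0:
            raise ValueError("thresholds must be >= 0")
        for ch, t in self.cytoplasm_thresholds.items():
            if t < 0:
                raise ValueError(f"cytoplasm threshold for {ch!r} must be >= 0")


@dataclass
class AnalysisConfig:
    """Analysis parameters for a full plate run."""

    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    channel_map: dict[str, int] = field(
        default_factory=lambda: {"nuclear": 0, "epithelial": 1, "marker": 2}
    )
    induction_threshold: float = 0.20
    alpha: float = 0.05
    induction_metric: str = "relative"  # or "absolute_points"
    intensity_statistic: str = "mean"  # or "integrated"
    marker_name: str = "ABCB1"
    pixel_size: float = 1.7  # µm/px
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.induction_threshold < 1 and self.induction_metric == "relative":
            raise ValueError("induction_threshold must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.induction_metric not in ("relative", "absolute_points"):
            raise ValueError("induction_metric must be 'relative' or 'absolute_points'")
        if self.intensity_statistic not in ("mean", "integrated"):
            raise ValueError("intensity_statistic must be 'mean' or 'integrated'")
        vals = list(self.channel_map.values())
        if len(set(self.channel_map)) != len(vals) or len(set(vals)) != len(vals):
            raise ValueError("channel_map names and indices must be distinct")
        if "nuclear" not in self.channel_map:
            raise ValueError("channel_map must include a 'nuclear' channel")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        d = dict(d)
        seg = d.pop("segmentation", {})
        if isinstance(seg, Mapping):
            seg = SegmentationParams(**seg)
        return cls(segmentation=seg, **d)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: Union[str, Path]) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    return AnalysisConfig.from_dict(data)
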