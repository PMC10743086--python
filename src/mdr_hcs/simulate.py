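"""Synthetic fluorescence plate simulator with complete ground truth.

Emulates the statistical structure of a mixed-culture high-content MDR assay:
~1000 cells seeded per 384-well, a cancer/stromal mix (e.g. 1:1 co-culture),
drug-dependent cell kill, and dose-dependent marker-positive fractions.
Survival and induction follow Hill curves:

    survival fraction  f(c) = 1 / (1 + (c / kill_ic50)^kill_hill)
    positive fraction  p(c) = p0 + (pmax - p0) * c^h / (c^h + ec50^h)

The surviving cell count per well is Poisson with mean ``n_cells_mean * f(c)``
and each survivor is independently marker-positive with probability ``p(c)``.
Rendering is deliberately simple — flat disks (nucleus) and cytoplasmic
annuli, Gaussian blur, Poisson shot noise plus additive Gaussian read noise —
so that every rendered structure has an exact ground-truth record.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from scipy.ndimage import gaussian_filter

from .plate import PlateLayout, well_to_index

__all__ = [
    "ScenarioSpec",
    "SimulationTruth",
    "CHANNELS",
    "CLASS_LABELS",
    "CONCENTRATION_PANELS",
    "survival_fraction",
    "marker_positive_fraction",
    "simulate_well_counts",
    "simulate_well",
    "simulate_plate",
    "write_well",
    "preset",
    "PRESETS",
]

CHANNELS = ("nuclear", "epithelial", "marker")

#: The four scored populations.
CLASS_LABELS = (
    "cancer_marker_pos",
    "cancer_marker_neg",
    "stromal_marker_pos",
    "stromal_marker_neg",
)

#: Five-point treatment panels (molar), as used in the validation experiments.
CONCENTRATION_PANELS: dict[str, list[float]] = {
    "vinorelbine": [100e-9, 250e-9, 500e-9, 750e-9, 1000e-9],
    "pemetrexed": [50e-6, 75e-6, 100e-6, 200e-6, 300e-6],
    "carboplatin": [10e-6, 25e-6, 50e-6, 75e-6, 100e-6],
    "cisplatin": [5e-6, 7.5e-6, 10e-6, 12.5e-6, 15e-6],
    "docetaxel": [1e-6, 2e-6, 3e-6, 4e-6, 5e-6],
    "etoposide": [10e-6, 15e-6, 20e-6, 25e-6, 30e-6],
    "gemcitabine": [10e-6, 25e-6, 50e-6, 75e-6, 100e-6],
    "paclitaxel": [1e-6, 2e-6, 3e-6, 4e-6, 5e-6],
    "gefitinib": [50e-9, 100e-9, 200e-9, 300e-9, 400e-9],
}

_POPS = ("cancer", "stromal")


def _per_pop(value, name: str) -> dict[str, float]:
    """Broadcast a scalar to the two populations, or validate a dict."""
    if isinstance(value, Mapping):
        d = {k: float(v) for k, v in value.items()}
        for p in d:
            if p not in _POPS:
                raise ValueError(f"{name}: unknown population {p!r}")
        return d
    return {p: float(value) for p in _POPS}


@dataclass
class ScenarioSpec:
    """Parameters of one simulated culture/drug scenario.

    Per-population parameters (kill, baseline/induced marker fractions) are
    dicts keyed ``"cancer"`` / ``"stromal"``; scalars broadcast to both.
    Lengths are µm; concentrations molar; intensities in 16-bit camera units.
    """

    n_cells_mean: float = 1000.0
    cancer_fraction: float = 1.0
    baseline_marker_pos: Union[float, dict] = 0.10
    kill_ic50: Union[float, dict] = 5e-6
    kill_hill: Union[float, dict] = 1.5
    induction_ec50: float = 5e-6
    induction_max: Union[float, dict] = 0.10  # = baseline -> no induction
    induction_hill: float = 1.5
    nucleus_diameter_mean: float = 12.0
    nucleus_diameter_sd: float = 1.5
    cell_diameter: float = 22.0
    intensity_pos: Union[float, dict] = field(
        default_factory=lambda: {"nuclear": 2000.0, "epithelial": 1200.0, "marker": 1200.0}
    )
    intensity_neg: Union[float, dict] = field(
        default_factory=lambda: {"nuclear": 0.0, "epithelial": 120.0, "marker": 120.0}
    )
    intensity_sigma: float = 0.15  # lognormal scale of per-cell brightness
    background: float = 100.0
    noise_sd: float = 8.0
    psf_sigma: float = 1.0  # px
    pixel_size: float = 1.7  # µm/px
    field_shape: tuple[int, int] = (2048, 2048)
    seed: int = 0

    def __post_init__(self):
        self.baseline_marker_pos = _per_pop(self.baseline_marker_pos, "baseline_marker_pos")
        self.kill_ic50 = _per_pop(self.kill_ic50, "kill_ic50")
        self.kill_hill = _per_pop(self.kill_hill, "kill_hill")
        self.induction_max = _per_pop(self.induction_max, "induction_max")
        if isinstance(self.intensity_pos, (int, float)):
            self.intensity_pos = {c: float(self.intensity_pos) for c in CHANNELS}
        if isinstance(self.intensity_neg, (int, float)):
            self.intensity_neg = {c: float(self.intensity_neg) for c in CHANNELS}
        if not 0 <= self.cancer_fraction <= 1:
            raise ValueError("cancer_fraction must be in [0, 1]")
        for p in _POPS:
            if not 0 <= self.baseline_marker_pos[p] <= 1:
                raise ValueError("baseline_marker_pos fractions must be in [0, 1]")
            if not 0 <= self.induction_max[p] <= 1:
                raise ValueError("induction_max fractions must be in [0, 1]")
            if self.induction_max[p] < self.baseline_marker_pos[p]:
                raise ValueError("induction_max must be >= baseline_marker_pos")
            if self.kill_hill[p] <= 0:
                raise ValueError("kill_hill must be > 0")
            if self.kill_ic50[p] <= 0:
                raise ValueError("kill_ic50 must be > 0")
        if self.nucleus_diameter_mean <= 0 or self.cell_diameter <= 0:
            raise ValueError("diameters must be > 0")
        if self.n_cells_mean < 0:
            raise ValueError("n_cells_mean must be >= 0")

    def replace(self, **kw) -> "ScenarioSpec":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["field_shape"] = list(self.field_shape)
        return d

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ScenarioSpec":
        data = yaml.safe_load(Path(path).read_text())
        if "field_shape" in data:
            data["field_shape"] = tuple(data["field_shape"])
        return cls(**data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))


def survival_fraction(dose: float, ic50: float, hill: float) -> float:
    """Hill survival f(c) = 1 / (1 + (c/ic50)^hill); f(0) = 1."""
    if dose <= 0:
        return 1.0
    return 1.0 / (1.0 + (dose / ic50) ** hill)


def marker_positive_fraction(
    dose: float, p0: float, pmax: float, ec50: float, hill: float
) -> float:
    """Net marker-positive probability p(c) = p0 + (pmax-p0)·c^h/(c^h+ec50^h)."""
    if dose <= 0:
        return p0
    x = dose**hill
    return p0 + (pmax - p0) * x / (x + ec50**hill)


@dataclass
class SimulationTruth:
    """Exact ground truth for one simulated well.

    ``cells`` has one row per rendered cell: centroid (row, col, px),
    nucleus_radius (px), population ∈ :data:`CLASS_LABELS`, and the
    cancer / marker_positive booleans they encode.
    """

    well_id: str
    dose: float
    cells: pd.DataFrame
    params: dict

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def class_counts(self) -> dict[str, int]:
        vc = self.cells["population"].value_counts()
        return {lab: int(vc.get(lab, 0)) for lab in CLASS_LABELS}


def simulate_well_counts(
    spec: ScenarioSpec, dose: float, rng: np.random.Generator
) -> dict[str, int]:
    """Draw the four-population cell counts for one well without rendering.

    This is the statistical layer of the simulator — identical population
    model to :func:`simulate_well`, used for Monte-Carlo studies where the
    imaging is not under test.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    counts: dict[str, int] = {}
    for pop, frac in (("cancer", spec.cancer_fraction), ("stromal", 1 - spec.cancer_fraction)):
        f = survival_fraction(dose, spec.kill_ic50[pop], spec.kill_hill[pop])
        n = rng.poisson(spec.n_cells_mean * frac * f)
        p = marker_positive_fraction(
            dose,
            spec.baseline_marker_pos[pop],
            spec.induction_max[pop],
            spec.induction_ec50,
            spec.induction_hill,
        )
        n_pos = rng.binomial(n, p) if n > 0 else 0
        counts[f"{pop}_marker_pos"] = int(n_pos)
        counts[f"{pop}_marker_neg"] = int(n - n_pos)
    return counts


def _place_hardcore(
    n: int, shape: tuple[int, int], min_dist: float, margin: float, rng: np.random.Generator
) -> np.ndarray:
    """Sequential hard-core placement: n centers, pairwise distance >= min_dist,
    at least `margin` px from every border. Raises if the field is too crowded."""
    h, w = shape
    lo_r, hi_r = margin, h - margin
    lo_c, hi_c = margin, w - margin
    if hi_r <= lo_r or hi_c <= lo_c:
        raise ValueError("field too small for the requested margin")
    pts = np.empty((n, 2))
    placed = 0
    max_tries = 200 * max(n, 1)
    tries = 0
    # coarse grid for neighbor lookup
    cell = max(min_dist, 1.0)
    grid: dict[tuple[int, int], list[int]] = {}
    while placed < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"hard-core placement failed after {max_tries} tries "
                f"({placed}/{n} placed): density too high for this field; "
                "use a larger field or fewer cells"
            )
        p = np.array([rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c)])
        gi, gj = int(p[0] // cell), int(p[1] // cell)
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for k in grid.get((gi + di, gj + dj), ()):
                    if np.hypot(*(pts[k] - p)) < min_dist:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            pts[placed] = p
            grid.setdefault((gi, gj), []).append(placed)
            placed += 1
    return pts


def _draw_disk(img: np.ndarray, center: np.ndarray, radius: float, value: float) -> None:
    """Paint max(img, value) on a disk; bounding-box local for speed."""
    r0 = max(int(np.floor(center[0] - radius)) - 1, 0)
    r1 = min(int(np.ceil(center[0] + radius)) + 2, img.shape[0])
    c0 = max(int(np.floor(center[1] - radius)) - 1, 0)
    c1 = min(int(np.ceil(center[1] + radius)) + 2, img.shape[1])
    rr, cc = np.ogrid[r0:r1, c0:c1]
    mask = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    sub = img[r0:r1, c0:c1]
    np.maximum(sub, np.where(mask, value, 0.0), out=sub)


def _draw_annulus(
    img: np.ndarray, center: np.ndarray, r_in: float, r_out: float, value: float
) -> None:
    r0 = max(int(np.floor(center[0] - r_out)) - 1, 0)
    r1 = min(int(np.ceil(center[0] + r_out)) + 2, img.shape[0])
    c0 = max(int(np.floor(center[1] - r_out)) - 1, 0)
    c1 = min(int(np.ceil(center[1] + r_out)) + 2, img.shape[1])
    rr, cc = np.ogrid[r0:r1, c0:c1]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    mask = (d2 <= r_out**2) & (d2 > r_in**2)
    sub = img[r0:r1, c0:c1]
    np.maximum(sub, np.where(mask, value, 0.0), out=sub)


def simulate_well(
    spec: ScenarioSpec,
    dose: float,
    rng: Optional[np.random.Generator] = None,
    well_id: str = "A1",
) -> tuple[np.ndarray, SimulationTruth]:
    """Simulate one well: a (3, H, W) uint16 channel stack plus ground truth.

    Channel order is nuclear, epithelial, marker. Cells are placed by a
    hard-core process (no two centers closer than 0.8 × mean nucleus
    diameter) with a one-cell-radius border margin, then rendered as flat
    disks/annuli, blurred, and corrupted with Poisson shot noise and
    additive Gaussian read noise.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    counts = simulate_well_counts(spec, dose, rng)
    labels = [lab for lab in CLASS_LABELS for _ in range(counts[lab])]
    n = len(labels)
    order = rng.permutation(n)
    labels = [labels[i] for i in order]

    px = spec.pixel_size
    min_dist = 0.8 * spec.nucleus_diameter_mean / px
    margin = spec.cell_diameter / 2 / px + 1
    centers = _place_hardcore(n, spec.field_shape, min_dist, margin, rng)
    nuc_d_um = rng.normal(spec.nucleus_diameter_mean, spec.nucleus_diameter_sd, size=n)
    nuc_d_um = np.clip(nuc_d_um, 0.3 * spec.nucleus_diameter_mean, None)
    nuc_r = nuc_d_um / 2 / px
    cell_r = np.full(n, spec.cell_diameter / 2 / px)

    imgs = {c: np.zeros(spec.field_shape, dtype=float) for c in CHANNELS}

    def brightness(mean: float) -> float:
        if mean <= 0:
            return 0.0
        return float(np.exp(rng.normal(np.log(mean), spec.intensity_sigma)))

    is_cancer = np.array([lab.startswith("cancer") for lab in labels])
    is_pos = np.array([lab.endswith("marker_pos") for lab in labels])
    for i in range(n):
        _draw_disk(imgs["nuclear"], centers[i], nuc_r[i], brightness(spec.intensity_pos["nuclear"]))
        epi_mean = spec.intensity_pos["epithelial"] if is_cancer[i] else spec.intensity_neg["epithelial"]
        _draw_annulus(imgs["epithelial"], centers[i], nuc_r[i], cell_r[i], brightness(epi_mean))
        mk_mean = spec.intensity_pos["marker"] if is_pos[i] else spec.intensity_neg["marker"]
        _draw_annulus(imgs["marker"], centers[i], nuc_r[i], cell_r[i], brightness(mk_mean))

    stack = np.empty((3,) + spec.field_shape, dtype=np.uint16)
    for ci, ch in enumerate(CHANNELS):
        im = imgs[ch]
        if spec.psf_sigma > 0:
            im = gaussian_filter(im, spec.psf_sigma)
        im = im + spec.background
        im = rng.poisson(np.clip(im, 0, None)).astype(float)
        im = im + rng.normal(0.0, spec.noise_sd, size=im.shape)
        stack[ci] = np.clip(np.round(im), 0, 65535).astype(np.uint16)

    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "row": centers[:, 0] if n else np.array([]),
            "col": centers[:, 1] if n else np.array([]),
            "nucleus_radius": nuc_r if n else np.array([]),
            "population": pd.Series(labels, dtype=str),
            "cancer": is_cancer if n else np.array([], dtype=bool),
            "marker_positive": is_pos if n else np.array([], dtype=bool),
        }
    )
    truth = SimulationTruth(
        well_id=well_id,
        dose=dose,
        cells=cells,
        params={
            "kill_ic50": dict(spec.kill_ic50),
            "kill_hill": dict(spec.kill_hill),
            "induction_ec50": spec.induction_ec50,
            "induction_max": dict(spec.induction_max),
            "baseline_marker_pos": dict(spec.baseline_marker_pos),
            "seed": spec.seed,
        },
    )
    return stack, truth


def simulate_plate(
    scenarios: Mapping,
    layout: PlateLayout,
    seed: Optional[int] = None,
) -> dict[str, tuple[np.ndarray, SimulationTruth]]:
    """Simulate every non-empty well of a plate.

    ``scenarios`` maps ``(culture, drug)`` and/or ``(culture, None)`` to a
    :class:`ScenarioSpec`; the drug-specific entry wins, the ``None`` entry
    is the fallback (used for controls). Per-well RNG streams are spawned
    deterministically from the plate seed and the well position, so any well
    can be re-simulated independently.
    """
    if seed is None:
        seed = next(iter(scenarios.values())).seed
    out: dict[str, tuple[np.ndarray, SimulationTruth]] = {}
    for w in layout.wells:
        if w.role == "empty":
            continue
        spec = scenarios.get((w.culture, w.drug)) or scenarios.get((w.culture, None))
        if spec is None:
            raise KeyError(
                f"no scenario parameters for culture {w.culture!r}, drug {w.drug!r}"
            )
        r, c = well_to_index(w.well_id)
        rng = np.random.default_rng(np.random.SeedSequence((seed, r * 24 + c)))
        out[w.well_id] = simulate_well(spec, w.concentration, rng, well_id=w.well_id)
    return out


def write_well(
    stack: np.ndarray, truth: SimulationTruth, outdir: Union[str, Path]
) -> tuple[Path, Path]:
    """Write a well as a multi-page TIFF (pages: nuclear, epithelial, marker)
    plus a truth CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tif = outdir / f"{truth.well_id}.tif"
    tifffile.imwrite(tif, stack, photometric="minisblack")
    csv = outdir / f"{truth.well_id}_truth.csv"
    truth.cells.to_csv(csv, index=False)
    return tif, csv


def _ci_imaging() -> dict:
    """Scaled-down imaging geometry for fast runs: 512×512 field, fewer cells."""
    return dict(field_shape=(512, 512), n_cells_mean=150.0)


PRESET_BUILDERS = {}


def _register(name):
    def deco(fn):
        PRESET_BUILDERS[name] = fn
        return fn

    return deco


@_register("h460")
def _h460(**kw) -> ScenarioSpec:
    """Drug-sensitive epithelial monoculture, modest baseline marker fraction."""
    base = dict(
        cancer_fraction=1.0,
        baseline_marker_pos={"cancer": 0.10, "stromal": 0.05},
        kill_ic50=5e-6,
        kill_hill=1.5,
        induction_max={"cancer": 0.10, "stromal": 0.05},
    )
    base.update(kw)
    return ScenarioSpec(**base)


@_register("h460-resistant")
def _h460r(**kw) -> ScenarioSpec:
    """Resistant variant: high baseline marker fraction, 27-fold higher kill IC50."""
    base = dict(
        cancer_fraction=1.0,
        baseline_marker_pos={"cancer": 0.85, "stromal": 0.05},
        kill_ic50=135e-6,
        kill_hill=1.5,
        induction_max={"cancer": 0.85, "stromal": 0.05},
    )
    base.update(kw)
    return ScenarioSpec(**base)


@_register("h460-coculture")
def _h460_co(**kw) -> ScenarioSpec:
    """1:1 cancer/stromal co-culture."""
    base = dict(
        cancer_fraction=0.5,
        baseline_marker_pos={"cancer": 0.10, "stromal": 0.03},
        kill_ic50={"cancer": 5e-6, "stromal": 20e-6},
        kill_hill=1.5,
        induction_max={"cancer": 0.10, "stromal": 0.03},
    )
    base.update(kw)
    return ScenarioSpec(**base)


@_register("induction")
def _induction(**kw) -> ScenarioSpec:
    """Marker induction scenario: positive fraction rises from 10% to 30%."""
    base = dict(
        cancer_fraction=1.0,
        baseline_marker_pos={"cancer": 0.10, "stromal": 0.05},
        kill_ic50=50e-6,
        kill_hill=1.0,
        induction_ec50=2e-6,
        induction_hill=2.0,
        induction_max={"cancer": 0.30, "stromal": 0.05},
    )
    base.update(kw)
    return ScenarioSpec(**base)


def preset(name: str, ci_scale: bool = True, **overrides) -> ScenarioSpec:
    """Build a named scenario preset.

    ``ci_scale=True`` (default) uses the 512×512 / 150-cell geometry suited
    to quick runs; ``ci_scale=False`` gives the full 2048×2048 field at
    ~1000 cells emulating a 4x-objective widefield image of a 384-well.
    """
    if name not in PRESET_BUILDERS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESET_BUILDERS)}")
    kw = _ci_imaging() if ci_scale else {}
    kw.update(overrides)
    return PRESET_BUILDERS[name](**kw)


PRESETS = tuple(sorted(PRESET_BUILDERS))
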