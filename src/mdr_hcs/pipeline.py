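"""End-to-end plate analysis: segmentation → scoring → dose-response →
induction calls, with a reproducibility manifest.

`analyze_plate` consumes a directory of per-well multi-page TIFFs (pages:
nuclear, epithelial, marker), a plate layout, and an analysis config, and
produces every result table. A well whose image is unreadable is skipped
with a warning and is absent from all downstream tables; a missing image
for a non-empty well is an error (listing the wells) unless
``skip_missing`` is set.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .doseresp import DoseResponseResult, fit_curve, viability
from .induction import (
    InductionResult,
    dunnett_vs_control,
    group_percentages,
    induction_call,
)
from .plate import AnalysisConfig, PlateLayout
from .scoring import WellSummary, records_to_frame, score_cells, summarize_well
from .segment import assign_cell_regions, segment_nuclei
from .tables import write_results

logger = logging.getLogger("mdr_hcs")

__all__ = ["AnalysisRun", "analyze_plate", "write_manifest"]


@dataclass
class AnalysisRun:
    """All results of one plate analysis."""

    layout: PlateLayout
    config: AnalysisConfig
    wells: dict[str, WellSummary]
    cells: pd.DataFrame
    dose_response: list[DoseResponseResult]
    induction: list[InductionResult]
    skipped_wells: list[str]
    timings: dict[str, float]

    def write(self, outdir: Union[str, Path]) -> dict[str, Path]:
        paths = write_results(
            outdir,
            dose_response=self.dose_response,
            induction=self.induction,
            cells=self.cells,
            wells=list(self.wells.values()),
        )
        paths["manifest"] = write_manifest(self, Path(outdir) / "manifest.json", paths)
        return paths


def _config_hash(config: AnalysisConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def write_manifest(run: AnalysisRun, path: Path, outputs: dict[str, Path]) -> Path:
    """Record config hash, inputs, seed, version, timings and output hashes."""
    out_hashes = {}
    for name, p in sorted(outputs.items()):
        if p.exists() and p != path:
            out_hashes[name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "tool": "mdr-hcs",
        "version": __version__,
        "config_sha256": _config_hash(run.config),
        "seed": run.config.seed,
        "plate_id": run.layout.plate_id,
        "n_wells_analyzed": len(run.wells),
        "skipped_wells": run.skipped_wells,
        "stage_timings_s": {k: round(v, 3) for k, v in run.timings.items()},
        "outputs_sha256": out_hashes,
    }
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _read_stack(path: Path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise ValueError(f"{path.name}: expected a 2-D or 3-D TIFF, got {arr.shape}")
    return arr


def analyze_plate(
    images_dir: Union[str, Path],
    layout: PlateLayout,
    config: AnalysisConfig,
    skip_missing: bool = False,
) -> AnalysisRun:
    """Run the full analysis over every non-empty well of the plate.

    Expects one ``<well>.tif`` per non-empty well in ``images_dir``.
    """
    images_dir = Path(images_dir)
    t0 = time.perf_counter()
    timings: dict[str, float] = {}

    active = [w for w in layout.wells if w.role != "empty"]
    missing = [w.well_id for w in active if not (images_dir / f"{w.well_id}.tif").exists()]
    if missing and not skip_missing:
        raise FileNotFoundError(
            f"missing images for non-empty wells: {', '.join(sorted(missing))}"
        )

    summaries: dict[str, WellSummary] = {}
    cell_frames = []
    skipped: list[str] = list(missing)
    for w in active:
        img_path = images_dir / f"{w.well_id}.tif"
        if not img_path.exists():
            continue
        try:
            stack = _read_stack(img_path)
            nuclear = stack[config.channel_map["nuclear"]]
            nuclei = segment_nuclei(nuclear, config.segmentation, config.pixel_size)
            cells_mask = assign_cell_regions(nuclei, config.segmentation, config.pixel_size)
            records = score_cells(stack, cells_mask, nuclei, config, well_id=w.well_id)
            summaries[w.well_id] = summarize_well(records, w.well_id)
            cell_frames.append(records_to_frame(records))
        except Exception as exc:
            warnings.warn(f"well {w.well_id} skipped: {exc}")
            logger.warning("well %s skipped: %s", w.well_id, exc)
            skipped.append(w.well_id)
    timings["segment_and_score"] = time.perf_counter() - t0
    logger.info("scored %d wells (%d skipped)", len(summaries), len(skipped))

    t1 = time.perf_counter()
    dr_results: list[DoseResponseResult] = []
    for culture in layout.cultures:
        ctrl_ids = [w.well_id for w in layout.controls(culture) if w.well_id in summaries]
        controls = [summaries[i] for i in ctrl_ids]
        if not controls:
            continue
        for drug in layout.drugs:
            treated = [w for w in layout.treated(culture, drug) if w.well_id in summaries]
            if not treated:
                continue
            for population in ("total", "cancer", "stromal"):
                conc, resp = [], []
                for w in treated:
                    try:
                        v = viability(summaries[w.well_id], controls, population)
                    except ValueError:
                        continue
                    conc.append(w.concentration)
                    resp.append(v)
                if len(set(conc)) < 4:
                    continue
                try:
                    dr_results.append(
                        fit_curve(conc, resp, culture=culture, drug=drug, population=population)
                    )
                except ValueError as exc:
                    logger.warning("fit failed for %s/%s/%s: %s", culture, drug, population, exc)
    timings["dose_response"] = time.perf_counter() - t1

    t2 = time.perf_counter()
    ind_results: list[InductionResult] = []
    has_marker = "marker" in config.channel_map
    if has_marker:
        rng = np.random.default_rng(config.seed)
        for culture in layout.cultures:
            for drug in layout.drugs:
                if not any(
                    w.well_id in summaries for w in layout.treated(culture, drug)
                ):
                    continue
                for population in ("cancer", "stromal"):
                    try:
                        groups = group_percentages(
                            summaries, layout, culture, drug, population
                        )
                        dn = dunnett_vs_control(groups, rng=rng)
                        ind_results.append(
                            induction_call(
                                groups,
                                dn,
                                config,
                                marker=config.marker_name,
                                culture=culture,
                                population=population,
                                drug=drug,
                            )
                        )
                    except ValueError as exc:
                        logger.warning(
                            "induction skipped for %s/%s/%s: %s",
                            culture, drug, population, exc,
                        )
    timings["induction"] = time.perf_counter() - t2
    timings["total"] = time.perf_counter() - t0

    cells = pd.concat(cell_frames, ignore_index=True) if cell_frames else records_to_frame([])
    return AnalysisRun(
        layout=layout,
        config=config,
        wells=summaries,
        cells=cells,
        dose_response=dr_results,
        induction=ind_results,
        skipped_wells=sorted(set(skipped)),
        timings=timings,
    )
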