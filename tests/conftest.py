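"""Shared fixtures: small simulated wells and plates.

Everything is generated programmatically at collection time; image-bearing
fixtures are session-scoped because rendering is the slow part.
"""

from __future__ import annotations

import numpy as np
import pytest

import mdr_hcs as m


def make_layout_csv(
    path,
    culture: str = "co",
    drug: str = "etoposide",
    concentrations=(1e-6, 2e-6, 5e-6, 1e-5, 2e-5),
    n_controls: int = 4,
    n_replicates: int = 2,
    plate_id: str = "plate",
):
    """Write a minimal one-culture, one-drug layout CSV and return its path."""
    wells = iter(f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 25))
    rows = ["well,culture,drug,concentration,replicate,role"]
    for i in range(n_controls):
        rows.append(f"{next(wells)},{culture},,0,{i + 1},control")
    for conc in concentrations:
        for rep in range(n_replicates):
            rows.append(f"{next(wells)},{culture},{drug},{conc},{rep + 1},treated")
    path.write_text("\n".join(rows) + "\n")
    return path


@pytest.fixture(scope="session")
def config():
    return m.AnalysisConfig()


@pytest.fixture(scope="session")
def ci_spec():
    """512x512 co-culture scenario (~150 cells/well), seeded."""
    return m.preset("h460-coculture", seed=7)


@pytest.fixture(scope="session")
def simulated_well(ci_spec):
    """One untreated co-culture well: (stack, truth)."""
    return m.simulate_well(ci_spec, 0.0, np.random.default_rng(11))


@pytest.fixture(scope="session")
def scored_well(simulated_well, config):
    """Segmentation + scoring of the simulated well: (records, truth)."""
    stack, truth = simulated_well
    nuclei = m.segment_nuclei(stack[0], config.segmentation, config.pixel_size)
    cells = m.assign_cell_regions(nuclei, config.segmentation, config.pixel_size)
    records = m.score_cells(stack, cells, nuclei, config, well_id=truth.well_id)
    return records, truth


@pytest.fixture(scope="session")
def mini_plate(tmp_path_factory):
    """A tiny rendered plate (256x256 wells, ~60 cells) with layout + images.

    Returns (layout, images_dir): 4 controls + 5 concentrations x 2 replicates.
    """
    root = tmp_path_factory.mktemp("mini_plate")
    layout_path = make_layout_csv(root / "layout.csv")
    layout = m.parse_layout(layout_path)
    spec = m.preset("h460-coculture", field_shape=(256, 256), n_cells_mean=60.0, seed=5)
    wells = m.simulate_plate({(c, None): spec for c in layout.cultures}, layout, seed=5)
    imgdir = root / "images"
    for well_id, (stack, truth) in wells.items():
        m.simulate.write_well(stack, truth, imgdir)
    return layout, imgdir
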