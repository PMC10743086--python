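"""Segmentation: auto-threshold, nuclei detection, cell-region growth."""

import numpy as np
import pytest
from scipy import ndimage as ndi

import mdr_hcs as m
from mdr_hcs.plate import SegmentationParams

PX = 1.0  # tests use 1 µm/px so widths are in pixels


def otsu_bruteforce(image):
    """Exhaustive between-class-variance maximization over candidate thresholds."""
    vals = np.unique(image)
    best_t, best_v = None, -1.0
    flat = image.ravel().astype(float)
    for t in vals[:-1]:
        lo, hi = flat[flat <= t], flat[flat > t]
        w0, w1 = lo.size / flat.size, hi.size / flat.size
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


def draw_disks(shape, centers, radius, value=200.0, background=10.0):
    img = np.full(shape, background)
    rr, cc = np.indices(shape)
    for r, c in centers:
        img[(rr - r) ** 2 + (cc - c) ** 2 <= radius**2] = value
    return img


class TestAutoThreshold:
    def test_bimodal_threshold_between_modes(self):
        rng = np.random.default_rng(0)
        img = np.concatenate([rng.normal(10, 1, 500), rng.normal(200, 5, 500)]).reshape(50, 20)
        t = m.auto_threshold(img)
        assert 10 < t < 200

    def test_matches_bruteforce_on_integer_image(self):
        rng = np.random.default_rng(1)
        img = np.concatenate(
            [rng.integers(5, 15, 300), rng.integers(180, 220, 300)]
        ).reshape(30, 20)
        t = m.auto_threshold(img)
        t_bf = otsu_bruteforce(img)
        assert abs(t - t_bf) <= (img.max() - img.min()) / 256 + 1  # within one bin

    def test_constant_image_is_error(self):
        with pytest.raises(ValueError):
            m.auto_threshold(np.full((10, 10), 7.0))

    def test_offset_invariance(self):
        rng = np.random.default_rng(2)
        img = np.concatenate([rng.normal(10, 1, 500), rng.normal(200, 5, 500)]).reshape(50, 20)
        t0 = m.auto_threshold(img)
        t1 = m.auto_threshold(img + 1000.0)
        assert t1 - t0 == pytest.approx(1000.0, abs=1e-6)


class TestSegmentNuclei:
    params = SegmentationParams(
        nucleus_min_width=6, nucleus_max_width=20, nuclear_intensity_threshold=100,
        cell_max_width=30,
    )

    def test_all_zero_image_no_nuclei(self):
        with pytest.warns(UserWarning):
            mask = m.segment_nuclei(np.zeros((64, 64)), self.params, PX)
        assert mask.max() == 0

    def test_fifty_disks_counted_exactly(self):
        """Non-overlapping in-gate disks at SNR ~10 are all found, nothing more."""
        rng = np.random.default_rng(4)
        centers = [(15 + 20 * (i // 10), 15 + 20 * (i % 10)) for i in range(50)]
        img = draw_disks((220, 220), centers, radius=5) + rng.normal(0, 2, (220, 220))
        mask = m.segment_nuclei(img, self.params, PX)
        assert mask.max() == 50

    def test_undersized_disk_gated_out(self):
        img = draw_disks((64, 64), [(32, 32)], radius=1.5)  # d=3 < min width 6
        mask = m.segment_nuclei(img, self.params, PX)
        assert mask.max() == 0

    def test_oversized_blob_gated_out(self):
        img = draw_disks((64, 64), [(32, 32)], radius=15, background=0)
        p = SegmentationParams(nucleus_min_width=6, nucleus_max_width=20,
                               nuclear_intensity_threshold=100, cell_max_width=30,
                               split_touching=False)
        mask = m.segment_nuclei(img, p, PX)
        assert mask.max() == 0

    def test_border_touching_excluded(self):
        img = draw_disks((64, 64), [(2, 32), (32, 32)], radius=5)
        mask = m.segment_nuclei(img, self.params, PX)
        assert mask.max() == 1

    def test_labels_consecutive(self, simulated_well, config):
        stack, _ = simulated_well
        mask = m.segment_nuclei(stack[0], config.segmentation, config.pixel_size)
        labels = np.unique(mask)
        assert np.array_equal(labels, np.arange(labels.size))

    def test_count_stable_under_rotation(self):
        rng = np.random.default_rng(5)
        centers = [(15 + 22 * i, 15 + 13 * i) for i in range(5)]
        img = draw_disks((140, 140), centers, radius=5) + rng.normal(0, 2, (140, 140))
        n0 = m.segment_nuclei(img, self.params, PX).max()
        n90 = m.segment_nuclei(np.rot90(img), self.params, PX).max()
        assert n0 == n90 == 5

    def test_detection_on_simulated_field(self, simulated_well, config):
        """Precision and recall >= 0.95 against simulator ground truth."""
        stack, truth = simulated_well
        mask = m.segment_nuclei(stack[0], config.segmentation, config.pixel_size)
        centroids = np.array(ndi.center_of_mass(mask > 0, mask, np.arange(1, mask.max() + 1)))
        from scipy.spatial import cKDTree

        tree = cKDTree(truth.cells[["row", "col"]].to_numpy())
        d, idx = tree.query(centroids)
        matched = set()
        hits = 0
        for di, ti in zip(d, idx):
            if di <= truth.cells["nucleus_radius"].iloc[ti] and ti not in matched:
                matched.add(ti)
                hits += 1
        precision = hits / len(centroids)
        recall = hits / len(truth.cells)
        assert precision >= 0.95
        assert recall >= 0.95


class TestCellRegions:
    def test_zero_growth_returns_nucleus_mask(self):
        img = draw_disks((64, 64), [(32, 32)], radius=6, background=0)
        p = SegmentationParams(nucleus_min_width=4, nucleus_max_width=14,
                               nuclear_intensity_threshold=100, cell_max_width=14)
        nuclei = m.segment_nuclei(img, p, PX)
        cells = m.assign_cell_regions(nuclei, p, PX)
        # growth radius ~ (14 - d_eq)/2 with d_eq ~ 12.6: under one pixel
        assert (cells > 0).sum() - (nuclei > 0).sum() <= np.pi * 13  # < 1px ring

    def test_isolated_nucleus_matches_dilation_oracle(self):
        img = draw_disks((96, 96), [(48, 48)], radius=6, background=0)
        p = SegmentationParams(nucleus_min_width=4, nucleus_max_width=14,
                               nuclear_intensity_threshold=100, cell_max_width=26)
        nuclei = m.segment_nuclei(img, p, PX)
        cells = m.assign_cell_regions(nuclei, p, PX)
        # brute-force: dilate the nucleus by the per-label growth radius
        from skimage.measure import regionprops

        d_eq = regionprops(nuclei)[0].equivalent_diameter_area
        r = (26 - d_eq) / 2
        dist = ndi.distance_transform_edt(nuclei == 0)
        oracle = (nuclei > 0) | (dist <= r)
        assert np.array_equal(cells > 0, oracle)

    def test_two_nuclei_partition_at_equidistant_boundary(self):
        img = draw_disks((80, 80), [(40, 30), (40, 50)], radius=5, background=0)
        p = SegmentationParams(nucleus_min_width=4, nucleus_max_width=14,
                               nuclear_intensity_threshold=100, cell_max_width=40)
        nuclei = m.segment_nuclei(img, p, PX)
        assert nuclei.max() == 2
        cells = m.assign_cell_regions(nuclei, p, PX)
        # brute-force nearest-nucleus assignment oracle on the contested band
        pts1 = np.argwhere(nuclei == 1)
        pts2 = np.argwhere(nuclei == 2)
        for rr, cc in np.argwhere(cells > 0):
            d1 = np.min(np.hypot(*(pts1 - (rr, cc)).T))
            d2 = np.min(np.hypot(*(pts2 - (rr, cc)).T))
            if abs(d1 - d2) > 1e-9:
                assert cells[rr, cc] == (1 if d1 < d2 else 2)

    def test_regions_disjoint_and_contain_nucleus(self, simulated_well, config):
        stack, _ = simulated_well
        nuclei = m.segment_nuclei(stack[0], config.segmentation, config.pixel_size)
        cells = m.assign_cell_regions(nuclei, config.segmentation, config.pixel_size)
        inside = nuclei > 0
        assert np.array_equal(cells[inside], nuclei[inside])
        assert set(np.unique(cells)) == set(np.unique(nuclei))
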