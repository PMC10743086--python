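"""Nuclei detection and cell-region assignment.

The segmentation mirrors the width-and-threshold parameterization of
commercial cell-scoring protocols: a global intensity threshold on the
nuclear channel (absolute, or automatic between-class-variance), hole
filling, optional watershed splitting of touching nuclei, and a size gate
on the equivalent diameter expressed in physical units (µm). Cell regions
are grown from each nucleus by nearest-nucleus expansion bounded by the
maximum whole-cell width. Nuclei touching the image border are discarded
because their intensity statistics are truncated. Fully overlapped nuclei
are not resolved and appear as a single object.
"""

from __future__ import annotations

import warnings
from typing import Union

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.segmentation import clear_border, relabel_sequential, watershed

from .plate import SegmentationParams

__all__ = ["auto_threshold", "segment_nuclei", "assign_cell_regions"]


def auto_threshold(image: np.ndarray) -> float:
    """Between-class-variance-maximizing (Otsu) global threshold.

    Deterministic; raises ``ValueError`` on a constant image, where no
    threshold separates anything.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if np.ptp(image) == 0:
        raise ValueError("constant image has no threshold")
    return float(threshold_otsu(image))


def segment_nuclei(
    nuclear_image: np.ndarray,
    params: SegmentationParams,
    pixel_size: float,
) -> np.ndarray:
    """Detect nuclei in the nuclear channel.

    Parameters
    ----------
    nuclear_image : 2-D array
        Raw nuclear-stain intensities.
    params : SegmentationParams
        Width gates (µm) and intensity threshold (absolute or ``"auto"``).
    pixel_size : float
        µm per pixel; converts the width gates to pixels.

    Returns
    -------
    2-D int array
        Label mask, 0 = background, labels consecutive ``1..K``. Objects
        outside the ``[nucleus_min_width, nucleus_max_width]`` equivalent-
        diameter window and objects touching the border are removed.
    """
    img = np.asarray(nuclear_image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("nuclear image must be a non-empty 2-D array")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")

    if np.ptp(img) == 0:
        warnings.warn("constant (possibly saturated) nuclear image: no nuclei detected")
        return np.zeros(img.shape, dtype=np.int32)

    thr = params.nuclear_intensity_threshold
    if isinstance(thr, str):  # "auto"
        thr = auto_threshold(img)
    binary = img > thr
    binary = ndi.binary_fill_holes(binary)
    if not binary.any():
        return np.zeros(img.shape, dtype=np.int32)

    if params.split_touching:
        distance = ndi.distance_transform_edt(binary)
        min_sep = max(int(round(0.5 * params.nucleus_min_width / pixel_size)), 1)
        coords = peak_local_max(
            distance, min_distance=min_sep, labels=binary, exclude_border=False
        )
        markers = np.zeros(img.shape, dtype=np.int32)
        markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
        markers, _ = ndi.label(markers > 0)
        labels = watershed(-distance, markers, mask=binary)
    else:
        labels = sk_label(binary, connectivity=1)

    labels = clear_border(labels)

    lo = params.nucleus_min_width / pixel_size
    hi = params.nucleus_max_width / pixel_size
    keep = np.zeros(labels.max() + 1, dtype=bool)
    for rp in regionprops(labels):
        if lo <= rp.equivalent_diameter_area <= hi:
            keep[rp.label] = True
    labels = np.where(keep[labels], labels, 0)
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def assign_cell_regions(
    nuclei: np.ndarray,
    params: SegmentationParams,
    pixel_size: float,
) -> np.ndarray:
    """Grow each nucleus into a cell region by nearest-nucleus expansion.

    Every background pixel is assigned to its nearest nucleus (Euclidean
    distance to the nearest nucleus pixel), provided that distance does not
    exceed the per-nucleus growth radius ``(cell_max_width - d_eq) / 2``,
    where ``d_eq`` is the nucleus' equivalent diameter — so a circular cell
    region's equivalent diameter never exceeds ``cell_max_width``. Regions
    are disjoint, partition shared zones at the equidistant boundary, and
    always contain their own nucleus.
    """
    nuclei = np.asarray(nuclei)
    if nuclei.ndim != 2:
        raise ValueError("nuclei mask must be 2-D")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    n_labels = int(nuclei.max())
    if n_labels == 0:
        return np.zeros_like(nuclei, dtype=np.int32)

    # per-label growth radius in px
    grow = np.zeros(n_labels + 1, dtype=float)
    cell_max_px = params.cell_max_width / pixel_size
    for rp in regionprops(nuclei):
        grow[rp.label] = max(0.0, (cell_max_px - rp.equivalent_diameter_area) / 2.0)

    background = nuclei == 0
    dist, (inds_r, inds_c) = ndi.distance_transform_edt(background, return_indices=True)
    nearest = nuclei[inds_r, inds_c]
    cells = np.where(dist <= grow[nearest], nearest, 0)
    cells[~background] = nuclei[~background]
    return cells.astype(np.int32)
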