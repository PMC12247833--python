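"""Per-cell label images: ingestion, a built-in blob segmenter, radial
expansion of nuclei into whole-cell masks, and nuclear-area filtering.

Nuclei segmentation proper is treated as an exchangeable input: label images
from any external segmenter (e.g. a star-convex deep model run elsewhere)
are ingested as-is, while :func:`segment_nuclei_builtin` provides a simple
smoothed-threshold-watershed segmenter adequate for synthetic disk nuclei.

Whole-cell masks are built by expanding each nucleus radially by a fixed
distance (default 5 µm), with the expansion partitioned between neighbours
by nearest-nucleus assignment (Euclidean, pixel-center metric; ties go to
the lower label id) so that cells never overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

__all__ = [
    "CellGeometry",
    "ingest_labels",
    "segment_nuclei_builtin",
    "expand_cells",
    "filter_by_area",
    "geometries_from_labels",
]


@dataclass
class CellGeometry:
    """Pixel sets and derived geometry of a single cell.

    ``nucleus_pixels`` and ``cell_pixels`` are ``(k, 2)`` integer arrays of
    0-based (row, col) coordinates; ``nucleus_pixels`` is always a subset of
    ``cell_pixels`` and cytoplasm is their set difference (possibly empty).
    The centroid is the mean of nucleus pixel centers, reported in µm with
    ``x = col * pixel_size`` and ``y = row * pixel_size``.
    """

    cell_id: int
    nucleus_pixels: np.ndarray
    cell_pixels: np.ndarray
    nucleus_area_um2: float
    centroid_um: tuple[float, float]

    @property
    def cytoplasm_pixels(self) -> np.ndarray:
        nuc = set(map(tuple, self.nucleus_pixels))
        return np.array(
            [p for p in self.cell_pixels if tuple(p) not in nuc], dtype=int
        ).reshape(-1, 2)


def _check_label_image(label_image: np.ndarray) -> np.ndarray:
    label_image = np.asarray(label_image)
    if not np.issubdtype(label_image.dtype, np.integer):
        if not np.all(label_image == np.round(label_image)):
            raise ValueError("label image must contain integers")
        label_image = label_image.astype(np.int64)
    if label_image.min() < 0:
        raise ValueError("label image must be non-negative (background = 0)")
    return label_image


def ingest_labels(
    label_image: np.ndarray, pixel_size_um: float
) -> list[CellGeometry]:
    """Turn an external nuclei label image into :class:`CellGeometry` records.

    One record per distinct positive label, ids preserved; areas converted to
    µm² via ``pixel_size_um ** 2``. ``cell_pixels`` starts equal to the
    nucleus (no expansion applied yet).
    """
    label_image = _check_label_image(label_image)
    out: list[CellGeometry] = []
    for cell_id in np.unique(label_image):
        if cell_id == 0:
            continue
        pix = np.argwhere(label_image == cell_id)
        centroid_rc = pix.mean(axis=0)
        out.append(
            CellGeometry(
                cell_id=int(cell_id),
                nucleus_pixels=pix,
                cell_pixels=pix,
                nucleus_area_um2=len(pix) * pixel_size_um**2,
                centroid_um=(
                    float(centroid_rc[1] * pixel_size_um),
                    float(centroid_rc[0] * pixel_size_um),
                ),
            )
        )
    return out


def segment_nuclei_builtin(
    dapi: np.ndarray,
    pixel_size_um: float,
    smooth_sigma_um: float = 1.0,
    min_distance_um: float = 4.0,
    threshold: float | None = None,
) -> np.ndarray:
    """Simple deterministic nuclei segmenter for synthetic images.

    Gaussian-smooths the nuclear channel, thresholds it (Otsu unless an
    explicit threshold is given), and splits touching nuclei by watershed on
    the distance transform seeded at local maxima at least
    ``min_distance_um`` apart.
    """
    dapi = np.asarray(dapi, dtype=float)
    if dapi.ndim != 2:
        raise ValueError("expected a 2D nuclear-channel image")
    smoothed = ndimage.gaussian_filter(dapi, smooth_sigma_um / pixel_size_um)
    if threshold is None:
        if smoothed.max() == smoothed.min():
            return np.zeros(dapi.shape, dtype=np.int32)
        threshold = threshold_otsu(smoothed)
    fg = smoothed > threshold
    if not fg.any():
        return np.zeros(dapi.shape, dtype=np.int32)
    dist = ndimage.distance_transform_edt(fg)
    min_dist_px = max(int(round(min_distance_um / pixel_size_um)), 1)
    peaks = peak_local_max(dist, min_distance=min_dist_px, labels=fg)
    markers = np.zeros(dapi.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    labels = watershed(-dist, markers, mask=fg)
    return labels.astype(np.int32)


def expand_cells(
    nuclei_labels: np.ndarray, radius_um: float, pixel_size_um: float
) -> np.ndarray:
    """Radially expand every nucleus by ``radius_um`` into a whole-cell label
    image.

    Each background pixel within ``radius_um`` (pixel-center Euclidean
    distance) of at least one nucleus is assigned to its nearest nucleus;
    exact ties go to the lower label id. Nucleus pixels keep their labels, so
    expansion is monotone in radius and cells never overlap.
    """
    if radius_um < 0:
        raise ValueError("expansion radius must be >= 0")
    nuclei_labels = _check_label_image(nuclei_labels)
    out = nuclei_labels.astype(np.int32).copy()
    ids = np.unique(nuclei_labels)
    ids = ids[ids > 0]
    if radius_um == 0 or len(ids) == 0:
        return out
    radius_px = radius_um / pixel_size_um
    best_dist = np.full(nuclei_labels.shape, np.inf)
    best_label = np.zeros(nuclei_labels.shape, dtype=np.int32)
    # Per-label EDT with a strict-< update, iterating ids in ascending order,
    # reproduces brute-force nearest-nucleus assignment with lower-id ties.
    for cell_id in ids:
        d = ndimage.distance_transform_edt(nuclei_labels != cell_id)
        closer = d < best_dist
        best_dist[closer] = d[closer]
        best_label[closer] = cell_id
    grow = (nuclei_labels == 0) & (best_dist <= radius_px)
    out[grow] = best_label[grow]
    return out


def geometries_from_labels(
    nuclei_labels: np.ndarray, cell_labels: np.ndarray, pixel_size_um: float
) -> list[CellGeometry]:
    """Combine a nuclei label image and its expanded cell label image."""
    nuclei_labels = _check_label_image(nuclei_labels)
    cell_labels = _check_label_image(cell_labels)
    out = []
    for geom in ingest_labels(nuclei_labels, pixel_size_um):
        cell_pix = np.argwhere(cell_labels == geom.cell_id)
        geom.cell_pixels = cell_pix
        out.append(geom)
    return out


def filter_by_area(
    cells: list[CellGeometry], low_pct: float = 5.0, high_pct: float = 99.0
) -> tuple[list[CellGeometry], list[CellGeometry]]:
    """Discard likely artifacts by per-image nuclear-area percentiles.

    Cells with nuclear area *strictly* below the ``low_pct`` percentile or
    *strictly* above the ``high_pct`` percentile of this image's area
    distribution are discarded (percentiles by linear interpolation between
    order statistics, so exact-percentile areas are kept). Returns
    ``(kept, discarded)`` with ``kept + discarded`` a partition of the input.
    """
    if not cells:
        raise ValueError("filter_by_area needs at least one cell")
    if not 0 <= low_pct < high_pct <= 100:
        raise ValueError("need 0 <= low_pct < high_pct <= 100")
    areas = np.array([c.nucleus_area_um2 for c in cells])
    lo = np.percentile(areas, low_pct)
    hi = np.percentile(areas, high_pct)
    kept = [c for c in cells if lo <= c.nucleus_area_um2 <= hi]
    discarded = [c for c in cells if not (lo <= c.nucleus_area_um2 <= hi)]
    return kept, discarded
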