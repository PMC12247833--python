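"""Stromal-region model and signed distances to the stromal border.

The stromal compartment is delineated from a matrix-protein channel
(fibronectin-like): the channel is Gaussian-smoothed, pixels strictly above
an intensity threshold form the stromal mask, and the mask's border — mask
pixels with at least one non-mask 4-neighbor; the image edge itself never
counts as border — is the zero reference for all signed distances. A cell's
signed distance is the Euclidean distance from its nuclear centroid to the
nearest border pixel center, negative when the centroid's containing pixel
lies inside the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import tifffile
from scipy import ndimage
from scipy.spatial import cKDTree
from shapely.geometry import mapping
from skimage import measure
from shapely.geometry import Polygon

__all__ = ["StromalModel", "build_stromal_model", "signed_distance"]


@dataclass
class StromalModel:
    """Binary stromal mask with border geometry and a signed distance map."""

    sigma_um: float
    intensity_threshold: float
    pixel_size_um: float
    mask: np.ndarray                       # bool, True = stromal
    border: np.ndarray                     # (k, 2) border pixel (row, col)
    signed_distance_map: np.ndarray        # µm; +inf sentinel when no border
    _tree: cKDTree | None = field(default=None, repr=False)

    @property
    def has_border(self) -> bool:
        return len(self.border) > 0

    def border_tree(self) -> cKDTree:
        if self._tree is None:
            if not self.has_border:
                raise ValueError("stromal mask has no border")
            self._tree = cKDTree(self.border.astype(float) * self.pixel_size_um)
        return self._tree

    # ------------------------------------------------------------------ I/O
    def write_mask_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(Path(path), self.mask.astype(np.uint8) * 255)

    def border_polygons(self) -> list[Polygon]:
        """Border as sub-pixel iso-contours of the mask, in µm coordinates."""
        polys = []
        for contour in measure.find_contours(self.mask.astype(float), 0.5):
            if len(contour) < 3:
                continue
            xy = contour[:, ::-1] * self.pixel_size_um  # (x, y)
            poly = Polygon(xy)
            if poly.is_valid and poly.area > 0:
                polys.append(poly)
        return polys

    def write_border_geojson(self, path: str | Path) -> None:
        features = [
            {"type": "Feature", "properties": {}, "geometry": mapping(p)}
            for p in self.border_polygons()
        ]
        Path(path).write_text(
            json.dumps({"type": "FeatureCollection", "features": features})
        )


def _border_pixels(mask: np.ndarray) -> np.ndarray:
    # border_value=1 treats out-of-image as stromal, so the image edge alone
    # never produces border pixels.
    interior = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1), border_value=1
    )
    return np.argwhere(mask & ~interior)


def build_stromal_model(
    fn_channel: np.ndarray,
    sigma_um: float,
    threshold: float,
    pixel_size_um: float,
) -> StromalModel:
    """Smooth the matrix channel, threshold it, and derive border + distances.

    ``sigma_um = 0`` means no smoothing. The mask is
    ``gaussian(channel, sigma_um / pixel_size) > threshold`` (strict). The
    signed distance map holds, per pixel, the distance of its center to the
    nearest border pixel center (µm), negative inside the mask; if the mask
    has no border (empty or full image) the map is the ``+inf`` sentinel.
    """
    fn_channel = np.asarray(fn_channel, dtype=float)
    if fn_channel.ndim != 2:
        raise ValueError("expected a 2D matrix-channel image")
    if sigma_um < 0:
        raise ValueError("sigma_um must be >= 0")
    if sigma_um > 0:
        smoothed = ndimage.gaussian_filter(fn_channel, sigma_um / pixel_size_um)
    else:
        smoothed = fn_channel
    mask = smoothed > threshold
    border = _border_pixels(mask)
    if len(border) == 0:
        dist_map = np.full(mask.shape, np.inf)
    else:
        on_border = np.zeros(mask.shape, dtype=bool)
        on_border[border[:, 0], border[:, 1]] = True
        dist_map = ndimage.distance_transform_edt(~on_border) * pixel_size_um
        dist_map[mask] *= -1.0
    return StromalModel(
        sigma_um=float(sigma_um),
        intensity_threshold=float(threshold),
        pixel_size_um=float(pixel_size_um),
        mask=mask,
        border=border,
        signed_distance_map=dist_map,
    )


def signed_distance(model: StromalModel, points_um: np.ndarray) -> np.ndarray:
    """Signed distances (µm) of continuous points to the stromal border.

    ``points_um`` is ``(n, 2)`` of (x, y) µm. The magnitude is the exact
    minimum Euclidean distance to any border pixel center; the sign comes
    from the stromal-mask membership of each point's containing pixel
    (nearest pixel center). Raises if the model has no border.
    """
    if not model.has_border:
        raise ValueError(
            "stromal mask has no border (all-stroma or no-stroma image); "
            "signed distances are undefined"
        )
    points_um = np.atleast_2d(np.asarray(points_um, dtype=float))
    if points_um.shape[1] != 2:
        raise ValueError("points_um must be (n, 2) of (x, y)")
    # KDTree holds border pixel centers in (row, col) µm; convert (x, y).
    pts_rc = points_um[:, ::-1]
    d, _ = model.border_tree().query(pts_rc)
    px = model.pixel_size_um
    rows = np.clip(
        np.round(pts_rc[:, 0] / px).astype(int), 0, model.mask.shape[0] - 1
    )
    cols = np.clip(
        np.round(pts_rc[:, 1] / px).astype(int), 0, model.mask.shape[1] - 1
    )
    inside = model.mask[rows, cols]
    return np.where(inside, -d, d)
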