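"""Synthetic multiplexed-tissue generator with exact ground truth.

Generates four co-registered channels — DAPI (nuclei), KER (epithelial /
cancer marker), FN (fibronectin-like stromal matrix) and MARKER (the analysis
marker) — together with the nuclei label image, true cell classes, the true
stromal mask and the true signed distance of every cell to the stromal
border. Per-cell marker means follow a configurable distance law and per-cell
intensities are drawn log-normally around those means, giving the
right-skewed intensity histograms typical of fluorescence data; a per-image
affine ``batch_shift`` emulates between-image staining variation.

Everything is a pure function of ``(spec, seed)``: one seeded
``numpy.random.Generator`` drives all randomness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .core import ChannelStack

__all__ = [
    "MarkerGradient",
    "BatchShift",
    "TissueSpec",
    "TissueGroundTruth",
    "generate_tissue",
]

GRADIENT_LAWS = ("exponential_decay", "monotone_increase", "flat")


@dataclass
class MarkerGradient:
    """Distance law for the noiseless per-cell MARKER mean.

    With signed distance ``d`` (µm, negative inside stroma) and
    ``u = max(d, 0)``:

    - ``exponential_decay``:  ``baseline + amplitude * exp(-u / length_scale_um)``
    - ``monotone_increase``:  ``baseline + amplitude * (1 - exp(-u / length_scale_um))``
    - ``flat``:               ``baseline``
    """

    law: str = "exponential_decay"
    amplitude: float = 100.0
    length_scale_um: float = 50.0
    baseline: float = 20.0

    def __post_init__(self) -> None:
        if self.law not in GRADIENT_LAWS:
            raise ValueError(f"law must be one of {GRADIENT_LAWS}, got {self.law!r}")
        if self.amplitude <= 0 or self.length_scale_um <= 0 or self.baseline < 0:
            raise ValueError("amplitude/length_scale must be > 0, baseline >= 0")

    def mean_at(self, d_um: np.ndarray) -> np.ndarray:
        u = np.maximum(np.asarray(d_um, dtype=float), 0.0)
        if self.law == "flat":
            return np.full_like(u, self.baseline)
        decay = np.exp(-u / self.length_scale_um)
        if self.law == "exponential_decay":
            return self.baseline + self.amplitude * decay
        return self.baseline + self.amplitude * (1.0 - decay)


@dataclass
class BatchShift:
    """Affine intensity transform ``I -> scale * I + offset`` applied to all
    generated channels, emulating between-image staining/acquisition shifts."""

    scale: float = 1.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("batch scale must be positive")

    def apply(self, image: np.ndarray) -> np.ndarray:
        return self.scale * image + self.offset


@dataclass
class TissueSpec:
    """Parameters of one synthetic tissue field.

    Defaults describe a desk-scale field: 512 × 512 px at 1 µm/px so that a
    −100…+300 µm distance range fits in one image; the grid can be refined to
    microscope pitch (e.g. 0.3215 µm/px) by setting ``pixel_size_um``.
    """

    image_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 1.0
    n_cells: int = 300
    nucleus_radius_um: tuple[float, float] = (3.5, 0.5)  # (mean, SD)
    stroma_fraction: float = 0.3
    marker_gradient: MarkerGradient = field(default_factory=MarkerGradient)
    batch_shift: BatchShift = field(default_factory=BatchShift)
    noise_sd: float = 2.0
    seed: int = 0
    # Composition of the cell population.
    cancer_fraction: float = 0.7         # fraction of cells that are KER-high
    contamination_rate: float = 0.02     # cancer cells allowed inside stroma
    marker_positive_fraction: float = 0.3
    marker_positive_boost: float = 3.0   # multiplicative mean boost for positives
    intensity_cv: float = 0.4            # sigma of the per-cell log-normal draw
    stroma_mode: str = "noise"           # "noise" (random field) or "simple" (half-plane)
    stroma_smoothness_um: float = 40.0   # correlation length of the random field

    def __post_init__(self) -> None:
        if isinstance(self.marker_gradient, dict):
            self.marker_gradient = MarkerGradient(**self.marker_gradient)
        if isinstance(self.batch_shift, dict):
            self.batch_shift = BatchShift(**self.batch_shift)
        h, w = self.image_size_px
        if h <= 0 or w <= 0 or self.pixel_size_um <= 0 or self.n_cells <= 0:
            raise ValueError("image size, pixel size and n_cells must be positive")
        mean_r, sd_r = self.nucleus_radius_um
        if mean_r <= 0 or sd_r < 0:
            raise ValueError("nucleus radius mean must be > 0 and SD >= 0")
        if not 0 < self.stroma_fraction < 1:
            raise ValueError("stroma_fraction must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.stroma_mode not in ("noise", "simple"):
            raise ValueError("stroma_mode must be 'noise' or 'simple'")


@dataclass
class TissueGroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    nuclei_label_image: np.ndarray          # int32, background 0, labels 1..n
    cell_centroids_um: np.ndarray           # (n, 2) array of (x, y) µm
    is_cancer: np.ndarray                   # (n,) bool
    is_marker_positive: np.ndarray          # (n,) bool
    stromal_mask: np.ndarray                # bool image, True = stromal
    true_signed_distance_um: np.ndarray     # (n,) µm, negative inside stroma
    noiseless_means: dict[str, np.ndarray]  # channel -> (n,) pre-batch-shift means

    @property
    def n_cells(self) -> int:
        return len(self.cell_centroids_um)

    def write(self, directory: str | Path, stem: str = "ground_truth") -> None:
        """Write the label image as 16-bit TIFF and the rest as JSON."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(
            directory / f"{stem}_labels.tif",
            self.nuclei_label_image.astype(np.uint16),
        )
        tifffile.imwrite(
            directory / f"{stem}_stroma_mask.tif",
            self.stromal_mask.astype(np.uint8) * 255,
        )
        payload = {
            "cell_centroids_um": self.cell_centroids_um.tolist(),
            "is_cancer": self.is_cancer.tolist(),
            "is_marker_positive": self.is_marker_positive.tolist(),
            "true_signed_distance_um": self.true_signed_distance_um.tolist(),
            "noiseless_means": {k: v.tolist() for k, v in self.noiseless_means.items()},
        }
        (directory / f"{stem}.json").write_text(json.dumps(payload))


# --------------------------------------------------------------------------
# internals
# --------------------------------------------------------------------------

def _stromal_mask(spec: TissueSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.image_size_px
    if spec.stroma_mode == "simple":
        # Half-plane: left `stroma_fraction` of the columns is stromal.
        split = int(round(w * spec.stroma_fraction))
        mask = np.zeros((h, w), dtype=bool)
        mask[:, :split] = True
        return mask
    # Thresholded smoothed noise gives contiguous, curvy regions; thresholding
    # at the empirical quantile pins the areal fraction.
    field_ = rng.standard_normal((h, w))
    sigma_px = spec.stroma_smoothness_um / spec.pixel_size_um
    field_ = ndimage.gaussian_filter(field_, sigma_px)
    thr = np.quantile(field_, 1.0 - spec.stroma_fraction)
    return field_ >= thr


def _border_pixels(mask: np.ndarray) -> np.ndarray:
    """Mask pixels with >= 1 non-mask 4-neighbor; the image edge itself does
    not create border (same rule as the stroma module)."""
    interior = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1), border_value=1
    )
    return np.argwhere(mask & ~interior)  # (k, 2) of (row, col)


def _signed_distance_bruteforce(
    mask: np.ndarray, points_rc_um: np.ndarray, pixel_size_um: float
) -> np.ndarray:
    """Signed distance of continuous points to the nearest border pixel
    center, by explicit minimisation (independent of the stroma module)."""
    border = _border_pixels(mask).astype(float) * pixel_size_um  # centers, µm
    if len(border) == 0:
        return np.full(len(points_rc_um), np.inf)
    d = np.sqrt(
        ((points_rc_um[:, None, :] - border[None, :, :]) ** 2).sum(axis=2)
    ).min(axis=1)
    rows = np.clip(np.round(points_rc_um[:, 0] / pixel_size_um).astype(int), 0, mask.shape[0] - 1)
    cols = np.clip(np.round(points_rc_um[:, 1] / pixel_size_um).astype(int), 0, mask.shape[1] - 1)
    inside = mask[rows, cols]
    return np.where(inside, -d, d)


def _place_cells(
    spec: TissueSpec, mask: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rejection-sample non-overlapping nuclei; returns (centers_rc_px,
    radii_px, is_cancer). Cancer cells avoid the stromal mask except at the
    contamination rate."""
    h, w = spec.image_size_px
    mean_r, sd_r = spec.nucleus_radius_um
    n = spec.n_cells
    n_cancer = int(round(spec.cancer_fraction * n))
    is_cancer = np.zeros(n, dtype=bool)
    is_cancer[:n_cancer] = True

    radii_px = np.maximum(
        rng.normal(mean_r, sd_r, size=n) / spec.pixel_size_um, 1.0
    )
    margin = radii_px + 1.0
    centers = np.empty((n, 2))
    max_attempts = 2000 * n
    attempts = 0
    placed = 0
    while placed < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} non-overlapping nuclei of mean radius "
                f"{mean_r} µm in a {h}x{w} px field after {max_attempts} "
                "attempts; reduce n_cells or the nucleus radius (density limit)"
            )
        attempts += 1
        r = radii_px[placed]
        p = rng.uniform([r, r], [h - 1 - r, w - 1 - r])
        if is_cancer[placed] and rng.uniform() >= spec.contamination_rate:
            pr, pc = int(round(p[0])), int(round(p[1]))
            if mask[pr, pc]:
                continue
        if placed:
            prev = centers[:placed]
            min_sep = radii_px[:placed] + r + 1.0
            if np.any(((prev - p) ** 2).sum(axis=1) < min_sep**2):
                continue
        centers[placed] = p
        placed += 1
    return centers, radii_px, is_cancer


def _paint_disks(
    shape: tuple[int, int],
    centers: np.ndarray,
    radii: np.ndarray,
    values: np.ndarray,
    gaussian_profile: bool = False,
) -> np.ndarray:
    """Paint per-cell disks of given per-cell value onto a zero image."""
    img = np.zeros(shape)
    for (cr, cc), r, v in zip(centers, radii, values):
        r0, r1 = int(np.floor(cr - r)), int(np.ceil(cr + r)) + 1
        c0, c1 = int(np.floor(cc - r)), int(np.ceil(cc + r)) + 1
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, shape[0]), min(c1, shape[1])
        rr, cc_ = np.mgrid[r0:r1, c0:c1]
        rho2 = (rr - cr) ** 2 + (cc_ - cc) ** 2
        inside = rho2 <= r**2
        if gaussian_profile:
            patch = v * np.exp(-rho2 / (2 * (r / 2) ** 2)) * inside
        else:
            patch = v * inside
        np.maximum(img[r0:r1, c0:c1], patch, out=img[r0:r1, c0:c1])
    return img


def _label_disks(
    shape: tuple[int, int], centers: np.ndarray, radii: np.ndarray
) -> np.ndarray:
    labels = np.zeros(shape, dtype=np.int32)
    for i, ((cr, cc), r) in enumerate(zip(centers, radii), start=1):
        r0, r1 = max(int(np.floor(cr - r)), 0), min(int(np.ceil(cr + r)) + 1, shape[0])
        c0, c1 = max(int(np.floor(cc - r)), 0), min(int(np.ceil(cc + r)) + 1, shape[1])
        rr, cc_ = np.mgrid[r0:r1, c0:c1]
        inside = (rr - cr) ** 2 + (cc_ - cc) ** 2 <= r**2
        labels[r0:r1, c0:c1][inside] = i
    return labels


# --------------------------------------------------------------------------
# public API
# --------------------------------------------------------------------------

def generate_tissue(spec: TissueSpec) -> tuple[ChannelStack, TissueGroundTruth]:
    """Generate one synthetic field and its ground truth.

    Returns a four-channel :class:`~stromapy.core.ChannelStack`
    (DAPI, KER, FN, MARKER) and a :class:`TissueGroundTruth`. Identical
    ``spec`` (including ``seed``) gives bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size_px
    px = spec.pixel_size_um

    mask = _stromal_mask(spec, rng)
    centers, radii_px, is_cancer = _place_cells(spec, mask, rng)
    labels = _label_disks((h, w), centers, radii_px)

    centroids_um = centers[:, ::-1] * px  # (x, y) = (col, row) * px
    d_true = _signed_distance_bruteforce(mask, centers * px, px)

    is_positive = rng.uniform(size=spec.n_cells) < spec.marker_positive_fraction

    # Noiseless channel means per cell (pre batch shift).
    marker_mean = spec.marker_gradient.mean_at(d_true)
    marker_mean = np.where(
        is_positive, marker_mean * spec.marker_positive_boost, marker_mean
    )
    ker_mean = np.where(is_cancer, 150.0, 15.0)
    dapi_mean = np.full(spec.n_cells, 200.0)
    noiseless = {"DAPI": dapi_mean, "KER": ker_mean, "MARKER": marker_mean}

    # Per-cell realised means: log-normal around the noiseless mean with unit
    # expectation (right-skewed per-cell histograms).
    s = spec.intensity_cv

    def draw(means: np.ndarray) -> np.ndarray:
        if s == 0:
            return means.copy()
        return means * rng.lognormal(-0.5 * s * s, s, size=len(means))

    dapi_cell = draw(dapi_mean)
    ker_cell = draw(ker_mean)
    marker_cell = draw(marker_mean)

    cyto_radii = radii_px + 2.0 / px  # marker/KER extend ~2 µm past the nucleus
    dapi = _paint_disks((h, w), centers, radii_px, dapi_cell, gaussian_profile=True)
    ker = _paint_disks((h, w), centers, cyto_radii, ker_cell) + 5.0
    marker = _paint_disks((h, w), centers, cyto_radii, marker_cell) + 5.0
    fn = np.where(mask, 120.0, 10.0)
    fn = ndimage.gaussian_filter(fn, 2.0)

    channels = {}
    for name, img in (("DAPI", dapi), ("KER", ker), ("FN", fn), ("MARKER", marker)):
        img = spec.batch_shift.apply(img)
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        channels[name] = np.maximum(img, 0.0)

    stack = ChannelStack(channels=channels, pixel_size_um=px, image_id=f"synthetic-{spec.seed}")
    truth = TissueGroundTruth(
        nuclei_label_image=labels,
        cell_centroids_um=centroids_um,
        is_cancer=is_cancer,
        is_marker_positive=is_positive,
        stromal_mask=mask,
        true_signed_distance_um=d_true,
        noiseless_means=noiseless,
    )
    return stack, truth
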