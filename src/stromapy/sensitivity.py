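"""Sensitivity of spatial conclusions to the stromal-model parameters.

The stromal mask depends on two tunables — the Gaussian smoothing sigma and
the matrix-channel intensity threshold. This module grid-searches both; at
every grid point it rebuilds the stromal model, recomputes each cell's signed
distance, and summarises the intensity–distance relationship with the Pearson
correlation r between marker intensity I and signed distance d, separately
for cells inside (d < 0) and outside (d >= 0) the stroma. Inside/outside r
values from the same image are paired measurements and are compared with a
two-sided Wilcoxon signed-rank test (exact by enumeration for small n);
means and standard errors of r are estimated by bootstrap across images.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import ChannelStack
from .stroma import build_stromal_model, signed_distance

logger = logging.getLogger(__name__)

__all__ = [
    "SensitivityResult",
    "pearson_r",
    "paired_wilcoxon",
    "run_grid",
]

EXACT_WILCOXON_MAX_N = 25


def pearson_r(I: Sequence[float], d: Sequence[float]) -> float:
    """Pearson correlation between intensity and signed distance.

    r = sum((I_i - Ibar)(d_i - dbar)) /
        sqrt(sum((I_i - Ibar)^2) * sum((d_i - dbar)^2))
    """
    I = np.asarray(I, dtype=float)
    d = np.asarray(d, dtype=float)
    if len(I) != len(d):
        raise ValueError("I and d must have equal length")
    if len(I) < 3:
        raise ValueError("need at least 3 points for a correlation")
    di = I - I.mean()
    dd = d - d.mean()
    denom = np.sqrt((di**2).sum() * (dd**2).sum())
    if denom == 0:
        raise ValueError("correlation undefined: an input has zero variance")
    return float((di * dd).sum() / denom)


def _exact_signed_rank_p(ranks: np.ndarray, w_pos: float) -> float:
    """Exact two-sided p for the signed-rank statistic by dynamic programming
    over all 2^n sign patterns (equivalent to full enumeration; average ranks
    make rank sums half-integral, so everything is doubled to stay integer)."""
    r2 = np.round(ranks * 2).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: len(counts) - r]
        counts = counts + shifted
    w2 = int(round(w_pos * 2))
    n_patterns = counts.sum()  # == 2 ** n
    p_le = counts[: w2 + 1].sum() / n_patterns
    p_ge = counts[w2:].sum() / n_patterns
    return min(1.0, 2.0 * min(p_le, p_ge))


def paired_wilcoxon(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped (Wilcoxon's original rule); ties among
    |differences| get average ranks. The p-value is exact — full sign-pattern
    enumeration via dynamic programming — for n <= 25 remaining pairs, and a
    normal approximation with tie correction above that.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    diff = x - y
    diff = diff[diff != 0]
    n = len(diff)
    if n == 0:
        raise ValueError("all paired differences are zero; test undefined")
    if n < 5:
        raise ValueError(f"need >= 5 nonzero paired differences, got {n}")
    order = np.abs(diff)
    ranks = pd.Series(order).rank(method="average").to_numpy()
    w_pos = float(ranks[diff > 0].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        return _exact_signed_rank_p(ranks, w_pos)
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(order, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    z = (w_pos - mean) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


@dataclass
class SensitivityResult:
    """Grid of inside/outside correlations with paired test and bootstrap."""

    grid: pd.DataFrame        # sigma_um, threshold, image_id, r_inside, r_outside
    p_value: float | None
    pairing: str              # "images" or "grid_points"
    boot_mean_inside: float | None
    boot_mean_outside: float | None
    boot_se_inside: float | None
    boot_se_outside: float | None
    n_boot: int

    def summary(self) -> dict:
        return {
            "pairing": self.pairing,
            "p_value": self.p_value,
            "n_grid_points": int(
                self.grid[["sigma_um", "threshold"]].drop_duplicates().shape[0]
            ),
            "n_images": int(self.grid["image_id"].nunique()),
            "r_inside_range": [
                float(np.nanmin(self.grid["r_inside"])),
                float(np.nanmax(self.grid["r_inside"])),
            ]
            if self.grid["r_inside"].notna().any()
            else None,
            "r_outside_range": [
                float(np.nanmin(self.grid["r_outside"])),
                float(np.nanmax(self.grid["r_outside"])),
            ]
            if self.grid["r_outside"].notna().any()
            else None,
            "bootstrap": {
                "n_boot": self.n_boot,
                "mean_r_inside": self.boot_mean_inside,
                "mean_r_outside": self.boot_mean_outside,
                "se_r_inside": self.boot_se_inside,
                "se_r_outside": self.boot_se_outside,
            },
        }

    def write(self, csv_path: str | Path, json_path: str | Path) -> None:
        self.grid.to_csv(Path(csv_path), index=False)
        Path(json_path).write_text(json.dumps(self.summary(), indent=2))


def _safe_r(values: np.ndarray, dists: np.ndarray) -> float:
    if len(values) < 3:
        return np.nan
    if np.ptp(values) == 0 or np.ptp(dists) == 0:
        return np.nan
    return pearson_r(values, dists)


def run_grid(
    stacks: ChannelStack | Mapping[str, ChannelStack],
    table: pd.DataFrame,
    sigmas: Sequence[float],
    thresholds: Sequence[float],
    marker_column: str,
    pairing: str,
    matrix_channel: str = "FN",
    n_boot: int = 500,
    seed: int = 0,
) -> SensitivityResult:
    """Recompute the stromal model and inside/outside correlations on a grid.

    For every (sigma, threshold) pair and every image: rebuild the stromal
    model from the matrix channel, recompute signed distances of that image's
    cells, split at d = 0 (border-bin cells count as outside) and evaluate r
    on each side. Grid points whose mask has no border are recorded as
    missing, not fatal. ``pairing`` chooses the Wilcoxon pairing unit:
    ``"images"`` (one inside/outside pair per image, r averaged over the
    grid) or ``"grid_points"`` (one pair per image × grid point). The
    bootstrap resamples *images* with replacement; with fewer than 3 images
    the bootstrap SE is reported as None with a warning.
    """
    if pairing not in ("images", "grid_points"):
        raise ValueError("pairing must be 'images' or 'grid_points'")
    if len(sigmas) == 0 or len(thresholds) == 0:
        raise ValueError("sigma and threshold grids must be non-empty")
    if isinstance(stacks, ChannelStack):
        stacks = {stacks.image_id: stacks}
    rows = []
    for sigma in sigmas:
        for thr in thresholds:
            for image_id, stack in stacks.items():
                sub = table[table["image_id"] == image_id]
                model = build_stromal_model(
                    stack[matrix_channel], sigma, thr, stack.pixel_size_um
                )
                if not model.has_border or len(sub) == 0:
                    logger.warning(
                        "grid point (sigma=%s, t=%s) on image %s has no border "
                        "or no cells; recorded as missing",
                        sigma,
                        thr,
                        image_id,
                    )
                    rows.append(
                        dict(
                            sigma_um=sigma,
                            threshold=thr,
                            image_id=image_id,
                            r_inside=np.nan,
                            r_outside=np.nan,
                        )
                    )
                    continue
                pts = sub[["centroid_x_um", "centroid_y_um"]].to_numpy()
                d = signed_distance(model, pts)
                values = sub[marker_column].to_numpy(dtype=float)
                inside = d < 0
                rows.append(
                    dict(
                        sigma_um=sigma,
                        threshold=thr,
                        image_id=image_id,
                        r_inside=_safe_r(values[inside], d[inside]),
                        r_outside=_safe_r(values[~inside], d[~inside]),
                    )
                )
    grid = pd.DataFrame(rows)

    # Paired Wilcoxon of r_inside vs r_outside.
    if pairing == "images":
        per_unit = grid.groupby("image_id")[["r_inside", "r_outside"]].mean()
    else:
        per_unit = grid[["r_inside", "r_outside"]]
    per_unit = per_unit.dropna()
    try:
        p_value: float | None = paired_wilcoxon(
            per_unit["r_inside"].to_numpy(), per_unit["r_outside"].to_numpy()
        )
    except ValueError as exc:
        logger.warning("paired Wilcoxon not computed: %s", exc)
        p_value = None

    # Bootstrap across images of the per-image mean r on each side.
    per_image = grid.groupby("image_id")[["r_inside", "r_outside"]].mean()
    image_ids = per_image.index.to_numpy()
    boot = {k: (None, None) for k in ("r_inside", "r_outside")}
    if len(image_ids) < 3:
        warnings.warn(
            "fewer than 3 images: bootstrap SE of r is not reported",
            stacklevel=2,
        )
    else:
        rng = np.random.default_rng(seed)
        picks = rng.integers(0, len(image_ids), size=(n_boot, len(image_ids)))
        for side in ("r_inside", "r_outside"):
            vals = per_image[side].to_numpy()
            boot_means = np.nanmean(vals[picks], axis=1)
            boot[side] = (
                float(np.nanmean(boot_means)),
                float(np.nanstd(boot_means, ddof=1)),
            )
    return SensitivityResult(
        grid=grid,
        p_value=p_value,
        pairing=pairing,
        boot_mean_inside=boot["r_inside"][0],
        boot_mean_outside=boot["r_outside"][0],
        boot_se_inside=boot["r_inside"][1],
        boot_se_outside=boot["r_outside"][1],
        n_boot=n_boot,
    )
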