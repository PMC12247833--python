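"""Percentile-preserving threshold propagation across images.

Staining and acquisition differences shift per-image intensity histograms,
so a grey-level threshold chosen by an expert on one reference image does not
transfer directly to other images. This module propagates the *percentile*
of the threshold instead: each image's per-cell intensity sample for a marker
is modelled by the best-fitting positive continuous distribution (log-normal,
gamma, Weibull or exponential by default; parameters by maximum likelihood,
family selected by least-squares error between the fitted density and the
normalised histogram), the reference threshold is mapped to its percentile
under the reference fit, and that percentile is inverted under every other
image's fit. A consistent top fraction of cells is thereby classified
positive in each image, whatever its absolute intensity scale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_FAMILIES",
    "FittedDistribution",
    "ThresholdMap",
    "fit_best_distribution",
    "threshold_to_percentile",
    "percentile_to_threshold",
    "propagate_thresholds",
]

# Positive-support candidate families, fitted with location pinned at zero.
# Order matters: ties in SSE are broken by candidate order.
DEFAULT_FAMILIES: tuple[str, ...] = ("lognorm", "gamma", "weibull_min", "expon")

_SCIPY = {
    "lognorm": stats.lognorm,
    "gamma": stats.gamma,
    "weibull_min": stats.weibull_min,
    "expon": stats.expon,
}


@dataclass
class FittedDistribution:
    """One fitted candidate family with its goodness-of-fit score.

    ``parameters`` are the scipy shape/loc/scale vector of ``family``;
    ``sse`` is the sum of squared differences between the fitted density and
    the normalised histogram at bin centers.
    """

    family: str
    parameters: tuple[float, ...]
    sse: float
    hist_bin_width: float
    n_samples: int

    def _frozen(self):
        return _SCIPY[self.family](*self.parameters)

    def cdf(self, x: float | np.ndarray) -> float | np.ndarray:
        return self._frozen().cdf(x)

    def quantile(self, p: float | np.ndarray) -> float | np.ndarray:
        return self._frozen().ppf(p)

    def pdf(self, x: float | np.ndarray) -> float | np.ndarray:
        return self._frozen().pdf(x)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "parameters": list(self.parameters),
            "sse": self.sse,
            "hist_bin_width": self.hist_bin_width,
            "n_samples": self.n_samples,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FittedDistribution":
        return cls(
            family=d["family"],
            parameters=tuple(d["parameters"]),
            sse=float(d["sse"]),
            hist_bin_width=float(d["hist_bin_width"]),
            n_samples=int(d["n_samples"]),
        )


def _freedman_diaconis_width(values: np.ndarray) -> float:
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        # Fall back to Scott's rule when the IQR degenerates.
        return 3.49 * values.std(ddof=1) / len(values) ** (1 / 3)
    return 2.0 * iqr / len(values) ** (1 / 3)


def _n_free_params(family: str) -> int:
    # location is pinned at zero, so expon has 1 free parameter, the rest 2
    return 1 if family == "expon" else 2


def fit_best_distribution(
    values: Sequence[float] | np.ndarray,
    candidates: Sequence[str] = DEFAULT_FAMILIES,
    hist_bin_width: float | None = None,
    parsimony_rtol: float = 0.10,
) -> FittedDistribution:
    """Fit every candidate family by MLE and return the histogram-SSE minimiser.

    Values ``<= 0`` are excluded before fitting (all candidates have positive
    support); their count is logged. Needs at least 50 positive samples.
    SSE compares each family's density with the normalised histogram at bin
    centers, with Freedman–Diaconis bin width unless overridden.

    Candidate families can be nested (gamma and Weibull contain the
    exponential), in which case the richer family beats the true one by a few
    percent of SSE simply by absorbing histogram noise. Families whose SSE is
    within ``parsimony_rtol`` (relative) of the minimum are therefore treated
    as indistinguishable and the one with fewest free parameters wins;
    remaining ties are broken by candidate order. Set ``parsimony_rtol=0``
    for the strict SSE minimiser.
    """
    values = np.asarray(values, dtype=float)
    n_nonpos = int(np.sum(values <= 0))
    if n_nonpos:
        logger.info("excluding %d non-positive values from distribution fit", n_nonpos)
        values = values[values > 0]
    if len(values) < 50:
        raise ValueError(f"need >= 50 positive samples to fit, got {len(values)}")
    if np.ptp(values) == 0:
        raise ValueError("degenerate sample: all values are identical")
    width = hist_bin_width if hist_bin_width is not None else _freedman_diaconis_width(values)
    if width <= 0:
        raise ValueError("histogram bin width must be positive")
    edges = np.arange(values.min(), values.max() + width, width)
    if len(edges) < 3:
        edges = np.linspace(values.min(), values.max(), 3)
        width = edges[1] - edges[0]
    density, edges = np.histogram(values, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    fitted: list[FittedDistribution] = []
    for family in candidates:
        dist = _SCIPY[family]
        try:
            params = dist.fit(values, floc=0)
        except Exception:  # a family can fail on extreme samples; skip it
            logger.warning("MLE failed for family %s", family)
            continue
        sse = float(np.sum((dist.pdf(centers, *params) - density) ** 2))
        if not np.isfinite(sse):
            continue
        fitted.append(
            FittedDistribution(
                family=family,
                parameters=tuple(float(p) for p in params),
                sse=sse,
                hist_bin_width=float(width),
                n_samples=len(values),
            )
        )
    if not fitted:
        raise RuntimeError("no candidate family could be fitted")
    min_sse = min(f.sse for f in fitted)
    contenders = [f for f in fitted if f.sse <= (1.0 + parsimony_rtol) * min_sse]
    # fewest free parameters first; candidate order breaks remaining ties
    return min(contenders, key=lambda f: _n_free_params(f.family))


def threshold_to_percentile(fit: FittedDistribution, threshold: float) -> float:
    """Map a grey-level threshold to its percentile (CDF value) under a fit."""
    if threshold <= 0:
        raise ValueError("threshold must be positive for positive-support families")
    return float(fit.cdf(threshold))


def percentile_to_threshold(fit: FittedDistribution, p: float) -> float:
    """Invert a percentile to a grey-level threshold (fitted quantile)."""
    if not 0 < p < 1:
        raise ValueError("percentile must lie strictly in (0, 1)")
    return float(fit.quantile(p))


@dataclass
class ThresholdMap:
    """Propagated thresholds for one marker across a batch of images."""

    reference_image_id: str
    marker: str                      # measurement column name
    reference_threshold: float
    percentile: float
    thresholds: dict[str, float]     # image_id -> translated threshold
    fits: dict[str, FittedDistribution] = field(default_factory=dict)

    def threshold_for(self, image_id: str) -> float:
        try:
            return self.thresholds[image_id]
        except KeyError:
            raise KeyError(
                f"image {image_id!r} has no translated threshold "
                f"(have {sorted(self.thresholds)})"
            ) from None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "reference_image_id": self.reference_image_id,
            "marker": self.marker,
            "reference_threshold": self.reference_threshold,
            "percentile": self.percentile,
            "thresholds": self.thresholds,
            "fits": {k: v.to_dict() for k, v in self.fits.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdMap":
        d = json.loads(Path(path).read_text())
        return cls(
            reference_image_id=d["reference_image_id"],
            marker=d["marker"],
            reference_threshold=float(d["reference_threshold"]),
            percentile=float(d["percentile"]),
            thresholds={k: float(v) for k, v in d["thresholds"].items()},
            fits={k: FittedDistribution.from_dict(v) for k, v in d["fits"].items()},
        )


def propagate_thresholds(
    tables: Mapping[str, pd.DataFrame],
    marker: str,
    reference_image_id: str,
    reference_threshold: float,
    candidates: Sequence[str] = DEFAULT_FAMILIES,
    hist_bin_width: float | None = None,
) -> ThresholdMap:
    """Propagate an expert threshold from a reference image to every image.

    ``tables`` maps image id to that image's cell table; ``marker`` is the
    measurement column holding the intensity the threshold applies to. The
    reference image's sample is fitted, the threshold mapped to its CDF
    percentile, and the percentile inverted under each image's own fit.
    """
    if reference_image_id not in tables:
        raise KeyError(f"reference image {reference_image_id!r} not among tables")
    fits: dict[str, FittedDistribution] = {}
    for image_id, table in tables.items():
        if marker not in table.columns:
            raise KeyError(f"marker column {marker!r} missing from image {image_id!r}")
        values = table[marker].dropna().to_numpy()
        try:
            fits[image_id] = fit_best_distribution(values, candidates, hist_bin_width)
        except Exception as exc:
            raise RuntimeError(
                f"distribution fit failed for image {image_id!r}: {exc}"
            ) from exc
    percentile = threshold_to_percentile(fits[reference_image_id], reference_threshold)
    thresholds = {
        image_id: percentile_to_threshold(fit, percentile)
        for image_id, fit in fits.items()
    }
    return ThresholdMap(
        reference_image_id=reference_image_id,
        marker=marker,
        reference_threshold=float(reference_threshold),
        percentile=percentile,
        thresholds=thresholds,
        fits=fits,
    )
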