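# Methods

This note documents the models, conventions and numerical choices behind
`stromapy`, in the order the pipeline runs.

## Coordinate and measurement conventions

Images are `[row, col]` arrays; physical coordinates are
`x = col · pixel_size`, `y = row · pixel_size` in µm (y grows downward).
Pixel `(r, c)` has its center at `(c·px, r·px)`; a continuous point's
*containing pixel* is the one with the nearest center. Centroids are means
of nucleus pixel centers. All intensity statistics are computed on raw grey
levels over exact pixel sets — no normalisation — with the population
standard deviation (divide by *n*) and numpy's even-set median (mean of the
two central order statistics). Cytoplasm statistics are NaN when the
cytoplasm pixel set is empty, never silently zero.

## Segmentation and cell geometry

Nuclei segmentation is an exchangeable input: label images from external
segmenters are ingested verbatim (ids preserved, areas converted by
`px²`). The built-in segmenter (Gaussian smooth → threshold, Otsu by
default → watershed on the distance transform seeded at local maxima) is
adequate for the synthetic disk nuclei and deterministic; it makes no claim
on real tissue.

Whole-cell masks radially expand each nucleus by 5 µm. The expansion is a
nearest-nucleus partition of the background within the radius: each pixel
joins the nucleus whose nearest pixel center is closest, with exact
equidistance going to the lower label id. This is implemented as one
per-label Euclidean distance transform with a strict-less update in
ascending id order, which reproduces brute-force assignment exactly. The
partition makes expansion monotone in radius and guarantees disjoint cells;
whether the original interactive-platform expansion constrains growth the
same way is not documented anywhere we know of, so this variant is spelled
out and tested instead.

Area filtering discards cells *strictly* below the 5th or *strictly* above
the 99th percentile of the per-image nuclear-area distribution, percentiles
by linear interpolation between order statistics; exact-percentile areas
are kept, so an all-equal image loses nothing.

## Threshold calibration (percentile propagation)

Per-cell intensity histograms of fluorescence markers are right-skewed and
well approximated by positive continuous families; a grey-level threshold
meaningful on one image is not meaningful on another stained or acquired
differently, but its *percentile* is. For each image the marker sample
(values ≤ 0 excluded, count logged) is fitted by maximum likelihood with
location pinned at zero for each candidate family — log-normal, gamma,
Weibull, exponential by default — and each fit is scored by the sum of
squared differences between its density and the normalised histogram at bin
centers (Freedman–Diaconis width unless overridden; MLE is used for
parameters because histogram-least-squares estimates would depend on
binning, while SSE remains the model-selection score).

Because gamma and Weibull *nest* the exponential, the raw SSE minimiser
systematically prefers the richer family on exponential data — it absorbs
histogram noise with its extra parameter, winning by a few percent of SSE
that carries no evidence. Families whose SSE lies within 10% (relative) of
the minimum are therefore treated as indistinguishable and the one with the
fewest free parameters is selected, remaining ties by candidate order;
`parsimony_rtol=0` restores the strict minimiser. On 20,000-sample draws
this identifies the generating family (log-normal / gamma / exponential)
in ≥ 18 of 20 trials while leaving non-nested contests untouched.

Propagation: `p = F_ref(t_ref)` under the reference fit, then
`t_img = F_img^{-1}(p)` per image. Two invariants are enforced by tests:
`F_img(t_img) = p` to 1e-9, and equivariance — a pure multiplicative
intensity scale `c` between images moves the translated threshold to
`c · t_ref` up to fit error (≈2% at n = 20,000). Classification applies the
translated threshold to *all* cells (including any non-positive values
excluded from fitting) with strict `>`; a value equal to the threshold is
negative.

## Stromal model and signed distance

The mask is `gaussian(matrix_channel, σ/px) > t` (strict, on smoothed
values; σ = 0 means no smoothing). Border pixels are mask pixels with at
least one non-mask 4-neighbor; the image edge itself never counts as
border, so cells near the frame measure to real tissue borders only. An
empty or borderless mask yields a `+inf` sentinel distance map, and
point-distance queries raise — the caller decides what an all-stroma image
means.

Signed distance of a point: magnitude is the exact minimum Euclidean
distance to any border pixel center (a KD-tree query over border centers —
identical, not approximately equal, to brute-force minimisation); the sign
is negative iff the point's containing pixel is in the mask. The per-pixel
`signed_distance_map` uses one Euclidean distance transform of the border
set and agrees with the point route exactly at pixel centers. Default
smoothing sigmas of 15 µm (diffuse cytoplasmic markers) and 10 µm
(punctate nuclear markers) are exposed in the pipeline config.

## Profiles and error propagation

Cells are binned by signed distance into half-open `[k·w, (k+1)·w)` bins,
w = 10 µm by default (≈ one cell diameter), aligned so 0 — the border — is
always an edge; the default display range −100…+300 µm is overridable, and
out-of-range cells carry a sentinel index. Per bin: count, mean intensity,
within-bin sample SD, and a bootstrap SEM (500 resamples of cells within
the bin, seeded; the resampling unit is the cell here, whereas the
sensitivity bootstrap resamples images, where batch structure matters). A
single-cell bin has SEM 0; an empty bin is null. Bootstrap SEM converges to
σ/√n within 10% for n ≥ 200.

Profile differences subtract bin means over identical edges and propagate
`SEM = sqrt(σ_a²/n_a + σ_b²/n_b)` from the within-bin SDs; bins empty on
either side are null. The `peak_bin` helper reports the argmax of bin means
over bins with at least `min_n` cells (default 1; analyses here use 5)
because single-digit bins are dominated by individual-cell noise.

## Sensitivity analysis

For every (σ, t) on the grid the stromal model is rebuilt, distances are
recomputed, and Pearson's r between marker intensity and signed distance is
evaluated separately for cells inside (d < 0) and outside (d ≥ 0; border
cells count as outside). Correlations with fewer than 3 cells or zero
variance, and grid points with borderless masks, are recorded as missing,
not fatal. Inside/outside pairs are compared with a two-sided Wilcoxon
signed-rank test: zero differences dropped (Wilcoxon's original rule), ties
given average ranks, exact p by a rank-sum dynamic program equivalent to
full 2ⁿ enumeration for n ≤ 25, normal approximation with tie correction
(no continuity correction) above. The pairing unit — one pair per image, or
one per image × grid point — is a required configuration choice because
both readings of "paired across images and parameter settings" are
defensible. Bootstrap means/SEs of r resample images with replacement (500
iterations); with fewer than 3 images the SE is reported as null with a
warning rather than a misleading number.

## Synthetic tissue generator

The generator emulates the class of images the pipeline targets: a DAPI
channel of Gaussian-profile disk nuclei (rejection-sampled without overlap;
exceeding the packing limit raises an error naming the density), a
fibronectin-like channel high inside a stromal compartment (thresholded
smoothed Gaussian random field, quantile-pinned to the requested areal
fraction, or an analytic half-plane in "simple" mode), a cytokeratin-like
channel distinguishing cancer cells (placed outside the stroma except for a
2% contamination rate), and a marker channel whose noiseless per-cell mean
follows a distance law — `baseline + amplitude·exp(−max(d,0)/λ)` for
exponential decay, its complement for monotone increase, or flat. Per-cell
intensities are drawn log-normally around those means with unit-mean noise
(CV 0.4), giving the right-skewed histograms real markers show; a per-image
affine `batch_shift` then emulates staining variation, and additive
Gaussian read noise is applied last. A latent marker-positive class
(default 30% of cells, 3× mean boost) exercises the classifiers. All
randomness flows from one seeded generator: identical spec + seed is
bit-identical.

Defaults describe a 512 × 512 px field at 1 µm/px. Real scanners deliver
finer pitch (≈0.32 µm/px) over vastly larger fields; a desk-scale field
must trade pixel pitch for field of view so that a −100…+300 µm profile
range fits inside one image, and the grid can be refined via
`pixel_size_um` when pitch matters. What the generator does *not* emulate —
nucleus shape irregularity, texture, marker bleed-through, 3D structure,
immune/vascular cell types — bounds what passing tests show: they validate
the measurement and statistics chain, not segmentation robustness on real
tissue.

## Known limitations

- Stroma delineation is intensity thresholding after smoothing; texture- or
  learning-based segmentation is out of scope.
- The builtin segmenter is for synthetic blobs; real nuclei need an
  external segmenter (label-image ingestion is the supported route).
- Percentile propagation assumes the marker's distributional *shape* is
  comparable across images; a reference threshold in a badly chosen image
  propagates its bias everywhere.
- 2D only; distances in sectioned tissue underestimate 3D proximity.
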