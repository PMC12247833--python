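# stromapy

Spatial profiling of cell markers relative to a stromal border in
multiplexed immunofluorescence tissue images.

Stroma-rich tumors (pancreatic ductal adenocarcinoma being the archetype)
surround their cancer cells with a dense extracellular-matrix compartment
that shapes drug response and cell state. A recurring analysis question is
therefore *how a marker's expression varies with a cell's distance to the
stromal border*. `stromapy` implements that analysis end to end for
multi-channel 2D fluorescence images (nuclear channel, matrix channel such
as fibronectin, an epithelial/cancer gate such as pan-cytokeratin, and one
or more analysis markers):

1. **Segmentation** — ingest a nuclei label image from any external
   segmenter, or use the built-in smoothed-threshold-watershed blob
   segmenter; expand each nucleus radially by 5 µm into a whole-cell mask
   (nearest-nucleus partitioned, so cells never overlap); filter nuclei
   outside the per-image 5th–99th area percentiles.
2. **Features** — per-cell `{mean, median, min, max, std}` of every channel
   over nucleus, cytoplasm and whole cell, on raw grey levels, in a
   QuPath-compatible cell table.
3. **Threshold calibration** — the core statistical method. An expert picks
   one grey-level threshold on one reference image. Each image's per-cell
   intensity sample for the marker is modelled by the best-fitting positive
   continuous distribution (log-normal, gamma, Weibull, exponential;
   maximum-likelihood parameters, family selected by least-squares error of
   the fitted density against the normalised histogram). The reference
   threshold maps to its percentile `p = F_ref(t_ref)` and is translated to
   every other image as `t_img = F_img^{-1}(p)` — so a consistent top
   fraction of cells is called positive regardless of staining intensity.
4. **Classification** — marker-positive/negative by translated thresholds
   (strict `>`), optionally compared with a random-forest classifier on
   intensity features; agreement summarised by confusion matrices.
5. **Stromal model & signed distance** — Gaussian-smooth the matrix
   channel, threshold it, take the mask border as the stromal edge, and
   measure each cell's signed Euclidean distance `d` to the nearest border
   point (negative inside the stroma).
6. **Spatial profiles** — bin cells in 10 µm distance intervals; per-bin
   mean marker intensity with bootstrap SEM; bin-wise group differences
   with error propagation `SEM = sqrt(σ_a²/n_a + σ_b²/n_b)`.
7. **Sensitivity** — grid-search the smoothing sigma and stromal threshold;
   at every grid point recompute mask, distances, and the Pearson
   correlation `r(I, d)` inside and outside the stroma; compare the paired
   sides with an exact two-sided Wilcoxon signed-rank test and bootstrap
   across images.

A fully ground-truthed synthetic tissue generator (`stromapy.simulate`)
produces four-channel fields with known cell classes, stromal masks,
distance-dependent marker laws and controllable between-image intensity
shifts, so the whole pipeline is testable without microscope data.

## Worked example

```python
import numpy as np
import stromapy as sp

# a 512x512 µm synthetic field: 300 cells, stroma fraction 0.3,
# marker decaying from the stromal border with a 50 µm length scale
spec = sp.TissueSpec(seed=1)
stack, truth = sp.generate_tissue(spec)

nuclei = sp.segment_nuclei_builtin(stack["DAPI"], stack.pixel_size_um)
cells = sp.expand_cells(nuclei, 5.0, stack.pixel_size_um)
geoms = sp.geometries_from_labels(nuclei, cells, stack.pixel_size_um)
kept, _ = sp.filter_by_area(geoms, 5, 99)
table = sp.measure_cells(stack, kept)

model = sp.build_stromal_model(stack["FN"], sigma_um=10, threshold=60,
                               pixel_size_um=stack.pixel_size_um)
pts = table[["centroid_x_um", "centroid_y_um"]].to_numpy()
table["signed_distance_um"] = sp.signed_distance(model, pts)

prof = sp.profile(table, "Cell: MARKER mean", seed=0)
peak_edge, peak_mean = prof.peak_bin(min_n=5)
print(f"{len(table)} cells, stromal fraction {model.mask.mean():.2f}")
print(f"profile peak at [{peak_edge:.0f}, {peak_edge+10:.0f}) µm, "
      f"mean {peak_mean:.1f}")
r = sp.pearson_r(table.loc[table.signed_distance_um >= 0, "Cell: MARKER mean"],
                 table.loc[table.signed_distance_um >= 0, "signed_distance_um"])
print(f"r(intensity, distance) outside stroma: {r:.2f}")
```

prints

```
282 cells, stromal fraction 0.31
profile peak at [-10, 0) µm, mean 150.3
r(intensity, distance) outside stroma: -0.45
```

i.e. over all cells the mean marker intensity peaks in the bin touching the
stromal border from inside (the generator's law plateaus at the interface)
and declines with distance outside it (negative correlation), recovering
the 50 µm decay law the generator embedded.

The same flow is available from the shell:

```bash
stromapy simulate --out sim/ --seed 1
stromapy run --config pipeline.yaml --image sim/image.tif --out results/
```

with subcommands `simulate · segment · measure · calibrate · classify ·
stroma · profile · sensitivity · run`.

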