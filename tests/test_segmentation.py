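"""Segmentation: label ingestion, built-in segmenter, expansion, area filter."""

import numpy as np
import pytest

from stromapy import (
    TissueSpec,
    expand_cells,
    filter_by_area,
    generate_tissue,
    ingest_labels,
    segment_nuclei_builtin,
)
from stromapy.segmentation import CellGeometry


# ------------------------------------------------------------- ingest_labels
def test_ingest_empty_image():
    assert ingest_labels(np.zeros((10, 10), dtype=int), 1.0) == []


def test_ingest_area_unit_conversion():
    img = np.zeros((10, 10), dtype=int)
    img[2:4, 3:8] = 1  # 10 pixels
    (cell,) = ingest_labels(img, 1.0)
    assert cell.nucleus_area_um2 == pytest.approx(10.0)
    (cell,) = ingest_labels(img, 0.5)
    assert cell.nucleus_area_um2 == pytest.approx(2.5)


def test_ingest_preserves_sparse_ids():
    img = np.zeros((10, 10), dtype=int)
    img[0, 0], img[5, 5], img[9, 9] = 1, 3, 7
    cells = ingest_labels(img, 1.0)
    assert [c.cell_id for c in cells] == [1, 3, 7]


def test_ingest_rejects_negative_labels():
    with pytest.raises(ValueError):
        ingest_labels(np.array([[-1, 0], [0, 1]]), 1.0)


def test_centroid_is_mean_of_pixel_centers():
    img = np.zeros((10, 10), dtype=int)
    img[2, 2], img[2, 4] = 1, 1
    (cell,) = ingest_labels(img, 2.0)
    assert cell.centroid_um == (pytest.approx(6.0), pytest.approx(4.0))  # (x, y)


# ---------------------------------------------------- segment_nuclei_builtin
def test_builtin_counts_well_separated_disks():
    spec = TissueSpec(
        image_size_px=(400, 400), n_cells=50, noise_sd=1.0,
        nucleus_radius_um=(4.0, 0.3), seed=2,
    )
    stack, truth = generate_tissue(spec)
    labels = segment_nuclei_builtin(stack["DAPI"], 1.0)
    assert labels.max() == truth.n_cells


def test_builtin_blank_image():
    assert segment_nuclei_builtin(np.zeros((64, 64)), 1.0).max() == 0


def test_builtin_splits_adjacent_disks():
    img = np.zeros((40, 60))
    yy, xx = np.mgrid[0:40, 0:60]
    img += 100 * ((yy - 20) ** 2 + (xx - 20) ** 2 <= 36)
    img += 100 * ((yy - 20) ** 2 + (xx - 33) ** 2 <= 36)  # 1 px gap
    labels = segment_nuclei_builtin(img, 1.0, smooth_sigma_um=0.5, threshold=50)
    assert labels.max() == 2


# ----------------------------------------------------------------- expansion
def test_expand_radius_zero_is_identity():
    labels = np.zeros((20, 20), dtype=int)
    labels[5:8, 5:8] = 1
    np.testing.assert_array_equal(expand_cells(labels, 0.0, 1.0), labels)


def test_expand_negative_radius_raises():
    with pytest.raises(ValueError):
        expand_cells(np.zeros((5, 5), dtype=int), -1.0, 1.0)


def test_expand_isolated_nucleus_matches_bruteforce_disk():
    labels = np.zeros((21, 21), dtype=int)
    labels[10, 10] = 1
    out = expand_cells(labels, 5.0, 1.0)
    rr, cc = np.mgrid[0:21, 0:21]
    expected = ((rr - 10) ** 2 + (cc - 10) ** 2 <= 25.0).astype(np.int32)
    np.testing.assert_array_equal(out, expected)


def test_expand_tie_goes_to_lower_id():
    labels = np.zeros((11, 21), dtype=int)
    labels[5, 8] = 2
    labels[5, 12] = 1  # higher column but lower id
    out = expand_cells(labels, 5.0, 1.0)
    # column 10 is equidistant from both nuclei -> label 1 everywhere reached
    reached = out[:, 10] > 0
    assert (out[reached, 10] == 1).all()
    # and the two cells never overlap
    assert ((out == 1) & (out == 2)).sum() == 0


def test_expand_monotone_in_radius(small_tissue):
    _, truth = small_tissue
    labels = truth.nuclei_label_image
    small = expand_cells(labels, 2.0, 1.0)
    large = expand_cells(labels, 5.0, 1.0)
    grown = small > 0
    np.testing.assert_array_equal(small[grown], large[grown])


def test_expand_matches_bruteforce_nearest_nucleus(rng):
    labels = np.zeros((32, 32), dtype=int)
    coords = rng.choice(32 * 32, size=6, replace=False)
    for i, flat in enumerate(coords, start=1):
        labels[flat // 32, flat % 32] = i
    radius = 6.0
    out = expand_cells(labels, radius, 1.0)
    nuclei = {i: np.argwhere(labels == i)[0] for i in range(1, 7)}
    for r in range(32):
        for c in range(32):
            dists = {
                i: np.hypot(r - p[0], c - p[1]) for i, p in nuclei.items()
            }
            best = min(dists.values())
            if labels[r, c]:
                assert out[r, c] == labels[r, c]
            elif best <= radius:
                winner = min(i for i, d in dists.items() if d == best)
                assert out[r, c] == winner
            else:
                assert out[r, c] == 0


# --------------------------------------------------------------- area filter
def _cells_from_areas(areas):
    return [
        CellGeometry(
            cell_id=i + 1,
            nucleus_pixels=np.zeros((1, 2), dtype=int),
            cell_pixels=np.zeros((1, 2), dtype=int),
            nucleus_area_um2=a,
            centroid_um=(0.0, 0.0),
        )
        for i, a in enumerate(areas)
    ]


def test_filter_matches_sortbased_percentile_oracle(rng):
    areas = rng.lognormal(3.0, 0.4, size=1000)
    kept, discarded = filter_by_area(_cells_from_areas(areas), 5, 99)
    # independent oracle: sorted-order linear interpolation percentiles
    s = np.sort(areas)
    def pct(p):
        idx = p / 100 * (len(s) - 1)
        lo, hi = int(np.floor(idx)), int(np.ceil(idx))
        return s[lo] + (idx - lo) * (s[hi] - s[lo])
    lo, hi = pct(5), pct(99)
    expected_kept = {i + 1 for i, a in enumerate(areas) if lo <= a <= hi}
    assert {c.cell_id for c in kept} == expected_kept
    assert len(kept) + len(discarded) == 1000


def test_filter_full_range_keeps_everything(rng):
    cells = _cells_from_areas(rng.uniform(1, 10, size=50))
    kept, discarded = filter_by_area(cells, 0, 100)
    assert len(kept) == 50 and not discarded


def test_filter_identical_areas_keeps_everything():
    kept, discarded = filter_by_area(_cells_from_areas([4.0] * 20), 5, 99)
    assert len(kept) == 20 and not discarded


def test_filter_idempotent_on_kept_set(rng):
    cells = _cells_from_areas(rng.lognormal(3.0, 0.5, size=300))
    kept, _ = filter_by_area(cells, 5, 99)
    kept2, discarded2 = filter_by_area(kept, 0, 100)
    assert len(kept2) == len(kept) and not discarded2


def test_filter_empty_input_raises():
    with pytest.raises(ValueError):
        filter_by_area([], 5, 99)
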