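"""Pearson correlation, exact Wilcoxon signed-rank, and the parameter grid."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stromapy import (
    MarkerGradient,
    TissueSpec,
    expand_cells,
    generate_tissue,
    geometries_from_labels,
    measure_cells,
    paired_wilcoxon,
    pearson_r,
    run_grid,
)


# ----------------------------------------------------------------- pearson_r
def test_pearson_identical_vectors(rng):
    x = rng.normal(size=50)
    assert pearson_r(x, x) == pytest.approx(1.0, abs=1e-12)


def test_pearson_affine_anticorrelation(rng):
    x = rng.normal(size=50)
    assert pearson_r(x, -2 * x + 7) == pytest.approx(-1.0, abs=1e-12)


def test_pearson_matches_term_by_term_formula(rng):
    I = rng.normal(10, 3, size=10)
    d = rng.normal(0, 50, size=10)
    Ibar, dbar = I.mean(), d.mean()
    num = sum((I[i] - Ibar) * (d[i] - dbar) for i in range(10))
    den = np.sqrt(
        sum((I[i] - Ibar) ** 2 for i in range(10))
        * sum((d[i] - dbar) ** 2 for i in range(10))
    )
    assert pearson_r(I, d) == pytest.approx(num / den, abs=1e-12)


def test_pearson_zero_variance_raises():
    with pytest.raises(ValueError):
        pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ------------------------------------------------------------------ Wilcoxon
def _bruteforce_wilcoxon(diff):
    """Full 2^n enumeration of the signed-rank null distribution."""
    diff = np.asarray(diff, dtype=float)
    diff = diff[diff != 0]
    ranks = pd.Series(np.abs(diff)).rank(method="average").to_numpy()
    w_obs = ranks[diff > 0].sum()
    n = len(ranks)
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    ws = np.array(ws)
    p_le = (ws <= w_obs + 1e-9).mean()
    p_ge = (ws >= w_obs - 1e-9).mean()
    return min(1.0, 2.0 * min(p_le, p_ge))


def test_all_positive_n5():
    x = np.arange(1.0, 6.0)
    assert paired_wilcoxon(x + 1.0, x) == pytest.approx(2 / 32)


def test_all_same_sign_n11():
    x = np.arange(1.0, 12.0)
    assert paired_wilcoxon(x, x + 3.0) == pytest.approx(2 / 2048)


def test_identical_pairs_raise():
    x = np.arange(1.0, 9.0)
    with pytest.raises(ValueError):
        paired_wilcoxon(x, x)


def test_exact_matches_bruteforce_enumeration(rng):
    for n in (5, 7, 9, 12):
        for _ in range(5):
            diff = rng.normal(size=n)
            diff[diff == 0] = 0.5
            p = paired_wilcoxon(diff, np.zeros(n))
            assert p == pytest.approx(_bruteforce_wilcoxon(diff), abs=1e-12)


def test_exact_with_tied_magnitudes(rng):
    diff = np.array([1.0, -1.0, 2.0, 2.0, -3.0, 4.0, 4.0, 5.0])
    p = paired_wilcoxon(diff, np.zeros(8))
    assert p == pytest.approx(_bruteforce_wilcoxon(diff), abs=1e-12)


def test_exact_agrees_with_scipy_when_untied(rng):
    diff = rng.normal(size=14)
    p = paired_wilcoxon(diff, np.zeros(14))
    ref = stats.wilcoxon(diff, alternative="two-sided", mode="exact").pvalue
    assert p == pytest.approx(ref, abs=1e-9)


def test_large_n_normal_approximation(rng):
    diff = rng.normal(0.3, 1.0, size=60)
    p = paired_wilcoxon(diff, np.zeros(60))
    ref = stats.wilcoxon(
        diff, alternative="two-sided", mode="approx", correction=False
    ).pvalue
    assert p == pytest.approx(ref, rel=1e-6)


# ---------------------------------------------------------------------- grid
def _tissue_table(law, seed, n_cells=250):
    spec = TissueSpec(
        image_size_px=(300, 300),
        n_cells=n_cells,
        marker_gradient=MarkerGradient(law=law, amplitude=100.0,
                                       length_scale_um=50.0, baseline=20.0),
        marker_positive_fraction=0.0,
        intensity_cv=0.2,
        seed=seed,
    )
    stack, truth = generate_tissue(spec)
    labels = truth.nuclei_label_image
    cells = expand_cells(labels, 5.0, 1.0)
    table = measure_cells(stack, geometries_from_labels(labels, cells, 1.0))
    return stack, table


def test_grid_decay_marker_negative_r_outside():
    stack, table = _tissue_table("exponential_decay", seed=31)
    res = run_grid(
        stack, table, [5.0, 10.0, 15.0], [48.0, 60.0, 72.0],
        "Cell: MARKER mean", pairing="grid_points", n_boot=50, seed=0,
    )
    assert (res.grid["r_outside"] < 0).all()


def test_grid_flat_marker_near_zero_r():
    stack, table = _tissue_table("flat", seed=32, n_cells=400)
    res = run_grid(
        stack, table, [10.0], [60.0],
        "Cell: MARKER mean", pairing="grid_points", n_boot=50, seed=0,
    )
    assert (res.grid["r_outside"].abs() < 0.2).all()
    assert (res.grid["r_inside"].abs() < 0.3).all()


def test_grid_deterministic():
    stack, table = _tissue_table("exponential_decay", seed=33, n_cells=150)
    kw = dict(marker_column="Cell: MARKER mean", pairing="grid_points",
              n_boot=50, seed=5)
    r1 = run_grid(stack, table, [10.0], [60.0], **kw)
    r2 = run_grid(stack, table, [10.0], [60.0], **kw)
    pd.testing.assert_frame_equal(r1.grid, r2.grid)
    assert r1.summary() == r2.summary()


def test_grid_empty_border_recorded_missing():
    stack, table = _tissue_table("flat", seed=34, n_cells=100)
    res = run_grid(
        stack, table, [10.0], [1e9],  # threshold above everything: no mask
        "Cell: MARKER mean", pairing="grid_points", n_boot=10, seed=0,
    )
    assert res.grid["r_outside"].isna().all()


def test_grid_requires_valid_pairing():
    stack, table = _tissue_table("flat", seed=35, n_cells=100)
    with pytest.raises(ValueError):
        run_grid(stack, table, [10.0], [60.0], "Cell: MARKER mean",
                 pairing="bogus")
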