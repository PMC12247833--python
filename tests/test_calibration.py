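"""Distribution fitting and percentile-preserving threshold propagation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stromapy import (
    ThresholdMap,
    fit_best_distribution,
    percentile_to_threshold,
    propagate_thresholds,
    threshold_to_percentile,
)


def _table(values, image_id="img"):
    return pd.DataFrame({"image_id": image_id, "Cell: M max": values})


# ------------------------------------------------------------- model fitting
def test_lognormal_recovery_and_selection(rng):
    mu, sigma = 3.0, 0.5
    values = rng.lognormal(mu, sigma, size=20_000)
    fit = fit_best_distribution(values)
    assert fit.family == "lognorm"
    s, _, scale = fit.parameters
    assert np.log(scale) == pytest.approx(mu, rel=0.05)
    assert s == pytest.approx(sigma, rel=0.05)


def test_gamma_selection(rng):
    values = rng.gamma(2.0, 50.0, size=20_000)
    fit = fit_best_distribution(values)
    assert fit.family == "gamma"


def test_degenerate_sample_raises():
    with pytest.raises(ValueError, match="degenerate"):
        fit_best_distribution([10.0] * 50)


def test_too_few_samples_raise():
    with pytest.raises(ValueError):
        fit_best_distribution([1.0, 2.0, 3.0])


def test_nonpositive_values_are_excluded(rng):
    values = np.concatenate([rng.lognormal(2, 0.4, 500), [-1.0, 0.0]])
    fit = fit_best_distribution(values)
    assert fit.n_samples == 500


# -------------------------------------------------- percentile <-> threshold
def test_lognormal_median_maps_to_half(rng):
    mu = 2.5
    fit = fit_best_distribution(rng.lognormal(mu, 0.4, size=5000))
    # use the *fitted* mu so the check is exact for the CDF contract
    fitted_mu = np.log(fit.parameters[2])
    assert threshold_to_percentile(fit, np.exp(fitted_mu)) == pytest.approx(0.5, abs=1e-9)


def test_cdf_limits_and_monotonicity(rng):
    fit = fit_best_distribution(rng.lognormal(2, 0.5, size=2000))
    assert threshold_to_percentile(fit, 1e9) == pytest.approx(1.0)
    assert percentile_to_threshold(fit, 0.1) < percentile_to_threshold(fit, 0.9)


def test_quantile_matches_bisection_oracle(rng):
    fit = fit_best_distribution(rng.lognormal(0.0, 1.0, size=10_000))
    p = 0.9
    # independent numeric inversion of the fitted CDF by bisection
    lo, hi = 1e-9, 1e6
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if fit.cdf(mid) < p:
            lo = mid
        else:
            hi = mid
    assert percentile_to_threshold(fit, p) == pytest.approx(0.5 * (lo + hi), rel=1e-6)


def test_roundtrip_within_tolerance(rng):
    fit = fit_best_distribution(rng.lognormal(3, 0.5, size=2000))
    for thr in (5.0, 20.0, 60.0):
        p = threshold_to_percentile(fit, thr)
        assert percentile_to_threshold(fit, p) == pytest.approx(thr, rel=1e-6)


def test_domain_errors(rng):
    fit = fit_best_distribution(rng.lognormal(3, 0.5, size=2000))
    with pytest.raises(ValueError):
        threshold_to_percentile(fit, -1.0)
    with pytest.raises(ValueError):
        percentile_to_threshold(fit, 1.5)


# --------------------------------------------------------------- propagation
def test_self_map_returns_reference_threshold(rng):
    values = rng.lognormal(3, 0.5, size=20_000)
    tmap = propagate_thresholds({"ref": _table(values, "ref")}, "Cell: M max", "ref", 25.0)
    assert tmap.threshold_for("ref") == pytest.approx(25.0, rel=1e-6)


def test_scale_shift_recovers_factor(rng):
    ref = rng.lognormal(3, 0.5, size=20_000)
    c = 1.8
    tables = {"ref": _table(ref, "ref"), "tgt": _table(c * ref, "tgt")}
    thr = float(np.quantile(ref, 0.9))
    tmap = propagate_thresholds(tables, "Cell: M max", "ref", thr)
    assert tmap.threshold_for("tgt") == pytest.approx(c * thr, rel=0.02)
    # positive fractions agree across images
    f_ref = (ref > tmap.threshold_for("ref")).mean()
    f_tgt = (c * ref > tmap.threshold_for("tgt")).mean()
    assert f_tgt == pytest.approx(f_ref, abs=0.005)


def test_propagation_positive_fraction(rng):
    ref = rng.lognormal(3.0, 0.5, size=20_000)
    tgt = rng.lognormal(3.7, 0.6, size=20_000)
    thr = float(stats.lognorm(0.5, scale=np.exp(3.0)).ppf(0.9))  # true 90th pct
    tmap = propagate_thresholds(
        {"ref": _table(ref, "ref"), "tgt": _table(tgt, "tgt")},
        "Cell: M max", "ref", thr,
    )
    frac = (tgt > tmap.threshold_for("tgt")).mean()
    assert frac == pytest.approx(0.10, abs=0.01)


def test_percentile_preservation_invariant(rng):
    tables = {
        "a": _table(rng.lognormal(3, 0.5, 10_000), "a"),
        "b": _table(rng.lognormal(3.5, 0.7, 10_000), "b"),
        "c": _table(rng.gamma(3, 20, 10_000), "c"),
    }
    tmap = propagate_thresholds(tables, "Cell: M max", "a", 22.0)
    for image_id, fit in tmap.fits.items():
        assert fit.cdf(tmap.threshold_for(image_id)) == pytest.approx(
            tmap.percentile, abs=1e-9
        )


def test_missing_reference_raises(rng):
    with pytest.raises(KeyError):
        propagate_thresholds(
            {"a": _table(rng.lognormal(3, 0.5, 100), "a")}, "Cell: M max", "zz", 5.0
        )


def test_fit_failure_names_the_image(rng):
    tables = {
        "good": _table(rng.lognormal(3, 0.5, 1000), "good"),
        "bad": _table(np.full(100, 7.0), "bad"),
    }
    with pytest.raises(RuntimeError, match="bad"):
        propagate_thresholds(tables, "Cell: M max", "good", 20.0)


def test_threshold_map_json_roundtrip(tmp_path, rng):
    tables = {
        "a": _table(rng.lognormal(3, 0.5, 5000), "a"),
        "b": _table(rng.lognormal(3.4, 0.5, 5000), "b"),
    }
    tmap = propagate_thresholds(tables, "Cell: M max", "a", 30.0)
    path = tmp_path / "map.json"
    tmap.to_json(path)
    back = ThresholdMap.from_json(path)
    assert back.percentile == pytest.approx(tmap.percentile)
    assert back.threshold_for("b") == pytest.approx(tmap.threshold_for("b"))
    assert back.fits["b"].family == tmap.fits["b"].family
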