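"""Thickness, intensity ratio, attenuation coefficient and beta fitting."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from octquant import geometry
from octquant.metrics import (AnalysisConfig, fit_beta, intensity_ratio_map,
                              integrated_ratio_map, oiac_from_rd, oiac_map,
                              select_reference_layer, thickness_map)
from octquant.phantom import generate_volume, _smooth_field
from octquant.types import BOUNDARY_NAMES, OCTVolume, SurfaceSet

from conftest import SMALL_VOXEL, planar_spec


def _stack(gaps: list[float], nx: int = 4, ny: int = 3) -> SurfaceSet:
    data = np.zeros((len(BOUNDARY_NAMES), nx, ny))
    data[0] = 20.0
    for k, g in enumerate(gaps):
        data[k + 1] = data[k] + g
    for k in range(len(gaps) + 1, len(BOUNDARY_NAMES)):
        data[k] = data[k - 1] + 5.0
    return SurfaceSet(data)


def test_thickness_is_voxel_count_times_pitch():
    """Ten voxels at the 2.3 μm axial pitch make 23.0 μm."""
    surf = _stack([10.0] * 10)
    t = thickness_map(surf, "RNFL", (11.72, 23.44, 2.3))
    assert np.all(t == pytest.approx(23.0))


def test_coincident_boundaries_give_zero_thickness():
    surf = _stack([0.0] + [8.0] * 9)
    assert np.all(thickness_map(surf, "RNFL", SMALL_VOXEL) == 0.0)


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_gcc_thickness_is_sum_of_parts(seed):
    """GCC = mRNFL + GCIPL exactly, for arbitrary fractional surfaces."""
    rng = np.random.default_rng(seed)
    gaps = rng.uniform(0.0, 12.0, size=(10, 6, 5))
    data = np.cumsum(np.concatenate([np.full((1, 6, 5), 15.0), gaps]), axis=0)
    surf = SurfaceSet(data)
    # voxel counts are exactly additive under the half-open slab convention
    t_gcc = np.subtract(*surf.slab("GCC")[::-1])
    t_sum = (np.subtract(*surf.slab("mRNFL")[::-1])
             + np.subtract(*surf.slab("GCIPL")[::-1]))
    assert np.array_equal(t_gcc, t_sum)
    gcc = thickness_map(surf, "GCC", SMALL_VOXEL)
    parts = (thickness_map(surf, "mRNFL", SMALL_VOXEL)
             + thickness_map(surf, "GCIPL", SMALL_VOXEL))
    np.testing.assert_allclose(gcc, parts, rtol=1e-12)


def test_ratio_of_layer_with_itself_is_one(pit_volume):
    vol, truth = pit_volume
    r = intensity_ratio_map(vol, truth.surfaces, "RPE", "RPE")
    assert np.nanmax(np.abs(r - 1.0)) < 1e-12


def test_ratio_reflects_backscatter_at_zero_attenuation():
    """With no attenuation the intensity ratio equals the backscatter ratio."""
    spec = planar_spec(seed=8, attenuation=dict.fromkeys(
        ("RNFL", "GCL", "IPL", "INL", "OPL", "ONL", "ELM", "ISOS", "OS", "RPE"), 0.0),
        vitreous_attenuation=0.0, speckle_shape=25.0)
    vol, truth = generate_volume(spec)
    r = intensity_ratio_map(vol, truth.surfaces, "ONL", "RPE")
    expected = spec.backscatter["ONL"] / spec.backscatter["RPE"]
    assert np.nanmean(r) == pytest.approx(expected, rel=0.02)


def test_ratio_and_oiac_scale_invariant(pit_volume):
    vol, truth = pit_volume
    half = OCTVolume(intensity=vol.intensity.astype(np.float64) / 2.0,
                     voxel_size=vol.voxel_size, laterality=vol.laterality,
                     quality_score=vol.quality_score)
    r1 = intensity_ratio_map(vol, truth.surfaces, "mRNFL", "RPE")
    r2 = intensity_ratio_map(half, truth.surfaces, "mRNFL", "RPE")
    np.testing.assert_allclose(r1, r2, rtol=1e-12)
    m1 = oiac_map(vol, truth.surfaces, "mRNFL")
    m2 = oiac_map(half, truth.surfaces, "mRNFL")
    np.testing.assert_allclose(m1, m2, rtol=1e-12)


def test_oiac_scalar_oracle():
    """R = 1, beta = 2.3, d = 0.030 mm gives ln(3.3)/0.060 mm^-1."""
    mu = oiac_from_rd(np.array([[1.0]]), np.array([[30.0]]), beta=2.3)
    assert mu[0, 0] == pytest.approx(math.log(3.3) / 0.060, rel=1e-12)
    assert mu[0, 0] == pytest.approx(19.90, abs=0.01)


def test_oiac_zero_ratio_gives_zero():
    mu = oiac_from_rd(np.array([0.0]), np.array([40.0]), beta=2.3)
    assert mu[0] == 0.0


def test_oiac_degenerate_alines_excluded():
    mu = oiac_from_rd(np.array([1.0, np.nan, 1.0]),
                      np.array([0.0, 30.0, 30.0]), beta=2.3)
    assert np.isnan(mu[0]) and np.isnan(mu[1]) and np.isfinite(mu[2])


def test_oiac_monotone_in_r_and_d():
    r = np.linspace(0.1, 4.0, 50)
    mu_r = oiac_from_rd(r, np.full(50, 30.0), beta=2.3)
    assert np.all(np.diff(mu_r) > 0)
    d = np.linspace(10.0, 80.0, 50)
    mu_d = oiac_from_rd(np.full(50, 1.0), d, beta=2.3)
    assert np.all(np.diff(mu_d) < 0)


def test_oiac_recovers_generative_attenuation_noise_free():
    """On a self-consistent noise-free phantom, the formula with a
    truth-calibrated beta inverts the generative model within 2%."""
    rng = np.random.default_rng(0)
    delta = 8.0 * (_smooth_field(48, 24, 0.8, rng) - 1.0)
    spec = planar_spec(seed=9, thickness_delta_maps={"RNFL": delta})
    vol, truth = generate_volume(spec)
    surf = truth.surfaces
    r = integrated_ratio_map(vol, surf, "mRNFL", "RPE")
    d = thickness_map(surf, "mRNFL", vol.voxel_size)
    mu_true = truth.mu_by_layer["RNFL"]
    ok = np.isfinite(r) & (d > 0)
    fit = fit_beta(r[ok], d[ok] / 1000.0, np.full(ok.sum(), mu_true))
    mu = oiac_from_rd(r, d, fit.beta)
    grid = geometry.make_quadrant_grid((23, 11), 5.0, "OD", SMALL_VOXEL, (48, 24))
    vals = geometry.region_values(mu, grid)
    for region, v in vals.items():
        assert abs(v - mu_true) / mu_true < 0.02, region


# ---------------------------------------------------------------------------
# reference-layer table

def _toy_table():
    quality = np.array([60.0, 65.0, 70.0, 75.0, 80.0])
    perfectly_coupled = 100.0 + 2.0 * quality          # r^2 = 1 exactly
    independent = np.array([5.0, 6.0, 6.0, 5.0, 5.5])  # r = 0 by construction
    independent = independent - np.polyval(
        np.polyfit(quality, independent, 1), quality) + 10.0
    df = pd.DataFrame({"coupled": perfectly_coupled, "free": independent})
    return df, quality


def test_r2_limits_zero_and_one():
    df, quality = _toy_table()
    res = select_reference_layer(df, quality, prefer=None)
    assert res.table.loc["coupled", "r2"] == pytest.approx(1.0)
    assert res.table.loc["coupled", "adjusted_variance"] == pytest.approx(0.0)
    assert res.table.loc["free", "r2"] == pytest.approx(0.0, abs=1e-12)
    assert res.table.loc["free", "adjusted_variance"] == pytest.approx(
        res.table.loc["free", "variance"])


def test_adjustment_identities_against_independent_recomputation(rng):
    """adjusted_var = var*(1-r^2), adjusted_sd = sqrt, adjusted_cv = sd/mean,
    with r^2 recomputed independently from OLS residuals."""
    quality = rng.normal(70, 6, size=40)
    df = pd.DataFrame({
        f"L{k}": 1000 + 30 * k + 3 * k * (quality - 70) + rng.normal(0, 25, 40)
        for k in range(1, 5)})
    res = select_reference_layer(df, quality, prefer=None)
    for col in df.columns:
        x = df[col].to_numpy()
        beta = np.polyfit(quality, x, 1)
        resid = x - np.polyval(beta, quality)
        ss_tot = np.sum((x - x.mean()) ** 2)
        r2 = 1.0 - np.sum(resid ** 2) / ss_tot
        row = res.table.loc[col]
        assert row["r2"] == pytest.approx(r2, abs=1e-9)
        assert row["adjusted_variance"] == pytest.approx(
            row["variance"] * (1 - r2), rel=1e-9)
        assert row["adjusted_sd"] == pytest.approx(
            math.sqrt(row["adjusted_variance"]), rel=1e-12)
        assert row["adjusted_cv"] == pytest.approx(
            row["adjusted_sd"] / row["mean"], rel=1e-12)


def test_reference_selection_requires_variation():
    df, quality = _toy_table()
    with pytest.raises(ValueError, match="constant"):
        select_reference_layer(df, np.full(5, 70.0))
    with pytest.raises(ValueError, match="3 subjects"):
        select_reference_layer(df.iloc[:2], quality[:2])


# ---------------------------------------------------------------------------
# beta fitting

def test_single_point_beta_is_algebraic():
    mu, d, r = 4.0, 0.030, 1.7
    fit = fit_beta(np.array([r]), np.array([d]), np.array([mu]))
    assert fit.beta == pytest.approx((math.exp(2 * mu * d) - 1.0) / r, rel=1e-12)


def test_truth_mode_recovers_generating_beta():
    """Data generated by inverting the formula is refit to within 5%."""
    rng = np.random.default_rng(2)
    beta_gen = 2.3
    mu = rng.uniform(2.0, 6.0, size=400)
    d = rng.uniform(0.015, 0.06, size=400)
    r = (np.exp(2.0 * mu * d) - 1.0) / beta_gen
    fit = fit_beta(r, d, mu)
    assert abs(fit.beta - beta_gen) / beta_gen < 0.05
    assert fit.mode == "truth"


def test_decorrelation_mode_on_designed_null():
    """When attenuation and thickness are independent by construction the
    decorrelation objective reaches ~0 at the optimum."""
    rng = np.random.default_rng(3)
    beta_gen = 2.3
    mu = rng.uniform(3.0, 5.0, size=4000)
    d = rng.uniform(0.02, 0.05, size=4000)
    r = (np.exp(2.0 * mu * d) - 1.0) / beta_gen
    fit = fit_beta(r, d)
    assert fit.mode == "decorrelate"
    assert fit.objective < 0.03
    assert len(fit.trace) >= 100


def test_fit_beta_rejects_empty():
    with pytest.raises(ValueError):
        fit_beta(np.array([np.nan]), np.array([0.03]))
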