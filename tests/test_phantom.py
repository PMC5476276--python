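"""Phantom generator: signal model, ground truth and cohort structure."""

import numpy as np
import pytest

from octquant.phantom import (CohortSpec, FoveaSpec, PhantomSpec, SpeckleModel,
                              _subject_draws, build_surfaces, generate_cohort,
                              generate_volume)
from octquant.types import LAYER_NAMES

from conftest import SMALL_GRID, SMALL_VOXEL, planar_spec, small_spec


def test_zero_attenuation_intensity_is_backscatter_times_incident():
    """With mu = 0 everywhere and no speckle, every layer renders as a
    constant block equal to incident intensity times its backscatter."""
    aligned = {  # multiples of the 2.3 μm pitch: boundaries on voxel edges
        "RNFL": 29.9, "GCL": 32.2, "IPL": 29.9, "INL": 29.9, "OPL": 27.6,
        "ONL": 55.2, "ELM": 9.2, "ISOS": 16.1, "OS": 13.8, "RPE": 23.0,
    }
    spec = planar_spec(seed=0, attenuation={l: 0.0 for l in LAYER_NAMES},
                       vitreous_attenuation=0.0, ilm_offset_um=41.4,
                       layer_thicknesses=aligned)
    vol, truth = generate_volume(spec)
    for k, layer in enumerate(LAYER_NAMES):
        top, bot = truth.surfaces.slab(layer, n_z=vol.shape[2])
        t, b = top[0, 0], bot[0, 0]
        block = vol.intensity[:, :, t:b]
        expected = spec.incident_intensity * spec.backscatter[layer]
        assert np.all(block == np.round(expected)), layer


def test_output_shape_and_16bit_range(speckled_volume):
    vol, _ = speckled_volume
    assert vol.shape == SMALL_GRID
    assert vol.intensity.dtype == np.uint16
    assert vol.intensity.max() <= 65535


def test_single_slab_mean_matches_beer_lambert_integral():
    """Mean intensity over an attenuating slab equals the closed-form depth
    integral of the two-way Beer-Lambert profile to within 0.5%."""
    mu = 5.0
    d_um = 230.0  # 100 voxels
    thick = {l: 0.0 for l in LAYER_NAMES}
    thick["ONL"] = d_um
    spec = planar_spec(
        seed=1, layer_thicknesses=thick,
        attenuation={l: (mu if l == "ONL" else 0.0) for l in LAYER_NAMES},
        vitreous_attenuation=0.0, ilm_offset_um=41.4)  # ILM on a voxel boundary
    vol, truth = generate_volume(spec)
    top, bot = truth.surfaces.slab("ONL", n_z=vol.shape[2])
    block = vol.intensity[:, :, top[0, 0]:bot[0, 0]].astype(float)
    d_mm = (bot[0, 0] - top[0, 0]) * SMALL_VOXEL[2] / 1000.0
    # independent oracle: (1/d) * int_0^d I0*b*exp(-2 mu z) dz
    i0b = spec.incident_intensity * spec.backscatter["ONL"]
    expected = i0b * (1.0 - np.exp(-2.0 * mu * d_mm)) / (2.0 * mu * d_mm)
    assert abs(block.mean() - expected) / expected < 0.005


def test_intensity_nonincreasing_with_depth_inside_layer(planar_volume):
    """Two-way attenuation makes the noise-free profile monotone within a
    homogeneous layer."""
    vol, truth = planar_volume
    for layer in ("ONL", "GCL"):
        top, bot = truth.surfaces.slab(layer, n_z=vol.shape[2])
        col = vol.intensity[5, 5, top[5, 5]:bot[5, 5]].astype(float)
        assert np.all(np.diff(col) <= 0)


def test_speckle_preserves_expected_intensity():
    """Unit-mean multiplicative speckle leaves the volume mean unbiased."""
    clean, _ = generate_volume(planar_spec(seed=3))
    noisy, _ = generate_volume(planar_spec(seed=3, speckle_shape=12.0))
    m_clean = clean.intensity.mean()
    m_noisy = noisy.intensity.mean()
    assert abs(m_noisy - m_clean) / m_clean < 0.01


def test_truth_surfaces_ordered_and_consistent_with_thickness(pit_volume):
    _, truth = pit_volume
    assert np.all(np.diff(truth.surfaces.data, axis=0) >= -1e-9)
    z_um = truth.voxel_size[2]
    for k, layer in enumerate(LAYER_NAMES):
        gap = (truth.surfaces.data[k + 1] - truth.surfaces.data[k]) * z_um
        assert np.allclose(gap, truth.thickness_maps[layer], atol=1e-9)


def test_grid_too_small_rejected():
    spec = small_spec()
    spec.grid_shape = (SMALL_GRID[0], SMALL_GRID[1], 60)
    with pytest.raises(ValueError, match="too small"):
        build_surfaces(spec)


def test_invalid_specs_rejected():
    spec = small_spec()
    spec.backscatter["RPE"] = 1.5
    with pytest.raises(ValueError, match="backscatter"):
        spec.validate()
    spec = small_spec()
    spec.attenuation["GCL"] = -1.0
    with pytest.raises(ValueError, match="attenuation"):
        spec.validate()


# ---------------------------------------------------------------------------
# cohorts

def _small_cohort(**kw):
    base = kw.pop("base", small_spec(speckle_shape=12.0))
    return CohortSpec(n_per_group=6, base=base, **kw)


def test_cohort_deterministic_given_seed():
    cs1 = _small_cohort(seed=5)
    cs2 = _small_cohort(seed=5)
    r1 = generate_cohort(cs1, render=True)
    r2 = generate_cohort(cs2, render=True)
    assert len(r1) == len(r2) == 12
    for a, b in zip(r1, r2):
        assert np.array_equal(a.volume.intensity, b.volume.intensity)
        assert np.array_equal(a.truth.surfaces.data, b.truth.surfaces.data)
        assert a.meta == b.meta


def test_null_cohort_groups_are_exchangeable():
    """With all group deltas zero, a subject's generative draw does not
    depend on its group label."""
    cs = _small_cohort(seed=7, thickness_deltas={},
                       attenuation_deltas={"mRNFL": 0.0, "GCIPL": 0.0})
    for s in range(4):
        d_pat = _subject_draws(cs, "patient", np.random.default_rng(s))
        d_ctl = _subject_draws(cs, "control", np.random.default_rng(s))
        assert d_pat[1] == d_ctl[1]          # quality
        assert d_pat[2] == d_ctl[2]          # backscatter
        assert d_pat[3] == d_ctl[3]          # thickness
        assert d_pat[4] == d_ctl[4]          # attenuation


def test_nasal_thinning_delta_recovered_in_truth():
    """A -5 μm nasal mRNFL delta with 3 μm between-subject SD shows up in
    the realized true nasal thickness difference within 2 SE."""
    from octquant import geometry

    n = 20
    delta = -5.0
    sd = 3.0
    base = small_spec(speckle_shape=None, pit=False)
    cs = CohortSpec(
        n_per_group=n, base=base, seed=21,
        thickness_deltas={"mRNFL": {"SN": delta, "IN": delta, "ST": 0.0, "IT": 0.0}},
        attenuation_deltas={}, thickness_sd={"mRNFL": sd, "GCIPL": 0.0, "outer": 0.0})
    records = generate_cohort(cs, render=False)
    nasal = {"patient": [], "control": []}
    for rec in records:
        grid = geometry.make_quadrant_grid(
            rec.truth.fovea_index, 5.0, rec.meta.laterality, SMALL_VOXEL,
            rec.truth.surfaces.grid_shape)
        vals = geometry.region_values(rec.truth.analysis_thickness("mRNFL"), grid)
        nasal[rec.meta.group].append(0.5 * (vals["SN"] + vals["IN"]))
    diff = np.mean(nasal["patient"]) - np.mean(nasal["control"])
    se = sd * np.sqrt(2.0 / n)
    # quadrant-edge smoothing shaves a little off the plateau delta
    assert abs(diff - delta) < 2.0 * se + 0.8


def test_negative_delta_clamped_and_flagged():
    base = small_spec(speckle_shape=None, pit=False)
    cs = CohortSpec(
        n_per_group=2, base=base, seed=3,
        thickness_deltas={"mRNFL": {"SN": -60.0, "IN": -60.0, "ST": 0.0, "IT": 0.0}},
        thickness_sd={"mRNFL": 0.0, "GCIPL": 0.0, "outer": 0.0})
    records = generate_cohort(cs, render=False)
    patients = [r for r in records if r.meta.group == "patient"]
    assert any("clamped" in w for r in patients for w in r.warnings)
    for r in patients:
        assert r.truth.thickness_maps["RNFL"].min() >= SMALL_VOXEL[2] - 1e-9
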