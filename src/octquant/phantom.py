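"""Layered speckle phantom for 3D SD-OCT.

The generator emulates the statistical structure the quantification pipeline
assumes: a stack of ten retinal layers tiling each A-line between vitreous
above and a rapidly attenuated sub-RPE region below, a two-way Beer–Lambert
backscatter signal, multiplicative unit-mean Gamma speckle, a foveal pit
that thins the inner layers to near zero, parabolic axial bowing, and a
scanner-style quality score coupled to per-layer intensities so the
reference-layer selection procedure has designed structure to recover.

The noise-free expected intensity of a voxel centered at depth z inside
layer l is::

    I(z) = I0 * b_l * exp(-2 * integral_0^z mu(z') dz')

with ``b_l`` the layer's backscatter fraction, ``mu`` in mm^-1 and the
factor 2 for the two-way light path. Speckle multiplies this by a
Gamma(k, 1/k) variate per voxel (unit mean, so expected intensity is
unbiased); the result is clipped to the 16-bit range and quantized.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .types import LAYER_NAMES, OCTVolume, PhantomTruth, SubjectMeta, SurfaceSet

# Desk-scale defaults keep the instrument's 6x6 mm field of view at a
# coarser transverse pitch; the axial pitch stays at 2.3 um because all
# thickness arithmetic is expressed in it.
DEFAULT_GRID = (128, 64, 256)
DEFAULT_VOXEL_UM = (46.88, 93.76, 2.3)
FULL_GRID = (512, 256, 992)
FULL_VOXEL_UM = (11.72, 23.44, 2.3)

#: Nominal layer thicknesses (μm), summing to a plausible macular retina.
DEFAULT_THICKNESS_UM = {
    "RNFL": 30.0, "GCL": 32.0, "IPL": 30.0, "INL": 30.0, "OPL": 28.0,
    "ONL": 55.0, "ELM": 9.0, "ISOS": 15.0, "OS": 14.0, "RPE": 23.0,
}

#: Per-layer attenuation (mm^-1) on the physically plausible retinal scale
#: (nerve fiber layer strongly scattering, nuclear layers weak, RPE highest).
DEFAULT_MU = {
    "RNFL": 4.0, "GCL": 2.2, "IPL": 2.2, "INL": 1.8, "OPL": 2.2,
    "ONL": 0.9, "ELM": 2.5, "ISOS": 3.5, "OS": 3.0, "RPE": 7.0,
}

#: Backscatter fractions; RPE brightest, vitreous darkest, with the usual
#: bright/dark alternation that gives every boundary a signed edge.
DEFAULT_BACKSCATTER = {
    "RNFL": 0.50, "GCL": 0.30, "IPL": 0.38, "INL": 0.25, "OPL": 0.35,
    "ONL": 0.18, "ELM": 0.42, "ISOS": 0.60, "OS": 0.45, "RPE": 0.75,
}

VITREOUS_BACKSCATTER = 0.02
VITREOUS_MU = 0.01
SUBRPE_BACKSCATTER = 0.30
SUBRPE_MU = 30.0  # rapid decay below Bruch's membrane


@dataclass
class FoveaSpec:
    """Foveal pit geometry: offset of the pit center from the scan center
    (mm), total inner-layer thinning at the center (μm) and the radius (mm)
    at which the thinning has fallen to half."""

    center_offset_mm: tuple[float, float] = (0.0, 0.0)
    pit_depth_um: float = 85.0
    pit_radius_mm: float = 0.6


@dataclass
class SpeckleModel:
    """Multiplicative unit-mean Gamma speckle; ``shape=None`` disables it.

    Larger shape means milder speckle (SNR ~ sqrt(shape))."""

    family: str = "gamma"
    shape: float | None = 12.0

    def __post_init__(self) -> None:
        if self.family != "gamma":
            raise ValueError("only the gamma speckle family is implemented")
        if self.shape is not None and self.shape <= 0:
            raise ValueError("speckle shape must be positive")


@dataclass
class QualityModel:
    """Scanner-style quality score and its coupling to layer intensities.

    The score is a deterministic map of the speckle shape k,
    ``q = intercept + slope * ln(k)`` clipped to [0, 100]; per-layer
    backscatter is modulated by ``1 + coupling_l * (q - q_ref)`` plus an
    independent relative jitter ``independent_sd_l`` per subject. The layer
    with near-zero coupling and the smallest jitter is the designed
    quality-independent reference layer.
    """

    intercept: float = 45.0
    slope: float = 10.0
    q_ref: float = 70.0
    coupling: dict[str, float] = field(default_factory=lambda: {
        **{layer: 0.004 for layer in LAYER_NAMES},
        "RPE": 0.0005, "vitreous": 0.001,
    })
    independent_sd: dict[str, float] = field(default_factory=lambda: {
        **{layer: 0.02 for layer in LAYER_NAMES},
        "RPE": 0.006, "vitreous": 0.012,
    })

    def score(self, speckle_shape: float | None) -> float:
        if speckle_shape is None:
            return 100.0
        return float(np.clip(self.intercept + self.slope * np.log(speckle_shape),
                             0.0, 100.0))


@dataclass
class PhantomSpec:
    """Full parameterization of one synthetic volume."""

    grid_shape: tuple[int, int, int] = DEFAULT_GRID
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_UM
    layer_thicknesses: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THICKNESS_UM))
    fovea: FoveaSpec = field(default_factory=FoveaSpec)
    curvature_um: float = 25.0
    attenuation: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MU))
    backscatter: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BACKSCATTER))
    vitreous_backscatter: float = VITREOUS_BACKSCATTER
    vitreous_attenuation: float = VITREOUS_MU
    incident_intensity: float = 40000.0
    speckle: SpeckleModel = field(default_factory=SpeckleModel)
    quality_model: QualityModel = field(default_factory=QualityModel)
    laterality: str = "OD"
    ilm_offset_um: float = 80.0
    thickness_ripple_frac: float = 0.03  # gentle smooth spatial variation
    seed: int = 0
    #: optional per-layer additive thickness maps (μm), e.g. quadrant effects
    thickness_delta_maps: dict[str, np.ndarray] | None = None

    def validate(self) -> None:
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        for layer in LAYER_NAMES:
            if self.layer_thicknesses.get(layer, 0.0) < 0:
                raise ValueError(f"negative thickness for {layer}")
            mu = self.attenuation.get(layer, 0.0)
            if mu < 0:
                raise ValueError(f"negative attenuation for {layer}")
            b = self.backscatter.get(layer)
            if b is None or not (0 < b <= 1):
                raise ValueError(f"backscatter for {layer} must be in (0, 1]")
        if self.laterality not in ("OD", "OS"):
            raise ValueError("laterality must be 'OD' or 'OS'")
        if self.incident_intensity <= 0:
            raise ValueError("incident_intensity must be positive")


# ---------------------------------------------------------------------------
# surface construction

def _smooth_field(nx: int, ny: int, amplitude: float, rng: np.random.Generator
                  ) -> np.ndarray:
    """Low-frequency multiplicative ripple in [1-a, 1+a]."""
    if amplitude <= 0:
        return np.ones((nx, ny))
    px, py = rng.uniform(0, 2 * np.pi, size=2)
    x = np.linspace(0, 2 * np.pi, nx)[:, None]
    y = np.linspace(0, 2 * np.pi, ny)[None, :]
    f = np.sin(x + px) * np.cos(0.7 * y + py) + 0.5 * np.sin(1.3 * y + px)
    return 1.0 + amplitude * f / 1.5


def build_surfaces(spec: PhantomSpec, rng: np.random.Generator | None = None
                   ) -> tuple[SurfaceSet, dict[str, np.ndarray]]:
    """Construct the 11 true boundaries (fractional voxels) and per-layer
    thickness maps (μm) implied by a spec."""
    spec.validate()
    rng = rng or np.random.default_rng(spec.seed)
    nx, ny, nz = spec.grid_shape
    vx, vy, vz = spec.voxel_size

    # en-face coordinates (mm) relative to the pit center
    cx = (nx - 1) / 2 + spec.fovea.center_offset_mm[0] * 1000.0 / vx
    cy = (ny - 1) / 2 + spec.fovea.center_offset_mm[1] * 1000.0 / vy
    x_mm = (np.arange(nx)[:, None] - cx) * vx / 1000.0
    y_mm = (np.arange(ny)[None, :] - cy) * vy / 1000.0
    r2 = x_mm**2 + y_mm**2

    thickness = {}
    for layer in LAYER_NAMES:
        base = spec.layer_thicknesses.get(layer, 0.0)
        t = base * _smooth_field(nx, ny, spec.thickness_ripple_frac, rng)
        if spec.thickness_delta_maps and layer in spec.thickness_delta_maps:
            # deltas may not erase a layer: clamp at one voxel
            t = np.clip(t + spec.thickness_delta_maps[layer], vz, None)
        thickness[layer] = np.clip(t, 0.0, None)

    # foveal pit: remove pit_depth_um from RNFL+GCL+IPL with a Gaussian
    # radial profile whose value halves at pit_radius_mm
    if spec.fovea.pit_depth_um > 0:
        sigma2 = spec.fovea.pit_radius_mm**2 / (2 * np.log(2.0))
        dip = spec.fovea.pit_depth_um * np.exp(-r2 / (2 * sigma2))
        inner_total = thickness["RNFL"] + thickness["GCL"] + thickness["IPL"]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.clip(np.where(inner_total > 0, dip / inner_total, 0.0), 0.0, 0.98)
        for layer in ("RNFL", "GCL", "IPL"):
            thickness[layer] = thickness[layer] * (1.0 - frac)

    # parabolic axial bowing of the whole stack (deeper at the periphery)
    rim2 = max(float(r2.max()), 1e-9)
    ilm = (spec.ilm_offset_um + spec.curvature_um * r2 / rim2) / vz

    data = np.empty((11, nx, ny))
    data[0] = ilm
    for k, layer in enumerate(LAYER_NAMES):
        data[k + 1] = data[k] + thickness[layer] / vz
    if float(np.ceil(data[-1]).max()) >= nz:
        raise ValueError(
            f"grid depth {nz} too small to contain all layers "
            f"(deepest boundary at voxel {float(data[-1].max()):.1f}); "
            "enlarge grid_shape[2] or reduce thicknesses/offset")
    return SurfaceSet(data), thickness


# ---------------------------------------------------------------------------
# rendering

def _render(spec: PhantomSpec, surfaces: SurfaceSet,
            rng: np.random.Generator) -> np.ndarray:
    nx, ny, nz = spec.grid_shape
    dz_mm = spec.voxel_size[2] / 1000.0
    zc = np.arange(nz) + 0.5  # voxel centers, fractional voxel units

    mus = np.array([spec.vitreous_attenuation]
                   + [spec.attenuation.get(l, 0.0) for l in LAYER_NAMES] + [SUBRPE_MU])
    bs = np.array([spec.vitreous_backscatter]
                  + [spec.backscatter[l] for l in LAYER_NAMES] + [SUBRPE_BACKSCATTER])

    # region bounds (fractional voxels): vitreous, 10 layers, sub-RPE
    lowers = np.concatenate([np.zeros((1, nx, ny)), surfaces.data])
    uppers = np.concatenate([surfaces.data, np.full((1, nx, ny), float(nz))])

    # two-way optical depth at each voxel center (analytic path integral)
    od = np.zeros((nx, ny, nz))
    for r in range(12):
        if mus[r] == 0:
            continue
        lo = lowers[r][:, :, None]
        hi = uppers[r][:, :, None]
        seg = np.clip(np.minimum(zc[None, None, :], hi) - lo, 0.0, None)
        od += mus[r] * seg * dz_mm
    signal = spec.incident_intensity * np.exp(-2.0 * od)

    # voxel-to-region assignment under the half-open ceil slab convention
    cs = np.clip(np.ceil(surfaces.data).astype(np.int64), 0, nz)
    region = np.zeros((nx, ny, nz), dtype=np.int8)
    z_idx = np.arange(nz)
    for k in range(11):
        region += (z_idx[None, None, :] >= cs[k][:, :, None]).astype(np.int8)
    signal *= bs[region]

    if spec.speckle.shape is not None:
        signal *= rng.gamma(spec.speckle.shape, 1.0 / spec.speckle.shape,
                            size=signal.shape)
    return np.rint(np.clip(signal, 0.0, 65535.0)).astype(np.uint16)


def generate_volume(spec: PhantomSpec,
                    rng: np.random.Generator | None = None
                    ) -> tuple[OCTVolume, PhantomTruth]:
    """Render one synthetic volume together with its exact ground truth."""
    spec.validate()
    rng = rng or np.random.default_rng(spec.seed)
    surfaces, thickness = build_surfaces(spec, rng)
    intensity = _render(spec, surfaces, rng)
    quality = spec.quality_model.score(spec.speckle.shape)
    nx, ny, _ = spec.grid_shape
    cx = (nx - 1) / 2 + spec.fovea.center_offset_mm[0] * 1000.0 / spec.voxel_size[0]
    cy = (ny - 1) / 2 + spec.fovea.center_offset_mm[1] * 1000.0 / spec.voxel_size[1]
    volume = OCTVolume(intensity=intensity, voxel_size=spec.voxel_size,
                       laterality=spec.laterality, quality_score=quality)
    truth = PhantomTruth(
        surfaces=surfaces,
        mu_by_layer={l: float(spec.attenuation.get(l, 0.0)) for l in LAYER_NAMES},
        backscatter_by_layer={**{l: float(spec.backscatter[l]) for l in LAYER_NAMES},
                              "vitreous": float(spec.vitreous_backscatter)},
        thickness_maps=thickness,
        quality_score=quality,
        incident_intensity=spec.incident_intensity,
        voxel_size=spec.voxel_size,
        fovea_index=(cx, cy),
    )
    return volume, truth


# ---------------------------------------------------------------------------
# analytic expectations (used by fast cohort paths and tests)

def expected_layer_means(spec: PhantomSpec,
                         backscatter: dict[str, float] | None = None
                         ) -> dict[str, float]:
    """Noise-free expected mean intensity per candidate reference layer for a
    flat stack at the spec's nominal thicknesses (pit and ripple ignored).

    Exact for the continuous Beer–Lambert profile; the rendered voxelized
    volume matches to midpoint-rule accuracy.
    """
    b = dict(spec.backscatter if backscatter is None else backscatter)
    b.setdefault("vitreous", spec.vitreous_backscatter)
    i0 = spec.incident_intensity
    out: dict[str, float] = {}
    # vitreous: thin attenuation above, essentially i0 * b
    d_vit_mm = spec.ilm_offset_um / 1000.0
    mu_vit = spec.vitreous_attenuation
    out["vitreous"] = i0 * b["vitreous"] * _mean_decay(mu_vit, d_vit_mm)
    trans = np.exp(-2 * mu_vit * d_vit_mm)
    means = {}
    for layer in LAYER_NAMES:
        mu = spec.attenuation.get(layer, 0.0)
        d_mm = spec.layer_thicknesses.get(layer, 0.0) / 1000.0
        means[layer] = i0 * b[layer] * trans * _mean_decay(mu, d_mm)
        trans *= np.exp(-2 * mu * d_mm)
    out.update(means)
    d_gcl = spec.layer_thicknesses.get("GCL", 0.0)
    d_ipl = spec.layer_thicknesses.get("IPL", 0.0)
    tot = d_gcl + d_ipl
    out["GCIPL"] = ((means["GCL"] * d_gcl + means["IPL"] * d_ipl) / tot
                    if tot > 0 else float("nan"))
    return out


def _mean_decay(mu: float, d_mm: float) -> float:
    """Depth-average of exp(-2 mu z) over a slab of length d."""
    if d_mm <= 0:
        return 1.0
    x = 2.0 * mu * d_mm
    return 1.0 if x < 1e-12 else float((1.0 - np.exp(-x)) / x)


# ---------------------------------------------------------------------------
# cohorts

#: Patient-group per-quadrant thickness deltas (μm): nasal-predominant
#: thinning of the inner layers, on the scale the study reports.
DEFAULT_THICKNESS_DELTAS = {
    "mRNFL": {"SN": -4.2, "IN": -5.1, "ST": -1.5, "IT": -1.3},
    "GCIPL": {"SN": -2.3, "IN": -2.8, "ST": -0.1, "IT": 0.1},
}
#: Patient-group attenuation deltas (mm^-1): a smaller optical effect.
DEFAULT_ATTENUATION_DELTAS = {"mRNFL": 0.18, "GCIPL": 0.01}
#: Between-subject SDs of global layer thickness (μm) and attenuation (mm^-1).
DEFAULT_THICKNESS_SD = {"mRNFL": 3.8, "GCIPL": 4.8, "outer": 7.0}
DEFAULT_ATTENUATION_SD = {"mRNFL": 0.38, "GCIPL": 0.27}


@dataclass
class CohortSpec:
    """Two-group study generator: patients carry thickness/attenuation deltas."""

    n_per_group: int = 20
    base: PhantomSpec = field(default_factory=PhantomSpec)
    thickness_deltas: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_THICKNESS_DELTAS.items()})
    attenuation_deltas: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ATTENUATION_DELTAS))
    thickness_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THICKNESS_SD))
    attenuation_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ATTENUATION_SD))
    speckle_log_sd: float = 0.65  # subject-to-subject spread of ln(speckle shape)
    age_mean: dict[str, float] = field(
        default_factory=lambda: {"patient": 44.7, "control": 40.8})
    age_sd: dict[str, float] = field(
        default_factory=lambda: {"patient": 13.8, "control": 11.9})
    male_fraction: dict[str, float] = field(
        default_factory=lambda: {"patient": 0.55, "control": 0.49})
    od_fraction: float = 0.35
    n_control: int | None = None  # unequal groups (study has 38 vs 39)
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for d in (self.thickness_sd, self.attenuation_sd):
            if any(v < 0 for v in d.values()):
                raise ValueError("between-subject SDs must be >= 0")
        self.base.validate()


_GROUP_LAYERS = {"mRNFL": ("RNFL",), "GCIPL": ("GCL", "IPL"),
                 "outer": ("INL", "OPL", "ONL", "ELM", "ISOS", "OS", "RPE")}


@dataclass
class SubjectRecord:
    volume: OCTVolume | None
    truth: PhantomTruth
    meta: SubjectMeta
    warnings: list[str] = field(default_factory=list)


def _subject_draws(cohort: CohortSpec, group: str, rng: np.random.Generator):
    """Sample one subject's generative parameters (no rendering)."""
    base = cohort.base
    qm = base.quality_model
    shape = float(np.exp(np.log(base.speckle.shape if base.speckle.shape else 12.0)
                         + cohort.speckle_log_sd * rng.standard_normal()))
    quality = qm.score(shape)

    backscatter = {}
    for layer in list(LAYER_NAMES) + ["vitreous"]:
        b0 = (base.vitreous_backscatter if layer == "vitreous"
              else base.backscatter[layer])
        c = qm.coupling.get(layer, 0.0)
        sd = qm.independent_sd.get(layer, 0.0)
        b = b0 * (1.0 + c * (quality - qm.q_ref) + sd * rng.standard_normal())
        backscatter[layer] = float(np.clip(b, 0.005, 1.0))

    # global between-subject thickness offsets shared within a layer group,
    # split across anatomical layers proportionally to nominal thickness
    thickness = dict(base.layer_thicknesses)
    clamped = []
    for grp, layers in _GROUP_LAYERS.items():
        sd = cohort.thickness_sd.get(grp, 0.0)
        off = sd * rng.standard_normal()
        tot = sum(base.layer_thicknesses[l] for l in layers)
        for l in layers:
            if tot > 0:
                thickness[l] = thickness[l] + off * base.layer_thicknesses[l] / tot

    mu = dict(base.attenuation)
    for grp, layers in (("mRNFL", ("RNFL",)), ("GCIPL", ("GCL", "IPL"))):
        off = cohort.attenuation_sd.get(grp, 0.0) * rng.standard_normal()
        delta = cohort.attenuation_deltas.get(grp, 0.0) if group == "patient" else 0.0
        for l in layers:
            mu[l] = max(0.0, mu[l] + off + delta)

    laterality = "OD" if rng.random() < cohort.od_fraction else "OS"
    age = float(np.clip(cohort.age_mean[group]
                        + cohort.age_sd[group] * rng.standard_normal(), 8.0, 90.0))
    sex = "M" if rng.random() < cohort.male_fraction[group] else "F"
    return shape, quality, backscatter, thickness, mu, laterality, age, sex, clamped


def _quadrant_delta_maps(cohort: CohortSpec, laterality: str
                         ) -> dict[str, np.ndarray]:
    """Per-layer additive thickness maps implementing per-quadrant deltas,
    smoothed so the segmenter never sees step edges."""
    base = cohort.base
    nx, ny, _ = base.grid_shape
    vx, vy = base.voxel_size[0], base.voxel_size[1]
    cx = (nx - 1) / 2 + cohort.base.fovea.center_offset_mm[0] * 1000.0 / vx
    cy = (ny - 1) / 2 + cohort.base.fovea.center_offset_mm[1] * 1000.0 / vy
    dx = np.arange(nx)[:, None] - cx
    dy = np.arange(ny)[None, :] - cy
    nasal = (dx > 0) if laterality == "OD" else (dx < 0)
    superior = dy > 0
    quad_masks = {
        "SN": nasal & superior, "IN": nasal & ~superior,
        "ST": ~nasal & superior, "IT": ~nasal & ~superior,
    }
    out: dict[str, np.ndarray] = {}
    for grp, deltas in cohort.thickness_deltas.items():
        layers = _GROUP_LAYERS.get(grp, (grp,))
        m = np.zeros((nx, ny))
        for q, d in deltas.items():
            m[quad_masks[q]] = d
        m = gaussian_filter(m, sigma=(2.0, 2.0), mode="nearest")
        tot = sum(cohort.base.layer_thicknesses.get(l, 0.0) for l in layers)
        for l in layers:
            w = cohort.base.layer_thicknesses.get(l, 0.0) / tot if tot > 0 else 0.0
            out[l] = out.get(l, 0.0) + m * w
    return out


def generate_cohort(cohort: CohortSpec, render: bool = True) -> list[SubjectRecord]:
    """Generate a two-group cohort; deterministic given ``cohort.seed``.

    With ``render=False`` only ground truth and metadata are produced
    (surfaces, thickness maps, generative parameters) — the fast path for
    statistical studies that quantify from truth surfaces.
    """
    cohort.validate()
    n_ctrl = cohort.n_control if cohort.n_control is not None else cohort.n_per_group
    groups = (["patient"] * cohort.n_per_group + ["control"] * n_ctrl)
    seeds = np.random.SeedSequence(cohort.seed).spawn(len(groups))
    records: list[SubjectRecord] = []
    counters = {"patient": 0, "control": 0}
    z_um = cohort.base.voxel_size[2]
    for group, ss in zip(groups, seeds):
        rng = np.random.default_rng(ss)
        counters[group] += 1
        sid = f"{'P' if group == 'patient' else 'C'}{counters[group]:03d}"
        (shape, quality, backscatter, thickness, mu,
         laterality, age, sex, warn) = _subject_draws(cohort, group, rng)

        delta_maps = (_quadrant_delta_maps(cohort, laterality)
                      if group == "patient" and cohort.thickness_deltas else None)
        spec = dataclasses.replace(
            cohort.base,
            layer_thicknesses=thickness,
            attenuation=mu,
            backscatter={l: backscatter[l] for l in LAYER_NAMES},
            vitreous_backscatter=backscatter["vitreous"],
            speckle=SpeckleModel(shape=shape if cohort.base.speckle.shape else None),
            laterality=laterality,
            thickness_delta_maps=delta_maps,
        )
        # layers driven negative by deltas are clamped at one voxel (flagged)
        if delta_maps:
            for l, dm in delta_maps.items():
                if np.min(thickness[l] + dm) < z_um:
                    warn = warn + [f"{l} thickness clamped at 1 voxel after delta"]
        child = ss.spawn(2)
        surfaces, tmaps = build_surfaces(spec, np.random.default_rng(child[0]))
        truth = PhantomTruth(
            surfaces=surfaces,
            mu_by_layer={l: float(mu[l]) for l in LAYER_NAMES},
            backscatter_by_layer=backscatter,
            thickness_maps=tmaps,
            quality_score=quality,
            incident_intensity=spec.incident_intensity,
            voxel_size=spec.voxel_size,
            fovea_index=((spec.grid_shape[0] - 1) / 2, (spec.grid_shape[1] - 1) / 2),
        )
        volume = None
        if render:
            intensity = _render(spec, surfaces, np.random.default_rng(child[1]))
            volume = OCTVolume(intensity=intensity, voxel_size=spec.voxel_size,
                               laterality=laterality, quality_score=quality,
                               subject_id=sid)
        meta = SubjectMeta(subject_id=sid, group=group, age=age, sex=sex,
                           laterality=laterality, quality_score=quality)
        records.append(SubjectRecord(volume=volume, truth=truth, meta=meta,
                                     warnings=warn))
    return records


def cohort_intensity_table(cohort: CohortSpec) -> pd.DataFrame:
    """Per-subject expected mean layer intensities and quality scores.

    Analytic fast path (no volume rendering) for reference-layer selection
    studies; one row per subject, one column per candidate layer plus
    ``quality`` and ``group``.
    """
    cohort.validate()
    n_ctrl = cohort.n_control if cohort.n_control is not None else cohort.n_per_group
    groups = (["patient"] * cohort.n_per_group + ["control"] * n_ctrl)
    seeds = np.random.SeedSequence(cohort.seed).spawn(len(groups))
    rows = []
    for group, ss in zip(groups, seeds):
        rng = np.random.default_rng(ss)
        shape, quality, backscatter, thickness, mu, *_ = _subject_draws(
            cohort, group, rng)
        spec = dataclasses.replace(cohort.base, layer_thicknesses=thickness,
                                   attenuation=mu)
        means = expected_layer_means(spec, backscatter=backscatter)
        rows.append({**means, "quality": quality, "group": group})
    return pd.DataFrame(rows)
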