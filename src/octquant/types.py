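"""Core domain containers for 3D SD-OCT quantification.

Conventions used throughout the package:

* Volumes are indexed ``intensity[x, y, z]`` with ``x`` the fast-scan axis
  (A-lines within a B-scan), ``y`` the slow-scan axis (B-scan index) and
  ``z`` depth, increasing from vitreous to choroid.
* Intensities are raw arbitrary units (AU) on the 16-bit scale [0, 65535].
* Surface depths are stored in fractional voxel units (0-based), not μm,
  so segmentations exchange cleanly between resolutions.
* A layer slab between boundaries ``a`` (top) and ``b`` (bottom) occupies
  the half-open voxel range ``[ceil(a), ceil(b))`` along z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The eleven segmented boundaries, ordered from vitreous to choroid.
BOUNDARY_NAMES: tuple[str, ...] = (
    "ILM",       # inner limiting membrane
    "RNFL_GCL",  # nerve fiber layer / ganglion cell layer
    "GCL_IPL",   # ganglion cell layer / inner plexiform layer
    "IPL_INL",   # inner plexiform / inner nuclear
    "INL_OPL",   # inner nuclear / outer plexiform
    "OPL_ONL",   # outer plexiform / outer nuclear
    "ONL_ELM",   # outer nuclear / external limiting membrane
    "ELM_ISOS",  # ELM / inner-outer segment junction
    "ISOS_OS",   # IS/OS junction / outer segments
    "OS_RPE",    # outer segments / retinal pigment epithelium
    "BM",        # Bruch's membrane (outer RPE boundary)
)

#: The ten anatomical layers delimited by consecutive boundaries.
LAYER_NAMES: tuple[str, ...] = (
    "RNFL", "GCL", "IPL", "INL", "OPL", "ONL", "ELM", "ISOS", "OS", "RPE",
)

#: Composite layers analyzed by the pipeline, as (top, bottom) boundary names.
ANALYSIS_LAYERS: dict[str, tuple[str, str]] = {
    "mRNFL": ("ILM", "RNFL_GCL"),
    "GCIPL": ("RNFL_GCL", "IPL_INL"),
    "GCC": ("ILM", "IPL_INL"),
    "total_retina": ("ILM", "BM"),
}

#: Candidate reference layers for intensity normalization (single slabs plus
#: the merged GCIPL and the vitreous above the ILM).
REFERENCE_CANDIDATES: tuple[str, ...] = (
    "vitreous", "RNFL", "GCIPL", "INL", "OPL", "ONL", "ELM", "ISOS", "OS", "RPE",
)

INTENSITY_MAX = 65535.0


def layer_boundaries(layer: str) -> tuple[str, str]:
    """Resolve a layer name to its (top, bottom) boundary names.

    Accepts the ten anatomical layer names, the composite analysis layers
    (mRNFL, GCIPL, GCC, total_retina) and ``"vitreous"`` (everything above
    the ILM, whose top is reported as ``None``-like boundary ``"TOP"``).
    """
    if layer in ANALYSIS_LAYERS:
        return ANALYSIS_LAYERS[layer]
    if layer in LAYER_NAMES:
        i = LAYER_NAMES.index(layer)
        return BOUNDARY_NAMES[i], BOUNDARY_NAMES[i + 1]
    if layer == "vitreous":
        return "TOP", "ILM"
    raise KeyError(f"unknown layer {layer!r}")


@dataclass
class OCTVolume:
    """A 3D SD-OCT intensity volume plus acquisition metadata.

    Parameters
    ----------
    intensity
        ``(n_x, n_y, n_z)`` array of raw AU values in [0, 65535].
    voxel_size
        Voxel pitch ``(x, y, z)`` in μm.
    laterality
        ``"OD"`` (right eye) or ``"OS"`` (left eye).
    quality_score
        Scanner-reported image quality index (0–100 scale).
    subject_id
        Identifier carried into all derived records.
    pad_mask
        Optional boolean array marking voxels filled during flattening;
        padded voxels are excluded from intensity statistics.
    """

    intensity: np.ndarray
    voxel_size: tuple[float, float, float]
    laterality: str
    quality_score: float
    subject_id: str = "anon"
    pad_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be a 3D (x, y, z) array")
        if self.laterality not in ("OD", "OS"):
            raise ValueError(f"laterality must be 'OD' or 'OS', got {self.laterality!r}")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError("voxel_size must be three positive values (μm)")
        self.voxel_size = vs
        lo = float(self.intensity.min()) if self.intensity.size else 0.0
        hi = float(self.intensity.max()) if self.intensity.size else 0.0
        if lo < 0 or hi > INTENSITY_MAX:
            raise ValueError("intensities must lie in [0, 65535]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape  # type: ignore[return-value]

    def enface_extent_mm(self) -> tuple[float, float]:
        """Transverse field of view (x, y) in mm."""
        nx, ny, _ = self.shape
        return nx * self.voxel_size[0] / 1000.0, ny * self.voxel_size[1] / 1000.0


class SurfaceSet:
    """Eleven ordered boundary depth maps (fractional voxels) per A-line.

    ``data`` has shape ``(11, n_x, n_y)``; ``data[k, x, y]`` is the depth of
    boundary ``BOUNDARY_NAMES[k]`` on that A-line. Boundaries must be
    non-crossing: ``data[k] <= data[k+1]`` everywhere.
    """

    def __init__(self, data: np.ndarray, names: tuple[str, ...] = BOUNDARY_NAMES,
                 validate: bool = True):
        data = np.asarray(data, dtype=float)
        if data.ndim != 3 or data.shape[0] != len(names):
            raise ValueError(
                f"surface data must have shape ({len(names)}, n_x, n_y), got {data.shape}")
        self.data = data
        self.names = tuple(names)
        if validate:
            self.validate()

    def validate(self, n_z: int | None = None) -> None:
        diff = np.diff(self.data, axis=0)
        if np.any(diff < -1e-9):
            k, x, y = np.argwhere(diff < -1e-9)[0]
            raise ValueError(
                f"surfaces cross: {self.names[k + 1]} above {self.names[k]} "
                f"at A-line (x={x}, y={y})")
        if np.any(self.data < -1e-9):
            raise ValueError("surface depths must be non-negative")
        if n_z is not None and np.any(self.data > n_z):
            raise ValueError(f"surface depths exceed grid depth {n_z}")

    def boundary(self, name: str) -> np.ndarray:
        """Depth map (n_x, n_y) for one named boundary."""
        try:
            return self.data[self.names.index(name)]
        except ValueError:
            raise KeyError(f"unknown boundary {name!r}") from None

    def slab(self, layer: str, n_z: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Half-open voxel index range [top, bot) for a layer on every A-line."""
        top_name, bot_name = layer_boundaries(layer)
        top = (np.zeros(self.data.shape[1:]) if top_name == "TOP"
               else np.ceil(self.boundary(top_name)))
        bot = np.ceil(self.boundary(bot_name))
        top = top.astype(np.int64)
        bot = bot.astype(np.int64)
        if n_z is not None:
            top = np.clip(top, 0, n_z)
            bot = np.clip(bot, 0, n_z)
        return top, bot

    def shifted(self, shift: np.ndarray) -> "SurfaceSet":
        """Return a copy with every boundary moved by a per-A-line z offset.

        Uniform per-A-line shifts preserve non-crossing by construction;
        boundaries may leave the grid (content rolled out during
        flattening), which ``slab`` handles by clipping.
        """
        return SurfaceSet(self.data + np.asarray(shift)[None, :, :], self.names,
                          validate=False)

    def copy(self) -> "SurfaceSet":
        return SurfaceSet(self.data.copy(), self.names, validate=False)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, SurfaceSet) and self.names == other.names
                and np.array_equal(self.data, other.data))


@dataclass
class SubjectMeta:
    """Per-subject study metadata."""

    subject_id: str
    group: str  # "patient" | "control"
    age: float
    sex: str  # "M" | "F"
    laterality: str  # "OD" | "OS"
    quality_score: float

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ValueError(f"group must be 'patient' or 'control', got {self.group!r}")
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.laterality not in ("OD", "OS"):
            raise ValueError("laterality must be 'OD' or 'OS'")


@dataclass
class PhantomTruth:
    """Ground truth recorded by the phantom generator for recovery tests."""

    surfaces: SurfaceSet
    mu_by_layer: dict[str, float]           # attenuation, mm^-1
    backscatter_by_layer: dict[str, float]  # realized per-subject fractions
    thickness_maps: dict[str, np.ndarray]   # per anatomical layer, μm
    quality_score: float
    incident_intensity: float
    voxel_size: tuple[float, float, float]
    fovea_index: tuple[float, float] = (0.0, 0.0)

    def analysis_thickness(self, layer: str) -> np.ndarray:
        """True thickness map (μm) for a composite analysis layer."""
        top, bot = layer_boundaries(layer)
        z_um = self.voxel_size[2]
        return (self.surfaces.boundary(bot) - self.surfaces.boundary(top)) * z_um

    def mu_analysis(self, layer: str) -> float:
        """Thickness-weighted true attenuation for a composite layer."""
        if layer in self.mu_by_layer:
            return self.mu_by_layer[layer]
        parts = {"mRNFL": ("RNFL",), "GCIPL": ("GCL", "IPL"),
                 "GCC": ("RNFL", "GCL", "IPL")}[layer]
        w = np.array([np.mean(self.thickness_maps[p]) for p in parts])
        mu = np.array([self.mu_by_layer[p] for p in parts])
        return float(np.sum(w * mu) / np.sum(w))


@dataclass
class QCReport:
    """Per-B-scan quality flags produced by segmentation QC."""

    flags: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def any_flagged(self) -> np.ndarray:
        arrs = list(self.flags.values())
        out = np.zeros_like(arrs[0], dtype=bool) if arrs else np.zeros(0, dtype=bool)
        for a in arrs:
            out |= a
        return out

    @property
    def n_flagged(self) -> int:
        return int(self.any_flagged.sum())
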