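"""Boundary segmentation, volume flattening and QC flags.

Segmentation is a deliberately simple per-B-scan shortest-path search: each
boundary is a minimal-cost path through a signed axial-gradient cost image
under a smoothness constraint (max inter-A-line depth change), found
sequentially from the ILM downward inside a search band relative to the
previously placed boundary. Because every band starts at or below the
previous boundary, non-crossing is guaranteed by construction. This is a
stand-in adequate for phantom-like data; externally segmented surface sets
can be imported through ``volume_io.read_surfaces`` to bypass it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter, minimum_filter1d

from .types import BOUNDARY_NAMES, OCTVolume, QCReport, SurfaceSet

_BIG = 1e18


class SegmentationError(RuntimeError):
    """Raised when no credible boundary structure is found."""


#: Per-boundary (gradient sign, min gap, max gap) relative to the boundary
#: above, in voxels at 2.3 μm axial pitch. Sign +1 means intensity rises
#: with depth across the boundary. Gaps bracket the plausible layer
#: thickness range; the inner boundaries allow zero gap for the foveal pit.
_DEFAULT_BOUNDS: dict[str, tuple[int, float, float]] = {
    "ILM": (+1, 0, 0),          # gaps unused for the first boundary
    "RNFL_GCL": (-1, 0, 30),
    "GCL_IPL": (+1, 0, 32),
    "IPL_INL": (-1, 0, 30),
    "INL_OPL": (+1, 4, 28),
    "OPL_ONL": (-1, 4, 26),
    "ONL_ELM": (+1, 8, 50),
    "ELM_ISOS": (+1, 1, 9),
    "ISOS_OS": (-1, 2, 14),
    "OS_RPE": (+1, 2, 13),
    "BM": (-1, 4, 20),
}


@dataclass
class SegmentationConfig:
    """Tunables of the stand-in segmenter.

    ``smoothness`` is the maximum permitted |Δz| (voxels) between adjacent
    A-lines of one boundary; ``median_window`` smooths each B-scan cost
    image (x, z footprint); ``bounds`` carries per-boundary gradient sign
    and search band; ``min_edge_strength`` is the weakest acceptable mean
    gradient (AU/voxel) along a found path before the B-scan is flagged.
    """

    smoothness: int = 3
    median_window: tuple[int, int] = (5, 5)
    bounds: dict[str, tuple[int, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_BOUNDS))
    min_edge_strength: float = 30.0
    ilm_search: tuple[float, float] = (1, 0.7)  # z range; upper as fraction of n_z

    def __post_init__(self) -> None:
        if self.smoothness < 0:
            raise ValueError("smoothness must be >= 0")
        for name, (_, lo, hi) in self.bounds.items():
            if hi < lo:
                raise ValueError(f"degenerate search band for {name}")


def _trace_boundary(cost: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                    smooth: int) -> tuple[np.ndarray, float]:
    """Minimal-cost path through ``cost[(x, z)]`` within per-column bands.

    Vectorized Viterbi: forward accumulation with a sliding-window minimum,
    then greedy backtracking (valid because transitions are free within the
    window). Returns the path and its mean cost.
    """
    nx, nz = cost.shape
    banded = cost + np.where(
        (np.arange(nz)[None, :] >= lo[:, None]) & (np.arange(nz)[None, :] <= hi[:, None]),
        0.0, _BIG)
    acc = np.empty_like(banded)
    acc[0] = banded[0]
    size = 2 * smooth + 1
    for x in range(1, nx):
        prev = minimum_filter1d(acc[x - 1], size=size, mode="nearest") if smooth \
            else acc[x - 1]
        acc[x] = banded[x] + prev
    path = np.empty(nx, dtype=np.int64)
    path[-1] = int(np.argmin(acc[-1]))
    for x in range(nx - 2, -1, -1):
        z0 = max(0, path[x + 1] - smooth)
        z1 = min(nz, path[x + 1] + smooth + 1)
        path[x] = z0 + int(np.argmin(acc[x, z0:z1]))
    mean_cost = float(np.mean(cost[np.arange(nx), path]))
    return path, mean_cost


def segment_surfaces(volume: OCTVolume,
                     config: SegmentationConfig | None = None) -> SurfaceSet:
    """Segment the eleven boundaries on every B-scan.

    The result satisfies the non-crossing invariant by construction. Weak or
    band-escaping B-scans are recorded on the returned surface set
    (``seg_flags``) for :func:`qc_report` to pick up; a volume with no
    credible layering at all raises :class:`SegmentationError`.
    """
    config = config or SegmentationConfig()
    vol = np.asarray(volume.intensity, dtype=np.float64)
    nx, ny, nz = vol.shape
    scale = 2.3 / volume.voxel_size[2]  # bands are stated at 2.3 μm pitch
    data = np.zeros((len(BOUNDARY_NAMES), nx, ny))
    weak = np.zeros(ny, dtype=bool)
    escape = np.zeros(ny, dtype=bool)
    for y in range(ny):
        bscan = median_filter(vol[:, y, :], size=config.median_window, mode="nearest")
        grad = np.zeros_like(bscan)
        grad[:, 1:] = bscan[:, 1:] - bscan[:, :-1]  # edge sits at the new voxel
        prev = None
        for k, name in enumerate(BOUNDARY_NAMES):
            sign, gap_lo, gap_hi = config.bounds[name]
            cost = -sign * grad
            if prev is None:
                lo = np.full(nx, config.ilm_search[0])
                hi = np.full(nx, config.ilm_search[1] * nz)
            else:
                lo = prev + gap_lo * scale
                hi = prev + gap_hi * scale
                if np.any(lo > nz - 1):
                    escape[y] = True
                lo = np.clip(lo, 0, nz - 1)
                hi = np.clip(np.maximum(hi, lo), 0, nz - 1)
            path, mean_cost = _trace_boundary(cost, lo, hi, config.smoothness)
            if name == "ILM" and -mean_cost < config.min_edge_strength:
                weak[y] = True
            data[k, :, y] = np.maximum(path, prev) if prev is not None else path
            prev = data[k, :, y]
    if weak.all():
        raise SegmentationError(
            "no credible retinal layering found in any B-scan "
            f"(ILM edge strength below {config.min_edge_strength} AU everywhere)")
    surfaces = SurfaceSet(data)
    surfaces.seg_flags = {"weak_edge": weak, "band_escape": escape}  # type: ignore[attr-defined]
    return surfaces


# ---------------------------------------------------------------------------
# flattening

def flatten(volume: OCTVolume, surfaces: SurfaceSet,
            reference_boundary: str = "OS_RPE",
            target_depth: int | None = None) -> tuple[OCTVolume, SurfaceSet]:
    """Shift every A-line by an integer voxel offset so the reference
    boundary sits at a constant depth; surfaces are shifted identically.

    Integer shifts keep per-A-line voxel counts between any two boundaries
    exactly unchanged, so thickness maps are bit-identical before and after.
    Voxels rolled in from outside the grid are filled with 0 AU and recorded
    in ``pad_mask`` so intensity statistics can exclude them.
    """
    ref = surfaces.boundary(reference_boundary)
    nz = volume.shape[2]
    if target_depth is None:
        target_depth = int(np.round(np.median(ref)))
    shift = np.rint(target_depth - ref).astype(np.int64)
    arr = np.asarray(volume.intensity)
    src = np.arange(nz)[None, None, :] - shift[:, :, None]
    valid = (src >= 0) & (src < nz)
    out = np.take_along_axis(arr, np.clip(src, 0, nz - 1), axis=2)
    out[~valid] = 0
    pad = ~valid
    new_surfaces = surfaces.shifted(shift)
    flat = OCTVolume(intensity=out, voxel_size=volume.voxel_size,
                     laterality=volume.laterality, quality_score=volume.quality_score,
                     subject_id=volume.subject_id, pad_mask=pad)
    if hasattr(surfaces, "seg_flags"):
        new_surfaces.seg_flags = surfaces.seg_flags  # type: ignore[attr-defined]
    return flat, new_surfaces


# ---------------------------------------------------------------------------
# QC

def qc_report(surfaces: SurfaceSet, volume: OCTVolume,
              retina_range_um: tuple[float, float] = (100.0, 500.0),
              max_zero_inner_fraction: float = 0.3) -> QCReport:
    """Per-B-scan plausibility flags.

    Flags crossing boundaries, band escapes and weak edges recorded during
    segmentation, B-scans whose total-retina thickness leaves a plausible
    range, and B-scans where the inner complex (ILM to IPL/INL) collapses to
    zero on more A-lines than a foveal pit can explain. Downstream
    aggregation may exclude flagged B-scans; nothing is repaired here.
    """
    ny = surfaces.data.shape[2]
    z_um = volume.voxel_size[2]
    flags: dict[str, np.ndarray] = {}
    flags["crossing"] = (np.diff(surfaces.data, axis=0) < -1e-9).any(axis=(0, 1))
    total = (surfaces.boundary("BM") - surfaces.boundary("ILM")) * z_um
    flags["implausible_thickness"] = ((total < retina_range_um[0]) |
                                      (total > retina_range_um[1])).any(axis=0)
    inner = surfaces.boundary("IPL_INL") - surfaces.boundary("ILM")
    flags["inner_collapse"] = (inner < 1.0).mean(axis=0) > max_zero_inner_fraction
    seg = getattr(surfaces, "seg_flags", None)
    if seg:
        flags["weak_edge"] = seg["weak_edge"].copy()
        flags["band_escape"] = seg["band_escape"].copy()
    else:
        flags["weak_edge"] = np.zeros(ny, dtype=bool)
        flags["band_escape"] = np.zeros(ny, dtype=bool)
    return QCReport(flags=flags)
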