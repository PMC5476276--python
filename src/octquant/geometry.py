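"""Fovea-centered square geometry and quadrant demarcation.

The analysis square (default width 5.0 mm) is centered on the foveal pit and
split by the vertical and horizontal midlines through the fovea into four
quadrants named by anatomy: superonasal (SN), inferonasal (IN),
superotemporal (ST) and inferotemporal (IT). Nasal vs temporal depends on
eye laterality; superior vs inferior on the slow-scan axis.

Stored-scan orientation convention (asserted by the mirror-invariance
tests): the slow axis runs inferior -> superior with increasing y; on the
fast axis, increasing x runs temporal -> nasal for right eyes (OD) and
nasal -> temporal for left eyes (OS). Offsets exactly on the vertical
midline are labeled temporal and offsets on the horizontal midline
inferior, so an x-mirrored volume with flipped laterality reproduces the
anatomical label sets exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import SurfaceSet

QUADRANTS = ("SN", "IN", "ST", "IT")
REGIONS = QUADRANTS + ("Average",)

_LABEL_CODES = {"outside": 0, "SN": 1, "IN": 2, "ST": 3, "IT": 4}


class FlatFoveaError(ValueError):
    """Raised when no foveal pit is detectable; supply the fovea manually."""


def locate_fovea(surfaces: SurfaceSet, central_fraction: float = 1.0 / 3.0
                 ) -> tuple[int, int]:
    """Find the foveal pit as the A-line minimizing ILM-to-RNFL/GCL distance.

    The search is restricted to the central ``central_fraction`` of both
    en-face axes (anatomical prior: the fovea lies near the scan center).
    Ties are broken by squared index distance to the scan center, then by
    scan order. Raises :class:`FlatFoveaError` when the inner layers show no
    pit (minimum not clearly below the window's typical value).
    """
    if not 0 < central_fraction <= 1:
        raise ValueError("central_fraction must be in (0, 1]")
    rnfl = surfaces.boundary("RNFL_GCL") - surfaces.boundary("ILM")
    nx, ny = rnfl.shape
    hx = max(1, int(round(nx * central_fraction / 2)))
    hy = max(1, int(round(ny * central_fraction / 2)))
    cx, cy = nx // 2, ny // 2
    x0, x1 = max(0, cx - hx), min(nx, cx + hx + 1)
    y0, y1 = max(0, cy - hy), min(ny, cy + hy + 1)
    window = rnfl[x0:x1, y0:y1]
    med = float(np.median(window))
    lo = float(window.min())
    if med <= 0 or lo > 0.5 * med:
        raise FlatFoveaError(
            "no foveal pit found in the central window (inner layers look flat); "
            "pass the fovea position manually")
    xs, ys = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1), indexing="ij")
    dist2 = (xs - cx) ** 2 + (ys - cy) ** 2
    # lexicographic minimum: thickness, then centrality, then scan order
    cand = np.argwhere(window <= lo + 1e-12)
    d2 = dist2[cand[:, 0], cand[:, 1]]
    best = cand[np.lexsort((cand[:, 1] + (x0 + cand[:, 0]) * ny, d2))][0]
    return int(x0 + best[0]), int(y0 + best[1])


@dataclass
class QuadrantGrid:
    """Per-A-line quadrant labels on the fovea-centered square."""

    labels: np.ndarray  # (n_x, n_y) uint8 codes, see _LABEL_CODES
    fovea_index: tuple[float, float]
    fovea_mm: tuple[float, float]
    width_mm: float
    laterality: str
    voxel_size: tuple[float, float, float]

    def mask(self, region: str) -> np.ndarray:
        if region == "Average":
            return self.labels > 0
        return self.labels == _LABEL_CODES[region]

    def counts(self) -> dict[str, int]:
        out = {q: int((self.labels == _LABEL_CODES[q]).sum()) for q in QUADRANTS}
        out["Average"] = int((self.labels > 0).sum())
        return out

    def to_csv(self, path) -> None:
        """Export the labeled en-face map for visual audit."""
        codes = np.array(["outside", "SN", "IN", "ST", "IT"])
        np.savetxt(path, codes[self.labels].astype("U8"), fmt="%s", delimiter=",")


def make_quadrant_grid(fovea: tuple[float, float], width_mm: float, laterality: str,
                       voxel_size: tuple[float, float, float],
                       grid_shape: tuple[int, int]) -> QuadrantGrid:
    """Label every A-line of an en-face grid with its quadrant.

    ``fovea`` is the (x, y) A-line index of the pit (fractional allowed).
    The square of ``width_mm`` is clipped to the scan; quadrants are the
    axis-aligned midline split through the fovea.
    """
    if laterality not in ("OD", "OS"):
        raise ValueError("laterality must be 'OD' or 'OS'")
    nx, ny = grid_shape
    fx, fy = fovea
    if not (0 <= fx < nx and 0 <= fy < ny):
        raise ValueError(f"fovea {fovea} lies outside the scan grid {grid_shape}")
    px, py = voxel_size[0] / 1000.0, voxel_size[1] / 1000.0  # mm per A-line
    dx = (np.arange(nx) - fx)[:, None] * px
    dy = (np.arange(ny) - fy)[None, :] * py
    half = width_mm / 2.0
    inside = (np.abs(dx) <= half) & (np.abs(dy) <= half)
    if not inside.any():
        raise ValueError("the analysis square does not intersect the scan")
    nasal = (dx > 0) if laterality == "OD" else (dx < 0)
    superior = dy > 0
    labels = np.zeros((nx, ny), dtype=np.uint8)
    labels[inside & superior & nasal] = _LABEL_CODES["SN"]
    labels[inside & ~superior & nasal] = _LABEL_CODES["IN"]
    labels[inside & superior & ~nasal] = _LABEL_CODES["ST"]
    labels[inside & ~superior & ~nasal] = _LABEL_CODES["IT"]
    return QuadrantGrid(labels=labels, fovea_index=(fx, fy),
                        fovea_mm=(fx * px, fy * py), width_mm=width_mm,
                        laterality=laterality, voxel_size=tuple(voxel_size))


def region_values(values: np.ndarray, grid: QuadrantGrid,
                  mask: np.ndarray | None = None,
                  return_counts: bool = False):
    """Quadrant means and the global average of a per-A-line map.

    ``mask`` marks A-lines to exclude (QC failures, degenerate values); NaNs
    in ``values`` are excluded as well. The global Average is the mean over
    all labeled, unmasked A-lines of the square — not the mean of the four
    quadrant means. Empty regions come back as NaN (missing), never zero.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != grid.labels.shape:
        raise ValueError("value map and quadrant grid are not congruent")
    ok = np.isfinite(values)
    if mask is not None:
        ok &= ~np.asarray(mask, dtype=bool)
    out: dict[str, float] = {}
    counts: dict[str, int] = {}
    for region in REGIONS:
        sel = grid.mask(region) & ok
        counts[region] = int(sel.sum())
        out[region] = float(values[sel].mean()) if counts[region] else float("nan")
    if return_counts:
        return out, counts
    return out
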