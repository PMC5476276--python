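"""Reading and writing OCT volumes, surface sets and cohort metadata.

Volumes travel as multi-page TIFF (one page per B-scan, page axes = depth ×
fast-scan) or as raw little-endian NRRD, always with a JSON sidecar carrying
voxel size, laterality, quality score and subject id. Surfaces travel as a
single JSON document or as a directory of per-boundary TSV matrices, with
depths in fractional voxels rounded to 3 decimals. Readers validate and
reject inconsistent inputs; they never repair them silently.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import BOUNDARY_NAMES, OCTVolume, SubjectMeta, SurfaceSet

SIDECAR_FIELDS = ("voxel_size_um", "laterality", "quality_score", "subject_id")
_SURFACE_DECIMALS = 3


# ---------------------------------------------------------------------------
# minimal NRRD (raw encoding, 3D uint16) — kept deliberately small

def _write_nrrd(path: Path, arr: np.ndarray, spacings: tuple[float, ...]) -> None:
    arr = np.ascontiguousarray(arr.transpose(2, 1, 0))  # x fastest in the file
    header = (
        "NRRD0004\n"
        "type: uint16\n"
        "dimension: 3\n"
        f"sizes: {arr.shape[2]} {arr.shape[1]} {arr.shape[0]}\n"
        "encoding: raw\n"
        "endian: little\n"
        f"spacings: {spacings[0]} {spacings[1]} {spacings[2]}\n"
        "\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(arr.astype("<u2").tobytes())


def _read_nrrd(path: Path) -> np.ndarray:
    with open(path, "rb") as fh:
        raw = fh.read()
    end = raw.find(b"\n\n")
    if end < 0:
        raise ValueError(f"{path}: malformed NRRD, no blank line after header")
    fields: dict[str, str] = {}
    for line in raw[:end].decode("ascii").splitlines()[1:]:
        if ":" in line:
            key, val = line.split(":", 1)
            fields[key.strip()] = val.strip()
    if fields.get("type") not in ("uint16", "unsigned short"):
        raise ValueError(f"{path}: unsupported NRRD type {fields.get('type')!r}")
    if fields.get("encoding") != "raw":
        raise ValueError(f"{path}: only raw NRRD encoding is supported")
    sizes = tuple(int(s) for s in fields["sizes"].split())
    data = np.frombuffer(raw[end + 2:], dtype="<u2")
    if data.size != int(np.prod(sizes)):
        raise ValueError(f"{path}: NRRD payload size does not match sizes {sizes}")
    # file order: x fastest -> reshape as (z, y, x), transpose to (x, y, z)
    return data.reshape(sizes[::-1]).transpose(2, 1, 0).copy()


# ---------------------------------------------------------------------------
# volumes

def default_sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".json")


def write_volume(volume: OCTVolume, path: str | Path,
                 sidecar_path: str | Path | None = None) -> Path:
    """Write a volume as multi-page TIFF (.tif/.tiff) or NRRD (.nrrd) + sidecar."""
    path = Path(path)
    arr = np.rint(np.asarray(volume.intensity, dtype=np.float64)).astype(np.uint16) \
        if volume.intensity.dtype != np.uint16 else volume.intensity
    if path.suffix.lower() in (".tif", ".tiff"):
        # one page per B-scan, page axes (z, x)
        tifffile.imwrite(path, arr.transpose(1, 2, 0))
    elif path.suffix.lower() == ".nrrd":
        _write_nrrd(path, arr, volume.voxel_size)
    else:
        raise ValueError(f"unrecognized volume format {path.suffix!r} (use .tif or .nrrd)")
    sidecar = Path(sidecar_path) if sidecar_path else default_sidecar_path(path)
    meta = {
        "voxel_size_um": list(volume.voxel_size),
        "laterality": volume.laterality,
        "quality_score": float(volume.quality_score),
        "subject_id": volume.subject_id,
        "shape": list(arr.shape),
    }
    sidecar.write_text(json.dumps(meta, indent=1))
    return sidecar


def read_volume(path: str | Path, sidecar_path: str | Path | None = None) -> OCTVolume:
    path = Path(path)
    sidecar = Path(sidecar_path) if sidecar_path else default_sidecar_path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for fld in SIDECAR_FIELDS:
        if fld not in meta:
            raise ValueError(f"sidecar {sidecar} lacks required field '{fld}'")
    if path.suffix.lower() in (".tif", ".tiff"):
        pages = tifffile.imread(path)
        arr = pages.transpose(2, 0, 1)  # (y, z, x) -> (x, y, z)
    elif path.suffix.lower() == ".nrrd":
        arr = _read_nrrd(path)
    else:
        raise ValueError(f"unrecognized volume format {path.suffix!r}")
    if "shape" in meta and tuple(meta["shape"]) != arr.shape:
        raise ValueError(
            f"dimension mismatch: sidecar says {tuple(meta['shape'])}, file holds {arr.shape}")
    return OCTVolume(
        intensity=arr,
        voxel_size=tuple(meta["voxel_size_um"]),
        laterality=meta["laterality"],
        quality_score=meta["quality_score"],
        subject_id=meta["subject_id"],
    )


# ---------------------------------------------------------------------------
# surfaces

def write_surfaces(surfaces: SurfaceSet, path: str | Path) -> None:
    """Write surfaces as a single JSON (path ends in .json) or per-boundary TSVs.

    Depths are rounded to 3 decimals of a voxel.
    """
    path = Path(path)
    data = np.round(surfaces.data, _SURFACE_DECIMALS)
    if path.suffix.lower() == ".json":
        doc = {
            "order": list(surfaces.names),
            "boundaries": {name: data[k].tolist() for k, name in enumerate(surfaces.names)},
        }
        path.write_text(json.dumps(doc))
    else:
        path.mkdir(parents=True, exist_ok=True)
        for k, name in enumerate(surfaces.names):
            np.savetxt(path / f"{name}.tsv", data[k], delimiter="\t", fmt="%.3f")


def read_surfaces(path: str | Path) -> SurfaceSet:
    """Read surfaces written by :func:`write_surfaces`; enforces ordering."""
    path = Path(path)
    if path.is_dir():
        maps = []
        for name in BOUNDARY_NAMES:
            f = path / f"{name}.tsv"
            if not f.exists():
                raise FileNotFoundError(f"surface directory lacks boundary file {f.name}")
            maps.append(np.atleast_2d(np.loadtxt(f, delimiter="\t")))
        data = np.stack(maps)
        names = BOUNDARY_NAMES
    else:
        doc = json.loads(path.read_text())
        names = tuple(doc["order"])
        data = np.stack([np.asarray(doc["boundaries"][n], dtype=float) for n in names])
    return SurfaceSet(data, names)  # validation rejects crossings


# ---------------------------------------------------------------------------
# cohort metadata

_META_COLUMNS = ["subject_id", "group", "age", "sex", "laterality", "quality"]


def write_metadata(metas: list[SubjectMeta], path: str | Path) -> None:
    rows = [
        {"subject_id": m.subject_id, "group": m.group, "age": m.age, "sex": m.sex,
         "laterality": m.laterality, "quality": m.quality_score}
        for m in metas
    ]
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, index=False)


def read_metadata(path: str | Path) -> list[SubjectMeta]:
    df = pd.read_csv(path)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata CSV lacks columns {missing}")
    return [
        SubjectMeta(subject_id=str(r.subject_id), group=str(r.group), age=float(r.age),
                    sex=str(r.sex), laterality=str(r.laterality),
                    quality_score=float(r.quality))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# phantom truth

def write_truth(truth, directory: str | Path) -> None:
    """Serialize PhantomTruth as JSON scalars + per-surface TSV maps."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    doc = {
        "mu_by_layer": truth.mu_by_layer,
        "backscatter_by_layer": truth.backscatter_by_layer,
        "quality_score": truth.quality_score,
        "incident_intensity": truth.incident_intensity,
        "voxel_size_um": list(truth.voxel_size),
        "fovea_index": list(truth.fovea_index),
    }
    (directory / "truth.json").write_text(json.dumps(doc, indent=1))
    write_surfaces(truth.surfaces, directory / "surfaces")


def read_truth(directory: str | Path):
    from .types import PhantomTruth  # local import to avoid cycle at module load

    directory = Path(directory)
    doc = json.loads((directory / "truth.json").read_text())
    surfaces = read_surfaces(directory / "surfaces")
    z_um = doc["voxel_size_um"][2]
    thickness = {
        layer: (surfaces.data[k + 1] - surfaces.data[k]) * z_um
        for k, layer in enumerate(
            ("RNFL", "GCL", "IPL", "INL", "OPL", "ONL", "ELM", "ISOS", "OS", "RPE"))
    }
    return PhantomTruth(
        surfaces=surfaces,
        mu_by_layer=doc["mu_by_layer"],
        backscatter_by_layer=doc["backscatter_by_layer"],
        thickness_maps=thickness,
        quality_score=doc["quality_score"],
        incident_intensity=doc["incident_intensity"],
        voxel_size=tuple(doc["voxel_size_um"]),
        fovea_index=tuple(doc["fovea_index"]),
    )
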