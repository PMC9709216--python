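"""3D image volumes with physical voxel metadata, plus TIFF/NRRD I/O.

Conventions used across the package (enforced by tests):

* arrays are indexed ``[x, y, z]`` with ``z`` the original sectioning
  (apico-basal) direction; multi-page TIFF stacks, which are stored
  page-major ``(z, y, x)``, are transposed on read/write;
* voxel indices are 0-based; the physical coordinate of a voxel centre is
  ``index * voxel_size_um`` (µm), origin at the volume corner;
* all angles elsewhere in the package are degrees.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "ImageVolume",
    "read_volume",
    "write_volume",
    "read_nrrd",
    "write_nrrd",
    "resample_isotropic",
]


@dataclass
class ImageVolume:
    """A 3D scalar field with per-axis voxel size in µm."""

    values: np.ndarray
    voxel_size_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got shape {self.values.shape}")
        vs = tuple(float(v) for v in np.atleast_1d(self.voxel_size_um).ravel())
        if len(vs) == 1:
            vs = vs * 3
        if len(vs) != 3:
            raise ValueError(f"voxel_size_um must have 1 or 3 entries, got {vs}")
        if any(v <= 0 or not np.isfinite(v) for v in vs):
            raise ValueError(f"voxel sizes must be positive and finite, got {vs}")
        self.voxel_size_um = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def is_isotropic(self) -> bool:
        vs = self.voxel_size_um
        return bool(np.allclose(vs, vs[0], rtol=1e-6, atol=0.0))


# ---------------------------------------------------------------------------
# NRRD (minimal raw-encoding subset of the NRRD0004 format)
# ---------------------------------------------------------------------------

_NRRD_TYPES = {
    "uint8": np.uint8,
    "int16": np.int16,
    "uint16": np.uint16,
    "int32": np.int32,
    "float": np.float32,
    "double": np.float64,
}
_NRRD_NAMES = {np.dtype(v): k for k, v in _NRRD_TYPES.items()}


def write_nrrd(path: str | Path, data: np.ndarray,
               voxel_size_um: tuple[float, float, float] | None = None,
               vector_axis: bool = False) -> None:
    """Write an array as raw little-endian NRRD.

    ``vector_axis=True`` marks the first axis as a per-voxel vector
    component axis (e.g. a 3-component eigenvector field); spacings then
    apply to the trailing three domain axes.
    """
    data = np.ascontiguousarray(data)
    dt = np.dtype(data.dtype)
    if dt not in _NRRD_NAMES:
        raise ValueError(f"unsupported dtype for NRRD: {dt}")
    lines = [
        "NRRD0004",
        "# generated by myoarch",
        f"type: {_NRRD_NAMES[dt]}",
        f"dimension: {data.ndim}",
        f"sizes: {' '.join(str(s) for s in data.shape)}",
        "encoding: raw",
        "endian: little",
    ]
    if vector_axis:
        lines.append("kinds: " + " ".join(["vector"] + ["domain"] * (data.ndim - 1)))
    else:
        lines.append("kinds: " + " ".join(["domain"] * data.ndim))
    if voxel_size_um is not None:
        vs = list(np.broadcast_to(np.atleast_1d(voxel_size_um), (3,)).astype(float))
        spacings = (["nan"] if vector_axis else []) + [repr(float(v))
                                                       for v in vs]
        lines.append("spacings: " + " ".join(spacings))
    header = "\n".join(lines) + "\n\n"
    buf = data.astype(dt.newbyteorder("<"), copy=False).tobytes()
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(buf)


def read_nrrd(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a raw-encoding NRRD file; returns (array, header dict)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    sep = raw.find(b"\n\n")
    if not raw.startswith(b"NRRD") or sep < 0:
        raise ValueError(f"{path}: not a raw NRRD file readable by myoarch")
    header: dict[str, str] = {}
    for line in raw[:sep].decode("ascii").splitlines()[1:]:
        if line.startswith("#") or ":" not in line:
            continue
        key, val = line.split(":", 1)
        header[key.strip()] = val.strip()
    if header.get("encoding") != "raw":
        raise ValueError(f"{path}: only raw encoding supported")
    dtype = np.dtype(_NRRD_TYPES[header["type"]]).newbyteorder("<")
    sizes = tuple(int(s) for s in header["sizes"].split())
    data = np.frombuffer(raw[sep + 2:], dtype=dtype)
    expected = int(np.prod(sizes))
    if data.size != expected:
        raise ValueError(
            f"{path}: truncated NRRD payload ({data.size} values, header "
            f"promises {expected})")
    return data.reshape(sizes).copy(), header


def _nrrd_spacings(header: dict) -> tuple[float, float, float] | None:
    if "spacings" not in header:
        return None
    vals = [float(v) for v in header["spacings"].split()]
    vals = [v for v in vals if np.isfinite(v)]
    if len(vals) != 3:
        return None
    return tuple(vals)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Volume-level read / write
# ---------------------------------------------------------------------------

def read_volume(path: str | Path,
                voxel_size_um: tuple[float, float, float] | None = None,
                ) -> ImageVolume:
    """Read a multi-page TIFF stack or NRRD volume.

    TIFF files carry no reliable 3D spacing tags, so ``voxel_size_um`` must
    be supplied for them (a sidecar config in practice). NRRD spacing
    metadata is honoured; an explicit ``voxel_size_um`` overrides it.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        try:
            pages = tifffile.imread(path)
        except Exception as exc:  # truncated / invalid container
            raise ValueError(f"{path}: cannot read TIFF stack ({exc})") from exc
        if pages.ndim == 2:
            pages = pages[None]
        if voxel_size_um is None:
            raise ValueError(
                f"{path}: TIFF stacks carry no voxel size; pass voxel_size_um")
        return ImageVolume(np.ascontiguousarray(pages.transpose(2, 1, 0)),
                           voxel_size_um)
    if suffix == ".nrrd":
        data, header = read_nrrd(path)
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a 3D NRRD, got {data.ndim}D")
        vs = voxel_size_um or _nrrd_spacings(header)
        if vs is None:
            raise ValueError(f"{path}: NRRD has no spacings; pass voxel_size_um")
        return ImageVolume(data, vs)
    raise ValueError(f"{path}: unknown volume format {suffix!r} (use .tif/.nrrd)")


def write_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write a volume as multi-page TIFF (page-major z) or NRRD."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, np.ascontiguousarray(volume.values.transpose(2, 1, 0)))
    elif suffix == ".nrrd":
        write_nrrd(path, volume.values, volume.voxel_size_um)
    else:
        raise ValueError(f"{path}: unknown volume format {suffix!r} (use .tif/.nrrd)")


def resample_isotropic(volume: ImageVolume, *, order: int = 1) -> ImageVolume:
    """Trilinearly resample to the smallest per-axis voxel size.

    Already-isotropic volumes are returned unchanged. Masks and label
    volumes should be resampled with ``order=0`` (nearest neighbour).
    """
    if volume.is_isotropic:
        return volume
    vs = np.asarray(volume.voxel_size_um, dtype=float)
    target = vs.min()
    zoom = vs / target
    out = ndimage.zoom(volume.values.astype(np.float32) if order > 0
                       else volume.values,
                       zoom, order=order, mode="nearest", grid_mode=True)
    return ImageVolume(out, (target, target, target))
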