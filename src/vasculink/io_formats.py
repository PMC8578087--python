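"""Image containers and on-disk formats.

The pipeline's interchange dialect is uncompressed 8-bit MetaImage
(``.mhd`` header + ``.raw`` data): every stage can read and write it, binary
vessel masks are serialized with foreground 255, and affine transforms may be
embedded in the header via the ``TransformMatrix``/``Offset`` fields.  NIfTI
and TIFF stacks are supported as acquisition-side inputs (TIFF carries no
voxel spacing, so spacing must always be supplied explicitly for it).

All volumes are axis-aligned with identity orientation: the physical
coordinate of voxel index ``(i, j, k)`` is ``origin + (i*sx, j*sy, k*sz)``
(voxel centers), and x varies fastest in raw files, following the MetaImage
convention.  Arrays are indexed ``voxels[i, j, k]`` = (x, y, z).
"""

from __future__ import annotations

import glob as _glob
import os
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import tifffile

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "MetaImageFormatError",
    "MetaImageCorruptionError",
    "read_metaimage",
    "write_metaimage",
    "read_tiff_stack",
    "write_tiff_stack",
    "read_nifti",
    "write_nifti",
    "quantize_to_8bit",
]

SUPPORTED_DTYPES = {
    np.dtype(np.uint8): "MET_UCHAR",
    np.dtype(np.uint16): "MET_USHORT",
    np.dtype(np.float32): "MET_FLOAT",
}
_MET_TO_DTYPE = {v: k for k, v in SUPPORTED_DTYPES.items()}


class MetaImageFormatError(ValueError):
    """Raised when a MetaImage header is missing or malformed."""


class MetaImageCorruptionError(ValueError):
    """Raised when raw data does not match the header's declared geometry."""


@dataclass
class ImageVolume:
    """3D scalar grid with physical geometry.

    Parameters
    ----------
    voxels
        3D array indexed ``[i, j, k]`` mapping to physical axes (x, y, z).
    spacing
        Voxel edge lengths ``(sx, sy, sz)`` in mm; all > 0.
    origin
        Physical coordinate (mm) of the center of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must be 3-vectors")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if any(d < 1 for d in self.voxels.shape):
            raise ValueError(f"all dimensions must be >= 1, got {self.voxels.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def element_type(self) -> np.dtype:
        return self.voxels.dtype

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def physical_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """Map voxel indices (possibly fractional), shape (..., 3), to mm."""
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def index_coordinates(self, points_mm: np.ndarray) -> np.ndarray:
        """Map physical points (mm), shape (..., 3), to fractional indices."""
        pts = np.asarray(points_mm, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def like(self, voxels: np.ndarray) -> "ImageVolume":
        """New volume sharing this geometry with different voxel data."""
        return ImageVolume(voxels, self.spacing, self.origin)


@dataclass
class BinaryMask(ImageVolume):
    """Binary vessel/tumor mask sharing :class:`ImageVolume` geometry.

    In memory voxels are {0, 1} (uint8); on disk the mask is 8-bit with
    foreground 255 and background 0.
    """

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("BinaryMask voxels must be 0/1; use from_volume() to binarize")
        self.voxels = arr.astype(np.uint8)
        super().__post_init__()

    @classmethod
    def from_volume(cls, vol: ImageVolume, threshold: float = 0) -> "BinaryMask":
        """Binarize a volume: foreground where voxels > ``threshold``."""
        return cls((vol.voxels > threshold).astype(np.uint8), vol.spacing, vol.origin)

    def like(self, voxels: np.ndarray) -> "BinaryMask":
        return BinaryMask(np.asarray(voxels).astype(np.uint8), self.spacing, self.origin)


def same_geometry(a: ImageVolume, b: ImageVolume, tol: float = 1e-9) -> bool:
    """True when two volumes share shape, spacing and origin (within tol)."""
    return (
        a.shape == b.shape
        and np.allclose(a.spacing, b.spacing, atol=tol)
        and np.allclose(a.origin, b.origin, atol=tol)
    )


# ---------------------------------------------------------------------------
# MetaImage (.mhd + .raw)
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = ("NDims", "DimSize", "ElementSpacing", "ElementType", "ElementDataFile")


def _parse_header(path: str) -> dict[str, str]:
    header: dict[str, str] = {}
    with open(path, "r") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if "=" not in line:
                raise MetaImageFormatError(f"malformed header line (no '='): {line!r}")
            key, value = line.split("=", 1)
            header[key.strip()] = value.strip()
    return header


def read_metaimage(path: str | os.PathLike) -> ImageVolume:
    """Read an uncompressed MetaImage volume (``.mhd`` + local raw file).

    Returns an :class:`ImageVolume`; if the header carries a non-identity
    ``TransformMatrix`` the reconstructed transform (matrix + Offset) is
    attached as the ``transform`` attribute (a plain object with ``matrix``
    and ``offset``), mirroring how the registration stage embeds transforms.
    """
    path = os.fspath(path)
    header = _parse_header(path)
    for key in _REQUIRED_KEYS:
        if key not in header:
            raise MetaImageFormatError(f"missing required header key: {key}")
    if int(header["NDims"]) != 3:
        raise MetaImageFormatError(f"only NDims = 3 supported, got {header['NDims']}")
    if header.get("CompressedData", "False").lower() == "true":
        raise MetaImageFormatError("CompressedData is not supported")

    dims = tuple(int(v) for v in header["DimSize"].split())
    spacing = tuple(float(v) for v in header["ElementSpacing"].split())
    offset = tuple(float(v) for v in header.get("Offset", "0 0 0").split())
    if len(dims) != 3:
        raise MetaImageFormatError(f"DimSize must have 3 entries, got {header['DimSize']!r}")
    if len(spacing) != 3:
        raise MetaImageFormatError(
            f"ElementSpacing must have 3 entries, got {header['ElementSpacing']!r}"
        )
    met_type = header["ElementType"]
    if met_type not in _MET_TO_DTYPE:
        raise MetaImageFormatError(f"unsupported ElementType: {met_type}")
    dtype = _MET_TO_DTYPE[met_type]
    if header.get("BinaryDataByteOrderMSB", "False").lower() == "true":
        dtype = dtype.newbyteorder(">")

    datafile = header["ElementDataFile"]
    if datafile == "LOCAL":
        raise MetaImageFormatError("ElementDataFile = LOCAL is not supported")
    raw_path = os.path.join(os.path.dirname(path), datafile)
    if not os.path.exists(raw_path):
        raise MetaImageFormatError(f"ElementDataFile not found: {raw_path}")
    raw = np.fromfile(raw_path, dtype=dtype)
    expected = dims[0] * dims[1] * dims[2]
    if raw.size != expected:
        raise MetaImageCorruptionError(
            f"raw data has {raw.size} elements, header declares {expected} "
            f"(DimSize {dims}, {met_type})"
        )
    # x fastest on disk -> Fortran-order reshape to [i, j, k] = (x, y, z)
    voxels = raw.reshape(dims, order="F").astype(dtype.newbyteorder("="))
    vol = ImageVolume(voxels, spacing, offset)
    tm = header.get("TransformMatrix")
    if tm is not None:
        entries = [float(v) for v in tm.split()]
        if len(entries) != 9:
            raise MetaImageFormatError(
                f"TransformMatrix must have 9 entries, got {len(entries)}"
            )
        matrix = np.array(entries).reshape(3, 3)
        if not np.allclose(matrix, np.eye(3)):
            vol.transform = _HeaderTransform(matrix, np.asarray(offset, dtype=float))
    return vol


@dataclass
class _HeaderTransform:
    """Affine read back from a MetaImage header (matrix + Offset)."""

    matrix: np.ndarray
    offset: np.ndarray


def _format_floats(values) -> str:
    return " ".join(repr(float(v)) for v in values)


def write_metaimage(
    vol: ImageVolume,
    path: str | os.PathLike,
    transform=None,
) -> None:
    """Write a volume as uncompressed MetaImage (``.mhd`` + ``.raw``).

    :class:`BinaryMask` inputs are serialized 8-bit with foreground 255.
    An optional affine ``transform`` (any object with 3×3 ``matrix`` and
    3-vector ``offset``) is embedded in the header's ``TransformMatrix`` and
    ``Offset`` fields, the convention the pipeline's registration stage uses
    for storing alignments alongside mask volumes.
    """
    path = os.fspath(path)
    if not path.endswith(".mhd"):
        raise ValueError(f"MetaImage header path must end in .mhd: {path}")
    voxels = vol.voxels
    if isinstance(vol, BinaryMask):
        voxels = (voxels.astype(np.uint8) * 255).astype(np.uint8)
    if voxels.dtype not in SUPPORTED_DTYPES:
        raise ValueError(
            f"unsupported element type {voxels.dtype}; supported: "
            f"{sorted(str(d) for d in SUPPORTED_DTYPES)}"
        )
    raw_name = os.path.basename(path)[:-4] + ".raw"
    if transform is not None:
        matrix = np.asarray(transform.matrix, dtype=float)
        offset = np.asarray(transform.offset, dtype=float)
        if matrix.shape != (3, 3) or offset.shape != (3,):
            raise ValueError("attached transform must have 3x3 matrix and 3-vector offset")
    else:
        matrix = np.eye(3)
        offset = np.asarray(vol.origin, dtype=float)
    lines = [
        "ObjectType = Image",
        "NDims = 3",
        "BinaryData = True",
        "BinaryDataByteOrderMSB = False",
        "CompressedData = False",
        f"TransformMatrix = {_format_floats(matrix.ravel())}",
        f"Offset = {_format_floats(offset)}",
        f"ElementSpacing = {_format_floats(vol.spacing)}",
        f"DimSize = {voxels.shape[0]} {voxels.shape[1]} {voxels.shape[2]}",
        f"ElementType = {SUPPORTED_DTYPES[voxels.dtype]}",
        f"ElementDataFile = {raw_name}",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    voxels.flatten(order="F").tofile(os.path.join(os.path.dirname(path), raw_name))


def read_mask(path: str | os.PathLike) -> BinaryMask:
    """Read a MetaImage file as a binary mask (any nonzero voxel = foreground)."""
    vol = read_metaimage(path)
    return BinaryMask.from_volume(vol, threshold=0)


# ---------------------------------------------------------------------------
# TIFF stacks and NIfTI
# ---------------------------------------------------------------------------

def read_tiff_stack(
    path_or_glob: str | os.PathLike | list,
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> ImageVolume:
    """Read a TIFF stack (multi-page file, glob pattern, or list of files).

    TIFF carries no voxel spacing, so ``spacing`` (mm) is mandatory — the
    pipeline refuses to guess physical units.  Slice order follows ascending
    filename order (globs/lists) or page order, mapping to increasing z.
    """
    if isinstance(path_or_glob, (list, tuple)):
        files = [os.fspath(p) for p in path_or_glob]
    else:
        pattern = os.fspath(path_or_glob)
        if any(ch in pattern for ch in "*?["):
            files = sorted(_glob.glob(pattern))
            if not files:
                raise FileNotFoundError(f"no files match {pattern!r}")
        else:
            files = [pattern]
    slices = []
    for f in files:
        pages = tifffile.imread(f)
        if pages.ndim == 2:
            slices.append(pages)
        elif pages.ndim == 3:
            slices.extend(pages)
        else:
            raise ValueError(f"unsupported TIFF dimensionality {pages.ndim} in {f}")
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent slice dimensions across stack: {sorted(shapes)}")
    stack = np.stack(slices, axis=0)          # (z, y, x)
    voxels = np.ascontiguousarray(stack.transpose(2, 1, 0))  # (x, y, z)
    return ImageVolume(voxels, spacing, origin)


def write_tiff_stack(vol: ImageVolume, path: str | os.PathLike) -> None:
    """Write a volume as a multi-page TIFF (pages = z slices)."""
    pages = vol.voxels.transpose(2, 1, 0)  # (z, y, x)
    tifffile.imwrite(os.fspath(path), np.ascontiguousarray(pages))


def read_nifti(path: str | os.PathLike) -> ImageVolume:
    """Read a NIfTI-1 volume; spacing from header zooms, origin from the affine."""
    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI volume, got ndim={data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return ImageVolume(data, spacing, origin)


def write_nifti(vol: ImageVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1 with a diagonal affine from spacing/origin."""
    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    nib.save(nib.Nifti1Image(vol.voxels, affine), os.fspath(path))


# ---------------------------------------------------------------------------
# Quantization
# ---------------------------------------------------------------------------

def quantize_to_8bit(
    vol: ImageVolume,
    lo: float | None = None,
    hi: float | None = None,
) -> ImageVolume:
    """Linearly map intensities in [lo, hi] to [0, 255] (uint8).

    Rounding is half-away-from-zero; values outside [lo, hi] are clipped.
    Defaults lo/hi to the volume min/max.  A degenerate range (hi == lo)
    yields an all-zero volume with a warning.
    """
    data = vol.voxels.astype(np.float64)
    lo = float(data.min()) if lo is None else float(lo)
    hi = float(data.max()) if hi is None else float(hi)
    if hi < lo:
        raise ValueError(f"hi ({hi}) must be >= lo ({lo})")
    if hi == lo:
        warnings.warn("degenerate intensity range (hi == lo); output is all zeros")
        out = np.zeros_like(data, dtype=np.uint8)
    else:
        scaled = (data - lo) / (hi - lo) * 255.0
        scaled = np.clip(scaled, 0.0, 255.0)
        out = np.floor(scaled + 0.5).astype(np.uint8)  # half-away-from-zero (values >= 0)
    return ImageVolume(out, vol.spacing, vol.origin)
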