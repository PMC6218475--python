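"""Volumetric I/O with voxel-size metadata.

Axis convention is ``(z, y, x)`` throughout: the slice index is the first
axis, matching slice-per-file micro-CT exports. Supported containers are
TIFF (multi-page file or a directory of per-slice files, natural filename
order), NRRD (raw/gzip encodings) and MHD/RAW. Per-bone label names travel
in a JSON sidecar (``<image>.labels.json``) so the image files themselves
stay standard.

Voxel sizes are carried in micrometres. When a file carries no spacing
metadata the documented default of 4.5 um is applied with a logged warning.
"""

from __future__ import annotations

import gzip
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

#: Isotropic default voxel edge length in micrometres.
DEFAULT_VOXEL_SIZE_UM = 4.5

#: Default bone numbering for the murine hindfoot.
DEFAULT_BONE_NAMES: dict[int, str] = {
    1: "Talus",
    2: "Calcaneus",
    3: "Navicular",
    4: "Cuneiform I",
    5: "Cuneiform II",
    6: "Cuneiform III",
    7: "Cuboid",
    8: "Metatarsal V",
    9: "Metatarsal IV",
    10: "Fibula",
    11: "Tibia",
    12: "Metatarsal I",
    13: "Metatarsal II",
    14: "Metatarsal III",
}


class VolumeIOError(IOError):
    """Raised for unreadable files, inconsistent stacks or bad format requests."""


def _as_spacing(voxel_size_um) -> tuple[float, float, float]:
    if np.isscalar(voxel_size_um):
        voxel_size_um = (float(voxel_size_um),) * 3
    spacing = tuple(float(s) for s in voxel_size_um)
    if len(spacing) != 3:
        raise ValueError(f"voxel_size_um must be a scalar or length-3, got {voxel_size_um!r}")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"voxel sizes must be positive, got {spacing}")
    return spacing


@dataclass
class VoxelVolume:
    """A 3D grayscale scalar field with voxel spacing in micrometres.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Intensity grid in arbitrary units.
    voxel_size_um : float or (float, float, float)
        Voxel edge lengths ``(z, y, x)``; a scalar means isotropic.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float] = (DEFAULT_VOXEL_SIZE_UM,) * 3

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume data must be 3D with all dims >= 1, got shape {self.data.shape}")
        self.voxel_size_um = _as_spacing(self.voxel_size_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class BoneMask:
    """Binary bone occupancy on the same grid/spacing conventions as VoxelVolume."""

    data: np.ndarray
    voxel_size_um: tuple[float, float, float] = (DEFAULT_VOXEL_SIZE_UM,) * 3

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"mask data must be 3D with all dims >= 1, got shape {self.data.shape}")
        if self.data.dtype != bool:
            self.data = self.data.astype(bool)
        self.voxel_size_um = _as_spacing(self.voxel_size_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        """Number of bone voxels."""
        return int(self.data.sum())


@dataclass
class LabeledBones:
    """Integer per-bone labeling (0 = background) plus a label -> name map."""

    data: np.ndarray
    label_names: dict[int, str] = field(default_factory=dict)
    voxel_size_um: tuple[float, float, float] = (DEFAULT_VOXEL_SIZE_UM,) * 3

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"label data must be 3D with all dims >= 1, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError(f"label data must be integer, got dtype {self.data.dtype}")
        if self.data.min() < 0:
            raise ValueError("label data must be non-negative")
        self.label_names = {int(k): str(v) for k, v in self.label_names.items()}
        present = self.labels_present()
        for lab in present:
            if lab not in self.label_names:
                self.label_names[lab] = DEFAULT_BONE_NAMES.get(lab, f"label {lab}")
        self.voxel_size_um = _as_spacing(self.voxel_size_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def labels_present(self) -> list[int]:
        """Sorted nonzero labels occurring in the volume."""
        labs = np.unique(self.data)
        return [int(v) for v in labs if v != 0]


# ---------------------------------------------------------------------------
# format helpers
# ---------------------------------------------------------------------------

_FORMATS = ("tiff-stack", "nrrd", "mhd")

_NRRD_TYPES = {
    "signed char": "int8", "int8": "int8", "int8_t": "int8",
    "uchar": "uint8", "unsigned char": "uint8", "uint8": "uint8", "uint8_t": "uint8",
    "short": "int16", "short int": "int16", "signed short": "int16", "int16": "int16", "int16_t": "int16",
    "ushort": "uint16", "unsigned short": "uint16", "uint16": "uint16", "uint16_t": "uint16",
    "int": "int32", "signed int": "int32", "int32": "int32", "int32_t": "int32",
    "uint": "uint32", "unsigned int": "uint32", "uint32": "uint32", "uint32_t": "uint32",
    "longlong": "int64", "long long": "int64", "int64": "int64", "int64_t": "int64",
    "ulonglong": "uint64", "unsigned long long": "uint64", "uint64": "uint64", "uint64_t": "uint64",
    "float": "float32", "float32": "float32",
    "double": "float64", "float64": "float64",
}

_MHD_TYPES = {
    "MET_CHAR": "int8", "MET_UCHAR": "uint8",
    "MET_SHORT": "int16", "MET_USHORT": "uint16",
    "MET_INT": "int32", "MET_UINT": "uint32",
    "MET_LONG_LONG": "int64", "MET_ULONG_LONG": "uint64",
    "MET_FLOAT": "float32", "MET_DOUBLE": "float64",
}
_MHD_TYPES_INV = {v: k for k, v in _MHD_TYPES.items()}


def _natural_key(name: str):
    return [int(tok) if tok.isdigit() else tok.lower() for tok in re.split(r"(\d+)", name)]


def _infer_format(path: Path) -> str:
    if path.is_dir():
        return "tiff-stack"
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "tiff-stack"
    if suffix == ".nrrd":
        return "nrrd"
    if suffix in (".mhd", ".mha"):
        return "mhd"
    raise VolumeIOError(f"cannot infer format from {path}; pass format= one of {_FORMATS}")


def _default_spacing_warning(path) -> tuple[float, float, float]:
    logger.warning(
        "no voxel-size metadata found in %s; assuming isotropic default %.1f um", path, DEFAULT_VOXEL_SIZE_UM
    )
    return (DEFAULT_VOXEL_SIZE_UM,) * 3


# ---------------------------------------------------------------------------
# TIFF
# ---------------------------------------------------------------------------

def _read_tiff(path: Path):
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")),
            key=lambda p: _natural_key(p.name),
        )
        if not files:
            raise VolumeIOError(f"no .tif/.tiff slices found in directory {path}")
        slices = []
        for f in files:
            arr = tifffile.imread(f)
            if arr.ndim != 2:
                raise VolumeIOError(f"slice {f} is not 2D (shape {arr.shape})")
            if slices and arr.shape != slices[0].shape:
                raise VolumeIOError(
                    f"slice {f} has shape {arr.shape}, inconsistent with first slice shape {slices[0].shape}"
                )
            slices.append(arr)
        data = np.stack(slices, axis=0)
        desc = _tiff_description(files[0])
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise VolumeIOError(f"TIFF {path} is not a 2D/3D image (shape {data.shape})")
        desc = _tiff_description(path)
    if desc and "voxel_size_um" in desc:
        spacing = _as_spacing(desc["voxel_size_um"])
    else:
        spacing = _default_spacing_warning(path)
    return data, spacing


def _tiff_description(path: Path) -> dict | None:
    with tifffile.TiffFile(path) as tf:
        desc = tf.pages[0].description
    if not desc:
        return None
    try:
        parsed = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        return None
    return parsed if isinstance(parsed, dict) else None


def _write_tiff(data: np.ndarray, spacing, path: Path) -> None:
    desc = json.dumps({"voxel_size_um": list(spacing)})
    tifffile.imwrite(path, data, description=desc, metadata=None)


# ---------------------------------------------------------------------------
# NRRD (minimal raw/gzip codec; header fields we do not use are ignored)
# ---------------------------------------------------------------------------

def _read_nrrd(path: Path):
    raw = path.read_bytes()
    header_end = raw.find(b"\n\n")
    if header_end < 0:
        header_end = raw.find(b"\r\n\r\n")
        if header_end < 0:
            raise VolumeIOError(f"{path}: no blank line terminating NRRD header")
        body = raw[header_end + 4:]
    else:
        body = raw[header_end + 2:]
    header_text = raw[:header_end].decode("ascii", errors="replace")
    lines = header_text.splitlines()
    if not lines or not lines[0].startswith("NRRD"):
        raise VolumeIOError(f"{path}: missing NRRD magic")
    fields: dict[str, str] = {}
    for line in lines[1:]:
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            continue
        key, _, value = line.partition(":")
        fields[key.strip().lower()] = value.lstrip("= ").strip()

    for required in ("type", "sizes", "dimension"):
        if required not in fields:
            raise VolumeIOError(f"{path}: NRRD header missing '{required}'")
    if int(fields["dimension"]) != 3:
        raise VolumeIOError(f"{path}: only 3D NRRD supported, got dimension {fields['dimension']}")
    type_key = fields["type"].lower()
    if type_key not in _NRRD_TYPES:
        raise VolumeIOError(f"{path}: unsupported NRRD type '{fields['type']}'")
    dtype = np.dtype(_NRRD_TYPES[type_key])
    if dtype.itemsize > 1:
        endian = fields.get("endian", "little")
        dtype = dtype.newbyteorder("<" if endian == "little" else ">")
    sizes = tuple(int(s) for s in fields["sizes"].split())  # fastest axis first: (nx, ny, nz)

    encoding = fields.get("encoding", "raw").lower()
    if encoding in ("gzip", "gz"):
        body = gzip.decompress(body)
    elif encoding != "raw":
        raise VolumeIOError(f"{path}: unsupported NRRD encoding '{encoding}' (raw/gzip only)")
    expected = int(np.prod(sizes)) * dtype.itemsize
    if len(body) < expected:
        raise VolumeIOError(f"{path}: NRRD payload truncated ({len(body)} < {expected} bytes)")
    flat = np.frombuffer(body[:expected], dtype=dtype)
    data = flat.reshape(sizes[::-1])  # -> (nz, ny, nx)

    spacing = None
    if "spacings" in fields:
        vals = [float(v) for v in fields["spacings"].split()]
        spacing = tuple(vals[::-1])  # header is fastest-first -> (z, y, x)
    elif "space directions" in fields:
        vecs = re.findall(r"\(([^)]*)\)", fields["space directions"])
        if len(vecs) == 3:
            norms = [float(np.linalg.norm([float(c) for c in v.split(",")])) for v in vecs]
            spacing = tuple(norms[::-1])
    if spacing is None:
        spacing = _default_spacing_warning(path)
    return np.ascontiguousarray(data.astype(data.dtype.newbyteorder("="))), _as_spacing(spacing)


def _write_nrrd(data: np.ndarray, spacing, path: Path) -> None:
    dtype = data.dtype.newbyteorder("=")
    name = dtype.name
    if name not in _NRRD_TYPES.values():
        raise VolumeIOError(f"dtype {data.dtype} not supported for NRRD output")
    nz, ny, nx = data.shape
    sz, sy, sx = spacing
    header = (
        "NRRD0004\n"
        f"type: {name}\n"
        "dimension: 3\n"
        f"sizes: {nx} {ny} {nz}\n"
        f"spacings: {sx!r} {sy!r} {sz!r}\n"
        "endian: little\n"
        "encoding: raw\n"
        "\n"
    )
    payload = np.ascontiguousarray(data.astype(dtype.newbyteorder("<"))).tobytes()
    path.write_bytes(header.encode("ascii") + payload)


# ---------------------------------------------------------------------------
# MHD / RAW
# ---------------------------------------------------------------------------

def _read_mhd(path: Path):
    fields: dict[str, str] = {}
    for line in path.read_text().splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip()] = value.strip()
    for required in ("DimSize", "ElementType", "ElementDataFile"):
        if required not in fields:
            raise VolumeIOError(f"{path}: MHD header missing '{required}'")
    if fields["ElementType"] not in _MHD_TYPES:
        raise VolumeIOError(f"{path}: unsupported ElementType '{fields['ElementType']}'")
    dtype = np.dtype(_MHD_TYPES[fields["ElementType"]])
    if dtype.itemsize > 1 and fields.get("ElementByteOrderMSB", "False").lower() == "true":
        dtype = dtype.newbyteorder(">")
    sizes = tuple(int(s) for s in fields["DimSize"].split())  # (nx, ny, nz)
    if len(sizes) != 3:
        raise VolumeIOError(f"{path}: only 3D MHD supported, got DimSize {fields['DimSize']}")
    raw_path = path.parent / fields["ElementDataFile"]
    if not raw_path.exists():
        raise VolumeIOError(f"{path}: data file {raw_path} not found")
    flat = np.frombuffer(raw_path.read_bytes(), dtype=dtype, count=int(np.prod(sizes)))
    data = flat.reshape(sizes[::-1])
    if "ElementSpacing" in fields:
        vals = [float(v) for v in fields["ElementSpacing"].split()]
        spacing = _as_spacing(tuple(vals[::-1]))
    else:
        spacing = _default_spacing_warning(path)
    return np.ascontiguousarray(data.astype(data.dtype.newbyteorder("="))), spacing


def _write_mhd(data: np.ndarray, spacing, path: Path) -> None:
    name = data.dtype.newbyteorder("=").name
    if name not in _MHD_TYPES_INV:
        raise VolumeIOError(f"dtype {data.dtype} not supported for MHD output")
    nz, ny, nx = data.shape
    sz, sy, sx = spacing
    raw_name = path.stem + ".raw"
    header = (
        "ObjectType = Image\n"
        "NDims = 3\n"
        "BinaryData = True\n"
        "BinaryDataByteOrderMSB = False\n"
        "ElementByteOrderMSB = False\n"
        f"DimSize = {nx} {ny} {nz}\n"
        f"ElementSpacing = {sx!r} {sy!r} {sz!r}\n"
        f"ElementType = {_MHD_TYPES_INV[name]}\n"
        f"ElementDataFile = {raw_name}\n"
    )
    path.write_text(header)
    payload = np.ascontiguousarray(data.astype(np.dtype(name).newbyteorder("<"))).tobytes()
    (path.parent / raw_name).write_bytes(payload)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_volume(path, format: str | None = None) -> VoxelVolume:
    """Read a grayscale volume.

    Parameters
    ----------
    path : str or Path
        Single file, or a directory of per-slice TIFFs (natural filename
        order defines the z index).
    format : {'tiff-stack', 'nrrd', 'mhd'}, optional
        Inferred from the path when omitted.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "tiff-stack":
        data, spacing = _read_tiff(path)
    elif fmt == "nrrd":
        data, spacing = _read_nrrd(path)
    elif fmt == "mhd":
        data, spacing = _read_mhd(path)
    else:
        raise VolumeIOError(f"unknown format {fmt!r}; supported: {_FORMATS}")
    return VoxelVolume(data=data, voxel_size_um=spacing)


def read_mask(path, format: str | None = None) -> BoneMask:
    """Read a binary mask (any nonzero voxel counts as bone)."""
    vol = read_volume(path, format=format)
    return BoneMask(data=vol.data > 0, voxel_size_um=vol.voxel_size_um)


def read_labels(path, format: str | None = None) -> LabeledBones:
    """Read an integer label volume; names come from ``<path>.labels.json`` if present."""
    vol = read_volume(path, format=format)
    data = vol.data
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.array_equal(rounded, data):
            raise VolumeIOError(f"{path}: label volume has non-integer values")
        data = rounded.astype(np.int32)
    sidecar = Path(str(path) + ".labels.json")
    names: dict[int, str] = {}
    if sidecar.exists():
        names = {int(k): str(v) for k, v in json.loads(sidecar.read_text()).items()}
    return LabeledBones(data=data.astype(np.int32), label_names=names, voxel_size_um=vol.voxel_size_um)


def write_volume(obj, path, format: str | None = None) -> Path:
    """Write a :class:`VoxelVolume`, :class:`BoneMask` or :class:`LabeledBones`.

    Masks are stored as uint8 {0,1}; labels as int32 plus a
    ``<path>.labels.json`` sidecar holding the label-name map. Round trips
    through :func:`read_volume` / :func:`read_mask` / :func:`read_labels`
    reproduce data and voxel size exactly.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if isinstance(obj, BoneMask):
        data = obj.data.astype(np.uint8)
    elif isinstance(obj, LabeledBones):
        data = obj.data.astype(np.int32)
    elif isinstance(obj, VoxelVolume):
        data = obj.data
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    spacing = obj.voxel_size_um

    if fmt == "tiff-stack":
        if path.suffix.lower() not in (".tif", ".tiff"):
            raise VolumeIOError("tiff-stack output must be a single .tif/.tiff path")
        _write_tiff(data, spacing, path)
    elif fmt == "nrrd":
        _write_nrrd(data, spacing, path)
    elif fmt == "mhd":
        _write_mhd(data, spacing, path)
    else:
        raise VolumeIOError(f"unknown format {fmt!r}; supported: {_FORMATS}")

    if isinstance(obj, LabeledBones):
        sidecar = Path(str(path) + ".labels.json")
        sidecar.write_text(json.dumps({str(k): v for k, v in obj.label_names.items()}, indent=0))
    return path
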