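"""Reading, writing and organising image volumes and measurement tables.

Conventions
-----------
Stacks live on disk as multi-page grayscale TIFFs whose page axis is the
optical-section (z) axis; in memory they are addressed as ``(x, y, z)``
with z increasing from the adaxial toward the abaxial leaf surface.
Physical voxel edge lengths are carried in micrometres by
:class:`VoxelGeometry` and every downstream quantity is derived from them
(μm, μm², μm³); nothing is ever silently rescaled.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import nibabel as nib
import pandas as pd
import tifffile

__all__ = [
    "VoxelGeometry",
    "ImageStack",
    "ProjectLayout",
    "read_stack",
    "write_stack",
    "export_nifti",
    "init_project",
    "write_measurements",
    "read_measurements",
]


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical voxel edge lengths in μm, ``(dx, dy, dz)``.

    ``dz`` is the optical-section spacing and may exceed ``dx``/``dy``
    (anisotropy is the rule for laser-scanning stacks, e.g. 0.22 × 0.22
    × 0.8 μm).  The z axis runs adaxial → abaxial.
    """

    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0 and self.dz > 0):
            raise ValueError(f"voxel edges must be positive, got {self}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in μm³."""
        return self.dx * self.dy * self.dz

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.dx, self.dy, self.dz)


@dataclass
class ImageStack:
    """A 3D grayscale volume with physical geometry and provenance.

    ``voxels`` is indexed ``(x, y, z)``; dtype is preserved bit-exactly
    through read/write round-trips (8- or 16-bit unsigned in practice).
    """

    voxels: np.ndarray
    geometry: VoxelGeometry
    sample_id: str = ""
    leaf_position: str = ""  # base | middle | tip | ""
    notes: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected 3D volume, got shape {self.voxels.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def is_degenerate(self) -> bool:
        """True when the stack carries no intensity contrast."""
        return bool(self.voxels.min() == self.voxels.max())


def _parse_resolution(page, z_spacing: float | None) -> VoxelGeometry | None:
    """Recover voxel size from TIFF resolution tags + ImageJ metadata."""
    try:
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
    except (KeyError, AttributeError):
        return None
    # resolution tags are pixels per unit as a rational
    def _edge(res):
        num, den = res if isinstance(res, tuple) else (res, 1)
        if num == 0:
            return None
        return den / num

    dx = _edge(xres)
    dy = _edge(yres)
    if dx is None or dy is None or z_spacing is None:
        return None
    return VoxelGeometry(dx, dy, z_spacing)


def read_stack(
    path: str | Path,
    geometry: VoxelGeometry | None = None,
    sample_id: str = "",
    leaf_position: str = "",
    flip_z: bool = False,
) -> ImageStack:
    """Read a multi-page grayscale TIFF as an :class:`ImageStack`.

    The page axis becomes z.  Voxel-size precedence: explicit
    ``geometry`` override > TIFF resolution tags (with ImageJ z
    ``spacing``) > error.  ``flip_z`` reverses the stack for datasets
    acquired abaxial-first, so the in-memory convention (adaxial at low
    z) always holds.

    Raises
    ------
    FileNotFoundError, ValueError
        For a missing file, an RGB/multichannel input, or when no voxel
        size can be resolved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        page0 = tf.pages[0]
        if getattr(page0, "samplesperpixel", 1) > 1:
            raise ValueError(
                f"{path}: RGB/multichannel input is ambiguous for wall signal; "
                "provide a single-channel stack"
            )
        data = tf.asarray()
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(
                f"{path}: expected single-channel z-stack, got shape {data.shape}"
            )
        if geometry is None:
            z_spacing = None
            meta = tf.imagej_metadata or {}
            if "spacing" in meta:
                z_spacing = float(meta["spacing"])
            geometry = _parse_resolution(tf.pages[0], z_spacing)
    if geometry is None:
        raise ValueError(
            f"{path}: no voxel size in metadata and no override supplied"
        )
    if flip_z:
        data = data[::-1]
    # disk pages are (z, y, x); internal order is (x, y, z)
    voxels = np.ascontiguousarray(data.transpose(2, 1, 0))
    return ImageStack(voxels, geometry, sample_id=sample_id, leaf_position=leaf_position)


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a multi-page grayscale TIFF with voxel size embedded.

    The resolution tags hold dx/dy and the ImageJ ``spacing`` field dz,
    so :func:`read_stack` can re-read the file without an override.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    g = stack.geometry
    pages = np.ascontiguousarray(stack.voxels.transpose(2, 1, 0))
    tifffile.imwrite(
        path,
        pages,
        imagej=True,
        resolution=(1.0 / g.dx, 1.0 / g.dy),
        metadata={"spacing": g.dz, "unit": "um", "axes": "ZYX"},
    )
    return path


def export_nifti(volume: "ImageStack | np.ndarray", path: str | Path,
                 geometry: VoxelGeometry | None = None) -> Path:
    """Export a stack or label volume as NIfTI-1.

    The header pixdims carry (dx, dy, dz) in μm as-is (documented
    convention; no rescaling to mm), matching what slice viewers expect
    for microscopy volumes.
    """
    if isinstance(volume, ImageStack):
        data, geometry = volume.voxels, volume.geometry
    else:
        data = np.asarray(volume)
        if geometry is None:
            raise ValueError("geometry required when exporting a bare array")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([geometry.dx, geometry.dy, geometry.dz, 1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms(geometry.as_tuple())
    img.header.set_xyzt_units(xyz="micron")
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Project layout: the ordered data structure holding raw images, treated
# images and all measurements for a phenotyping campaign.
# ---------------------------------------------------------------------------

_STORES = ("raw", "treated", "measurements")
_MANIFEST = "manifest.json"


@dataclass
class ProjectLayout:
    """Directory layout: raw/, treated/, measurements/ plus a JSON manifest.

    The manifest maps stack id → ``{"state": ..., "files": {...}}``.
    Creation is idempotent: re-initialising never touches existing data.
    """

    root: Path
    manifest: dict = field(default_factory=dict)

    @property
    def raw(self) -> Path:
        return self.root / "raw"

    @property
    def treated(self) -> Path:
        return self.root / "treated"

    @property
    def measurements(self) -> Path:
        return self.root / "measurements"

    @property
    def manifest_path(self) -> Path:
        return self.root / _MANIFEST

    def register(self, stack_id: str, state: str = "raw",
                 files: Mapping[str, str] | None = None) -> None:
        entry = self.manifest.setdefault(stack_id, {"state": state, "files": {}})
        entry["state"] = state
        if files:
            entry["files"].update(files)
        self.save()

    def state(self, stack_id: str) -> str:
        return self.manifest[stack_id]["state"]

    def save(self) -> None:
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2, sort_keys=True))


def init_project(root: str | Path) -> ProjectLayout:
    """Create (or reopen) a project layout under ``root``.

    Calling twice on the same directory returns the same layout and
    leaves the manifest untouched.
    """
    root = Path(root)
    if root.exists() and not root.is_dir():
        raise NotADirectoryError(f"{root} exists and is not a directory")
    for store in _STORES:
        (root / store).mkdir(parents=True, exist_ok=True)
    manifest_path = root / _MANIFEST
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
    else:
        manifest = {}
        manifest_path.write_text(json.dumps(manifest))
    return ProjectLayout(root=root, manifest=manifest)


# ---------------------------------------------------------------------------
# Measurement tables
# ---------------------------------------------------------------------------

def _records_to_frame(records: Iterable) -> pd.DataFrame:
    rows = []
    keys: tuple | None = None
    for rec in records:
        d = asdict(rec) if hasattr(rec, "__dataclass_fields__") else dict(rec)
        if keys is None:
            keys = tuple(d)
        elif tuple(d) != keys:
            raise ValueError("records with mixed schemas cannot share one table")
        rows.append(d)
    return pd.DataFrame(rows, columns=list(keys) if keys else None)


def write_measurements(
    records: Sequence | pd.DataFrame,
    path: str | Path,
    units: Mapping[str, str] | None = None,
) -> Path:
    """Write records (dataclasses or dicts sharing one schema) to CSV.

    Unit annotations go into ``#``-prefixed header comments so the data
    block stays machine-parseable; the dialect is comma-separated, '.'
    decimal, UTF-8.  Numeric round-trip is lossless via ``repr``
    precision.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = _records_to_frame(records)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if units:
            for col, unit in units.items():
                fh.write(f"# {col}: {unit}\n")
        frame.to_csv(fh, index=False, float_format=None)
    return path


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Re-parse a measurement CSV written by :func:`write_measurements`.

    ``float_precision="round_trip"`` guarantees bit-identical numeric
    round-trips; a header-only file parses to an empty frame.
    """
    try:
        return pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
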