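"""Image-stack and feature-table I/O.

All voxel grids use the fixed axis order ``(channel, z, y, x)`` with
0-based coordinates; physical spacing is carried as ``(z, y, x)`` in
micrometres.  Stacks are read and written as OME-TIFF via tifffile so
spacing and channel names round-trip; label masks are 16-bit TIFFs;
feature tables are CSV.
"""

from __future__ import annotations

import hashlib
import uuid
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

#: fallback physical spacing (z, y, x) in micrometres when a file
#: carries no calibration metadata
DEFAULT_SPACING = (0.15, 0.06, 0.06)


@dataclass
class ImageStack:
    """A multi-channel 3D voxel grid with physical calibration.

    Parameters
    ----------
    voxels
        Array of shape ``(channels, z, y, x)``, intensities in ADU.
    spacing
        Physical voxel spacing ``(z, y, x)`` in micrometres.
    channel_names
        One label per channel, e.g. ``["DAPI", "H3K27ac", "ER"]``.
    is_interpolated
        Whether the Z axis has been resampled to balanced voxels.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    channel_names: list[str]
    is_interpolated: bool = False

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim == 3:
            self.voxels = self.voxels[np.newaxis]
        if self.voxels.ndim != 4:
            raise ValueError(f"expected (c,z,y,x) voxels, got ndim={self.voxels.ndim}")
        if np.any(np.asarray(self.voxels.min(axis=(1, 2, 3))) < 0):
            raise ValueError("intensities must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.voxels.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        """Return the 3D ``(z, y, x)`` grid of the named channel."""
        return self.voxels[self.channel_index(name)]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown channel {name!r}; stack has {self.channel_names}"
            ) from None

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class LabelVolume:
    """3D integer label grid: 0 = background, k > 0 = region id."""

    labels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D (z,y,x)")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        present = np.unique(self.labels)
        present = present[present > 0]
        if present.size and not np.array_equal(present, np.arange(1, present.size + 1)):
            raise ValueError("label ids must be contiguous from 1")
        self.spacing = tuple(float(s) for s in self.spacing)


def _resolve_axes(axes: str, data: np.ndarray) -> np.ndarray:
    """Normalize a tifffile series to (c, z, y, x)."""
    axes = axes.upper().replace("S", "C").replace("I", "Z").replace("Q", "Z")
    keep = [a for a in axes if a in "CZYX"]
    if len(keep) != data.ndim or set(keep) - set("CZYX"):
        raise ValueError(f"cannot resolve TIFF axes {axes!r} to (c,z,y,x)")
    for missing in set("CZYX") - set(keep):
        data = data[np.newaxis]
        keep = [missing] + keep
    order = [keep.index(a) for a in "CZYX"]
    return np.transpose(data, order)


def _ome_spacing(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    xml = tif.ome_metadata
    if not xml:
        return None
    try:
        root = ET.fromstring(xml)
    except ET.ParseError:
        return None
    for pix in root.iter():
        if pix.tag.endswith("Pixels"):
            try:
                return (
                    float(pix.attrib["PhysicalSizeZ"]),
                    float(pix.attrib["PhysicalSizeY"]),
                    float(pix.attrib["PhysicalSizeX"]),
                )
            except KeyError:
                return None
    return None


def _ome_channel_names(tif: tifffile.TiffFile) -> list[str] | None:
    xml = tif.ome_metadata
    if not xml:
        return None
    try:
        root = ET.fromstring(xml)
    except ET.ParseError:
        return None
    names = [
        ch.attrib["Name"]
        for ch in root.iter()
        if ch.tag.endswith("Channel") and "Name" in ch.attrib
    ]
    return names or None


def read_stack(
    path: str | Path,
    channel_names: list[str] | None = None,
    default_spacing: tuple[float, float, float] = DEFAULT_SPACING,
) -> ImageStack:
    """Read a TIFF/OME-TIFF into an :class:`ImageStack`.

    Axis order is normalized to ``(c, z, y, x)``; a plain 2D image is
    promoted to a single-channel, single-slide stack.  Spacing and
    channel names come from OME metadata when present, otherwise from
    `default_spacing` and generated ``ch0..chN`` labels.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = _resolve_axes(series.axes, series.asarray())
        spacing = _ome_spacing(tif) or tuple(default_spacing)
        names = channel_names or _ome_channel_names(tif)
    if names is None:
        names = [f"ch{i}" for i in range(data.shape[0])]
    return ImageStack(voxels=data, spacing=spacing, channel_names=names)


def _content_uuid(data: np.ndarray) -> str:
    """Deterministic OME UUID from the voxel content (reproducible files)."""
    digest = hashlib.md5(np.ascontiguousarray(data).tobytes()).digest()
    return f"urn:uuid:{uuid.UUID(bytes=digest)}"


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an :class:`ImageStack` as OME-TIFF, preserving calibration."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.asarray(stack.voxels)
    if data.dtype.kind == "f":
        data = data.astype(np.float32)
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "UUID": _content_uuid(data),
            "PhysicalSizeZ": stack.spacing[0],
            "PhysicalSizeY": stack.spacing[1],
            "PhysicalSizeX": stack.spacing[2],
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
            "Channel": {"Name": list(stack.channel_names)},
        },
    )


def write_label_volume(volume: LabelVolume, path: str | Path) -> None:
    """Write a label mask as a 16-bit label TIFF (32-bit if >65535 ids)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dtype = np.uint16 if volume.labels.max(initial=0) < 2**16 else np.uint32
    labels = volume.labels.astype(dtype)
    tifffile.imwrite(
        path,
        labels,
        ome=True,
        metadata={
            "axes": "ZYX",
            "UUID": _content_uuid(labels),
            "PhysicalSizeZ": volume.spacing[0],
            "PhysicalSizeY": volume.spacing[1],
            "PhysicalSizeX": volume.spacing[2],
        },
    )


def read_label_volume(
    path: str | Path,
    default_spacing: tuple[float, float, float] = DEFAULT_SPACING,
) -> LabelVolume:
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        if data.ndim == 2:
            data = data[np.newaxis]
        spacing = _ome_spacing(tif) or tuple(default_spacing)
    return LabelVolume(labels=data.astype(np.int64), spacing=spacing)


# columns emitted for every feature table, in stable order; extra
# columns are appended after these
FEATURE_COLUMNS = [
    "batch",
    "cell",
    "condition",
    "genotype",
    "domain_id",
    "volume_vox",
    "volume_um3",
    "sphericity",
    "correlation",
    "boundary_distance_um",
    "length_um",
]


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a domain feature table as CSV with stable column order.

    Floats are serialized at full precision (shortest round-trip repr),
    so write-then-read is lossless well below 1e-9.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ordered = [c for c in FEATURE_COLUMNS if c in table.columns]
    ordered += [c for c in table.columns if c not in ordered]
    table.loc[:, ordered].to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
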