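"""Data model and container I/O for OCT angiography volumes.

The unit of OCTA computation is the *B-scan block*: N cross-sectional
intensity images (B-scans) acquired repeatedly at one slow-axis (Y)
position.  A C-scan volume is an ordered list of such blocks along Y.
Arrays are laid out ``(y, n, z, x)`` with ``z = 0`` the shallowest pixel
(nearest the probe); depth ranges quoted elsewhere in the package are
measured from a detected tissue-surface row, not from ``z = 0``.

Two lossless container formats are supported: an HDF5 layout with a
rank-4 ``/oct`` dataset, and multi-page TIFF (pages ordered y-major,
n-minor) with a YAML sidecar carrying the acquisition metadata.
"""

from __future__ import annotations

import dataclasses
import pathlib
from dataclasses import dataclass, field
from typing import Iterator

import h5py
import numpy as np
import tifffile
import yaml

__all__ = [
    "BScanBlock",
    "OCTVolume",
    "DecorrelationMap",
    "ValidationError",
    "DegenerateInputError",
    "read_volume",
    "write_volume",
    "normalize_intensity",
    "save_map_tiff",
]

#: recognised provenance tags for a decorrelation map
MAP_SOURCES = ("label10", "sd", "unet", "unet_se")


class ValidationError(ValueError):
    """An array or container violates a structural invariant."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but degenerate (e.g. constant image)."""


@dataclass
class BScanBlock:
    """N co-located OCT intensity B-scans at one slow-axis location.

    Parameters
    ----------
    frames
        Intensity tensor of shape ``(N, H, W)`` = (repeat, depth, fast axis).
        Dimensionless OCT intensity; finite and non-negative before
        normalization, in ``[0, 1]`` after.
    y_index
        Slow-axis position of the block.
    pixel_size_x_um, pixel_size_z_um
        Physical pixel pitch in micrometres.
    """

    frames: np.ndarray
    y_index: int = 0
    pixel_size_x_um: float = 5.0
    pixel_size_z_um: float = 5.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValidationError(
                f"frames must be (N, H, W) with N >= 1, got shape {self.frames.shape}"
            )
        if not np.isfinite(self.frames).all():
            raise ValidationError("frames contain non-finite values")
        if (self.frames < 0).any():
            raise ValidationError("OCT intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of a single frame."""
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class OCTVolume:
    """A C-scan: ordered B-scan blocks along the slow axis."""

    blocks: list[BScanBlock]
    block_spacing_um: float = 10.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValidationError("volume must contain at least one block")
        shapes = {b.frames.shape for b in self.blocks}
        if len(shapes) != 1:
            raise ValidationError(f"blocks have inconsistent shapes: {sorted(shapes)}")

    @property
    def n_frames(self) -> int:
        return self.blocks[0].n_frames

    @property
    def shape(self) -> tuple[int, int, int, int]:
        """(n_y, N, H, W)."""
        n, h, w = self.blocks[0].frames.shape
        return len(self.blocks), n, h, w

    def as_array(self) -> np.ndarray:
        """Stack the blocks into a ``(y, n, z, x)`` array (copy)."""
        return np.stack([b.frames for b in self.blocks])

    def __iter__(self) -> Iterator[BScanBlock]:
        return iter(self.blocks)

    def __len__(self) -> int:
        return len(self.blocks)


@dataclass
class DecorrelationMap:
    """Per-pixel decorrelation image at one slow-axis location.

    ``source`` tags provenance: the 10-frame ground-truth label
    (``label10``), the sliding-window baseline (``sd``), or a network
    prediction (``unet`` / ``unet_se``); ``n_used`` records how many
    B-scans the method consumed.
    """

    values: np.ndarray
    y_index: int = 0
    source: str = "sd"
    n_used: int = 2

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError(f"map must be 2-D, got shape {self.values.shape}")
        if not np.isfinite(self.values).all():
            raise ValidationError("map contains non-finite values")
        if (self.values < 0).any():
            raise ValidationError("decorrelation values must be non-negative")
        if self.source not in MAP_SOURCES:
            raise ValidationError(f"unknown source {self.source!r}; expected one of {MAP_SOURCES}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


# ---------------------------------------------------------------------------
# normalization

def normalize_intensity(block: BScanBlock) -> BScanBlock:
    """Min-max normalize a block to [0, 1] with one min/max shared by all N frames.

    A single affine map per block preserves inter-frame intensity
    differences — the decorrelation signal — which per-frame scaling
    would corrupt.

    Raises
    ------
    DegenerateInputError
        If the block is constant (max == min).
    """
    lo = float(block.frames.min())
    hi = float(block.frames.max())
    if hi == lo:
        raise DegenerateInputError("constant block cannot be min-max normalized")
    return dataclasses.replace(block, frames=(block.frames - lo) / (hi - lo))


# ---------------------------------------------------------------------------
# readers / writers

_HDF5_ATTRS = ("pixel_size_x_um", "pixel_size_z_um", "block_spacing_um")


def _volume_from_array(data: np.ndarray, attrs: dict) -> OCTVolume:
    if data.ndim != 4:
        raise ValidationError(f"expected rank-4 (y, n, z, x) data, got rank {data.ndim}")
    data = data.astype(np.float64, copy=False)
    px = float(attrs.get("pixel_size_x_um", 5.0))
    pz = float(attrs.get("pixel_size_z_um", 5.0))
    blocks = [
        BScanBlock(frames=data[y], y_index=y, pixel_size_x_um=px, pixel_size_z_um=pz)
        for y in range(data.shape[0])
    ]
    meta = {k: v for k, v in attrs.items() if k not in ("axis_order",)}
    return OCTVolume(
        blocks=blocks,
        block_spacing_um=float(attrs.get("block_spacing_um", 10.0)),
        metadata=meta,
    )


def read_volume(path: str | pathlib.Path, format: str | None = None) -> OCTVolume:
    """Read an OCT volume from HDF5 (dataset ``/oct``) or multi-page TIFF.

    ``format`` is inferred from the suffix when omitted.  The returned
    volume has axis order ``(y, n, z, x)`` and float64 intensities.
    """
    path = pathlib.Path(path)
    fmt = format or _infer_format(path)
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            if "oct" not in f:
                raise ValidationError(f"{path}: no '/oct' dataset")
            ds = f["oct"]
            attrs = dict(ds.attrs)
            data = _reorder_axes(ds[()], str(attrs.get("axis_order", "ynzx")))
        return _volume_from_array(data, attrs)
    if fmt == "tiff":
        pages = tifffile.imread(path)
        meta_path = path.with_suffix(path.suffix + ".meta.yaml")
        attrs: dict = {}
        if meta_path.exists():
            attrs = yaml.safe_load(meta_path.read_text()) or {}
        n_y = int(attrs.get("n_y", 1))
        n = int(attrs.get("n_frames", pages.shape[0] // max(n_y, 1)))
        if pages.ndim == 2:
            pages = pages[None]
        if pages.shape[0] != n_y * n:
            raise ValidationError(
                f"{path}: {pages.shape[0]} pages inconsistent with n_y={n_y}, N={n}"
            )
        data = pages.reshape(n_y, n, *pages.shape[1:])
        return _volume_from_array(data, attrs)
    raise ValueError(f"unknown format {fmt!r}")


def write_volume(volume: OCTVolume, path: str | pathlib.Path, format: str | None = None) -> None:
    """Write a volume; ``read_volume`` round-trips it bit-identically (float64)."""
    path = pathlib.Path(path)
    fmt = format or _infer_format(path)
    data = volume.as_array()
    b0 = volume.blocks[0]
    attrs = {
        "axis_order": "ynzx",
        "pixel_size_x_um": b0.pixel_size_x_um,
        "pixel_size_z_um": b0.pixel_size_z_um,
        "block_spacing_um": volume.block_spacing_um,
        **{k: v for k, v in volume.metadata.items() if isinstance(v, (int, float, str))},
    }
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("oct", data=data)
            for k, v in attrs.items():
                ds.attrs[k] = v
        return
    if fmt == "tiff":
        n_y, n, h, w = data.shape
        tifffile.imwrite(path, data.reshape(n_y * n, h, w).astype(np.float32))
        meta = {**attrs, "n_y": n_y, "n_frames": n}
        path.with_suffix(path.suffix + ".meta.yaml").write_text(yaml.safe_dump(meta))
        return
    raise ValueError(f"unknown format {fmt!r}")


def save_map_tiff(dmap: DecorrelationMap, path: str | pathlib.Path, as_uint8: bool = False) -> None:
    """Export a decorrelation map as single-page TIFF.

    With ``as_uint8`` the map is min-max scaled so the minimum maps to 0
    and the maximum to 255; otherwise 32-bit float values are written
    verbatim.
    """
    v = dmap.values
    if as_uint8:
        lo, hi = float(v.min()), float(v.max())
        if hi == lo:
            raise DegenerateInputError("constant map cannot be scaled to 8-bit")
        v = np.round((v - lo) / (hi - lo) * 255.0).astype(np.uint8)
        tifffile.imwrite(pathlib.Path(path), v)
    else:
        tifffile.imwrite(pathlib.Path(path), v.astype(np.float32))


def _infer_format(path: pathlib.Path) -> str:
    s = path.suffix.lower()
    if s in (".h5", ".hdf5", ".hdf"):
        return "hdf5"
    if s in (".tif", ".tiff"):
        return "tiff"
    raise ValueError(f"cannot infer format from suffix {s!r}")


def _reorder_axes(data: np.ndarray, axis_order: str) -> np.ndarray:
    canonical = "ynzx"
    if axis_order == canonical:
        return data
    if sorted(axis_order) != sorted(canonical):
        raise ValidationError(f"bad axis_order {axis_order!r}")
    return np.transpose(data, [axis_order.index(a) for a in canonical])
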