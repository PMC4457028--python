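"""Image container with physical voxel geometry, plus TIFF + manifest I/O.

All physical quantities are in micrometres. Arrays are indexed
``(channel, z, y, x)`` for 3D stacks and ``(channel, y, x)`` for 2D
images; voxel/pixel sizes follow the same axis order (z, y, x) / (y, x).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

#: conventional channel roles
FOCI = "foci"
NUCLEUS = "nucleus"
COMET = "comet"


@dataclass
class ImageStack:
    """A multi-channel intensity image with per-axis physical voxel size.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, z, y, x)`` or ``(n_channels, y, x)``.
        Intensities must be finite and non-negative.
    voxel_size
        Physical size of one voxel per spatial axis, μm, ordered like the
        spatial axes of ``data`` (``(z, y, x)`` or ``(y, x)``).
    channels
        Role name per channel, e.g. ``("foci", "nucleus")``.
    """

    data: np.ndarray
    voxel_size: tuple[float, ...]
    channels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError(
                f"expected (c, z, y, x) or (c, y, x) array, got ndim={self.data.ndim}"
            )
        if self.data.size == 0:
            raise ValueError("empty image array")
        if not self.channels:
            self.channels = tuple(f"ch{i}" for i in range(self.data.shape[0]))
        self.channels = tuple(self.channels)
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel roles do not match first array axis")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != self.data.ndim - 1:
            raise ValueError("voxel_size length must match spatial rank")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if not np.all(np.isfinite(self.data)) or self.data.min() < 0:
            raise ValueError("intensities must be finite and non-negative")

    # -- geometry ---------------------------------------------------------
    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.data.shape[1:]

    @property
    def physical_extent(self) -> tuple[float, ...]:
        """Physical size of the field of view per axis (μm)."""
        return tuple(n * v for n, v in zip(self.spatial_shape, self.voxel_size))

    def channel(self, role: str) -> np.ndarray:
        """Return the intensity array of the channel with the given role."""
        try:
            idx = self.channels.index(role)
        except ValueError:
            raise KeyError(f"no channel with role {role!r}; have {self.channels}")
        return self.data[idx]

    def has_channel(self, role: str) -> bool:
        return role in self.channels

    def voxel_to_physical(self, index: np.ndarray) -> np.ndarray:
        """Convert (fractional) voxel indices to voxel-centre μm coordinates."""
        return np.asarray(index, dtype=float) * np.asarray(self.voxel_size)


# ---------------------------------------------------------------------------
# TIFF + sidecar I/O
# ---------------------------------------------------------------------------

def write_stack(stack: ImageStack, path: str | Path, sidecar: dict | None = None) -> Path:
    """Write a stack as an ImageJ-flavoured TIFF with voxel size in the tags.

    Channels are stored along the ImageJ channel axis. If ``sidecar`` is
    given it is written next to the TIFF as ``<path>.json`` (truth/config
    records travel with the image).
    """
    path = Path(path)
    data = stack.data.astype(np.float32)
    if data.ndim == 3:  # (c, y, x) -> insert z
        data = data[:, None]
        vz, vy, vx = 1.0, *stack.voxel_size
    else:
        vz, vy, vx = stack.voxel_size
    # ImageJ axis order TZCYXS; we write CZYX -> transpose to ZCYX
    tifffile.imwrite(
        path,
        np.ascontiguousarray(np.swapaxes(data, 0, 1)),
        imagej=True,
        resolution=(1.0 / vx, 1.0 / vy),
        metadata={
            "spacing": vz,
            "unit": "um",
            "axes": "ZCYX",
            "Labels": list(stack.channels),
            "locipair_channels": ",".join(stack.channels),
            "locipair_ndim": str(stack.data.ndim - 1),
        },
    )
    if sidecar is not None:
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1, default=_json_default))
    return path


def read_stack(path: str | Path) -> ImageStack:
    """Read a stack written by :func:`write_stack` (voxel size from tags)."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        meta = tif.imagej_metadata or {}
        page = tif.pages[0]
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
    vx = xres[1] / xres[0]
    vy = yres[1] / yres[0]
    vz = float(meta.get("spacing", 1.0))
    # normalise to (c, z, y, x): reorder present axes to the ZCYX
    # subsequence, expand the missing ones, then swap to channel-first
    present = [a for a in "ZCYX" if a in axes]
    data = np.transpose(data, [axes.index(a) for a in present])
    for i, a in enumerate("ZCYX"):
        if a not in present:
            data = np.expand_dims(data, i)
    data = np.swapaxes(data, 0, 1)
    channels = tuple(str(meta.get("locipair_channels", "")).split(",")) if meta.get(
        "locipair_channels"
    ) else ()
    ndim = int(meta.get("locipair_ndim", 3))
    if ndim == 2:
        data = data[:, 0]
        voxel = (vy, vx)
    else:
        voxel = (vz, vy, vx)
    return ImageStack(data=data, voxel_size=voxel, channels=channels)


def read_sidecar(path: str | Path) -> dict:
    return json.loads(Path(str(path) + ".json").read_text())


MANIFEST_COLUMNS = [
    "path", "nucleus_id", "root_id", "zone", "dose_gy", "time_h", "genotype",
    "truth_separation_um", "truth_volume_um3",
]


def write_manifest(rows: Sequence[dict], path: str | Path) -> Path:
    """Write a panel manifest CSV: one row per generated stack."""
    df = pd.DataFrame(list(rows))
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[MANIFEST_COLUMNS + [c for c in df.columns if c not in MANIFEST_COLUMNS]]
    df.to_csv(path, index=False)
    return Path(path)


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
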