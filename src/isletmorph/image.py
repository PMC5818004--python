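"""Volumetric image container and TIFF I/O.

Convention used throughout the package: arrays are indexed ``(z, y, x)``
(2D images ``(y, x)``), physical coordinates are in micrometres, and the
centre of voxel ``i`` lies at ``(i + 0.5) * voxel_size``.  All physical
measurements (volumes, distances, sigmas) are computed in micrometre
space, never in voxel space, so anisotropic confocal stacks (z-step
larger than the xy pixel size) are handled correctly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["VolumetricImage", "read_stack", "write_stack"]


@dataclass
class VolumetricImage:
    """One channel of a confocal stack plus its physical voxel sizes.

    Parameters
    ----------
    voxels : ndarray
        Scalar intensity grid, axis order ``(z, y, x)``.
    voxel_size : tuple of float
        Physical size of one voxel along each axis in µm, same axis
        order as ``voxels``.  Must be strictly positive.
    channel_label : str
        Free-text label, e.g. ``"ela:mCherry"`` or ``"pax6b:GFP"``.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, ...]
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.voxel_size = tuple(float(s) for s in self.voxel_size)
        if len(self.voxel_size) != self.voxels.ndim:
            raise ValueError(
                f"voxel_size has {len(self.voxel_size)} entries for a "
                f"{self.voxels.ndim}-dimensional grid"
            )
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError(f"voxel sizes must be strictly positive, got {self.voxel_size}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm^ndim (µm³ for a stack, µm² for a frame)."""
        return float(np.prod(self.voxel_size))

    @property
    def physical_extent(self) -> tuple[float, ...]:
        """Physical size of the grid along each axis in µm."""
        return tuple(n * s for n, s in zip(self.voxels.shape, self.voxel_size))

    def coordinates(self) -> list[np.ndarray]:
        """Per-axis physical coordinates of voxel centres in µm."""
        return [
            (np.arange(n) + 0.5) * s for n, s in zip(self.voxels.shape, self.voxel_size)
        ]

    def sigma_in_voxels(self, sigma_um: float | tuple[float, ...]) -> tuple[float, ...]:
        """Convert an isotropic-or-per-axis physical sigma (µm) to voxel units."""
        sig = np.broadcast_to(np.asarray(sigma_um, dtype=float), (self.voxels.ndim,))
        return tuple(sig / np.asarray(self.voxel_size))


def write_stack(path: str | Path, channels: dict[str, VolumetricImage]) -> None:
    """Write one or more channels to a multi-channel TIFF with voxel metadata.

    Channels are stacked along a leading axis; voxel sizes go into the
    ImageJ-style resolution tags plus a JSON description so round trips
    are lossless.
    """
    if not channels:
        raise ValueError("no channels to write")
    images = list(channels.values())
    vs = images[0].voxel_size
    for im in images:
        if im.voxel_size != vs or im.voxels.shape != images[0].voxels.shape:
            raise ValueError("all channels must share shape and voxel size")
    data = np.stack([im.voxels.astype(np.float32) for im in images])
    meta = {
        "axes_order": "czyx" if data.ndim == 4 else "cyx",
        "voxel_size_um": list(vs),
        "channel_labels": list(channels.keys()),
    }
    tifffile.imwrite(str(path), data, description=json.dumps(meta),
                     photometric="minisblack")


def read_stack(
    path: str | Path, voxel_size: tuple[float, ...] | None = None
) -> dict[str, VolumetricImage]:
    """Read a TIFF written by :func:`write_stack` (or any TIFF with an override).

    Parameters
    ----------
    voxel_size : optional
        Physical voxel size override in µm.  Required if the file carries
        no parseable metadata: volumes computed without physical voxel
        sizes would be meaningless, so this is a hard error.
    """
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description or ""
    meta = None
    try:
        meta = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        pass
    if meta and "voxel_size_um" in meta:
        vs = tuple(meta["voxel_size_um"])
        labels = meta.get("channel_labels")
    else:
        if voxel_size is None:
            raise ValueError(
                f"{path}: no voxel-size metadata and no override given; "
                "physical volumes would be meaningless"
            )
        vs = tuple(voxel_size)
        labels = None
    if voxel_size is not None:
        vs = tuple(voxel_size)
    if data.ndim == len(vs):  # single channel
        data = data[None]
    if labels is None:
        labels = [f"ch{i}" for i in range(data.shape[0])]
    return {
        lab: VolumetricImage(data[i], vs, channel_label=lab) for i, lab in enumerate(labels)
    }
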