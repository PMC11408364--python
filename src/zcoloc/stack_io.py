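"""Reading and writing multi-channel TIFF z-stacks.

A z-stack is a 3D grid of voxels with one grayscale intensity volume per
fluorescence channel.  All channels share one voxel grid and one bit depth
(8-, 16- or 32-bit).  Axis order is (z, y, x), 0-based, everywhere in the
library; channel indices are 1-based only in labels and reports.

Two TIFF dialects are accepted:

* hyperstack-style files whose series metadata carries an explicit channel
  axis (e.g. ImageJ ``ZCYX``/``CZYX`` stacks) — channels are taken from the
  axis;
* plain multi-page files, where ``n_channels`` de-interleaves the pages as
  repeating channel blocks (channel-fastest: page order is z0c1, z0c2, ...,
  z1c1, ...).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import FormatError, ValidationError

MAX_CHANNELS = 15

_DEPTH_OF_DTYPE = {
    np.dtype(np.uint8): 8,
    np.dtype(np.uint16): 16,
    np.dtype(np.uint32): 32,
    np.dtype(np.float32): 32,
}


@dataclass
class ChannelVolume:
    """One grayscale channel of a z-stack.

    ``index`` is the 1-based channel ordinal used in labels and reports;
    ``voxels`` keeps the original grayscale values, never rescaled on load.
    """

    index: int
    voxels: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValidationError(
                f"channel {self.index}: voxels must be 3D (z, y, x), "
                f"got {self.voxels.ndim}D"
            )
        if not self.label:
            self.label = f"Channel {self.index}"


@dataclass
class ZStack:
    """An ordered set of grayscale channel volumes on one voxel grid."""

    channels: list[ChannelVolume]
    name: str = "stack"
    voxel_spacing: tuple[float, float, float] | None = None  # (dz, dy, dx), microns

    bit_depth: int = field(init=False)

    def __post_init__(self) -> None:
        if not 1 <= len(self.channels) <= MAX_CHANNELS:
            raise ValidationError(
                f"stack must have 1..{MAX_CHANNELS} channels, "
                f"got {len(self.channels)}"
            )
        dims = self.channels[0].voxels.shape
        dtype = self.channels[0].voxels.dtype
        for ch in self.channels:
            if ch.voxels.shape != dims:
                raise ValidationError(
                    f"channel {ch.index} dims {ch.voxels.shape} != {dims}"
                )
            if ch.voxels.dtype != dtype:
                raise ValidationError(
                    f"channel {ch.index} dtype {ch.voxels.dtype} != {dtype}"
                )
        depth = _DEPTH_OF_DTYPE.get(np.dtype(dtype))
        if depth is None:
            raise ValidationError(
                f"unsupported voxel dtype {dtype}; supported: "
                "uint8, uint16, uint32, float32 (8/16/32-bit)"
            )
        self.bit_depth = depth

    @property
    def dims(self) -> tuple[int, int, int]:
        """(nz, ny, nx) voxel counts."""
        return self.channels[0].voxels.shape

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel(self, index: int) -> ChannelVolume:
        """Return the channel with 1-based ordinal ``index``."""
        for ch in self.channels:
            if ch.index == index:
                return ch
        raise ValidationError(
            f"no channel {index}; valid indices are "
            f"{[c.index for c in self.channels]}"
        )


def _stack_from_cube(cube: np.ndarray, name: str,
                     spacing: tuple[float, float, float] | None) -> ZStack:
    # cube has axes (c, z, y, x)
    channels = [ChannelVolume(index=i + 1, voxels=np.ascontiguousarray(cube[i]))
                for i in range(cube.shape[0])]
    return ZStack(channels=channels, name=name, voxel_spacing=spacing)


def read_zstack(path: str | os.PathLike, n_channels: int | None = None) -> ZStack:
    """Read a multi-channel TIFF z-stack.

    Parameters
    ----------
    path
        A readable TIFF file: grayscale pages, 8-/16-/32-bit.
    n_channels
        Override for plain multi-page files without a channel axis: pages
        are de-interleaved channel-fastest into ``n_channels`` channels.
        Ignored when the file itself declares a channel axis.

    Raises
    ------
    FormatError
        If the file is unreadable or not a TIFF.
    ValidationError
        If the stack has >15 channels, mismatched dimensions, or an
        unsupported bit depth.
    """
    try:
        with tifffile.TiffFile(os.fspath(path)) as tif:
            series = tif.series[0]
            data = series.asarray()
            axes = series.axes
    except (tifffile.TiffFileError, FileNotFoundError, IsADirectoryError,
            PermissionError, ValueError) as exc:
        raise FormatError(f"cannot read TIFF {path!r}: {exc}") from exc

    name = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    data = np.asarray(data)

    # Normalize to (c, z, y, x).  tifffile axes letters: C channel,
    # Z depth, Y/X in-plane, S samples (treated as channels), Q unknown.
    axes = axes.replace("S", "C").replace("I", "Z").replace("Q", "Z")
    if data.ndim == 2:
        cube = data[None, None]
    elif data.ndim == 3:
        if "C" in axes and "Z" not in axes:
            order = [axes.index(a) for a in "CYX"]
            cube = data.transpose(order)[:, None]
        else:
            # plain z-stack of pages; may hide interleaved channels
            nc = n_channels or 1
            if data.shape[0] % nc != 0:
                raise ValidationError(
                    f"{data.shape[0]} pages not divisible by "
                    f"{nc} channels"
                )
            cube = data.reshape(data.shape[0] // nc, nc, *data.shape[1:])
            cube = cube.transpose(1, 0, 2, 3)
    elif data.ndim == 4 and "C" in axes and "Z" in axes:
        order = [axes.index(a) for a in "CZYX"]
        cube = data.transpose(order)
    else:
        raise ValidationError(
            f"unsupported TIFF layout: axes {axes!r}, shape {data.shape}"
        )

    if cube.shape[0] > MAX_CHANNELS:
        raise ValidationError(
            f"stack has {cube.shape[0]} channels; at most "
            f"{MAX_CHANNELS} are supported"
        )
    if np.dtype(cube.dtype) not in _DEPTH_OF_DTYPE:
        raise ValidationError(
            f"unsupported bit depth (dtype {cube.dtype}); the input must "
            "be 8-, 16- or 32-bit grayscale"
        )
    return _stack_from_cube(cube, name, _read_spacing(path))


def _read_spacing(path: str | os.PathLike) -> tuple[float, float, float] | None:
    """Voxel spacing (dz, dy, dx) in microns from ImageJ metadata, if any."""
    try:
        with tifffile.TiffFile(os.fspath(path)) as tif:
            meta = tif.imagej_metadata
            if not meta:
                return None
            dz = meta.get("spacing")
            page = tif.pages[0]
            yres = page.tags.get("YResolution")
            xres = page.tags.get("XResolution")
            if dz is None or yres is None or xres is None:
                return None
            dy = yres.value[1] / yres.value[0]
            dx = xres.value[1] / xres.value[0]
            return (float(dz), float(dy), float(dx))
    except Exception:
        return None


def write_zstack(stack: ZStack, path: str | os.PathLike) -> None:
    """Write ``stack`` as an ImageJ-style hyperstack TIFF (axes ZCYX).

    The file re-reads with :func:`read_zstack` to a voxel-identical stack.
    """
    cube = np.stack([ch.voxels for ch in stack.channels])  # (c, z, y, x)
    data = np.ascontiguousarray(cube.transpose(1, 0, 2, 3))  # (z, c, y, x)
    metadata = {"axes": "ZCYX"}
    kwargs = {}
    if stack.voxel_spacing is not None:
        dz, dy, dx = stack.voxel_spacing
        metadata["spacing"] = dz
        metadata["unit"] = "um"
        kwargs["resolution"] = (1.0 / dx, 1.0 / dy)
    # ImageJ hyperstacks support uint8/uint16/float32 only; uint32 falls
    # back to tifffile's shaped format, which also round-trips the axes.
    imagej = data.dtype != np.uint32
    try:
        tifffile.imwrite(os.fspath(path), data, imagej=imagej,
                         photometric="minisblack", metadata=metadata,
                         **kwargs)
    except (OSError, PermissionError) as exc:
        raise IOError(f"cannot write TIFF {path!r}: {exc}") from exc
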