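"""Axis-aligned ROI boxes restricting analysis to a sub-volume.

Coordinates are 0-based voxel indices with half-open intervals
``[min, max)`` per axis, matching array slicing.  A box partially outside
the stack is clamped to the stack extent; a box with no overlap at all is
rejected.  Omitting the box means "analyze the whole stack".
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError
from .stack_io import ChannelVolume, ZStack


@dataclass(frozen=True)
class ROIBox:
    """Half-open axis-aligned box in (z, y, x) voxel coordinates."""

    min_corner: tuple[int, int, int]
    max_corner: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.min_corner) != 3 or len(self.max_corner) != 3:
            raise ValidationError("ROI corners must be (z, y, x) triples")
        if any(a > b for a, b in zip(self.min_corner, self.max_corner)):
            raise ValidationError(
                f"ROI min corner {self.min_corner} exceeds "
                f"max corner {self.max_corner}"
            )

    @classmethod
    def from_string(cls, spec: str) -> "ROIBox":
        """Parse ``"z0:z1,y0:y1,x0:x1"`` (half-open ranges)."""
        parts = spec.split(",")
        if len(parts) != 3:
            raise ValidationError(
                f"ROI spec {spec!r} must be 'z0:z1,y0:y1,x0:x1'"
            )
        mins, maxs = [], []
        for p in parts:
            try:
                a, b = p.split(":")
                mins.append(int(a))
                maxs.append(int(b))
            except ValueError as exc:
                raise ValidationError(f"bad ROI range {p!r}") from exc
        return cls(tuple(mins), tuple(maxs))

    def clamped(self, dims: tuple[int, int, int]) -> "ROIBox":
        """Intersect with the stack extent; error if the result is empty."""
        lo = tuple(min(max(c, 0), d) for c, d in zip(self.min_corner, dims))
        hi = tuple(min(max(c, 0), d) for c, d in zip(self.max_corner, dims))
        if any(a >= b for a, b in zip(lo, hi)):
            raise ValidationError(
                f"ROI {self.min_corner}..{self.max_corner} outside "
                f"volume of dims {dims}"
            )
        return ROIBox(lo, hi)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(b - a for a, b in zip(self.min_corner, self.max_corner))

    @property
    def n_voxels(self) -> int:
        nz, ny, nx = self.shape
        return nz * ny * nx

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(a, b) for a, b in
                     zip(self.min_corner, self.max_corner))


def full_box(stack: ZStack) -> ROIBox:
    """The box covering the entire stack extent."""
    return ROIBox((0, 0, 0), stack.dims)


def crop(stack: ZStack, box: ROIBox) -> ZStack:
    """Extract the sub-volume of every channel inside ``box``.

    All channels are cropped identically; labels, channel indices, bit
    depth and voxel spacing are preserved.  The box is clamped to the
    stack extent first; an empty intersection raises ValidationError.
    """
    b = box.clamped(stack.dims)
    sl = b.slices()
    channels = [
        ChannelVolume(index=ch.index, voxels=ch.voxels[sl].copy(),
                      label=ch.label)
        for ch in stack.channels
    ]
    return ZStack(channels=channels, name=stack.name,
                  voxel_spacing=stack.voxel_spacing)
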