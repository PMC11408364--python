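"""Synthetic multi-channel z-stacks with analytically known ground truth.

Each channel is a constant background plus solid plateau shapes (boxes
and spheres) plus optional seeded Gaussian noise, clipped to the bit
depth's value range.  Because shape membership is decided per voxel
center, every mask volume and overlap volume is an exact integer known in
advance, so all intersection coefficients have closed-form values and
thresholding at the background/plateau midpoint recovers the ground-truth
masks exactly on noiseless stacks.

The plateau must clear the background by more than five noise standard
deviations so that the midpoint threshold still separates signal from
background at realistic noise levels.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .stack_io import ChannelVolume, ZStack
from .thresholding import ThresholdRange, WeightMask


@dataclass(frozen=True)
class Box:
    """Solid axis-aligned box: half-open corner..corner+size, (z, y, x)."""

    corner: tuple[int, int, int]
    size: tuple[int, int, int]
    intensity: float

    def membership(self, dims: tuple[int, int, int]) -> np.ndarray:
        hi = tuple(c + s for c, s in zip(self.corner, self.size))
        if any(c < 0 for c in self.corner) or any(h > d for h, d in zip(hi, dims)):
            raise ValidationError(
                f"box {self.corner}+{self.size} outside dims {dims}")
        m = np.zeros(dims, dtype=bool)
        m[self.corner[0]:hi[0], self.corner[1]:hi[1], self.corner[2]:hi[2]] = True
        return m

    @property
    def volume(self) -> int:
        return int(np.prod(self.size))


@dataclass(frozen=True)
class Sphere:
    """Solid sphere; a voxel belongs iff its center is within ``radius``."""

    center: tuple[float, float, float]
    radius: float
    intensity: float

    def membership(self, dims: tuple[int, int, int]) -> np.ndarray:
        lo = [c - self.radius for c in self.center]
        hi = [c + self.radius for c in self.center]
        if any(l < -0.5 for l in lo) or any(h > d - 0.5 for h, d in zip(hi, dims)):
            raise ValidationError(
                f"sphere {self.center} r={self.radius} outside dims {dims}")
        zz, yy, xx = np.ogrid[:dims[0], :dims[1], :dims[2]]
        d2 = ((zz - self.center[0]) ** 2 + (yy - self.center[1]) ** 2
              + (xx - self.center[2]) ** 2)
        return d2 <= self.radius ** 2


@dataclass
class FixtureSpec:
    """Recipe for one synthetic stack.

    ``shapes[k]`` lists the shapes of channel k+1.  Same seed, same spec
    => bit-identical stack.
    """

    dims: tuple[int, int, int] = (8, 32, 32)
    bit_depth: int = 8
    n_channels: int = 2
    shapes: list[list[Box | Sphere]] = field(default_factory=list)
    background_level: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ValidationError(
                f"fixture bit depth must be 8 or 16, got {self.bit_depth}")
        if self.n_channels not in (2, 3):
            raise ValidationError(
                f"fixtures have 2 or 3 channels, got {self.n_channels}")
        if len(self.shapes) != self.n_channels:
            raise ValidationError(
                f"{len(self.shapes)} shape lists for "
                f"{self.n_channels} channels")
        for shapes in self.shapes:
            for s in shapes:
                if not s.intensity > self.background_level + 5 * self.noise_sd:
                    raise ValidationError(
                        f"plateau {s.intensity} must exceed background "
                        f"{self.background_level} + 5*noise_sd "
                        f"({self.noise_sd})")

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(np.uint8 if self.bit_depth == 8 else np.uint16)

    @property
    def max_value(self) -> int:
        return 2 ** self.bit_depth - 1

    def midpoint_threshold(self, channel: int) -> ThresholdRange:
        """Threshold halfway between background and the lowest plateau.

        On a noiseless stack the resulting weight mask equals the
        ground-truth membership mask exactly.
        """
        shapes = self.shapes[channel - 1]
        if not shapes:
            return ThresholdRange(self.max_value, self.max_value)
        lowest = min(self.background_level + s.intensity for s in shapes)
        lower = (self.background_level + lowest) / 2.0
        return ThresholdRange(lower, self.max_value)


def generate_stack(spec: FixtureSpec) -> tuple[ZStack, list[WeightMask]]:
    """Materialize the stack and its per-channel ground-truth masks.

    Each channel is ``background + sum of plateau intensities over its
    shapes + N(0, noise_sd)`` per voxel, truncated to [0, 2^depth - 1]
    and rounded to the integer dtype.  The returned masks are the exact
    shape-membership indicators (union over the channel's shapes).
    """
    rng = np.random.default_rng(spec.seed)
    channels: list[ChannelVolume] = []
    truth: list[WeightMask] = []
    for k in range(spec.n_channels):
        member = np.zeros(spec.dims, dtype=bool)
        vol = np.full(spec.dims, spec.background_level, dtype=np.float64)
        for shape in spec.shapes[k]:
            m = shape.membership(spec.dims)
            member |= m
            vol[m] += shape.intensity
        if spec.noise_sd > 0:
            vol += rng.normal(0.0, spec.noise_sd, size=spec.dims)
        vol = np.clip(np.rint(vol), 0, spec.max_value).astype(spec.dtype)
        channels.append(ChannelVolume(index=k + 1, voxels=vol))
        truth.append(WeightMask(weights=member.astype(np.uint8),
                                source_channel=k + 1,
                                threshold=spec.midpoint_threshold(k + 1)))
    stack = ZStack(channels=channels, name=f"synthetic_seed{spec.seed}")
    return stack, truth


def engineered_overlap_spec(seed: int = 0, noise_sd: float = 0.0) -> FixtureSpec:
    """Two-channel fixture with |A| = 4000, |B| = 3000, |A∩B| = 2000.

    Built from two overlapping boxes on a (10, 20, 25) grid, giving exact
    coefficients I = 2000/5000 = 0.4, i1 = 0.5, i2 = 2/3.
    """
    a = Box(corner=(0, 0, 0), size=(10, 20, 20), intensity=120.0)
    b = Box(corner=(0, 0, 10), size=(10, 20, 15), intensity=120.0)
    return FixtureSpec(dims=(10, 20, 25), bit_depth=8, n_channels=2,
                       shapes=[[a], [b]], background_level=10.0,
                       noise_sd=noise_sd, seed=seed)


def ground_truth_sidecar(spec: FixtureSpec) -> dict:
    """Exact voxel counts and coefficients implied by the geometry."""
    _, truth = generate_stack(spec)
    arrs = [m.weights.astype(bool) for m in truth]
    out: dict = {"channel_volumes": [int(a.sum()) for a in arrs]}
    inter = np.logical_and.reduce(arrs)
    union = np.logical_or.reduce(arrs)
    out["intersection_volume"] = int(inter.sum())
    out["union_volume"] = int(union.sum())
    if int(union.sum()) > 0:
        out["global_intersection"] = int(inter.sum()) / int(union.sum())
        out["per_channel_intersection"] = [
            (int(inter.sum()) / int(a.sum())) if int(a.sum()) else None
            for a in arrs
        ]
    return out


def write_fixture(spec: FixtureSpec, tiff_path: str | os.PathLike,
                  sidecar_path: str | os.PathLike | None = None) -> None:
    """Write the fixture TIFF plus a JSON sidecar with ground-truth counts."""
    from .stack_io import write_zstack

    stack, _ = generate_stack(spec)
    write_zstack(stack, tiff_path)
    if sidecar_path is None:
        sidecar_path = os.path.splitext(os.fspath(tiff_path))[0] + ".json"
    payload = ground_truth_sidecar(spec)
    payload["dims"] = list(spec.dims)
    payload["bit_depth"] = spec.bit_depth
    payload["seed"] = spec.seed
    payload["noise_sd"] = spec.noise_sd
    payload["midpoint_thresholds"] = [
        [spec.midpoint_threshold(k + 1).lower,
         spec.midpoint_threshold(k + 1).upper]
        for k in range(spec.n_channels)
    ]
    with open(os.fspath(sidecar_path), "w") as fh:
        json.dump(payload, fh, indent=2)
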