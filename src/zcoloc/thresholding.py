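"""Per-channel intensity thresholding.

Two distinct threshold semantics coexist and must not be conflated:

* **Weight masks** for the intersection coefficients: a voxel carries
  meaningful signal iff ``lower < v <= upper`` (strict at the lower bound,
  inclusive at the upper), giving a binary weight image per channel.
* **PCC preprocessing**: intensities above the upper threshold are set to
  0, then the lower threshold is subtracted and negative results are
  clamped to 0.  The correlation is computed on these preprocessed values
  over the full (ROI-cropped) grid — zeroed voxels stay in the sums.

The ``auto`` rule assigns a range that excludes the top and bottom 0.1% of
the channel's intensity distribution (nearest-rank percentiles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .stack_io import ChannelVolume


@dataclass(frozen=True)
class ThresholdRange:
    """Lower/upper intensity bounds, in the channel's raw intensity units.

    Note the asymmetry of the mask rule: a voxel exactly at ``lower`` is
    excluded, one exactly at ``upper`` is included.  ``lower == upper``
    therefore yields an empty mask.
    """

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower <= self.upper:
            raise ValidationError(
                f"threshold lower {self.lower} > upper {self.upper}"
            )


@dataclass
class WeightMask:
    """Binary signal-presence volume for one channel.

    ``weights`` is a uint8 grid of exactly 0/1 values with the shape of the
    (possibly ROI-cropped) source channel.
    """

    weights: np.ndarray
    source_channel: int
    threshold: ThresholdRange

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights)
        vals = np.unique(self.weights)
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("weight mask values must be exactly 0 or 1")
        self.weights = self.weights.astype(np.uint8, copy=False)

    @property
    def volume(self) -> int:
        """Number of signal voxels (sum of weights)."""
        return int(self.weights.sum(dtype=np.int64))


def _voxels(channel: ChannelVolume | np.ndarray) -> np.ndarray:
    return channel.voxels if isinstance(channel, ChannelVolume) else np.asarray(channel)


def full_range(channel: ChannelVolume | np.ndarray) -> ThresholdRange:
    """The channel's original intensity range (the on-load default)."""
    v = _voxels(channel)
    return ThresholdRange(float(v.min()), float(v.max()))


def weight_mask(channel: ChannelVolume | np.ndarray,
                t: ThresholdRange) -> WeightMask:
    """Binary weight image: 1 where ``lower < v <= upper``, else 0."""
    v = _voxels(channel)
    w = ((v > t.lower) & (v <= t.upper)).astype(np.uint8)
    idx = channel.index if isinstance(channel, ChannelVolume) else 0
    return WeightMask(weights=w, source_channel=idx, threshold=t)


def preprocess_for_pcc(channel: ChannelVolume | np.ndarray,
                       t: ThresholdRange) -> np.ndarray:
    """Clip-and-subtract preprocessing applied before Pearson correlation.

    Returns a float64 volume ``v'`` with ``v' = 0`` where ``v > upper`` and
    ``v' = max(v - lower, 0)`` elsewhere.  The output shape equals the
    input shape; all values are >= 0.
    """
    v = _voxels(channel).astype(np.float64)
    out = np.where(v > t.upper, 0.0, np.maximum(v - t.lower, 0.0))
    return out


def auto_threshold(channel: ChannelVolume | np.ndarray) -> ThresholdRange:
    """Threshold range excluding the top and bottom 0.1% of intensities.

    Uses nearest-rank percentiles: on the ascending sorted values of the n
    voxels, lower is the value at rank ``ceil(0.001 n)`` and upper at rank
    ``ceil(0.999 n)`` (1-based), so exactly the bottom 0.1% of ranks fall
    at-or-below lower and the top 0.1% fall above upper.
    """
    v = _voxels(channel).ravel()
    if v.size == 0:
        raise ValidationError("auto_threshold requires at least one voxel")
    s = np.sort(v)
    n = s.size
    lo_idx = max(int(np.ceil(0.001 * n)) - 1, 0)
    hi_idx = max(int(np.ceil(0.999 * n)) - 1, 0)
    return ThresholdRange(float(s[lo_idx]), float(s[hi_idx]))
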