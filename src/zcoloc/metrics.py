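"""Colocalization metrics on thresholded, ROI-restricted volumes.

Two families of coefficients are computed:

* **Pearson's correlation coefficient (PCC)**, the normalized covariance
  of two channels' voxel intensities after clip-and-subtract threshold
  preprocessing, over every voxel of the cropped grid (zeroed voxels
  included).  Range [-1, +1]; +1 is perfect linear correlation, -1
  perfect inverse correlation, 0 no correlation.
* **Intersection coefficients** on the binary weight masks: the global
  coefficient I is the intersection volume divided by the union volume of
  all selected channels (inclusion-exclusion for three); the per-channel
  coefficient i_k is the intersection volume divided by channel k's
  volume.  All in [0, 1].

Results that are mathematically undefined (zero variance after
preprocessing, empty mask denominators) are reported as NaN markers and
rendered as "n/a" downstream — never silently coerced to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .roi import ROIBox, crop, full_box
from .stack_io import ChannelVolume, ZStack
from .thresholding import ThresholdRange, WeightMask, preprocess_for_pcc, weight_mask
from .venn import VennRegions, venn_regions

#: Marker for mathematically undefined coefficients ("n/a" in reports).
UNDEFINED = float("nan")


def is_defined(x: float) -> bool:
    """True unless ``x`` is the undefined-result marker."""
    return not math.isnan(x)


def _check_same_grid(*arrays: np.ndarray) -> None:
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise ValidationError(f"volumes on different grids: {sorted(shapes)}")


def pearson(ch_a: ChannelVolume | np.ndarray, ch_b: ChannelVolume | np.ndarray,
            t_a: ThresholdRange, t_b: ThresholdRange) -> float:
    """PCC of two channels after clip-and-subtract preprocessing.

    Each channel is preprocessed with its own thresholds (values above the
    upper bound set to 0, then the lower bound subtracted with clamping at
    0) and the correlation is taken over all voxels of the shared grid.
    Returns NaN when either preprocessed channel has zero variance.
    """
    a = preprocess_for_pcc(ch_a, t_a)
    b = preprocess_for_pcc(ch_b, t_b)
    _check_same_grid(a, b)
    da = a.ravel() - a.mean()
    db = b.ravel() - b.mean()
    denom = math.sqrt(float(da @ da)) * math.sqrt(float(db @ db))
    if denom == 0.0:
        return UNDEFINED
    return float(da @ db) / denom


def _mask_arrays(*masks: WeightMask) -> list[np.ndarray]:
    arrs = [m.weights.astype(np.int64) for m in masks]
    _check_same_grid(*arrs)
    return arrs


def intersection_2ch(mask_a: WeightMask, mask_b: WeightMask
                     ) -> tuple[float, float, float]:
    """Global and per-channel intersection coefficients for two masks.

    Returns ``(I, i1, i2)`` with ``I = |A∩B| / |A∪B|``, ``i1 = |A∩B|/|A|``,
    ``i2 = |A∩B|/|B|``.  An empty union makes all three undefined; an
    empty single mask makes only its own i_k undefined.
    """
    a, b = _mask_arrays(mask_a, mask_b)
    na = int(a.sum())
    nb = int(b.sum())
    nab = int((a * b).sum())
    union = na + nb - nab
    I = nab / union if union > 0 else UNDEFINED
    i1 = nab / na if na > 0 else UNDEFINED
    i2 = nab / nb if nb > 0 else UNDEFINED
    return I, i1, i2


def intersection_3ch(mask_a: WeightMask, mask_b: WeightMask,
                     mask_c: WeightMask) -> tuple[float, float, float, float]:
    """Global and per-channel intersection coefficients for three masks.

    ``I = |A∩B∩C| / |A∪B∪C|`` with the union volume given by
    inclusion-exclusion; ``i_k = |A∩B∩C| / |channel k|``.
    """
    a, b, c = _mask_arrays(mask_a, mask_b, mask_c)
    na, nb, nc = int(a.sum()), int(b.sum()), int(c.sum())
    nab = int((a * b).sum())
    nac = int((a * c).sum())
    nbc = int((b * c).sum())
    nabc = int((a * b * c).sum())
    union = na + nb + nc - nab - nac - nbc + nabc
    I = nabc / union if union > 0 else UNDEFINED
    i1 = nabc / na if na > 0 else UNDEFINED
    i2 = nabc / nb if nb > 0 else UNDEFINED
    i3 = nabc / nc if nc > 0 else UNDEFINED
    return I, i1, i2, i3


@dataclass
class ColocResult:
    """All coefficients of one colocalization run.

    ``pcc`` maps each ascending channel-index pair to its correlation;
    ``per_channel_intersection`` maps each selected channel index to i_k;
    ``venn_fractions`` maps each Venn region (a frozenset of channel
    indices) to its fraction of the union volume.  Undefined values are
    NaN markers.
    """

    selected_channels: list[int]
    thresholds: dict[int, ThresholdRange]
    roi: ROIBox
    pcc: dict[tuple[int, int], float]
    global_intersection: float
    per_channel_intersection: dict[int, float]
    venn_fractions: dict[frozenset[int], float]
    n_voxels: int
    masks: dict[int, WeightMask] = field(default_factory=dict, repr=False)


def analyze(stack: ZStack, selected: list[int],
            thresholds: dict[int, ThresholdRange],
            box: ROIBox | None = None) -> ColocResult:
    """Run the full metric pipeline on 2 or 3 selected channels.

    Crops the stack to ``box`` (default: full extent), builds the weight
    masks, and computes the PCC for every channel pair plus the matching
    intersection coefficients and Venn region fractions.

    Parameters
    ----------
    stack
        The loaded z-stack.
    selected
        2 or 3 distinct 1-based channel indices.
    thresholds
        ThresholdRange per selected channel index.
    box
        Optional ROI; clamped to the stack extent.
    """
    if not 2 <= len(selected) <= 3:
        raise ValidationError(
            f"{len(selected)} channels selected; colocalization is "
            "computed for 2 or 3 channels"
        )
    if len(set(selected)) != len(selected):
        raise ValidationError(f"duplicate channel indices in {selected}")
    for idx in selected:
        stack.channel(idx)  # raises on invalid index
        if idx not in thresholds:
            raise ValidationError(f"no threshold given for channel {idx}")

    b = (box or full_box(stack)).clamped(stack.dims)
    sub = crop(stack, b)

    chans = {i: sub.channel(i) for i in selected}
    masks = {i: weight_mask(chans[i], thresholds[i]) for i in selected}

    pcc = {}
    for k, i in enumerate(selected):
        for j in selected[k + 1:]:
            lo, hi = min(i, j), max(i, j)
            pcc[(lo, hi)] = pearson(chans[lo], chans[hi],
                                    thresholds[lo], thresholds[hi])

    ordered = sorted(selected)
    if len(ordered) == 2:
        I, i1, i2 = intersection_2ch(masks[ordered[0]], masks[ordered[1]])
        per_ch = {ordered[0]: i1, ordered[1]: i2}
    else:
        I, i1, i2, i3 = intersection_3ch(masks[ordered[0]], masks[ordered[1]],
                                         masks[ordered[2]])
        per_ch = {ordered[0]: i1, ordered[1]: i2, ordered[2]: i3}

    regions: VennRegions = venn_regions([masks[i] for i in ordered])

    return ColocResult(
        selected_channels=ordered,
        thresholds={i: thresholds[i] for i in ordered},
        roi=b,
        pcc=pcc,
        global_intersection=I,
        per_channel_intersection=per_ch,
        venn_fractions=regions.region_fractions,
        n_voxels=sub.dims[0] * sub.dims[1] * sub.dims[2],
        masks=masks,
    )
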