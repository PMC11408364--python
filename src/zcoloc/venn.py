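"""Venn region fractions and unweighted 2-/3-circle Venn diagrams.

Each exclusive/overlap region of the selected channels' weight masks is
counted and normalized by the union volume, so the displayed percentages
sum to 100% and the all-channels region equals the global intersection
coefficient.  Diagrams use fixed-size (unweighted) circles; percentages
are printed with four decimal places.  A CSV twin of the region table is
written next to every diagram.
"""

from __future__ import annotations

import csv
import itertools
import os
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .thresholding import WeightMask

#: Default channel pseudo-colors, matching common red/green/blue staining.
DEFAULT_COLORS = ("#e41a1c", "#4daf4a", "#377eb8")


@dataclass
class VennRegions:
    """Fractions of the mask-union volume per Venn region.

    ``region_fractions`` maps each non-empty subset of channel indices
    (as a frozenset) to the fraction of union voxels lying in exactly
    those channels' masks.  Fractions are NaN markers when the union is
    empty.
    """

    region_fractions: dict[frozenset[int], float]
    union_volume: int
    channel_indices: tuple[int, ...]
    region_counts: dict[frozenset[int], int]


def _mask_channels(masks: list[WeightMask]) -> tuple[int, ...]:
    idx = tuple(m.source_channel for m in masks)
    if len(set(idx)) == len(idx) and all(i > 0 for i in idx):
        return idx
    return tuple(range(1, len(masks) + 1))


def venn_regions(masks: list[WeightMask]) -> VennRegions:
    """Partition the union of 2 or 3 weight masks into Venn regions."""
    if not 2 <= len(masks) <= 3:
        raise ValidationError(f"need 2 or 3 masks, got {len(masks)}")
    arrs = [m.weights.astype(bool) for m in masks]
    shapes = {a.shape for a in arrs}
    if len(shapes) > 1:
        raise ValidationError(f"masks on different grids: {sorted(shapes)}")
    channels = _mask_channels(masks)

    union = np.logical_or.reduce(arrs)
    union_volume = int(union.sum())

    counts: dict[frozenset[int], int] = {}
    for r in range(1, len(masks) + 1):
        for combo in itertools.combinations(range(len(masks)), r):
            inside = np.logical_and.reduce([arrs[i] for i in combo])
            outside = [arrs[i] for i in range(len(masks)) if i not in combo]
            region = inside
            for o in outside:
                region = region & ~o
            counts[frozenset(channels[i] for i in combo)] = int(region.sum())

    if union_volume > 0:
        fractions = {k: c / union_volume for k, c in counts.items()}
    else:
        fractions = {k: float("nan") for k in counts}
    return VennRegions(region_fractions=fractions, union_volume=union_volume,
                       channel_indices=channels, region_counts=counts)


def format_percent(fraction: float) -> str:
    """Render a fraction as a percentage with four decimal places."""
    if np.isnan(fraction):
        return "n/a"
    return f"{fraction * 100.0:.4f}"


def _region_label(fraction: float) -> str:
    return format_percent(fraction) + ("" if np.isnan(fraction) else "%")


def render_venn(regions: VennRegions, channel_labels: list[str] | None = None,
                title: str = "", out_path: str | os.PathLike = "venn.png",
                colors: tuple[str, ...] = DEFAULT_COLORS) -> None:
    """Draw an unweighted 2- or 3-circle Venn diagram to ``out_path``.

    Circle colors follow the channel pseudo-colors; each region is
    annotated with its percentage of the union volume at four decimal
    places.  A CSV with the region table is written alongside the image.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    k = len(regions.channel_indices)
    if channel_labels is None:
        channel_labels = [f"Channel {i}" for i in regions.channel_indices]
    if len(channel_labels) != k:
        raise ValidationError(
            f"{len(channel_labels)} labels for {k} channels"
        )

    fig, ax = plt.subplots(figsize=(6, 5.5))
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)

    c = regions.channel_indices
    f = regions.region_fractions
    if k == 2:
        centers = [(-0.55, 0.0), (0.55, 0.0)]
        radius = 1.0
        text_at = {
            frozenset({c[0]}): (-1.0, 0.0),
            frozenset({c[1]}): (1.0, 0.0),
            frozenset({c[0], c[1]}): (0.0, 0.0),
        }
        label_at = [(-0.9, 1.15), (0.9, 1.15)]
    else:
        centers = [(-0.55, 0.35), (0.55, 0.35), (0.0, -0.6)]
        radius = 1.0
        text_at = {
            frozenset({c[0]}): (-1.0, 0.65),
            frozenset({c[1]}): (1.0, 0.65),
            frozenset({c[2]}): (0.0, -1.2),
            frozenset({c[0], c[1]}): (0.0, 0.75),
            frozenset({c[0], c[2]}): (-0.62, -0.35),
            frozenset({c[1], c[2]}): (0.62, -0.35),
            frozenset({c[0], c[1], c[2]}): (0.0, 0.03),
        }
        label_at = [(-1.25, 1.5), (1.25, 1.5), (0.0, -1.85)]

    for (cx, cy), color in zip(centers, colors):
        ax.add_patch(Circle((cx, cy), radius, alpha=0.35, facecolor=color,
                            edgecolor=color, linewidth=2))
    for key, (tx, ty) in text_at.items():
        ax.text(tx, ty, _region_label(f[key]), ha="center", va="center",
                fontsize=9)
    for (lx, ly), label, color in zip(label_at, channel_labels, colors):
        ax.text(lx, ly, label, ha="center", va="center", fontsize=11,
                color=color, fontweight="bold")
    ax.set_xlim(-2.1, 2.1)
    ax.set_ylim(-2.1 if k == 3 else -1.6, 1.9)

    out_path = os.fspath(out_path)
    try:
        fig.savefig(out_path, dpi=150, bbox_inches="tight")
    except OSError as exc:
        raise IOError(f"cannot write {out_path!r}: {exc}") from exc
    finally:
        plt.close(fig)

    csv_path = os.path.splitext(out_path)[0] + ".csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["region", "voxels", "percent_of_union"])
        for key in sorted(regions.region_counts, key=lambda s: (len(s), sorted(s))):
            name = "&".join(str(i) for i in sorted(key))
            writer.writerow([name, regions.region_counts[key],
                             format_percent(f[key])])
        writer.writerow(["union", regions.union_volume, "100.0000"
                         if regions.union_volume else "n/a"])
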