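"""2D intensity histograms (fluorograms) for channel pairs.

For every voxel, the intensities of the two channels form a coordinate in
a joint histogram: x-axis is the first channel, y-axis the second.
Background voxels — those whose intensities are outside the valid
threshold range in *both* channels — are not plotted; a voxel is counted
iff at least one channel's intensity satisfies ``lower < v <= upper``.
Tight clustering of counts along a straight line indicates strong
correlation, the slope being the fluorescence ratio.

Counting always uses raw intensities (no clip-and-subtract); the valid
ranges match those of the intersection coefficients, so the histogram's
three populated regions (valid in both / only first / only second)
correspond exactly to the regions of the matching 2-channel Venn diagram.
"""

from __future__ import annotations

import base64
import io
import json
import os
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .stack_io import ChannelVolume
from .thresholding import ThresholdRange


@dataclass
class Histogram2D:
    """Joint intensity histogram of a channel pair after background removal.

    ``counts[i, j]`` is the number of plotted voxels whose first-channel
    intensity falls in x-bin i and second-channel intensity in y-bin j.
    ``region_counts`` holds the (both, only_a, only_b) partition of
    ``n_plotted``.
    """

    counts: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    thresholds: tuple[ThresholdRange, ThresholdRange]
    n_plotted: int
    region_counts: dict[str, int]
    channel_labels: tuple[str, str] = ("Channel 1", "Channel 2")


def _valid(v: np.ndarray, t: ThresholdRange) -> np.ndarray:
    return (v > t.lower) & (v <= t.upper)


def default_bins(bit_depth: int) -> int:
    """Per-axis bin count: 256 for 8-bit data, 512 otherwise."""
    return 256 if bit_depth == 8 else 512


def build_histogram2d(ch_a: ChannelVolume | np.ndarray,
                      ch_b: ChannelVolume | np.ndarray,
                      t_a: ThresholdRange, t_b: ThresholdRange,
                      bins: int = 256) -> Histogram2D:
    """Count background-excluded intensity pairs of two channels.

    A voxel is plotted iff its intensity is inside the valid range
    (strictly above lower, at-or-below upper) in at least one of the two
    channels.  Bin edges span [0, max intensity] per axis and are
    recorded on the result.
    """
    if bins < 2:
        raise ValidationError(f"bins must be >= 2, got {bins}")
    a = (ch_a.voxels if isinstance(ch_a, ChannelVolume) else np.asarray(ch_a))
    b = (ch_b.voxels if isinstance(ch_b, ChannelVolume) else np.asarray(ch_b))
    if a.shape != b.shape:
        raise ValidationError(f"channel grids differ: {a.shape} vs {b.shape}")

    va = _valid(a, t_a)
    vb = _valid(b, t_b)
    keep = va | vb
    region_counts = {
        "both": int((va & vb).sum()),
        "only_a": int((va & ~vb).sum()),
        "only_b": int((~va & vb).sum()),
    }

    a_kept = a[keep].astype(np.float64)
    b_kept = b[keep].astype(np.float64)
    x_max = max(float(a.max()) if a.size else 1.0, t_a.upper, 1.0)
    y_max = max(float(b.max()) if b.size else 1.0, t_b.upper, 1.0)
    counts, x_edges, y_edges = np.histogram2d(
        a_kept, b_kept, bins=bins, range=[[0.0, x_max], [0.0, y_max]])

    labels = tuple(
        ch.label if isinstance(ch, ChannelVolume) else f"Channel {i + 1}"
        for i, ch in enumerate((ch_a, ch_b))
    )
    return Histogram2D(counts=counts.astype(np.int64), x_edges=x_edges,
                       y_edges=y_edges, thresholds=(t_a, t_b),
                       n_plotted=int(keep.sum()), region_counts=region_counts,
                       channel_labels=labels)


def render_histogram2d(h: Histogram2D,
                       out_path_static: str | os.PathLike,
                       out_path_interactive: str | os.PathLike | None = None,
                       log_scale: bool = False, title: str = "") -> None:
    """Write a static PNG and an optional self-contained interactive HTML.

    The PNG shows the count matrix with a color bar (optionally
    log-scaled).  The HTML embeds the same image plus the raw counts and
    bin edges as JSON with a cursor readout, so individual intensity
    combinations can be inspected in a browser without any server.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LogNorm

    fig, ax = plt.subplots(figsize=(6.5, 5.5))
    masked = np.ma.masked_equal(h.counts.T, 0)
    norm = LogNorm(vmin=1, vmax=max(int(h.counts.max()), 1)) if log_scale else None
    mesh = ax.pcolormesh(h.x_edges, h.y_edges, masked, norm=norm,
                         cmap="viridis")
    cbar = fig.colorbar(mesh, ax=ax)
    cbar.set_label("voxel count")
    ax.set_xlabel(f"{h.channel_labels[0]} intensity")
    ax.set_ylabel(f"{h.channel_labels[1]} intensity")
    if title:
        ax.set_title(title)

    out_path_static = os.fspath(out_path_static)
    try:
        fig.savefig(out_path_static, dpi=150, bbox_inches="tight")
    except OSError as exc:
        raise IOError(f"cannot write {out_path_static!r}: {exc}") from exc

    if out_path_interactive is not None:
        buf = io.BytesIO()
        fig.savefig(buf, format="png", dpi=110, bbox_inches="tight")
        png64 = base64.b64encode(buf.getvalue()).decode("ascii")
        payload = {
            "counts": h.counts.tolist(),
            "x_edges": h.x_edges.tolist(),
            "y_edges": h.y_edges.tolist(),
            "n_plotted": h.n_plotted,
            "max_count": int(h.counts.max()) if h.counts.size else 0,
            "labels": list(h.channel_labels),
        }
        html = _INTERACTIVE_TEMPLATE.format(
            title=title or "2D intensity histogram",
            png64=png64, payload=json.dumps(payload))
        try:
            with open(os.fspath(out_path_interactive), "w") as fh:
                fh.write(html)
        except OSError as exc:
            raise IOError(
                f"cannot write {out_path_interactive!r}: {exc}") from exc
    plt.close(fig)


_INTERACTIVE_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{title}</title></head>
<body>
<h3>{title}</h3>
<img id="hist" src="data:image/png;base64,{png64}" alt="2D histogram">
<p id="readout">Move the cursor over the plot area to inspect counts.</p>
<script>
const data = {payload};
const img = document.getElementById("hist");
const out = document.getElementById("readout");
img.addEventListener("mousemove", (ev) => {{
  const r = img.getBoundingClientRect();
  const fx = (ev.clientX - r.left) / r.width;
  const fy = 1 - (ev.clientY - r.top) / r.height;
  const nx = data.counts.length, ny = data.counts[0].length;
  const i = Math.min(nx - 1, Math.max(0, Math.floor(fx * nx)));
  const j = Math.min(ny - 1, Math.max(0, Math.floor(fy * ny)));
  const x0 = data.x_edges[i].toFixed(1), x1 = data.x_edges[i + 1].toFixed(1);
  const y0 = data.y_edges[j].toFixed(1), y1 = data.y_edges[j + 1].toFixed(1);
  out.textContent = `${{data.labels[0]}} [${{x0}}, ${{x1}})  /  ` +
    `${{data.labels[1]}} [${{y0}}, ${{y1}})  count ~ ${{data.counts[i][j]}}` +
    ` (max ${{data.max_count}}, plotted ${{data.n_plotted}})`;
}});
</script>
</body></html>
"""
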