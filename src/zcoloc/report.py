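"""Results spreadsheet assembly.

Every run is archived as an XLSX workbook with a summary sheet (stack
name, timestamp, annotation, thresholds, ROI) and a results sheet (PCC
per channel pair, global and per-channel intersection coefficients, Venn
region percentages), with the generated diagrams embedded.  A plain CSV
twin of the results sheet is written alongside for scripted parsing;
the CSV carries the 4-decimal display strings so that identical runs
produce byte-identical files (the timestamp is supplied by the caller,
never sampled here).

Undefined coefficients appear as the literal string "n/a".
"""

from __future__ import annotations

import csv
import math
import os
from dataclasses import dataclass, field

from .errors import ValidationError
from .metrics import ColocResult
from .venn import format_percent


def fmt4(x: float | None) -> str:
    """4-decimal display string, or "n/a" for undefined values."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "n/a"
    return f"{float(x):.4f}"


@dataclass
class RunReport:
    """Everything recorded about one colocalization run."""

    stack_name: str
    result: ColocResult
    channel_labels: dict[int, str] = field(default_factory=dict)
    annotation: str = ""
    timestamp: str = ""  # ISO-8601, supplied by the caller
    artifact_paths: list[str] = field(default_factory=list)


def _results_rows(report: RunReport) -> list[tuple[str, str]]:
    res = report.result
    labels = {
        i: report.channel_labels.get(i, f"Channel {i}")
        for i in res.selected_channels
    }
    rows: list[tuple[str, str]] = []
    for (a, b), v in sorted(res.pcc.items()):
        rows.append((f"PCC ({labels[a]} vs {labels[b]})", fmt4(v)))
    rows.append(("Global intersection coefficient I",
                 fmt4(res.global_intersection)))
    for i in res.selected_channels:
        rows.append((f"Intersection coefficient i{i} ({labels[i]})",
                     fmt4(res.per_channel_intersection[i])))
    for key in sorted(res.venn_fractions, key=lambda s: (len(s), sorted(s))):
        name = " & ".join(labels[i] for i in sorted(key))
        rows.append((f"Venn region [{name}] % of union",
                     format_percent(res.venn_fractions[key])))
    rows.append(("Voxels analyzed", str(res.n_voxels)))
    return rows


def _summary_rows(report: RunReport) -> list[tuple[str, str]]:
    res = report.result
    rows = [
        ("Stack", report.stack_name),
        ("Timestamp", report.timestamp),
        ("Annotation", report.annotation),
        ("Selected channels",
         ", ".join(str(i) for i in res.selected_channels)),
    ]
    for i in res.selected_channels:
        t = res.thresholds[i]
        rows.append((f"Threshold channel {i}", f"{t.lower:g}..{t.upper:g}"))
    rows.append(("ROI (z, y, x; half-open)",
                 f"{res.roi.min_corner}..{res.roi.max_corner}"))
    return rows


def write_report(report: RunReport, out_path: str | os.PathLike) -> str:
    """Write the XLSX workbook and its CSV twin.

    ``out_path`` is the workbook path (``.xlsx`` appended if missing);
    the CSV twin replaces the extension with ``.csv``.  Returns the CSV
    path.  All referenced artifact files must exist at write time.
    """
    from openpyxl import Workbook
    from openpyxl.drawing.image import Image as XLImage

    for p in report.artifact_paths:
        if not os.path.exists(p):
            raise ValidationError(f"artifact file missing: {p!r}")

    out_path = os.fspath(out_path)
    if not out_path.endswith(".xlsx"):
        out_path += ".xlsx"
    csv_path = out_path[:-5] + ".csv"

    wb = Workbook()
    ws = wb.active
    ws.title = "Summary"
    ws.append(["Field", "Value"])
    for row in _summary_rows(report):
        ws.append(list(row))

    rs = wb.create_sheet("Results")
    rs.append(["Metric", "Value"])
    results = _results_rows(report)
    for row in results:
        rs.append(list(row))

    anchor_row = len(results) + 4
    for k, p in enumerate(report.artifact_paths):
        if os.path.splitext(p)[1].lower() in (".png", ".jpg", ".jpeg"):
            img = XLImage(p)
            rs.add_image(img, f"{chr(ord('D') + 0)}{anchor_row}")
            anchor_row += max(1, int(img.height / 19) + 2)
        rs.append(["Artifact", os.path.basename(p)])

    try:
        wb.save(out_path)
        with open(csv_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["Metric", "Value"])
            writer.writerows(results)
    except OSError as exc:
        raise IOError(f"cannot write report {out_path!r}: {exc}") from exc
    return csv_path
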