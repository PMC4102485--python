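"""Reading quantities, exporting diagrams, and the batch evaluation harness."""

from __future__ import annotations

import json
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd

from .datagen import DataLibrary
from .diagram import (
    CURVE_LABELS,
    REGION_LABELS,
    Ellipse,
    FitResult,
    Quantities7,
    VennDiagram3,
)
from .metrics import GOOD_EPS
from .optimizer import fit

__all__ = [
    "EvalSummary",
    "read_quantities",
    "write_diagram",
    "read_diagram_txt",
    "evaluate",
]

#: exported SVG/PNG viewport size in pixels
VIEWPORT = 600.0
_MARGIN = 0.05

#: heterogeneous stroke channels per curve: colour, dash pattern, width
_STYLE = {
    "a": ("#1b9e77", "none", 3.0),
    "b": ("#d95f02", "12,6", 2.2),
    "c": ("#7570b3", "4,4", 1.6),
}


def read_quantities(path: Union[str, Path], format: Optional[str] = None) -> List[Quantities7]:
    """Parse one or more 7-quantity data sets from CSV, TSV or JSON.

    CSV/TSV files carry a header with the seven region labels in any order
    and one data set per row; JSON holds a single object keyed by the labels
    or a list of such objects.  Non-positive or non-numeric entries raise a
    ``ValueError`` naming the offending row and column.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "json":
        payload = json.loads(path.read_text())
        records = payload if isinstance(payload, list) else [payload]
        df = pd.DataFrame(records)
    elif fmt in ("csv", "tsv"):
        df = pd.read_csv(path, sep="\t" if fmt == "tsv" else ",")
    else:
        raise ValueError(f"unsupported input format {fmt!r}")
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [lab for lab in REGION_LABELS if lab not in df.columns]
    if missing:
        raise ValueError(f"missing region column(s): {', '.join(missing)}")
    out = []
    for idx, row in df.iterrows():
        vals = {}
        for lab in REGION_LABELS:
            v = row[lab]
            try:
                v = float(v)
            except (TypeError, ValueError):
                raise ValueError(f"row {idx}, column {lab!r}: non-numeric value {v!r}")
            if not math.isfinite(v) or v <= 0:
                raise ValueError(
                    f"row {idx}, column {lab!r}: quantities must be strictly "
                    f"positive, got {v!r}"
                )
            vals[lab] = v
        out.append(Quantities7(vals))
    return out


def _viewport_transform(d: VennDiagram3):
    """Scale + offset mapping diagram coordinates into the export viewport."""
    los, his = [], []
    for lab in CURVE_LABELS:
        e = d[lab]
        ex = math.hypot(e.s1 * math.cos(e.theta), e.s2 * math.sin(e.theta))
        ey = math.hypot(e.s1 * math.sin(e.theta), e.s2 * math.cos(e.theta))
        los.append((e.cx - ex, e.cy - ey))
        his.append((e.cx + ex, e.cy + ey))
    lo = np.min(los, axis=0)
    hi = np.max(his, axis=0)
    span = float(max(hi - lo))
    scale = VIEWPORT * (1 - 2 * _MARGIN) / span
    centre = 0.5 * (lo + hi)
    return scale, centre


def _svg_document(d: VennDiagram3) -> ET.Element:
    scale, centre = _viewport_transform(d)
    half = VIEWPORT / 2
    root = ET.Element(
        "svg",
        xmlns="http://www.w3.org/2000/svg",
        width=f"{VIEWPORT:.0f}",
        height=f"{VIEWPORT:.0f}",
        viewBox=f"0 0 {VIEWPORT:.0f} {VIEWPORT:.0f}",
    )
    for lab in CURVE_LABELS:
        e = d[lab]
        # SVG y grows downward: mirror the y offset and flip the angle
        px = half + scale * (e.cx - centre[0])
        py = half - scale * (e.cy - centre[1])
        colour, dash, width = _STYLE[lab]
        attrs = {
            "cx": "0",
            "cy": "0",
            "rx": f"{scale * e.s1:.6f}",
            "ry": f"{scale * e.s2:.6f}",
            "transform": f"translate({px:.6f},{py:.6f}) rotate({-math.degrees(e.theta):.6f})",
            "fill": "none",
            "stroke": colour,
            "stroke-width": f"{width}",
        }
        if dash != "none":
            attrs["stroke-dasharray"] = dash
        el = ET.SubElement(root, "ellipse", attrs)
        el.set("id", f"curve-{lab}")
    return root


def _write_png(d: VennDiagram3, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse as MplEllipse

    fig, ax = plt.subplots(figsize=(6, 6), dpi=100)
    for lab in CURVE_LABELS:
        e = d[lab]
        colour, dash, width = _STYLE[lab]
        ls = "-" if dash == "none" else (0, tuple(float(v) for v in dash.split(",")))
        ax.add_patch(
            MplEllipse(
                (e.cx, e.cy),
                2 * e.s1,
                2 * e.s2,
                angle=math.degrees(e.theta),
                fill=False,
                edgecolor=colour,
                linestyle=ls,
                linewidth=width,
                label=lab,
            )
        )
    scale, centre = _viewport_transform(d)
    half = VIEWPORT / 2 / scale
    ax.set_xlim(centre[0] - half, centre[0] + half)
    ax.set_ylim(centre[1] - half, centre[1] + half)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.legend(loc="upper right", frameon=False)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def write_diagram(
    result: Union[FitResult, VennDiagram3], path: Union[str, Path], format: Optional[str] = None
) -> Path:
    """Export a diagram as ``svg``, ``png`` or full-precision ``txt``.

    The text form (one line per curve: label cx cy s1 s2 theta) round-trips
    to the identical diagram via :func:`read_diagram_txt`.  Output bodies
    contain no timestamps, so identical inputs give identical files.
    """
    d = result.diagram if isinstance(result, FitResult) else result
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "svg":
        root = _svg_document(d)
        ET.indent(root)
        path.write_text(ET.tostring(root, encoding="unicode") + "\n")
    elif fmt == "png":
        _write_png(d, path)
    elif fmt == "txt":
        lines = []
        for lab in CURVE_LABELS:
            e = d[lab]
            lines.append(
                f"{lab} {e.cx!r} {e.cy!r} {e.s1!r} {e.s2!r} {e.theta!r}"
            )
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unsupported output format {fmt!r}")
    return path


def read_diagram_txt(path: Union[str, Path]) -> VennDiagram3:
    """Re-import a diagram written in the text format."""
    ellipses: Dict[str, Ellipse] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        lab, *vals = line.split()
        cx, cy, s1, s2, theta = (float(v) for v in vals)
        ellipses[lab] = Ellipse(cx, cy, s1, s2, theta)
    return VennDiagram3(ellipses)


@dataclass(frozen=True)
class EvalSummary:
    """Aggregate statistics of a batch evaluation."""

    n: int
    fraction_good: float
    diag_error_stats: Dict[str, float]  # over non-good items only
    iteration_stats: Dict[str, float]
    rerun_histogram: Dict[int, int]
    errors: int = 0


def evaluate(
    library: DataLibrary,
    mode: str = "ellipses",
    rerun: bool = True,
    records_path: Optional[Union[str, Path]] = None,
) -> EvalSummary:
    """Fit every item of a library and aggregate the outcome.

    Per-item records (diagError, accuracy, iterations, reruns) are streamed
    to ``records_path`` as CSV when given.  Item-level failures are recorded,
    not fatal.  The summary is independent of item order.
    """
    if len(library) == 0:
        raise ValueError("library is empty")
    records = []
    for i, item in enumerate(library.items):
        try:
            r = fit(item, rerun=rerun, mode=mode)
            records.append(
                {
                    "item": i,
                    "diag_error": r.diag_error,
                    "accurate": r.accurate,
                    "iterations": r.iterations,
                    "reruns": r.reruns_used,
                    "error": "",
                }
            )
        except Exception as exc:  # pragma: no cover - defensive
            records.append(
                {
                    "item": i,
                    "diag_error": float("nan"),
                    "accurate": False,
                    "iterations": 0,
                    "reruns": 0,
                    "error": str(exc),
                }
            )
    df = pd.DataFrame(records)
    if records_path is not None:
        df.to_csv(records_path, index=False)
    good = df["accurate"]
    bad = df.loc[~good & df["error"].eq(""), "diag_error"]
    stats = (
        {
            "min": float(bad.min()),
            "median": float(bad.median()),
            "mean": float(bad.mean()),
            "max": float(bad.max()),
        }
        if len(bad)
        else {}
    )
    hist = df.loc[good, "reruns"].value_counts().to_dict()
    return EvalSummary(
        n=len(df),
        fraction_good=float(good.mean()),
        diag_error_stats=stats,
        iteration_stats={
            "median": float(df["iterations"].median()),
            "mean": float(df["iterations"].mean()),
        },
        rerun_histogram={int(k): int(v) for k, v in sorted(hist.items())},
        errors=int(df["error"].ne("").sum()),
    )
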