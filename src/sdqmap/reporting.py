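"""Choropleth maps and run reports.

Maps mirror the study's presentation: ward-level median score and
percentage of high scorers, relative rates (RR) before/after covariate
adjustment, and exceedance probabilities with a binary emphasis at 0.8
(the conventional threshold for "high certainty" of an elevated RR).
Every map writes a sidecar CSV with the plotted values so that figure and
table never disagree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.collections import PatchCollection
from matplotlib.patches import Polygon as MplPolygon

from .geography import Geography

EXCEEDANCE_THRESHOLD = 0.8


@dataclass
class MapLayer:
    """Per-ward values to map. ``kind`` is "continuous" (quantile breaks,
    5 classes) or "exceedance" (binary emphasis at 0.8)."""

    values: dict[int, float]
    title: str = ""
    kind: str = "continuous"
    n_classes: int = 5

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "exceedance"):
            raise ValueError(f"unknown layer kind {self.kind!r}")


def _legend_breaks(vals: np.ndarray, layer: MapLayer) -> np.ndarray:
    if layer.kind == "exceedance":
        return np.array([0.0, EXCEEDANCE_THRESHOLD, 1.0 + 1e-9])
    uniq = np.unique(vals)
    if uniq.size == 1:
        return np.array([uniq[0], uniq[0] + 1e-9])
    qs = np.linspace(0, 1, layer.n_classes + 1)
    breaks = np.quantile(vals, qs)
    breaks = np.unique(breaks)
    breaks[-1] += 1e-9
    return breaks


def render_choropleth(geo: Geography, layer: MapLayer,
                      out_path: str | Path) -> Path:
    """Render one ward map to ``out_path`` (PNG/SVG by extension) and its
    values to a sidecar CSV."""
    missing = [w for w in layer.values if w not in set(geo.ward_ids)]
    if missing:
        raise ValueError(f"wards not in geometry: {sorted(missing)}")
    vals = np.array([layer.values.get(w, np.nan) for w in geo.ward_ids])
    breaks = _legend_breaks(vals[~np.isnan(vals)], layer)
    n_cls = len(breaks) - 1
    cmap = plt.get_cmap("OrRd" if layer.kind == "exceedance" else "viridis",
                        n_cls)

    fig, ax = plt.subplots(figsize=(6, 6))
    patches, colors = [], []
    for wid, poly, v in zip(geo.ward_ids, geo.polygons, vals):
        ext = np.asarray(poly.exterior.coords)
        patches.append(MplPolygon(ext, closed=True))
        cls = (np.searchsorted(breaks, v, side="right") - 1
               if not np.isnan(v) else -1)
        cls = min(max(cls, 0), n_cls - 1)
        colors.append(cmap(cls) if not np.isnan(v) else (0.8, 0.8, 0.8, 1))
        c = poly.centroid
        ax.annotate(str(wid), (c.x, c.y), ha="center", va="center",
                    fontsize=7)
    coll = PatchCollection(patches, facecolor=colors, edgecolor="black",
                           linewidth=0.6)
    ax.add_collection(coll)
    ax.autoscale()
    ax.set_aspect("equal")
    ax.set_axis_off()
    ax.set_title(layer.title)
    handles = [plt.Rectangle((0, 0), 1, 1, facecolor=cmap(i))
               for i in range(n_cls)]
    labels = [f"{breaks[i]:.3g}–{breaks[i + 1]:.3g}"
              for i in range(n_cls)]
    if layer.kind == "exceedance" and n_cls == 2:
        labels = [f"< {EXCEEDANCE_THRESHOLD}", f">= {EXCEEDANCE_THRESHOLD}"]
    ax.legend(handles, labels, loc="lower left", fontsize=7,
              title="value", title_fontsize=7)
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)

    sidecar = out_path.with_suffix(".csv")
    pd.DataFrame({"ward_id": geo.ward_ids, "value": vals}
                 ).to_csv(sidecar, index=False)
    return out_path


def layer_from_table(table: pd.DataFrame, key: str, value: str,
                     title: str = "", kind: str = "continuous") -> MapLayer:
    return MapLayer(dict(zip(table[key].astype(int), table[value])),
                    title=title, kind=kind)


# ---------------------------------------------------------------------------
# report assembly


def _section_table(path: Path, title: str) -> str:
    if not path.exists():
        return f"## {title}\n\n*Not available: {path.name} missing.*\n"
    df = pd.read_csv(path)
    return f"## {title}\n\n{df.to_markdown(index=False)}\n"


def build_report(run_dir: str | Path, out_name: str = "report.md") -> Path:
    """Assemble a self-contained Markdown report from a pipeline run
    directory. Every number shown is read back from the run's CSV outputs;
    missing stages get an explicit gap notice."""
    run = Path(run_dir)
    parts = ["# SDQ spatiotemporal analysis report\n"]

    parts.append(_section_table(run / "descriptives.csv",
                                "Descriptive summary"))

    parts.append("# Disease-mapping model (ward-year high-score counts)\n")
    for name, title in [("dm_dic_ledger.csv", "DIC forward-build ledger"),
                        ("dm_rr_fixed.csv", "Fixed-effect relative rates"),
                        ("dm_rr_ward.csv", "Ward relative rates")]:
        parts.append(_section_table(run / name, title))

    parts.append("# Multilevel model (individual scores)\n")
    for name, title in [("ml_dic_ledger.csv", "DIC forward-build ledger"),
                        ("ml_rr_fixed.csv", "Fixed-effect relative rates"),
                        ("ml_rr_ward.csv", "Ward relative rates"),
                        ("ml_rr_preschool.csv", "Preschool relative rates")]:
        parts.append(_section_table(run / name, title))

    diag_path = run / "diagnostics.json"
    if diag_path.exists():
        diag = json.loads(diag_path.read_text())
        parts.append("## Diagnostics\n\n```json\n"
                     + json.dumps(diag, indent=1, sort_keys=True)
                     + "\n```\n")
    else:
        parts.append("## Diagnostics\n\n*Not available: diagnostics.json "
                     "missing.*\n")

    maps = sorted(p.name for p in run.glob("map_*.png"))
    if maps:
        parts.append("## Maps\n\n"
                     + "\n".join(f"![{m}]({m})" for m in maps) + "\n")
    else:
        parts.append("## Maps\n\n*No maps rendered.*\n")

    out = run / out_name
    out.write_text("\n".join(parts))
    return out
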