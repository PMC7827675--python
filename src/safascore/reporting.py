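"""Sustainability polygons and report export.

The polygon is a radar-style chart with one spoke per theme (21 for the
default framework), spoke radius encoding the theme rating (ordinal + 1 on a
1-5 scale), a connecting rating line, arc segments grouping themes by
dimension, and the information-quality label (1/2/3) beside each theme name.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .aggregation import FarmAssessment
from .framework import Framework, Rating
from .valuation import RatingBands, ValuationResult

__all__ = ["RATING_COLORS", "DIMENSION_COLORS", "render_polygon", "export_report"]

#: Rating colour semantics (best = dark green ... unacceptable = red).
RATING_COLORS: dict[Rating, str] = {
    Rating.BEST: "#1b7837",  # dark green
    Rating.GOOD: "#a6dba0",  # light green
    Rating.MODERATE: "#ffd92f",  # yellow
    Rating.LIMITED: "#f4a442",  # orange
    Rating.UNACCEPTABLE: "#d73027",  # red
}

#: Dimension group colours.
DIMENSION_COLORS: dict[str, str] = {
    "good-governance": "#4477aa",  # blue
    "environmental-integrity": "#228833",  # green
    "economic-resilience": "#ccbb44",  # yellow
    "social-well-being": "#888888",  # grey
}


def render_polygon(
    assessment: FarmAssessment,
    framework: Framework,
    out: str | Path,
    dpi: int = 150,
) -> Path:
    """Render one farm's sustainability polygon to a vector image (SVG).

    Themes are ordered around the ring grouped by dimension, in published
    table order.  Output carries no embedded timestamp, so rendering is
    byte-deterministic for a fixed assessment.
    """
    out = Path(out)
    themes = [t for d in framework.dimensions for t in framework.themes_of(d.id)]
    missing = [t.id for t in themes if t.id not in assessment.theme_results]
    if missing:
        raise ValueError(f"assessment lacks theme results: {missing}")
    n = len(themes)
    angles = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False) + np.pi / 2.0

    # fixed hash salt + no date metadata -> byte-deterministic SVG output
    plt.rcParams["svg.hashsalt"] = "safascore"
    fig, ax = plt.subplots(figsize=(9, 9), subplot_kw={"projection": "polar"})
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    radii = []
    for theme, angle in zip(themes, angles):
        tr = assessment.theme_results[theme.id]
        radius = tr.rating.value + 1  # 1..5
        radii.append(radius)
        ax.plot(
            [angle - np.pi / 2.0],
            [radius],
            "o",
            markersize=11,
            color=RATING_COLORS[tr.rating],
            zorder=3,
        )
        ax.text(
            angle - np.pi / 2.0,
            5.9,
            f"{theme.name} [{tr.accuracy_quality}]",
            fontsize=7,
            ha="center",
            va="center",
            color=DIMENSION_COLORS[theme.dimension_id],
        )
    # connecting rating line (closed)
    theta = np.append(angles, angles[0]) - np.pi / 2.0
    r = np.append(radii, radii[0])
    ax.plot(theta, r, "-", color="black", linewidth=1.6, zorder=2)
    # dimension group arcs just outside the rating rings
    for dim in framework.dimensions:
        idx = [i for i, t in enumerate(themes) if t.dimension_id == dim.id]
        arc = np.linspace(angles[idx[0]] - 0.12, angles[idx[-1]] + 0.12, 50) - np.pi / 2.0
        ax.plot(arc, np.full_like(arc, 5.35), color=DIMENSION_COLORS[dim.id], linewidth=5)
    ax.set_ylim(0, 6.4)
    ax.set_yticks([1, 2, 3, 4, 5])
    ax.set_yticklabels([lvl.label for lvl in Rating], fontsize=6)
    ax.set_xticks([])
    ax.set_title(f"{assessment.farm_id} ({assessment.system_type})", pad=28)
    fig.savefig(out, dpi=dpi, bbox_inches="tight", metadata={"Date": None})
    plt.close(fig)
    return out


def export_report(
    assessments: Sequence[FarmAssessment],
    valuations: Sequence[ValuationResult],
    pos_bands: RatingBands,
    neg_bands: RatingBands,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the ranking table, per-farm theme tables and band definitions.

    Emits byte-stable JSON and CSV (no timestamps).  Farm ids in the two
    inputs must agree.
    """
    if not assessments:
        raise ValueError("at least one assessment required")
    a_ids = {a.farm_id for a in assessments}
    v_ids = {v.farm_id for v in valuations}
    if a_ids != v_ids:
        raise ValueError(
            f"farm-id mismatch between assessments and valuations: "
            f"{sorted(a_ids ^ v_ids)}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ranking = pd.DataFrame([v.to_dict() for v in sorted(valuations, key=lambda v: v.rank)])
    ranking_csv = out_dir / "ranking.csv"
    ranking.to_csv(ranking_csv, index=False)
    ranking_json = out_dir / "ranking.json"
    ranking_json.write_text(json.dumps(ranking.to_dict(orient="records"), indent=2) + "\n")

    def _bands_doc(b: RatingBands) -> dict:
        return {
            "direction": b.direction,
            "max_value": b.max_value,
            "intervals": [
                {"lo": lo, "hi": hi, "label": lab.label} for lo, hi, lab in b.intervals
            ],
        }

    bands_json = out_dir / "bands.json"
    bands_json.write_text(
        json.dumps(
            {"positive": _bands_doc(pos_bands), "negative": _bands_doc(neg_bands)},
            indent=2,
        )
        + "\n"
    )

    themes_rows = [
        {
            "farm_id": a.farm_id,
            "theme_id": tid,
            "percent": round(tr.percent, 4),
            "rating": tr.rating.label,
            "accuracy_quality": tr.accuracy_quality,
        }
        for a in assessments
        for tid, tr in a.theme_results.items()
    ]
    themes_csv = out_dir / "theme_results.csv"
    pd.DataFrame(themes_rows).to_csv(themes_csv, index=False)
    return {
        "ranking_csv": ranking_csv,
        "ranking_json": ranking_json,
        "bands_json": bands_json,
        "themes_csv": themes_csv,
    }
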