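"""Readers and writers for the delimited-text field-data formats.

All inputs are plain CSV:

* generic indicator scores: ``farm_id,indicator_id,percent,timeframe,data_type,methodology``
* capture tables: ``farm_id,taxon_group,species,count,endemic,at_risk,introduced``
* soil measurements: ``farm_id,property,measured,reference,units``
* WQ scores: ``farm_id,score_name,score_type,value`` (score_type: principle|criterion)
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .adapters import CAPTURE_COLUMNS, CaptureTable, SoilMeasurementSet, WQScoreSet

__all__ = [
    "read_generic_scores",
    "read_capture_tables",
    "read_soil_sets",
    "read_wq_sets",
    "write_generic_scores",
    "write_capture_tables",
    "write_soil_sets",
    "write_wq_sets",
]

GENERIC_COLUMNS = [
    "farm_id",
    "indicator_id",
    "percent",
    "timeframe",
    "data_type",
    "methodology",
]


def _read(path: str | Path, required: list[str], **kwargs) -> pd.DataFrame:
    df = pd.read_csv(path, **kwargs)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_generic_scores(path: str | Path) -> pd.DataFrame:
    """Generic per-indicator percent scores with accuracy metadata."""
    df = _read(path, GENERIC_COLUMNS)
    if not df["percent"].between(0, 100).all():
        raise ValueError(f"{path}: percent values outside [0, 100]")
    return df


def read_capture_tables(path: str | Path) -> dict[str, CaptureTable]:
    df = _read(
        path,
        ["farm_id", *CAPTURE_COLUMNS],
        dtype={"endemic": bool, "at_risk": bool, "introduced": bool},
    )
    return {
        fid: CaptureTable(fid, grp[CAPTURE_COLUMNS].reset_index(drop=True))
        for fid, grp in df.groupby("farm_id", sort=False)
    }


def read_soil_sets(path: str | Path) -> dict[str, SoilMeasurementSet]:
    df = _read(path, ["farm_id", "property", "measured", "reference", "units"])
    out = {}
    for fid, grp in df.groupby("farm_id", sort=False):
        props = {
            row["property"]: (float(row["measured"]), float(row["reference"]), row["units"])
            for _, row in grp.iterrows()
        }
        out[fid] = SoilMeasurementSet(fid, props)
    return out


def read_wq_sets(path: str | Path) -> dict[str, WQScoreSet]:
    df = _read(path, ["farm_id", "score_name", "score_type", "value"])
    out = {}
    for fid, grp in df.groupby("farm_id", sort=False):
        principles = {
            row["score_name"]: float(row["value"])
            for _, row in grp.iterrows()
            if row["score_type"] == "principle"
        }
        criteria = {
            row["score_name"]: float(row["value"])
            for _, row in grp.iterrows()
            if row["score_type"] == "criterion"
        }
        out[fid] = WQScoreSet(fid, principles, criteria or None)
    return out


def write_generic_scores(df: pd.DataFrame, path: str | Path) -> None:
    df[GENERIC_COLUMNS].to_csv(path, index=False)


def write_capture_tables(tables: dict[str, CaptureTable], path: str | Path) -> None:
    frames = []
    for fid, tbl in tables.items():
        frame = tbl.rows.copy()
        frame.insert(0, "farm_id", fid)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_soil_sets(sets: dict[str, SoilMeasurementSet], path: str | Path) -> None:
    rows = [
        {"farm_id": fid, "property": prop, "measured": m, "reference": r, "units": u}
        for fid, ms in sets.items()
        for prop, (m, r, u) in ms.properties.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_wq_sets(sets: dict[str, WQScoreSet], path: str | Path) -> None:
    rows = []
    for fid, wq in sets.items():
        for name, value in wq.principle_scores.items():
            rows.append(
                {"farm_id": fid, "score_name": name, "score_type": "principle", "value": value}
            )
        for name, value in (wq.criterion_scores or {}).items():
            rows.append(
                {"farm_id": fid, "score_name": name, "score_type": "criterion", "value": value}
            )
    pd.DataFrame(rows).to_csv(path, index=False)
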