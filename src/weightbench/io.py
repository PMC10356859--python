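"""Delimited-table and config I/O.

The participant table is a CSV with one row per enrollment record; missing
values use the token ``NA``.  Columns::

    subject_id, age_years, sex, height_m, consented,
    mr_usage_percent, attendance_fraction,
    weight_kg_wk_m1, weight_kg_wk_0, ..., weight_kg_wk_7
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .types import ALL_WEEKS, ParticipantRecord, Sex

NA_TOKEN = "NA"


def _week_col(week: int) -> str:
    return f"weight_kg_wk_{'m1' if week == -1 else week}"


PARTICIPANT_COLUMNS = [
    "subject_id",
    "age_years",
    "sex",
    "height_m",
    "consented",
    "mr_usage_percent",
    "attendance_fraction",
    *[_week_col(w) for w in ALL_WEEKS],
]


def records_to_frame(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "age_years": r.age,
            "sex": None if r.sex is None else Sex(r.sex).value,
            "height_m": r.height,
            "consented": bool(r.consented),
            "mr_usage_percent": r.mr_usage_percent,
            "attendance_fraction": r.attendance_fraction,
        }
        for w in ALL_WEEKS:
            row[_week_col(w)] = r.weights_by_week.get(w)
        rows.append(row)
    return pd.DataFrame(rows, columns=PARTICIPANT_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[ParticipantRecord]:
    missing = [c for c in PARTICIPANT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"participant table lacks columns: {missing}")
    records = []
    for i, row in frame.iterrows():
        try:
            weights = {}
            for w in ALL_WEEKS:
                v = row[_week_col(w)]
                if pd.notna(v):
                    weights[w] = float(v)
            records.append(
                ParticipantRecord(
                    subject_id=str(row["subject_id"]),
                    age=float(row["age_years"]) if pd.notna(row["age_years"]) else None,
                    sex=Sex(row["sex"]) if pd.notna(row["sex"]) else None,
                    height=float(row["height_m"]) if pd.notna(row["height_m"]) else None,
                    consented=bool(row["consented"]),
                    weights_by_week=weights,
                    mr_usage_percent=(
                        float(row["mr_usage_percent"])
                        if pd.notna(row["mr_usage_percent"])
                        else None
                    ),
                    attendance_fraction=(
                        float(row["attendance_fraction"])
                        if pd.notna(row["attendance_fraction"])
                        else None
                    ),
                )
            )
        except (ValueError, TypeError) as err:
            raise ValueError(f"participant table row {i}: {err}") from err
    return records


def write_participant_table(records: Sequence[ParticipantRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False, na_rep=NA_TOKEN, float_format="%.6f")


def read_participant_table(path: str | Path) -> list[ParticipantRecord]:
    frame = pd.read_csv(path, na_values=[NA_TOKEN], keep_default_na=True)
    return frame_to_records(frame)


def write_yaml(payload: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def config_hash(payload: dict) -> str:
    """Short stable hash of a config mapping (canonical YAML, sha256)."""
    canon = yaml.safe_dump(payload, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
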