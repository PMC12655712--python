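"""CSV interchange for feed diaries and cohort tables.

Diary CSV layout: one row per event with columns dyad_id, start_time,
end_time, kind, pre_weight_g, post_weight_g, breast_side. Times are either
decimal hours from the diary origin (``dialect="hours"``) or ISO-8601
timestamps (``dialect="iso"``, converted to minutes from each dyad's first
start).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .measures import FeedDiary, FeedEvent, FeedKind

DIARY_COLUMNS = ["dyad_id", "start_time", "end_time", "kind",
                 "pre_weight_g", "post_weight_g", "breast_side"]


def write_diaries_csv(diaries: dict[str, FeedDiary], path, dialect: str = "hours"):
    """Write diaries to one flat CSV (times as decimal hours)."""
    if dialect != "hours":
        raise ValueError("writing supports the 'hours' dialect only")
    rows = []
    for diary in diaries.values():
        for e in diary.events:
            rows.append(
                {
                    "dyad_id": diary.dyad_id,
                    "start_time": e.start_time / 60.0,
                    "end_time": e.end_time / 60.0,
                    "kind": e.kind.value,
                    "pre_weight_g": e.pre_weight_g,
                    "post_weight_g": e.post_weight_g,
                    "breast_side": e.breast_side,
                }
            )
    pd.DataFrame(rows, columns=DIARY_COLUMNS).to_csv(path, index=False)


def read_diaries_csv(path, dialect: str = "hours") -> dict[str, FeedDiary]:
    """Read a diary CSV back into per-dyad :class:`FeedDiary` objects."""
    df = pd.read_csv(path)
    missing = set(DIARY_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise ValueError(f"diary CSV missing columns: {sorted(missing)}")
    if dialect == "hours":
        df["_start_min"] = df["start_time"].astype(float) * 60.0
        df["_end_min"] = df["end_time"].astype(float) * 60.0
    elif dialect == "iso":
        start = pd.to_datetime(df["start_time"])
        end = pd.to_datetime(df["end_time"])
        origin = start.groupby(df["dyad_id"]).transform("min")
        df["_start_min"] = (start - origin).dt.total_seconds() / 60.0
        df["_end_min"] = (end - origin).dt.total_seconds() / 60.0
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    diaries: dict[str, FeedDiary] = {}
    for dyad_id, grp in df.groupby("dyad_id", sort=False):
        events = [
            FeedEvent(
                float(r["_start_min"]), float(r["_end_min"]),
                FeedKind(r["kind"]),
                None if pd.isna(r["pre_weight_g"]) else float(r["pre_weight_g"]),
                None if pd.isna(r["post_weight_g"]) else float(r["post_weight_g"]),
                None if ("breast_side" not in r or pd.isna(r["breast_side"]))
                else str(r["breast_side"]),
            )
            for _, r in grp.iterrows()
        ]
        diaries[str(dyad_id)] = FeedDiary(str(dyad_id), events)
    return diaries


def write_cohort_csv(cohort: pd.DataFrame, path):
    cohort.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    from .measures import RISK_FACTOR_COLUMNS

    for col in RISK_FACTOR_COLUMNS:
        if col in df.columns:
            df[col] = df[col].astype("boolean")
    return df
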