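"""CSV / JSON readers and writers for the pipeline's tabular interfaces.

All tables are plain comma-separated text with a header row; missing
values are written as empty fields.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import DailyChart
from .windows import classify_cms

CHART_COLUMNS = ["woman_id", "cycle_id", "day", "bbt", "cms_feeling",
                 "cms_appearance", "cms_secretion", "cms_level",
                 "intercourse", "protected", "disturbance"]


def write_charts(charts: Sequence[DailyChart], path) -> None:
    frames = [c.to_frame() for c in charts]
    df = pd.concat(frames, ignore_index=True) if frames \
        else pd.DataFrame(columns=CHART_COLUMNS)
    df.to_csv(path, index=False, na_rep="")


def read_charts(path) -> list[DailyChart]:
    """Read ``charts.csv``; the numeric mucus level is re-derived from the
    text triple when the ``cms_level`` field is empty."""
    df = pd.read_csv(path, dtype={"woman_id": str},
                     keep_default_na=True)
    charts = []
    for (wid, cid), g in df.groupby(["woman_id", "cycle_id"], sort=True):
        g = g.sort_values("day")
        if "cms_level" in g and g["cms_level"].notna().all():
            lv = g["cms_level"].to_numpy(dtype=int)
        else:
            lv = np.array([
                int(row.cms_level) if pd.notna(row.cms_level)
                else classify_cms(str(row.cms_feeling) if pd.notna(row.cms_feeling) else "",
                                  str(row.cms_appearance) if pd.notna(row.cms_appearance) else "",
                                  str(row.cms_secretion) if pd.notna(row.cms_secretion) else "")
                for row in g.itertuples()
            ])
        charts.append(DailyChart(
            woman_id=str(wid), cycle_id=int(cid),
            day=g["day"].to_numpy(dtype=int),
            bbt=g["bbt"].to_numpy(dtype=float),
            cms_level=lv,
            intercourse=g["intercourse"].fillna(0).to_numpy(dtype=int),
            protected=g.get("protected", pd.Series(0, index=g.index))
                       .fillna(0).to_numpy(dtype=int),
            disturbance=g.get("disturbance", pd.Series(0, index=g.index))
                         .fillna(0).to_numpy(dtype=int),
        ))
    return charts


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
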