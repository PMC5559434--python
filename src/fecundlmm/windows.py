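"""Symptothermal rule engine.

Implements the chart-reading rules of the C.A.Me.N. symptothermal method:
the five-level cervical-mucus classification, the three-over-six basal
body temperature shift, the mucus peak, the delimitation of the fertile
window (first day of felt or detected mucus through the evening of the
third high-temperature day after the peak), the partition of the cycle
into pre-ovulatory / fertile / post-ovulatory phases, the cycle-exclusion
cascade, and per-couple aggregate covariates for the conception model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .simulate import DailyChart

logger = logging.getLogger(__name__)

__all__ = [
    "FertileWindow",
    "CyclePhases",
    "FilterReport",
    "classify_cms",
    "detect_bbt_shift",
    "detect_mucus_peak",
    "delimit_fertile_window",
    "assign_cycle_phases",
    "filter_cycles",
    "aggregate_covariates",
]

# (feeling, appearance, secretion) -> ordinal level, lowercase keys
_CMS_TABLE = {
    ("not registered", "not registered", "not registered"): 0,
    ("dry or nothing felt", "nothing seen", "none"): 1,
    ("damp", "nothing seen", "none"): 2,
    ("damp", "yellowish and sticky", "secretions"): 3,
    ("wet and slippery", "transparent, stretchy, and watery", "secretions"): 4,
}

#: canonical text triple for each level (used when writing charts to CSV)
CMS_TEXT = {
    0: ("Not registered", "Not registered", "Not registered"),
    1: ("Dry or nothing felt", "Nothing seen", "None"),
    2: ("Damp", "Nothing seen", "None"),
    3: ("Damp", "Yellowish and sticky", "Secretions"),
    4: ("Wet and slippery", "Transparent, stretchy, and watery", "Secretions"),
}


def classify_cms(feeling: str, appearance: str, secretion: str) -> int:
    """Map a (feeling, appearance, secretion) triple to its 0-4 mucus level.

    Matching is case-insensitive; any triple outside the vocabulary maps to
    level 0 ("not registered") with a logged warning, so the function is
    total.
    """
    key = tuple(str(v).strip().lower() for v in (feeling, appearance, secretion))
    if key == ("", "", ""):
        return 0
    level = _CMS_TABLE.get(key)
    if level is None:
        logger.warning("unrecognized CMS triple %r -> level 0", key)
        return 0
    return level


@dataclass
class FertileWindow:
    """A delimited fertile interval, or the reason it could not be delimited."""

    woman_id: str = ""
    cycle_id: int = 0
    open_day: int | None = None
    peak_day: int | None = None
    shift_day: int | None = None
    close_day: int | None = None
    valid: bool = False
    reason: str = ""
    salvaged: bool = False  # non-strict fallback was used

    @property
    def length(self) -> int | None:
        if self.open_day is None or self.close_day is None:
            return None
        return self.close_day - self.open_day + 1


@dataclass
class CyclePhases:
    pre_ovulatory: tuple[int, int] | None
    fertile: tuple[int, int]
    post_ovulatory: tuple[int, int] | None


@dataclass
class FilterReport:
    n_input: int
    removed_protected: int
    removed_invalid_window: int
    removed_no_intercourse: int
    n_retained: int
    women_remaining: int


def _recorded(days: np.ndarray, bbt: np.ndarray,
              disturbance: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    """Days and values of usable temperatures (recorded, not disturbed)."""
    ok = ~np.isnan(bbt)
    if disturbance is not None:
        ok &= np.asarray(disturbance, dtype=bool) == False  # noqa: E712
    return np.asarray(days, dtype=int)[ok], np.asarray(bbt, dtype=float)[ok]


def detect_bbt_shift(days: Sequence[int], bbt: Sequence[float],
                     disturbance: Sequence[int] | None = None,
                     after_day: int | None = None,
                     max_gap_days: int = 1) -> int | None:
    """Three-over-six rule: first day of three consecutive recorded
    temperatures each strictly greater than the maximum of the six most
    recent recorded temperatures before it.

    Missing (NaN) and disturbance-flagged days are skipped, not imputed:
    "previous six" means the six most recent usable values.  The three
    high temperatures must fall on consecutive recorded days with calendar
    gaps of at most ``max_gap_days`` missing days between them.  With
    ``after_day`` set, only start days strictly later are considered.
    Returns None when no qualifying day exists or fewer than nine usable
    temperatures are available.
    """
    d, v = _recorded(np.asarray(days), np.asarray(bbt, dtype=float), disturbance)
    m = d.size
    if m < 9:
        return None
    for j in range(6, m - 2):
        if after_day is not None and d[j] <= after_day:
            continue
        if d[j + 2] - d[j] > 2 + 2 * max_gap_days or \
           d[j + 1] - d[j] > 1 + max_gap_days or \
           d[j + 2] - d[j + 1] > 1 + max_gap_days:
            continue
        base = v[j - 6:j].max()
        if v[j] > base and v[j + 1] > base and v[j + 2] > base:
            return int(d[j])
    return None


def _third_high_day(days, bbt, disturbance, shift_day) -> int | None:
    """Calendar day of the third recorded high temperature from shift_day."""
    d, _ = _recorded(np.asarray(days), np.asarray(bbt, dtype=float), disturbance)
    pos = np.flatnonzero(d == shift_day)
    if pos.size == 0 or pos[0] + 2 >= d.size:
        return None
    return int(d[pos[0] + 2])


def detect_mucus_peak(days: Sequence[int], cms_level: Sequence[int],
                      shift_day: int | None = None,
                      threshold: int = 2) -> int | None:
    """Mucus peak: last day attaining the cycle's maximum mucus level.

    Level 0 counts as unregistered, never as dry.  When ``shift_day`` is
    given, only days at or before it qualify.  Returns None when the
    cycle's maximum level is below ``threshold`` (no secretory day) or no
    qualifying day precedes the shift.
    """
    d = np.asarray(days, dtype=int)
    lv = np.asarray(cms_level, dtype=int)
    if d.size == 0:
        return None
    observed = lv > 0
    if not observed.any():
        return None
    peak_level = lv[observed].max()
    if peak_level < threshold:
        return None
    cand = (lv == peak_level)
    if shift_day is not None:
        cand &= d <= shift_day
    if not cand.any():
        return None
    return int(d[np.flatnonzero(cand)[-1]])


def delimit_fertile_window(chart: DailyChart, open_threshold: int = 2,
                           strict: bool = True,
                           max_gap_days: int = 1) -> FertileWindow:
    """Delimit the fertile window of one cycle.

    Opens on the first day with mucus level >= ``open_threshold`` (2 by
    default; 3 gives the less restrictive opening).  Closes on the third
    recorded high-temperature day, where the temperature shift is the first
    three-over-six day after the mucus peak.  In non-strict mode a chart
    whose shift cannot be placed after the peak is salvaged by accepting
    the whole-cycle shift, flagged via ``salvaged``.
    """
    w = FertileWindow(woman_id=chart.woman_id, cycle_id=chart.cycle_id)
    d_rec, _ = _recorded(chart.day, chart.bbt, chart.disturbance)
    if d_rec.size < 9:
        w.reason = "insufficient bbt"
        return w

    opens = np.flatnonzero(chart.cms_level >= open_threshold)
    if opens.size == 0:
        w.reason = "no mucus onset"
        return w
    w.open_day = int(chart.day[opens[0]])

    shift_full = detect_bbt_shift(chart.day, chart.bbt, chart.disturbance,
                                  max_gap_days=max_gap_days)
    peak = detect_mucus_peak(chart.day, chart.cms_level, shift_day=shift_full,
                             threshold=open_threshold)
    if peak is None:
        w.reason = "no mucus peak"
        return w
    w.peak_day = peak

    shift = detect_bbt_shift(chart.day, chart.bbt, chart.disturbance,
                             after_day=peak, max_gap_days=max_gap_days)
    if shift is None:
        if strict or shift_full is None:
            w.reason = "no bbt shift"
            return w
        shift = shift_full
        w.salvaged = True
    w.shift_day = shift

    close = _third_high_day(chart.day, chart.bbt, chart.disturbance, shift)
    if close is None:
        w.reason = "no bbt shift"
        return w
    w.close_day = close

    if not (w.open_day <= w.peak_day <= w.close_day):
        w.valid = False
        w.reason = "inconsistent window"
        return w
    w.valid = True
    w.reason = "ok" if not w.salvaged else "salvaged"
    return w


def assign_cycle_phases(chart: DailyChart, window: FertileWindow) -> CyclePhases:
    """Partition the cycle into pre-ovulatory / fertile / post-ovulatory.

    Closed intervals; the pre-ovulatory (or post-ovulatory) phase is None
    when the window opens on day 1 (or closes on the last day).
    """
    if not window.valid:
        raise ValueError("cannot assign phases for an invalid window")
    n = int(chart.day[-1])
    o, c = int(window.open_day), int(window.close_day)
    if not (1 <= o <= c <= n):
        raise ValueError("window does not fit inside the cycle")
    pre = (1, o - 1) if o > 1 else None
    post = (c + 1, n) if c < n else None
    return CyclePhases(pre_ovulatory=pre, fertile=(o, c), post_ovulatory=post)


def _acts_in_window(chart: DailyChart, window: FertileWindow) -> int:
    if window.open_day is None or window.close_day is None:
        return 0
    inside = (chart.day >= window.open_day) & (chart.day <= window.close_day)
    return int(chart.intercourse[inside].sum())


def filter_cycles(charts: Sequence[DailyChart],
                  windows: Sequence[FertileWindow]):
    """Apply the cycle-exclusion cascade, in order:

    1. cycles with any protected intercourse;
    2. cycles whose fertile window could not be delimited (missing
       BBT/CMS information);
    3. cycles with no intercourse act inside the fertile window.

    Returns ``(retained, report)`` where ``retained`` is a list of
    (chart, window) pairs and ``report`` counts removals per stage.
    """
    if len(charts) != len(windows):
        raise ValueError("charts and windows must be matched lists")
    n_protected = n_invalid = n_nointercourse = 0
    retained: list[tuple[DailyChart, FertileWindow]] = []
    for chart, window in zip(charts, windows):
        if int(np.sum(chart.protected)) > 0:
            n_protected += 1
            continue
        if not window.valid:
            n_invalid += 1
            continue
        if _acts_in_window(chart, window) == 0:
            n_nointercourse += 1
            continue
        retained.append((chart, window))
    women = {c.woman_id for c, _ in retained}
    report = FilterReport(
        n_input=len(charts),
        removed_protected=n_protected,
        removed_invalid_window=n_invalid,
        removed_no_intercourse=n_nointercourse,
        n_retained=len(retained),
        women_remaining=len(women),
    )
    return retained, report


def aggregate_covariates(retained: Iterable[tuple[DailyChart, FertileWindow]],
                         couples: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-couple aggregates over retained cycles: mean fertile-window
    length and mean number of intercourse acts inside the window, merged
    with the couple-level baseline covariates when supplied.
    """
    rows: dict[str, list] = {}
    for chart, window in retained:
        rows.setdefault(chart.woman_id, []).append(
            (window.length, _acts_in_window(chart, window)))
    if not rows:
        return pd.DataFrame(columns=["couple_id", "fertile_len",
                                     "intercourse_freq", "n_cycles"])
    agg = pd.DataFrame(
        {
            "couple_id": list(rows),
            "fertile_len": [float(np.mean([r[0] for r in v])) for v in rows.values()],
            "intercourse_freq": [float(np.mean([r[1] for r in v])) for v in rows.values()],
            "n_cycles": [len(v) for v in rows.values()],
        }
    )
    if couples is not None:
        base = couples.drop(columns=[c for c in ("fertile_len", "intercourse_freq")
                                     if c in couples.columns])
        dropped = set(base["couple_id"]) - set(agg["couple_id"])
        if dropped:
            logger.warning("%d couples dropped: no retained cycles", len(dropped))
        agg = agg.merge(base, on="couple_id", how="left")
    return agg.sort_values("couple_id", ignore_index=True)


def windows_to_frame(windows: Sequence[FertileWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "woman_id": [w.woman_id for w in windows],
            "cycle_id": [w.cycle_id for w in windows],
            "open_day": [w.open_day for w in windows],
            "peak_day": [w.peak_day for w in windows],
            "shift_day": [w.shift_day for w in windows],
            "close_day": [w.close_day for w in windows],
            "valid": [w.valid for w in windows],
            "reason": [w.reason for w in windows],
        }
    )
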