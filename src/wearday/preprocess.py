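"""Raw usage logs -> clean day-by-hour matrix A.

A *day of use* is an 18-value vector of minutes of hearing-aid use for clock
hours 6..23.  Preprocessing resolves binaural logs to a single series per
day (per-hour maximum of the two ears), reconstructs hours lost to
temporary disconnections from the device's per-window minute counters, and
applies five filtering rules before stacking the retained days into the
matrix A (one row per day, 18 columns) that the clustering operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import HOURS, N_HOURS

HOUR_COLUMNS = [f"h{h}" for h in HOURS]

#: a single on-off disconnection window longer than this disqualifies the day
MAX_ON_OFF_WINDOW_HOURS = 2
#: days with less total use than this are not days of hearing-aid use
MIN_DAILY_MINUTES = 60.0
#: users need at least this many retained days to be analyzable
MIN_DAYS_PER_USER = 10

FILTER_RULES = (
    "on_off_disconnection_gt_2h",
    "hour_exceeds_60min",
    "total_use_lt_60min",
    "hours_outside_6_24",
    "user_lt_10_days",
)


@dataclass
class FilterAudit:
    """Days/users removed per filtering rule, in application order."""

    input_days: int = 0
    removed: dict[str, int] = field(default_factory=lambda: {r: 0 for r in FILTER_RULES})
    removed_users: int = 0
    retained_days: int = 0
    both_ears_absent_hours: int = 0

    def as_dict(self) -> dict:
        return {
            "input_days": self.input_days,
            "removed": dict(self.removed),
            "removed_users": self.removed_users,
            "retained_days": self.retained_days,
            "both_ears_absent_hours": self.both_ears_absent_hours,
        }


@dataclass
class DayUseMatrix:
    """The analysis matrix A: one row per retained day, 18 hourly columns.

    ``index`` carries the (user_id, date) back-reference for each row, in
    the same order as ``values``.
    """

    values: np.ndarray  # (r, 18) minutes per hour
    index: pd.DataFrame  # columns: user_id, date

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_HOURS:
            raise ValueError(f"A must have exactly {N_HOURS} columns")
        if len(self.index) != self.values.shape[0]:
            raise ValueError("index length must match row count")

    @property
    def n_days(self) -> int:
        return self.values.shape[0]

    @property
    def user_ids(self) -> np.ndarray:
        return self.index["user_id"].to_numpy()

    def to_frame(self) -> pd.DataFrame:
        out = self.index.reset_index(drop=True).copy()
        out[HOUR_COLUMNS] = self.values
        return out


def resolve_binaural(left: np.ndarray | None, right: np.ndarray | None) -> np.ndarray:
    """Merge the two ears' hourly minutes by taking the per-hour maximum.

    An absent ear contributes nothing; if both are absent for an hour the
    hour counts as zero use.  NaN marks absent hours within a series.
    """
    if left is None and right is None:
        return np.zeros(N_HOURS)
    if left is None:
        left = np.full(N_HOURS, np.nan)
    if right is None:
        right = np.full(N_HOURS, np.nan)
    merged = np.fmax(np.asarray(left, dtype=float), np.asarray(right, dtype=float))
    return np.where(np.isnan(merged), 0.0, merged)


def impute_disconnection(
    start_hour: int, end_hour: int, counter_minutes: float
) -> tuple[np.ndarray, str]:
    """Reconstruct hourly minutes inside a disconnection window.

    The device's counter records total minutes of use during the window
    (hours ``start_hour..end_hour`` inclusive).  Full-time use (counter
    equals 60 min for every hour) is assigned directly; otherwise the
    on-off use is spread evenly, e.g. 60 counter-minutes over a 2-h window
    give 30 min/h.  Totals are conserved exactly.

    Returns (per-hour minutes, flag) with flag "full_time" or "on_off".
    """
    if not (6 <= start_hour <= end_hour <= 23):
        raise ValueError("window must lie within clock hours 6..23")
    n_hours = end_hour - start_hour + 1
    if not (0 <= counter_minutes <= 60.0 * n_hours + 1e-9):
        raise ValueError(
            f"counter {counter_minutes} min exceeds window capacity {60 * n_hours} min"
        )
    if np.isclose(counter_minutes, 60.0 * n_hours):
        return np.full(n_hours, 60.0), "full_time"
    return np.full(n_hours, counter_minutes / n_hours), "on_off"


def _resolve_log(log: pd.DataFrame, audit: FilterAudit) -> pd.DataFrame:
    """Long log -> one row per (user_id, date) with 18 hourly columns (NaN = absent)."""
    log = log.copy()
    log["date"] = pd.to_datetime(log["date"])
    outside = ~log["hour"].isin(HOURS)
    if outside.any():
        audit.removed["hours_outside_6_24"] += int(outside.sum())
        log = log[~outside]
    wide = log.pivot_table(
        index=["user_id", "date"], columns="hour", values="minutes", aggfunc="max"
    )
    wide = wide.reindex(columns=HOURS)
    wide.columns = HOUR_COLUMNS
    return wide.reset_index()


def _apply_windows(
    days: pd.DataFrame, windows: pd.DataFrame, audit: FilterAudit
) -> tuple[pd.DataFrame, set]:
    """Impute each disconnection window in place; return days whose on-off
    window exceeds the 2-hour limit (to be removed by rule 1)."""
    bad_days: set = set()
    if windows is None or len(windows) == 0:
        return days, bad_days
    windows = windows.copy()
    windows["date"] = pd.to_datetime(windows["date"])
    seen: dict[tuple, list[tuple[int, int]]] = {}
    pos = {k: i for i, k in enumerate(zip(days["user_id"], days["date"]))}
    mat = days[HOUR_COLUMNS].to_numpy()
    for row in windows.itertuples(index=False):
        key = (row.user_id, row.date)
        span = (int(row.start_hour), int(row.end_hour))
        for s, e in seen.setdefault(key, []):
            if span[0] <= e and s <= span[1]:
                raise ValueError(f"overlapping disconnection windows for {key}")
        seen[key].append(span)
        values, flag = impute_disconnection(span[0], span[1], float(row.counter_minutes))
        if flag == "on_off" and (span[1] - span[0] + 1) > MAX_ON_OFF_WINDOW_HOURS:
            bad_days.add(key)
        if key in pos:
            mat[pos[key], span[0] - 6 : span[1] - 6 + 1] = values
    days = days.copy()
    days[HOUR_COLUMNS] = mat
    return days, bad_days


def clean_days(
    days: pd.DataFrame, windows: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, FilterAudit]:
    """Apply the five filtering rules to a wide day table.

    In order: (1) drop days containing an on-off disconnection window longer
    than 2 h; (2) drop malformed days with any hour above 60 min; (3) drop
    days with under 60 min total use; (4) hours outside 6:00-23:59 are
    excluded at construction; (5) drop users left with fewer than 10 days,
    together with all their days.
    """
    audit = FilterAudit(input_days=len(days))
    days = days.copy()
    days["date"] = pd.to_datetime(days["date"])

    days, bad = _apply_windows(days, windows, audit)
    if bad:
        keys = pd.MultiIndex.from_frame(days[["user_id", "date"]])
        drop = keys.isin(bad)
        audit.removed["on_off_disconnection_gt_2h"] = int(drop.sum())
        days = days[~drop]

    mat = days[HOUR_COLUMNS].to_numpy(dtype=float)
    audit.both_ears_absent_hours = int(np.isnan(mat).sum())
    mat = np.nan_to_num(mat, nan=0.0)
    days = days.copy()
    days[HOUR_COLUMNS] = mat

    over = (mat > 60.0 + 1e-9).any(axis=1)
    audit.removed["hour_exceeds_60min"] = int(over.sum())
    days, mat = days[~over], mat[~over]

    low = mat.sum(axis=1) < MIN_DAILY_MINUTES - 1e-9  # exactly 60 min is kept
    audit.removed["total_use_lt_60min"] = int(low.sum())
    days = days[~low]

    counts = days.groupby("user_id")["date"].transform("size")
    thin = counts < MIN_DAYS_PER_USER
    audit.removed["user_lt_10_days"] = int(thin.sum())
    audit.removed_users = int(days.loc[thin, "user_id"].nunique())
    days = days[~thin]

    audit.retained_days = len(days)
    return days.reset_index(drop=True), audit


def build_day_matrix(days: pd.DataFrame) -> DayUseMatrix:
    """Stack retained days into A, rows sorted by (user_id, date)."""
    days = days.sort_values(["user_id", "date"], kind="mergesort").reset_index(drop=True)
    return DayUseMatrix(
        values=days[HOUR_COLUMNS].to_numpy(dtype=float),
        index=days[["user_id", "date"]].copy(),
    )


def preprocess_logs(
    log: pd.DataFrame, windows: pd.DataFrame | None = None
) -> tuple[DayUseMatrix, FilterAudit]:
    """Full preprocessing: binaural resolution, imputation, filtering, A."""
    audit = FilterAudit()
    wide = _resolve_log(log, audit)
    outside = audit.removed["hours_outside_6_24"]
    days, audit = clean_days(wide, windows)
    audit.removed["hours_outside_6_24"] = outside
    if len(days) == 0:
        raise ValueError("no days survive preprocessing (empty input?)")
    return build_day_matrix(days), audit
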