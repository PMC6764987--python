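"""Per-larva behavioral scores and group summaries.

Activity ("lmpi", larval movement per interval) is the percentage of
6-second inter-frame intervals in which a larva's thresholded difference
area reached the move cutoff.  The visual response E-O is the mean
percentage of intervals spent in the upper half of the well during the
even-numbered (stimulus-up) periods minus the same during odd-numbered
(stimulus-down) periods; positive values mean the larva follows the moving
lines.  Larvae below an activity floor (5% by default) move too rarely for
a reliable E-O and are flagged invalid.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .schedule import PeriodSchedule

log = logging.getLogger(__name__)

#: Default E-O period sets of the standard two-hour assay.
EVEN_PERIODS = (4, 6, 8, 10, 12)
ODD_PERIODS = (3, 5, 7, 9, 11)

WELL_KEY = ["plate", "row", "col"]


class ScoreError(ValueError):
    """Undefined score (e.g. no intervals, empty group)."""


def activity_percent(move_flags: Sequence[int]) -> float:
    """100 x moved intervals / scored intervals."""
    flags = np.asarray(move_flags, dtype=float)
    if flags.size == 0:
        raise ScoreError("activity is undefined for zero intervals")
    return 100.0 * float(flags.sum()) / flags.size


def eo_statistic(
    up_pct_by_period: Mapping[int, float],
    even: Sequence[int] = EVEN_PERIODS,
    odd: Sequence[int] = ODD_PERIODS,
) -> float:
    """mean(up% over even periods) - mean(up% over odd periods).

    Periods without a defined up% (the larva never produced a centroid) are
    skipped; NaN when either side has no defined period at all.  Swapping the
    even/odd labels flips the sign.
    """
    ev = [up_pct_by_period[p] for p in even
          if p in up_pct_by_period and np.isfinite(up_pct_by_period[p])]
    od = [up_pct_by_period[p] for p in odd
          if p in up_pct_by_period and np.isfinite(up_pct_by_period[p])]
    if not ev or not od:
        return float("nan")
    return float(np.mean(ev) - np.mean(od))


def per_period_scores(results: pd.DataFrame) -> pd.DataFrame:
    """Collapse the detection results to one row per (well, period).

    Columns: plate, row, col, period, stimulus, n_intervals, activity_pct,
    up_pct.  up_pct averages only intervals with a defined up flag (i.e. a
    defined centroid); acclimation rows (period 0) are dropped.
    """
    df = results[results["period"] > 0]
    grouped = df.groupby(WELL_KEY + ["period"], sort=True)
    out = grouped.agg(
        stimulus=("stimulus", "first"),
        n_intervals=("move", "size"),
        activity_pct=("move", lambda s: 100.0 * s.mean()),
        up_pct=("up", lambda s: 100.0 * s.mean()),  # pandas mean skips NaN
    ).reset_index()
    return out


def score_larvae(
    results: pd.DataFrame,
    schedule: PeriodSchedule | None = None,
    activity_floor: float = 5.0,
) -> pd.DataFrame:
    """One score row per well from a detection results table.

    Columns: plate, row, col, n_intervals, activity_pct (over the whole
    recording), activity_first_pct (the headline value: the first 10-minute
    period immediately after acclimation), eo, eo_valid.  ``eo_valid`` is
    False when overall activity is below ``activity_floor`` (percent) or the
    E-O is undefined.  Wells absent from the results table simply produce no
    row (empty wells are excluded, not imputed).
    """
    if schedule is not None:
        even, odd = schedule.up_periods, schedule.down_periods
    else:
        even, odd = EVEN_PERIODS, ODD_PERIODS

    df = results[results["period"] > 0]
    if df.empty:
        raise ScoreError("no scored intervals (only acclimation rows?)")
    first_period = int(df["period"].min())

    pp = per_period_scores(results)
    rows = []
    for key, sub in df.groupby(WELL_KEY, sort=True):
        activity = activity_percent(sub["move"].to_numpy())
        first = sub.loc[sub["period"] == first_period, "move"]
        activity_first = (
            activity_percent(first.to_numpy()) if len(first) else float("nan")
        )
        wp = pp[(pp[WELL_KEY] == key).all(axis=1)]
        up_by_period = dict(zip(wp["period"], wp["up_pct"]))
        eo = eo_statistic(up_by_period, even=even, odd=odd)
        rows.append(
            {
                "plate": key[0],
                "row": key[1],
                "col": key[2],
                "n_intervals": int(len(sub)),
                "activity_pct": activity,
                "activity_first_pct": activity_first,
                "eo": eo,
                "eo_valid": bool(np.isfinite(eo) and activity >= activity_floor),
            }
        )
    scores = pd.DataFrame(rows)
    log.info(
        "scored %d larvae (%d with a valid E-O)",
        len(scores), int(scores["eo_valid"].sum()),
    )
    return scores


def assign_groups(
    scores: pd.DataFrame, groups: Mapping[tuple[int, int], str]
) -> pd.DataFrame:
    """Attach a 'group' label column from a (plate, row) -> label mapping;
    unmapped wells are dropped."""
    labels = [
        groups.get((p, r)) for p, r in zip(scores["plate"], scores["row"])
    ]
    out = scores.assign(group=labels)
    return out[out["group"].notna()].reset_index(drop=True)


def _sem(values: np.ndarray) -> float:
    values = values[np.isfinite(values)]
    if values.size < 2:
        return float("nan")
    return float(values.std(ddof=1) / np.sqrt(values.size))


def summarize_group(
    scores: pd.DataFrame, groups: Mapping[tuple[int, int], str] | None = None
) -> pd.DataFrame:
    """Mean and SEM of activity and E-O per group.

    ``groups`` maps (plate, row) to a label; when omitted, ``scores`` must
    already carry a 'group' column.  E-O statistics use only larvae with a
    valid E-O; ``n_eo`` counts them.  SEM is the sample SD over sqrt(n)
    (NaN for a single larva).
    """
    df = assign_groups(scores, groups) if groups is not None else scores
    if "group" not in df.columns or df.empty:
        raise ScoreError("no grouped larvae to summarize")
    rows = []
    for label, sub in df.groupby("group", sort=True):
        act = sub["activity_pct"].to_numpy(dtype=float)
        eo = sub.loc[sub["eo_valid"], "eo"].to_numpy(dtype=float)
        rows.append(
            {
                "group": label,
                "n": int(len(sub)),
                "activity_mean": float(np.mean(act)),
                "activity_sem": _sem(act),
                "n_eo": int(len(eo)),
                "eo_mean": float(np.mean(eo)) if len(eo) else float("nan"),
                "eo_sem": _sem(eo),
            }
        )
    return pd.DataFrame(rows)


def row_means(scores: pd.DataFrame) -> pd.DataFrame:
    """Mean activity and E-O per physical row (typically 12 larvae) —
    row averages are far more stable over time than individual larvae."""
    grouped = scores.groupby(["plate", "row"], sort=True)
    return grouped.agg(
        n=("col", "size"),
        activity_mean=("activity_pct", "mean"),
        eo_mean=("eo", lambda s: float(np.nanmean(s.to_numpy(dtype=float)))
                 if np.isfinite(s.to_numpy(dtype=float)).any() else float("nan")),
    ).reset_index()
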