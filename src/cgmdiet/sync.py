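"""Synchronize diary meals with CGM scan annotations.

Participants scan the sensor just before eating and note the main meal
type; those scan timestamps are the reliable food-intake times. Diary
entries are matched to annotations greedily by smallest time gap within a
tolerance, each annotation serving at most one meal and the noted meal type
having to agree. Matched meals are then joined with windowed CGM metrics
into the tidy meal x window analysis table.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

import cgmdiet.metrics as cgm_metrics
from cgmdiet.diary import MealRecord, meal_gl


@dataclass(frozen=True)
class ScanAnnotation:
    """A sensor scan noted with the upcoming main meal's type."""

    participant_id: str
    timestamp: datetime
    noted_meal_type: str


@dataclass
class MatchedMeal:
    """A diary meal paired with its scan-derived intake time."""

    meal: MealRecord
    intake_time: datetime
    match_gap: float  # minutes


def match_meals(
    meals: list[MealRecord],
    annotations: list[ScanAnnotation],
    tolerance: float = 30.0,
) -> tuple[list[MatchedMeal], list[tuple[MealRecord, str]]]:
    """Greedy nearest-in-time matching of main meals to annotations.

    Candidate (meal, annotation) pairs within the same participant, with
    agreeing meal type and absolute gap <= ``tolerance`` minutes, are
    assigned in order of increasing gap; each meal and each annotation is
    used at most once. Snacks and drinks never enter windowed analysis.
    Returns (matched, dropped) where ``dropped`` lists unmatched main
    meals with the reason.
    """
    mains = [m for m in meals if m.is_main]
    candidates = []
    ann_by_pid: dict[str, list[int]] = {}
    for j, a in enumerate(annotations):
        ann_by_pid.setdefault(a.participant_id, []).append(j)
    for i, m in enumerate(mains):
        for j in ann_by_pid.get(m.participant_id, []):
            a = annotations[j]
            if a.noted_meal_type != m.meal_type:
                continue
            gap = abs((a.timestamp - m.timestamp).total_seconds()) / 60.0
            if gap <= tolerance:
                candidates.append((gap, i, j))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))

    used_meal: set[int] = set()
    used_ann: set[int] = set()
    matched: list[MatchedMeal] = []
    for gap, i, j in candidates:
        if i in used_meal or j in used_ann:
            continue
        used_meal.add(i)
        used_ann.add(j)
        matched.append(MatchedMeal(mains[i], annotations[j].timestamp, gap))
    matched.sort(key=lambda mm: (mm.meal.participant_id, mm.intake_time))

    dropped = [
        (m, "no annotation within tolerance") for i, m in enumerate(mains) if i not in used_meal
    ]
    return matched, dropped


def build_meal_dataset(
    matched: list[MatchedMeal],
    traces: dict[str, "cgm_metrics.CGMTrace"],
    windows: tuple[float, ...] = cgm_metrics.WINDOW_HOURS,
    min_coverage: float = 0.8,
) -> tuple[pd.DataFrame, dict[float, int]]:
    """Assemble the meal x window analysis table.

    One row per (matched meal, window duration) carrying the meal's GL and
    the 19 windowed metrics; windows with insufficient CGM coverage are
    excluded and counted per duration. Later meals falling inside an
    earlier meal's window are allowed but flagged (``overlap``) so
    sensitivity analyses can drop them.
    """
    intake_by_pid: dict[str, list[datetime]] = {}
    for mm in matched:
        intake_by_pid.setdefault(mm.meal.participant_id, []).append(mm.intake_time)

    rows = []
    excluded: dict[float, int] = {float(w): 0 for w in windows}
    for mm in matched:
        trace = traces.get(mm.meal.participant_id)
        if trace is None:
            for w in windows:
                excluded[float(w)] += 1
            continue
        gl = mm.meal.gl if mm.meal.gl is not None else meal_gl(mm.meal)
        for w in windows:
            window = cgm_metrics.AnalysisWindow(mm.intake_time, float(w))
            win = cgm_metrics.extract_window(trace, window, min_coverage=min_coverage)
            if not win.sufficient or win.glucose.size < 3:
                excluded[float(w)] += 1
                continue
            overlap = any(
                mm.intake_time < other <= mm.intake_time + timedelta(hours=float(w))
                for other in intake_by_pid[mm.meal.participant_id]
            )
            row = {
                "participant_id": mm.meal.participant_id,
                "intake_time": mm.intake_time,
                "meal_type": mm.meal.meal_type,
                "window_h": float(w),
                "gl": np.nan if gl is None else gl,
                "true_gl": np.nan if mm.meal.true_gl is None else mm.meal.true_gl,
                "match_gap_min": mm.match_gap,
                "overlap": overlap,
            }
            row.update(cgm_metrics.windowed_metrics(win).as_dict())
            rows.append(row)
    cols = [
        "participant_id",
        "intake_time",
        "meal_type",
        "window_h",
        "gl",
        "true_gl",
        "match_gap_min",
        "overlap",
        *cgm_metrics.WINDOWED_METRIC_NAMES,
    ]
    return pd.DataFrame(rows, columns=cols), excluded
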