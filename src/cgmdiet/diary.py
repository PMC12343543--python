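"""Food-diary handling: per-meal glycemic load, daily intake, outlier filters.

The glycemic load of a meal combines each food item's glycemic index (GI)
with its carbohydrate mass::

    MealGL = sum_i GI_i * gCarbs_i / 100

A meal is only assigned a GL when every item has a known GI; meals with any
unknown-GI item are excluded from the GL analysis but still contribute to
daily macronutrient totals. Gross diary-entry errors (e.g. a portion logged
in the wrong unit) are removed by a z-score filter computed over the pooled
analysis series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta

import numpy as np
import pandas as pd

MAIN_MEAL_TYPES = ("breakfast", "lunch", "dinner")
MEAL_TYPES = MAIN_MEAL_TYPES + ("snack", "drink")


@dataclass(frozen=True)
class FoodItem:
    """One diary line: a food with its carbohydrate mass and nutrients.

    ``gi`` is the glycemic index on the conventional 0-150 scale, or
    ``None`` when the food is absent from the GI table.
    """

    name: str
    grams_carbs: float
    energy: float
    fiber: float
    sugar: float
    gi: float | None = None

    def __post_init__(self) -> None:
        for attr in ("grams_carbs", "energy", "fiber", "sugar"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0, got {getattr(self, attr)}")
        if self.gi is not None and not (0 <= self.gi <= 150):
            raise ValueError(f"gi must lie in [0, 150], got {self.gi}")


@dataclass
class MealRecord:
    """A diary meal: items eaten together at one timestamp.

    ``gl`` is populated by :func:`meal_gl`; ``true_gl`` is an optional
    ground-truth channel used by the synthetic cohort simulator.
    """

    participant_id: str
    timestamp: datetime
    meal_type: str
    items: list[FoodItem]
    gl: float | None = None
    true_gl: float | None = None
    true_energy: float | None = None

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("a meal must contain at least one item")
        if self.meal_type not in MEAL_TYPES:
            raise ValueError(f"unknown meal_type {self.meal_type!r}")

    @property
    def is_main(self) -> bool:
        return self.meal_type in MAIN_MEAL_TYPES

    @property
    def energy(self) -> float:
        return sum(it.energy for it in self.items)

    @property
    def carbohydrate(self) -> float:
        return sum(it.grams_carbs for it in self.items)


@dataclass(frozen=True)
class DailyIntake:
    """Macronutrient totals for one participant-day (energy kCal, masses g)."""

    participant_id: str
    date: date
    energy: float
    carbohydrate: float
    fiber: float
    sugar: float
    complete: bool = True


def meal_gl(meal: MealRecord) -> float | None:
    """Per-meal glycemic load, or ``None`` when any item lacks a GI.

    GL = sum over items of GI * gCarbs / 100. Meals containing an item
    without a validated GI are excluded from GL analysis (returned as
    ``None``), mirroring strict GI-table coverage.
    """
    total = 0.0
    for item in meal.items:
        if item.grams_carbs < 0:
            raise ValueError("negative carbohydrate mass")
        if item.gi is None:
            return None
        total += item.gi * item.grams_carbs / 100.0
    return total


def attach_gl(meals: list[MealRecord]) -> list[MealRecord]:
    """Return copies of ``meals`` with the ``gl`` field computed."""
    return [replace(m, gl=meal_gl(m)) for m in meals]


def daily_intake(
    meals: list[MealRecord],
    day: date,
    complete: bool = True,
) -> DailyIntake:
    """Sum macronutrients over meals falling in [day 00:00, next 00:00).

    All meals, including those without a computable GL, contribute.
    ``complete`` flags whether the day's diary is fully reported; an
    incomplete day is kept but marked so downstream daily analyses can
    drop it.
    """
    pids = {m.participant_id for m in meals}
    if len(pids) > 1:
        raise ValueError("daily_intake expects meals from a single participant")
    start = datetime.combine(day, time.min)
    end = start + timedelta(days=1)
    todays = [m for m in meals if start <= m.timestamp < end]
    return DailyIntake(
        participant_id=next(iter(pids)) if pids else "",
        date=day,
        energy=sum(it.energy for m in todays for it in m.items),
        carbohydrate=sum(it.grams_carbs for m in todays for it in m.items),
        fiber=sum(it.fiber for m in todays for it in m.items),
        sugar=sum(it.sugar for m in todays for it in m.items),
        complete=complete,
    )


def zscore_exclude(values: list[float] | np.ndarray, threshold: float) -> list[int]:
    """Indices of entries whose pooled z-score magnitude is <= ``threshold``.

    Mean and SD are computed over the pooled input (the whole analysis
    series, not per participant). Zero-variance input excludes nothing.
    Returns kept indices in original order.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError("z-score exclusion needs at least 3 values")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values in z-score input")
    sd = arr.std(ddof=1)
    if sd == 0 or not math.isfinite(sd):
        return list(range(arr.size))
    z = np.abs(arr - arr.mean()) / sd
    return [int(i) for i in np.flatnonzero(z <= threshold)]


# ---------------------------------------------------------------------------
# CSV interchange


DIARY_COLUMNS = [
    "participant_id",
    "timestamp",
    "meal_type",
    "food_name",
    "grams_carbs",
    "energy_kcal",
    "fiber_g",
    "sugar_g",
]


def read_gi_table(path) -> dict[str, float]:
    """Read a GI lookup CSV (columns ``food_name, gi``) into a dict.

    Keys are lower-cased: name matching is exact but case-insensitive.
    """
    df = pd.read_csv(path, comment="#")
    table = {str(n).strip().lower(): float(g) for n, g in zip(df["food_name"], df["gi"])}
    if not table:
        raise ValueError("empty GI table")
    return table


def lookup_gi(name: str, gi_table: dict[str, float]) -> float | None:
    """Exact case-insensitive GI lookup; no fuzzy matching."""
    return gi_table.get(name.strip().lower())


def read_diary_csv(path, gi_table: dict[str, float] | None = None) -> list[MealRecord]:
    """Read a diary CSV (one row per food item) into meal records.

    Rows sharing (participant_id, timestamp, meal_type) form one meal.
    When ``gi_table`` is given, each item's GI is looked up by exact
    case-insensitive name match; items absent from the table get no GI.
    """
    df = pd.read_csv(path, comment="#", parse_dates=["timestamp"])
    meals: list[MealRecord] = []
    for (pid, ts, mtype), grp in df.groupby(
        ["participant_id", "timestamp", "meal_type"], sort=True
    ):
        items = []
        for row in grp.itertuples():
            gi = lookup_gi(str(row.food_name), gi_table) if gi_table else None
            items.append(
                FoodItem(
                    name=str(row.food_name),
                    grams_carbs=float(row.grams_carbs),
                    energy=float(row.energy_kcal),
                    fiber=float(row.fiber_g),
                    sugar=float(row.sugar_g),
                    gi=gi,
                )
            )
        meals.append(
            MealRecord(
                participant_id=str(pid),
                timestamp=ts.to_pydatetime(),
                meal_type=str(mtype),
                items=items,
            )
        )
    meals.sort(key=lambda m: (m.participant_id, m.timestamp))
    return meals


def meals_to_frame(meals: list[MealRecord]) -> pd.DataFrame:
    """Flatten meals back to one-row-per-item diary form."""
    rows = []
    for m in meals:
        for it in m.items:
            rows.append(
                {
                    "participant_id": m.participant_id,
                    "timestamp": m.timestamp,
                    "meal_type": m.meal_type,
                    "food_name": it.name,
                    "grams_carbs": it.grams_carbs,
                    "energy_kcal": it.energy,
                    "fiber_g": it.fiber,
                    "sugar_g": it.sugar,
                }
            )
    return pd.DataFrame(rows, columns=DIARY_COLUMNS)


def meal_gl_frame(meals: list[MealRecord]) -> pd.DataFrame:
    """Per-meal GL table (GL blank for meals with unknown-GI items)."""
    rows = [
        {
            "participant_id": m.participant_id,
            "timestamp": m.timestamp,
            "meal_type": m.meal_type,
            "n_items": len(m.items),
            "gl": meal_gl(m),
            "energy_kcal": m.energy,
            "carbohydrate_g": m.carbohydrate,
        }
        for m in meals
    ]
    return pd.DataFrame(rows)


def daily_intake_frame(meals: list[MealRecord]) -> pd.DataFrame:
    """Daily macronutrient totals for every participant-day in the diary."""
    rows = []
    by_pid: dict[str, list[MealRecord]] = {}
    for m in meals:
        by_pid.setdefault(m.participant_id, []).append(m)
    for pid, ms in sorted(by_pid.items()):
        days = sorted({m.timestamp.date() for m in ms})
        for d in days:
            di = daily_intake(ms, d)
            rows.append(
                {
                    "participant_id": pid,
                    "date": d,
                    "energy": di.energy,
                    "carbohydrate": di.carbohydrate,
                    "fiber": di.fiber,
                    "sugar": di.sugar,
                    "complete": di.complete,
                }
            )
    return pd.DataFrame(rows)
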