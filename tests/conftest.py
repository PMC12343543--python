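from datetime import datetime

import numpy as np
import pytest

from cgmdiet.diary import attach_gl
from cgmdiet.metrics import WindowData, CGMTrace
from cgmdiet.pipeline import build_daily_table
from cgmdiet.synthetic import CohortScenario, simulate_cohort
from cgmdiet.sync import build_meal_dataset, match_meals


def make_window(t_min, glucose, sufficient=True):
    return WindowData(
        np.asarray(t_min, float), np.asarray(glucose, float), sufficient, coverage=1.0
    )


def make_trace(t_min, glucose, pid="P000", start="2024-03-04T00:00:00", interval=15.0):
    start64 = np.datetime64(start, "s")
    times = start64 + (np.asarray(t_min, float) * 60).astype("timedelta64[s]")
    return CGMTrace(pid, times, np.asarray(glucose, float), nominal_interval=interval)


@pytest.fixture(scope="session")
def small_cohort():
    """A 10-participant, 5-day synthetic study used across test modules."""
    scenario = CohortScenario(n_participants=10, days=5, annotation_rate=0.9, seed=42)
    return simulate_cohort(scenario)


@pytest.fixture(scope="session")
def analysis_tables(small_cohort):
    """Meal x window and daily analysis tables built from the small cohort."""
    meals = attach_gl(small_cohort.meals)
    matched, _ = match_meals(meals, small_cohort.annotations, tolerance=30.0)
    meal_table, _ = build_meal_dataset(matched, small_cohort.traces)
    daily_table, _ = build_daily_table(small_cohort)
    return meal_table, daily_table
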