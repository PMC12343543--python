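"""Synthetic cohort generator: determinism, demographics, forward model."""

from dataclasses import replace
from datetime import datetime, timedelta

import numpy as np
import pytest

from cgmdiet.diary import FoodItem, MealRecord, meal_gl
from cgmdiet.metrics import AnalysisWindow, extract_window, windowed_metrics
from cgmdiet.synthetic import (
    CohortScenario,
    ParticipantProfile,
    ResponseModelParams,
    generate_annotations,
    generate_cgm,
    generate_cohort,
    generate_diary,
    generate_gi_table,
    inject_portion_outlier,
    simulate_cohort,
    thin_trace,
)

NOISELESS = ResponseModelParams(
    baseline_glucose=5.0, circadian_amplitude=0.0, gl_to_amplitude_gain=0.1,
    noise_sd=0.0, time_to_peak=45.0, decay_time=60.0,
)


def single_meal(gl_carbs=20.0, gi=100.0, ts=datetime(2024, 3, 4, 12, 0), pid="P000"):
    it = FoodItem("food_000", gl_carbs, 300.0, 1.0, 2.0, gi=gi)
    m = MealRecord(pid, ts, "lunch", [it])
    m.true_gl = meal_gl(m)
    return m


@pytest.fixture
def profile():
    return generate_cohort(1, seed=5)[0]


class TestCohort:
    def test_sex_split_is_exact_at_study_size(self):
        profiles = generate_cohort(48, seed=1)
        assert len(profiles) == 48
        assert sum(p.sex == "female" for p in profiles) == 27
        assert sum(p.sex == "male" for p in profiles) == 21

    def test_seeded_determinism(self):
        assert generate_cohort(1, seed=9) == generate_cohort(1, seed=9)

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(0, seed=1)

    def test_female_waist_matches_configured_distribution(self):
        profiles = generate_cohort(10_000, seed=3)
        waists = np.array([p.waist_circumference for p in profiles if p.sex == "female"])
        se = 11.7 / np.sqrt(waists.size)
        assert abs(waists.mean() - 77.4) < 3 * se

    def test_profile_invariants_enforced(self):
        with pytest.raises(ValueError):
            ParticipantProfile("X", "female", 30, 80, 50, 150.0, 7,
                               dict.fromkeys(("sedentary", "light", "moderate", "vigorous"), 1.0))
        with pytest.raises(ValueError):
            ParticipantProfile("X", "female", 30, 80, 50, 25.0, 7,
                               dict.fromkeys(("sedentary", "light", "moderate", "vigorous"), 7.0))


class TestDiary:
    def test_no_missing_gi_means_every_meal_has_gl(self, profile):
        gi = generate_gi_table(30, seed=2)
        meals = generate_diary(profile, 5, gi, missing_gi_rate=0.0, seed=4)
        assert all(meal_gl(m) is not None for m in meals)

    def test_all_missing_gi_means_no_gl_meal(self, profile):
        gi = generate_gi_table(30, seed=2)
        meals = generate_diary(profile, 5, gi, missing_gi_rate=1.0, seed=4)
        assert all(meal_gl(m) is None for m in meals)

    def test_cohort_meal_counts_at_study_scale(self):
        data = simulate_cohort(CohortScenario(n_participants=48, days=7, seed=6))
        mains = sum(m.is_main for m in data.meals)
        snacks = sum(m.meal_type == "snack" for m in data.meals)
        # free-living study of this size recorded 595 mains / 292 snacks
        assert 595 / 3 < mains < 595 * 3
        assert 292 / 3 < snacks < 292 * 3

    def test_empty_gi_table_rejected(self, profile):
        with pytest.raises(ValueError):
            generate_diary(profile, 3, {}, seed=1)

    def test_true_gl_recorded_even_for_offtable_items(self, profile):
        gi = generate_gi_table(30, seed=2)
        meals = generate_diary(profile, 7, gi, missing_gi_rate=0.5, seed=4)
        assert all(m.true_gl is not None and m.true_gl >= 0 for m in meals)
        with_gl = [m for m in meals if meal_gl(m) is not None]
        for m in with_gl:
            assert m.true_gl == pytest.approx(meal_gl(m))


class TestForwardModel:
    def test_no_meals_flat_baseline(self, profile):
        tr = generate_cgm(profile, [], NOISELESS,
                          start=datetime(2024, 3, 4), duration_days=1)
        assert np.allclose(tr.glucose, 5.0)

    def test_peak_excursion_equals_gain_times_gl(self, profile):
        meal = single_meal(gl_carbs=20.0, gi=100.0)  # GL = 20
        tr = generate_cgm(profile, [meal], NOISELESS)
        # kernel peak 45 min post-meal lands on the 15-min grid
        assert tr.glucose.max() - 5.0 == pytest.approx(0.1 * 20.0)

    def test_superposition_of_meal_responses(self, profile):
        m1 = single_meal(ts=datetime(2024, 3, 4, 9, 0))
        m2 = single_meal(gl_carbs=35.0, ts=datetime(2024, 3, 4, 13, 0))
        start, days = datetime(2024, 3, 4), 1
        joint = generate_cgm(profile, [m1, m2], NOISELESS, start, days).glucose
        a = generate_cgm(profile, [m1], NOISELESS, start, days).glucose
        b = generate_cgm(profile, [m2], NOISELESS, start, days).glucose
        assert np.allclose(joint - 5.0, (a - 5.0) + (b - 5.0))

    def test_amp_monotone_in_gl(self, profile):
        amps = []
        for carbs in (5.0, 15.0, 30.0, 60.0):
            meal = single_meal(gl_carbs=carbs)
            tr = generate_cgm(profile, [meal], NOISELESS)
            win = extract_window(tr, AnalysisWindow(meal.timestamp, 4.0))
            amps.append(windowed_metrics(win).amp)
        assert all(b >= a for a, b in zip(amps, amps[1:]))

    def test_meal_outside_span_rejected(self, profile):
        meal = single_meal(ts=datetime(2024, 3, 10, 12, 0))
        with pytest.raises(ValueError):
            generate_cgm(profile, [meal], NOISELESS,
                         start=datetime(2024, 3, 4), duration_days=1)

    def test_trace_reproducible_and_positive(self, profile):
        params = replace(NOISELESS, noise_sd=2.5, seed=77)
        meal = single_meal()
        t1 = generate_cgm(profile, [meal], params)
        t2 = generate_cgm(profile, [meal], params)
        assert np.array_equal(t1.glucose, t2.glucose)
        assert np.all(t1.glucose > 1.0)


class TestScenario:
    def test_simulate_cohort_bit_reproducible(self):
        scen = CohortScenario(n_participants=4, days=2, seed=13)
        a, b = simulate_cohort(scen), simulate_cohort(scen)
        assert [m.true_gl for m in a.meals] == [m.true_gl for m in b.meals]
        for pid in a.traces:
            assert np.array_equal(a.traces[pid].glucose, b.traces[pid].glucose)

    def test_annotations_precede_their_meals(self):
        scen = CohortScenario(n_participants=3, days=3, seed=8)
        data = simulate_cohort(scen)
        mains = [m for m in data.meals if m.is_main]
        assert 0 < len(data.annotations) <= len(mains)
        assert all(a.noted_meal_type in ("breakfast", "lunch", "dinner")
                   for a in data.annotations)

    def test_thin_trace_reduces_coverage(self, profile):
        meal = single_meal()
        tr = generate_cgm(profile, [meal], NOISELESS)
        thin = thin_trace(tr, drop_fraction=0.5, seed=3)
        assert thin.times.size < tr.times.size
        win = extract_window(thin, AnalysisWindow(meal.timestamp, 4.0))
        assert win.coverage < 1.0

    def test_outlier_injection_multiplies_one_meal(self, profile):
        gi = generate_gi_table(30, seed=2)
        meals = generate_diary(profile, 5, gi, missing_gi_rate=0.0, seed=4)
        blown, idx = inject_portion_outlier(meals, factor=50.0, seed=9)
        assert meal_gl(blown[idx]) == pytest.approx(50.0 * meal_gl(meals[idx]))
        others = [i for i in range(len(meals)) if i != idx]
        for i in others:
            assert blown[i] is meals[i]
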