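"""Synthetic cohort: participants, food diaries, scan annotations, CGM traces.

The generator emulates a one-week free-living diet-monitoring study in
healthy adults: demographics are drawn from published cohort means/SDs by
sex; each participant logs three main meals plus occasional snacks per day,
with a configurable fraction of food items missing from the GI table; CGM
traces follow a forward model

    glucose(t) = baseline + circadian(t) + sum_meals gain * GL_meal * k(t - t_meal) + noise

where ``k`` is a log-normal-shaped kernel rising to 1 at ``time_to_peak``
and decaying on the ``decay_time`` scale. The kernel is smooth and
single-peaked, so rise- and fall-times are well defined on clean traces,
and meal contributions superpose additively. Diaries carry the true GL and
energy used by the simulator as a ground-truth channel for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta

import numpy as np
import pandas as pd
import yaml

from cgmdiet.diary import FoodItem, MealRecord, MAIN_MEAL_TYPES
from cgmdiet.metrics import CGMTrace
from cgmdiet.sync import ScanAnnotation

ACTIVITY_KEYS = ("sedentary", "light", "moderate", "vigorous")

# Cohort demographic distributions by sex: mean, SD per characteristic,
# matching the study population this generator emulates (healthy adults,
# 25-34 y; waist cm, muscle kg, body fat %, sleep h/day, activity h/day).
DEMOGRAPHICS = {
    "female": {
        "waist_circumference": (77.4, 11.7),
        "muscle_mass": (45.6, 6.1),
        "body_fat": (26.3, 6.9),
        "sleep_duration": (6.5, 2.2),
        "sedentary": (9.7, 3.4),
        "light": (2.5, 2.1),
        "moderate": (2.3, 1.4),
        "vigorous": (0.06, 0.1),
    },
    "male": {
        "waist_circumference": (86.5, 6.7),
        "muscle_mass": (59.7, 6.6),
        "body_fat": (20.1, 4.0),
        "sleep_duration": (5.7, 2.3),
        "sedentary": (10.0, 3.2),
        "light": (2.4, 2.1),
        "moderate": (2.6, 1.8),
        "vigorous": (0.11, 0.25),
    },
}
AGE_MEAN, AGE_SD, AGE_RANGE = 28.2, 2.5, (25.0, 34.0)
DEFAULT_FEMALE_FRACTION = 27 / 48


@dataclass(frozen=True)
class ParticipantProfile:
    """Anthropometrics, sleep and physical-activity summary of one subject."""

    participant_id: str
    sex: str  # 'female' | 'male'
    age: float
    waist_circumference: float
    muscle_mass: float
    body_fat: float
    sleep_duration: float
    activity_hours: dict[str, float]

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError("sex must be 'female' or 'male'")
        for attr in ("age", "waist_circumference", "muscle_mass"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be strictly positive")
        if not 0 < self.body_fat < 100:
            raise ValueError("body_fat must lie in (0, 100)")
        if not 0 < self.sleep_duration < 24:
            raise ValueError("sleep_duration must lie in (0, 24)")
        if set(self.activity_hours) != set(ACTIVITY_KEYS):
            raise ValueError(f"activity_hours must have keys {ACTIVITY_KEYS}")
        if any(v < 0 for v in self.activity_hours.values()):
            raise ValueError("activity hours must be >= 0")
        if sum(self.activity_hours.values()) > 24:
            raise ValueError("activity hours must sum to <= 24")


@dataclass(frozen=True)
class ResponseModelParams:
    """Forward-model parameters for simulated CGM traces.

    ``gl_to_amplitude_gain`` (mmol/L per GL unit) sets the peak excursion
    height of a meal of unit GL; ``time_to_peak``/``decay_time`` (min)
    shape the excursion kernel; ``noise_sd`` is the per-reading Gaussian
    noise, truncated so glucose stays above 1 mmol/L.
    """

    baseline_glucose: float = 5.2
    circadian_amplitude: float = 0.3
    gl_to_amplitude_gain: float = 0.05
    time_to_peak: float = 45.0
    decay_time: float = 60.0
    noise_sd: float = 0.3
    sampling_interval: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_glucose <= 0:
            raise ValueError("baseline_glucose must be > 0")
        for attr in ("circadian_amplitude", "gl_to_amplitude_gain", "time_to_peak",
                     "decay_time", "noise_sd"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be > 0")


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)
    return float(min(max(mean, lo + 1e-9), hi - 1e-9))


def generate_cohort(
    n: int,
    seed: int,
    female_fraction: float = DEFAULT_FEMALE_FRACTION,
) -> list[ParticipantProfile]:
    """Draw ``n`` participant profiles from the sex-specific demographics.

    The number of women is ``round(n * female_fraction)`` (27 of 48 at the
    default), assigned deterministically then shuffled, so the sex split is
    exact rather than binomial. All draws are truncated normals respecting
    the profile invariants.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    n_female = int(round(n * female_fraction))
    sexes = ["female"] * n_female + ["male"] * (n - n_female)
    rng.shuffle(sexes)

    profiles = []
    for i, sex in enumerate(sexes):
        d = DEMOGRAPHICS[sex]
        act = {
            "sedentary": _truncnorm(rng, *d["sedentary"], 0.0, 20.0),
            "light": _truncnorm(rng, *d["light"], 0.0, 12.0),
            "moderate": _truncnorm(rng, *d["moderate"], 0.0, 12.0),
            "vigorous": max(0.0, rng.normal(*d["vigorous"])),
        }
        total = sum(act.values())
        if total > 23.9:  # leave headroom so the sum<=24 invariant is float-safe
            act = {k: v * 23.9 / total for k, v in act.items()}
        profiles.append(
            ParticipantProfile(
                participant_id=f"P{i:03d}",
                sex=sex,
                age=_truncnorm(rng, AGE_MEAN, AGE_SD, *AGE_RANGE),
                waist_circumference=_truncnorm(rng, *d["waist_circumference"], 40.0, 160.0),
                muscle_mass=_truncnorm(rng, *d["muscle_mass"], 20.0, 100.0),
                body_fat=_truncnorm(rng, *d["body_fat"], 3.0, 60.0),
                sleep_duration=_truncnorm(rng, *d["sleep_duration"], 1.0, 14.0),
                activity_hours=act,
            )
        )
    return profiles


def generate_gi_table(n_foods: int = 80, seed: int = 0) -> dict[str, float]:
    """A synthetic GI lookup table: food name -> glycemic index."""
    rng = np.random.default_rng(seed)
    gis = np.clip(rng.normal(55.0, 18.0, size=n_foods), 5.0, 120.0)
    return {f"food_{i:03d}": float(round(g, 1)) for i, g in enumerate(gis)}


_MEAL_CLOCK = {"breakfast": (7.75, 0.5), "lunch": (12.5, 0.7), "dinner": (18.5, 0.75)}
_SNACK_COUNT_P = (0.45, 0.35, 0.15, 0.05)  # P(0..3 snacks/day)


def _make_items(
    rng: np.random.Generator,
    n_items: int,
    gi_table: dict[str, float],
    missing_gi_rate: float,
    carb_scale: float,
) -> tuple[list[FoodItem], float]:
    """Compose meal items; returns (items, true GL incl. off-table foods)."""
    names = list(gi_table)
    items, true_gl = [], 0.0
    for _ in range(n_items):
        carbs = float(rng.lognormal(math.log(carb_scale), 0.5))
        energy = carbs * 4.0 + float(rng.lognormal(math.log(70.0), 0.6))
        fiber = carbs * float(rng.uniform(0.02, 0.15))
        sugar = carbs * float(rng.uniform(0.05, 0.6))
        if rng.uniform() < missing_gi_rate:
            # off-table food: no GI entry, but a true GI drives the simulator
            name = f"offtable_{rng.integers(0, 10_000):04d}"
            gi_entry = None
            true_gi = float(np.clip(rng.normal(55.0, 18.0), 5.0, 120.0))
        else:
            name = names[int(rng.integers(0, len(names)))]
            gi_entry = gi_table[name]
            true_gi = gi_entry
        items.append(FoodItem(name, carbs, energy, fiber, sugar, gi=gi_entry))
        true_gl += true_gi * carbs / 100.0
    return items, true_gl


def generate_diary(
    profile: ParticipantProfile,
    days: int,
    gi_table: dict[str, float],
    missing_gi_rate: float = 0.3,
    seed: int = 0,
    start: date = date(2024, 3, 4),
) -> list[MealRecord]:
    """One participant's diary: 3 main meals + 0-3 snacks per day.

    Each item carries carbohydrate, energy, fiber, sugar, and a GI entry
    when the food is in the table; a fraction ``missing_gi_rate`` of items
    is off-table. Every meal records the true GL and energy the simulator
    will use, regardless of table coverage.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    if not 0 <= missing_gi_rate <= 1:
        raise ValueError("missing_gi_rate must lie in [0, 1]")
    if not gi_table:
        raise ValueError("empty GI table")
    rng = np.random.default_rng(seed)
    meals: list[MealRecord] = []
    for d in range(days):
        day = start + timedelta(days=d)
        times: list[tuple[str, float]] = []
        for mtype, (mu, sd) in _MEAL_CLOCK.items():
            times.append((mtype, _truncnorm(rng, mu, sd, 5.0, 23.5)))
        n_snacks = int(rng.choice(4, p=_SNACK_COUNT_P))
        for _ in range(n_snacks):
            times.append(("snack", float(rng.uniform(9.0, 22.0))))
        times.sort(key=lambda x: x[1])
        for mtype, hour in times:
            is_main = mtype in MAIN_MEAL_TYPES
            n_items = int(rng.choice([1, 2, 3, 4], p=[0.2, 0.4, 0.3, 0.1])) if is_main else 1
            items, true_gl = _make_items(
                rng, n_items, gi_table, missing_gi_rate, carb_scale=18.0 if is_main else 10.0
            )
            ts = datetime.combine(day, time.min) + timedelta(
                minutes=round(hour * 60 / 5) * 5  # diary times logged to 5 min
            )
            meals.append(
                MealRecord(
                    participant_id=profile.participant_id,
                    timestamp=ts,
                    meal_type=mtype,
                    items=items,
                    true_gl=true_gl,
                    true_energy=sum(it.energy for it in items),
                )
            )
    meals.sort(key=lambda m: m.timestamp)
    return meals


def generate_annotations(
    meals: list[MealRecord],
    rate: float = 0.85,
    jitter_sd: float = 4.0,
    seed: int = 0,
) -> list[ScanAnnotation]:
    """Sensor-scan annotations: participants scan shortly before main meals.

    Each main meal is annotated with probability ``rate``; the scan
    precedes intake by a few minutes with Gaussian jitter.
    """
    rng = np.random.default_rng(seed)
    ann = []
    for m in meals:
        if not m.is_main:
            continue
        if rng.uniform() < rate:
            offset = -abs(rng.normal(3.0, jitter_sd))
            ann.append(
                ScanAnnotation(
                    participant_id=m.participant_id,
                    timestamp=m.timestamp + timedelta(minutes=float(offset)),
                    noted_meal_type=m.meal_type,
                )
            )
    ann.sort(key=lambda a: a.timestamp)
    return ann


def _kernel(tau_min: np.ndarray, time_to_peak: float, decay_time: float) -> np.ndarray:
    """Log-normal-shaped excursion kernel, unit peak at ``time_to_peak``.

    Width is set so the kernel has fallen to half its peak a ``decay_time``
    after the peak; single-peaked and smooth, so landmark extraction on
    clean traces is unambiguous.
    """
    k = np.zeros_like(tau_min, dtype=float)
    pos = tau_min > 0
    s = math.log1p(decay_time / time_to_peak) / math.sqrt(2.0 * math.log(2.0))
    k[pos] = np.exp(-(np.log(tau_min[pos] / time_to_peak)) ** 2 / (2.0 * s**2))
    return k


def generate_cgm(
    profile: ParticipantProfile,
    meals: list[MealRecord],
    params: ResponseModelParams,
    start: datetime | None = None,
    duration_days: int | None = None,
) -> CGMTrace:
    """Simulate a CGM trace covering the diary span.

    The span defaults to midnight of the first meal's day through midnight
    after the last meal's day; meals outside an explicit span are rejected.
    Noise is truncated so glucose stays above 1 mmol/L.
    """
    if start is None:
        if not meals:
            raise ValueError("need meals or an explicit start/duration")
        start = datetime.combine(meals[0].timestamp.date(), time.min)
    if duration_days is None:
        if not meals:
            raise ValueError("need meals or an explicit start/duration")
        last = meals[-1].timestamp.date()
        duration_days = (last - start.date()).days + 1
    end = start + timedelta(days=duration_days)
    for m in meals:
        if not (start <= m.timestamp < end):
            raise ValueError(f"meal at {m.timestamp} outside trace span [{start}, {end})")
    if any(meals[i].timestamp > meals[i + 1].timestamp for i in range(len(meals) - 1)):
        raise ValueError("meals must be time-sorted")

    n = int(round((end - start).total_seconds() / 60.0 / params.sampling_interval))
    t_min = np.arange(n) * params.sampling_interval
    times = np.datetime64(start, "s") + (t_min * 60).astype("timedelta64[s]")

    hour_of_day = ((start.hour * 60 + start.minute) + t_min) / 60.0
    g = np.full(n, params.baseline_glucose)
    g = g + params.circadian_amplitude * np.sin(2 * np.pi * (hour_of_day - 7.0) / 24.0)
    for m in meals:
        tau = t_min - (m.timestamp - start).total_seconds() / 60.0
        gl = m.true_gl if m.true_gl is not None else (m.gl or 0.0)
        g = g + params.gl_to_amplitude_gain * gl * _kernel(
            tau, params.time_to_peak, params.decay_time
        )
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        g = g + rng.normal(0.0, params.noise_sd, size=n)
    g = np.maximum(g, 1.0 + 1e-9)  # truncation: glucose stays physiological
    return CGMTrace(profile.participant_id, times, g, nominal_interval=params.sampling_interval)


def thin_trace(trace: CGMTrace, drop_fraction: float, seed: int, block: int = 6) -> CGMTrace:
    """Remove random contiguous blocks of readings, emulating scan gaps.

    Scan-based sensors only store a window of history, so unscanned spans
    are lost; this exercises the insufficient-coverage exclusion path.
    """
    if not 0 <= drop_fraction < 1:
        raise ValueError("drop_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n = trace.times.size
    keep = np.ones(n, dtype=bool)
    n_blocks = int(drop_fraction * n / block)
    for _ in range(n_blocks):
        i = int(rng.integers(0, max(1, n - block)))
        keep[i : i + block] = False
    if keep.sum() < 2:
        keep[:2] = True
    return CGMTrace(
        trace.participant_id, trace.times[keep], trace.glucose[keep], trace.nominal_interval
    )


def inject_portion_outlier(
    meals: list[MealRecord],
    factor: float = 50.0,
    seed: int = 0,
    require_gl: bool = True,
) -> tuple[list[MealRecord], int]:
    """Multiply one main meal's portions by ``factor`` (unit-entry error).

    Emulates a diary mistake such as logging grams as tablespoons; the
    inflated meal should be caught by the z-score filters. Returns the
    modified meal list and the index of the tampered meal. The true GL /
    energy channels are NOT inflated: the error lives in the diary only.
    """
    rng = np.random.default_rng(seed)
    candidates = [
        i
        for i, m in enumerate(meals)
        if m.is_main and (not require_gl or all(it.gi is not None for it in m.items))
    ]
    if not candidates:
        raise ValueError("no eligible meal to tamper with")
    idx = int(candidates[int(rng.integers(0, len(candidates)))])
    m = meals[idx]
    blown = [
        FoodItem(
            it.name,
            it.grams_carbs * factor,
            it.energy * factor,
            it.fiber * factor,
            it.sugar * factor,
            gi=it.gi,
        )
        for it in m.items
    ]
    out = list(meals)
    out[idx] = replace(m, items=blown)
    return out, idx


# ---------------------------------------------------------------------------
# Scenario-level orchestration


@dataclass
class CohortScenario:
    """All knobs of one simulated study, driving end-to-end generation."""

    n_participants: int = 48
    days: int = 7
    female_fraction: float = DEFAULT_FEMALE_FRACTION
    n_foods: int = 80
    missing_gi_rate: float = 0.3
    annotation_rate: float = 0.85
    response: ResponseModelParams = field(default_factory=ResponseModelParams)
    baseline_between_sd: float = 0.35  # between-participant baseline spread
    inject_gl_outlier: bool = False
    inject_energy_outlier: bool = False
    outlier_factor: float = 50.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "CohortScenario":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        resp = ResponseModelParams(**raw.pop("response", {}))
        return cls(response=resp, **raw)


@dataclass
class CohortData:
    profiles: list[ParticipantProfile]
    gi_table: dict[str, float]
    meals: list[MealRecord]  # all participants, diary order
    annotations: list[ScanAnnotation]
    traces: dict[str, CGMTrace]
    outlier_meal_index: int | None = None


def simulate_cohort(scenario: CohortScenario) -> CohortData:
    """Generate a full synthetic study: profiles, GI table, diaries,
    annotations, and CGM traces, all reproducible from ``scenario.seed``."""
    root = np.random.default_rng(scenario.seed)
    sub = lambda: int(root.integers(0, 2**31 - 1))  # noqa: E731

    profiles = generate_cohort(scenario.n_participants, sub(), scenario.female_fraction)
    gi_table = generate_gi_table(scenario.n_foods, sub())

    all_meals: list[MealRecord] = []
    per_participant: dict[str, list[MealRecord]] = {}
    for prof in profiles:
        diary = generate_diary(
            prof, scenario.days, gi_table, scenario.missing_gi_rate, seed=sub()
        )
        per_participant[prof.participant_id] = diary
        all_meals.extend(diary)

    outlier_idx = None
    if scenario.inject_gl_outlier or scenario.inject_energy_outlier:
        all_meals, outlier_idx = inject_portion_outlier(
            all_meals,
            factor=scenario.outlier_factor,
            seed=sub(),
            require_gl=scenario.inject_gl_outlier,
        )
        tampered = all_meals[outlier_idx]
        per_participant[tampered.participant_id] = [
            m for m in all_meals if m.participant_id == tampered.participant_id
        ]

    annotations = generate_annotations(all_meals, scenario.annotation_rate, seed=sub())

    traces = {}
    for prof in profiles:
        baseline = _truncnorm(
            root, scenario.response.baseline_glucose, scenario.baseline_between_sd, 3.0, 8.0
        )
        params = replace(scenario.response, baseline_glucose=baseline, seed=sub())
        traces[prof.participant_id] = generate_cgm(prof, per_participant[prof.participant_id], params)

    return CohortData(profiles, gi_table, all_meals, annotations, traces, outlier_idx)


# ---------------------------------------------------------------------------
# CSV writers


def profiles_frame(profiles: list[ParticipantProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {
            "participant_id": p.participant_id,
            "sex": p.sex,
            "age": p.age,
            "waist_circumference": p.waist_circumference,
            "muscle_mass": p.muscle_mass,
            "body_fat": p.body_fat,
            "sleep_duration": p.sleep_duration,
        }
        row.update({f"activity_{k}": v for k, v in p.activity_hours.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def gi_table_frame(gi_table: dict[str, float]) -> pd.DataFrame:
    return pd.DataFrame({"food_name": list(gi_table), "gi": list(gi_table.values())})


def annotations_frame(annotations: list[ScanAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [a.participant_id for a in annotations],
            "timestamp": [a.timestamp for a in annotations],
            "noted_meal_type": [a.noted_meal_type for a in annotations],
        }
    )


def cgm_frame(traces: dict[str, CGMTrace]) -> pd.DataFrame:
    return pd.concat([tr.to_frame() for tr in traces.values()], ignore_index=True)
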