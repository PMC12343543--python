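"""End-to-end pipeline: simulate/load -> GL -> metrics -> sync -> stats.

Every exclusion step (unknown-GI meals, unmatched meals, insufficient
CGM coverage, z-score outliers) is counted in a run manifest whose
numbers reconcile exactly: at each stage, input count = output count +
exclusions. All interchange is plain CSV with a ``# seed=<seed>`` header
line, so any stage can be re-run standalone and seeded runs are
byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cgmdiet import correlations as corr
from cgmdiet import diary as diary_mod
from cgmdiet import lmm as lmm_mod
from cgmdiet import metrics as metrics_mod
from cgmdiet import synthetic as synth
from cgmdiet import sync as sync_mod


@dataclass
class RunConfig:
    """All knobs of one pipeline run; the seed lives in the scenario."""

    scenario: synth.CohortScenario = field(default_factory=synth.CohortScenario)
    input_dir: str | None = None  # read CSVs instead of simulating
    outdir: str = "cgmdiet_run"
    windows: tuple[float, ...] = metrics_mod.WINDOW_HOURS
    min_coverage: float = 0.8
    match_tolerance: float = 30.0
    gl_z_threshold: float = 3.0
    energy_z_threshold: float = 6.0
    energy_z_basis: str = "daily"  # 'daily' | 'meal'
    base_alpha: float = 0.05
    gate_mode: str = "per_pair"
    include_personal: bool = True
    run_cv: bool = True
    make_plots: bool = False

    def __post_init__(self) -> None:
        if not self.windows:
            raise ValueError("windows must be nonempty")
        for attr in ("gl_z_threshold", "energy_z_threshold", "min_coverage", "base_alpha"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be > 0")
        if self.energy_z_basis not in ("daily", "meal"):
            raise ValueError("energy_z_basis must be 'daily' or 'meal'")

    @property
    def seed(self) -> int:
        return self.scenario.seed

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scen_raw = raw.pop("scenario", {})
        resp = synth.ResponseModelParams(**scen_raw.pop("response", {}))
        scenario = synth.CohortScenario(response=resp, **scen_raw)
        if "windows" in raw:
            raw["windows"] = tuple(float(w) for w in raw["windows"])
        return cls(scenario=scenario, **raw)


def write_csv(df: pd.DataFrame, path: Path, seed: int) -> None:
    """Write a stage CSV with the run seed recorded in its header."""
    with open(path, "w") as fh:
        fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)


def load_cohort_csvs(input_dir: str | Path) -> synth.CohortData:
    """Rehydrate a cohort from the CSVs a previous simulate stage wrote."""
    d = Path(input_dir)
    prof_df = pd.read_csv(d / "profiles.csv", comment="#")
    profiles = [
        synth.ParticipantProfile(
            participant_id=str(r.participant_id),
            sex=str(r.sex),
            age=float(r.age),
            waist_circumference=float(r.waist_circumference),
            muscle_mass=float(r.muscle_mass),
            body_fat=float(r.body_fat),
            sleep_duration=float(r.sleep_duration),
            activity_hours={
                k: float(getattr(r, f"activity_{k}")) for k in synth.ACTIVITY_KEYS
            },
        )
        for r in prof_df.itertuples()
    ]
    gi_df = pd.read_csv(d / "gi_table.csv", comment="#")
    gi_table = {str(n).strip().lower(): float(g) for n, g in zip(gi_df.food_name, gi_df.gi)}
    meals = diary_mod.read_diary_csv(d / "diary.csv", gi_table)
    ann_df = pd.read_csv(d / "annotations.csv", comment="#", parse_dates=["timestamp"])
    annotations = [
        sync_mod.ScanAnnotation(str(r.participant_id), r.timestamp.to_pydatetime(),
                                str(r.noted_meal_type))
        for r in ann_df.itertuples()
    ]
    cgm_df = pd.read_csv(d / "cgm.csv", comment="#", parse_dates=["timestamp"])
    traces = {
        str(pid): metrics_mod.CGMTrace.from_frame(grp)
        for pid, grp in cgm_df.groupby("participant_id")
    }
    return synth.CohortData(profiles, gi_table, meals, annotations, traces)


def build_daily_table(
    data: synth.CohortData, min_coverage: float = 0.8
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Join daily macronutrient totals, daily CGM metrics and covariates.

    One row per participant-day; days whose CGM coverage is below
    ``min_coverage`` carry no metrics and are dropped, counted in the
    returned accounting dict.
    """
    prof_by_id = {p.participant_id: p for p in data.profiles}
    intake = diary_mod.daily_intake_frame(data.meals)
    rows, insufficient = [], 0
    for r in intake.itertuples():
        trace = data.traces.get(r.participant_id)
        met = (
            metrics_mod.daily_metrics(trace, r.date, min_coverage=min_coverage)
            if trace is not None
            else None
        )
        if met is None:
            insufficient += 1
            continue
        p = prof_by_id[r.participant_id]
        row = {
            "participant_id": r.participant_id,
            "date": r.date,
            "energy": r.energy,
            "carbohydrate": r.carbohydrate,
            "fiber": r.fiber,
            "sugar": r.sugar,
            **met,
            "sex_code": lmm_mod.SEX_CODING[p.sex],
            "moderate_pa": p.activity_hours["moderate"],
            "sedentary_pa": p.activity_hours["sedentary"],
            "age": p.age,
            "waist_circumference": p.waist_circumference,
            "muscle_mass": p.muscle_mass,
            "body_fat": p.body_fat,
            "sleep_duration": p.sleep_duration,
        }
        rows.append(row)
    counts = {
        "days_total": len(intake),
        "days_insufficient_cgm": insufficient,
        "days_with_metrics": len(rows),
    }
    return pd.DataFrame(rows), counts


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    # --- stage 1: inputs -------------------------------------------------
    if config.input_dir is not None:
        data = load_cohort_csvs(config.input_dir)
    else:
        data = synth.simulate_cohort(config.scenario)
    write_csv(synth.profiles_frame(data.profiles), outdir / "profiles.csv", seed)
    write_csv(synth.gi_table_frame(data.gi_table), outdir / "gi_table.csv", seed)
    write_csv(diary_mod.meals_to_frame(data.meals), outdir / "diary.csv", seed)
    write_csv(synth.annotations_frame(data.annotations), outdir / "annotations.csv", seed)
    write_csv(synth.cgm_frame(data.traces), outdir / "cgm.csv", seed)

    # --- stage 2: per-meal GL and daily intake ---------------------------
    meals = diary_mod.attach_gl(data.meals)
    mains = [m for m in meals if m.is_main]
    n_snacks = sum(m.meal_type == "snack" for m in meals)
    n_drinks = sum(m.meal_type == "drink" for m in meals)
    mains_with_gl = sum(m.gl is not None for m in mains)
    write_csv(diary_mod.meal_gl_frame(meals), outdir / "meal_gl.csv", seed)
    write_csv(diary_mod.daily_intake_frame(meals), outdir / "daily_intake.csv", seed)

    # --- stage 3: daily analysis table -----------------------------------
    daily_table, daily_counts = build_daily_table(data, config.min_coverage)

    # --- stage 4: synchronization and windowed metrics -------------------
    matched, dropped = sync_mod.match_meals(meals, data.annotations, config.match_tolerance)
    meal_table, window_excluded = sync_mod.build_meal_dataset(
        matched, data.traces, config.windows, config.min_coverage
    )
    rows_built = {float(w): int((meal_table["window_h"] == float(w)).sum()) for w in config.windows}

    # --- stage 5: z-score outlier filters --------------------------------
    matched_gl = [(mm.meal.participant_id, mm.intake_time, mm.meal.gl)
                  for mm in matched if mm.meal.gl is not None]
    gl_outlier_keys: set[tuple] = set()
    if len(matched_gl) >= 3:
        gls = [g for _, _, g in matched_gl]
        kept = set(diary_mod.zscore_exclude(gls, config.gl_z_threshold))
        gl_outlier_keys = {
            (pid, ts) for i, (pid, ts, _) in enumerate(matched_gl) if i not in kept
        }
    if gl_outlier_keys:
        drop_mask = meal_table.apply(
            lambda r: (r["participant_id"], r["intake_time"]) in gl_outlier_keys, axis=1
        )
        outlier_rows_removed = int(drop_mask.sum())
        meal_table = meal_table[~drop_mask].reset_index(drop=True)
    else:
        outlier_rows_removed = 0

    energy_outliers = 0
    if config.energy_z_basis == "daily":
        if len(daily_table) >= 3:
            kept = diary_mod.zscore_exclude(
                daily_table["energy"].to_numpy(), config.energy_z_threshold
            )
            energy_outliers = len(daily_table) - len(kept)
            daily_table = daily_table.iloc[kept].reset_index(drop=True)
    else:  # per-meal energies; exclude the day containing an outlier meal
        meal_energy = [(m.participant_id, m.timestamp.date(), m.energy) for m in meals]
        if len(meal_energy) >= 3:
            kept = set(
                diary_mod.zscore_exclude([e for _, _, e in meal_energy],
                                         config.energy_z_threshold)
            )
            bad_days = {
                (pid, d) for i, (pid, d, _) in enumerate(meal_energy) if i not in kept
            }
            if bad_days:
                mask = daily_table.apply(
                    lambda r: (r["participant_id"], r["date"]) in bad_days, axis=1
                )
                energy_outliers = int(mask.sum())
                daily_table = daily_table[~mask].reset_index(drop=True)

    write_csv(meal_table, outdir / "meal_windows.csv", seed)
    write_csv(daily_table, outdir / "daily_analysis.csv", seed)

    # --- stage 6: correlation family -------------------------------------
    results = corr.correlation_family(
        meal_table,
        daily_table,
        base_alpha=config.base_alpha,
        gate_mode=config.gate_mode,
        windows=config.windows,
    )
    write_csv(corr.results_frame(results), outdir / "correlations.csv", seed)
    corr.gl_correlation_grid(results).to_csv(outdir / "gl_correlation_grid.csv")
    corr.macro_correlation_grid(results).to_csv(outdir / "macro_correlation_grid.csv")

    # --- stage 7: mixed models -------------------------------------------
    reports = lmm_mod.model_suite(
        meal_table,
        daily_table,
        include_personal=config.include_personal,
        run_cv=config.run_cv,
    )
    write_csv(lmm_mod.suite_summary_frame(reports), outdir / "models.csv", seed)
    if config.make_plots:
        _write_residual_plots(reports, outdir)

    # --- manifest ---------------------------------------------------------
    manifest = {
        "seed": seed,
        "config": _config_dict(config),
        "diary": {
            "meals_recorded": len(meals),
            "mains": len(mains),
            "snacks": n_snacks,
            "drinks": n_drinks,
            "items": sum(len(m.items) for m in meals),
        },
        "gl": {
            "mains_with_gl": mains_with_gl,
            "mains_without_gl": len(mains) - mains_with_gl,
        },
        "sync": {
            "mains_matched": len(matched),
            "mains_unmatched": len(dropped),
        },
        "gl_filter": {
            "matched_with_gl": len(matched_gl),
            "gl_outliers_excluded": len(gl_outlier_keys),
            "gl_analysis_meals": len(matched_gl) - len(gl_outlier_keys),
        },
        "windows": {
            f"{w:g}h": {
                "candidates": len(matched),
                "insufficient_excluded": window_excluded[float(w)],
                "rows_built": rows_built[float(w)],
                "outlier_rows_removed": int(
                    rows_built[float(w)]
                    - (meal_table["window_h"] == float(w)).sum()
                ),
                "rows_final": int((meal_table["window_h"] == float(w)).sum()),
            }
            for w in config.windows
        },
        "daily": {
            **daily_counts,
            "energy_outliers_excluded": energy_outliers,
            "days_analyzed": len(daily_table),
        },
        "correlations": {
            "n_tests": len(results),
            "family_alpha": corr.bonferroni_alpha(len(results), config.base_alpha),
            "n_significant": sum(r.significant for r in results),
        },
        "models": {
            "n_models": len(reports),
            "n_valid": sum(1 for r in reports if r.fit is not None and r.fit.valid),
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def _write_residual_plots(reports, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy import stats as sps

    for rep in reports:
        if rep.fit is None:
            continue
        fig, axes = plt.subplots(2, 1, figsize=(5, 7))
        axes[0].scatter(rep.fit.fitted, rep.fit.residuals, s=8)
        axes[0].axhline(0.0, color="grey", lw=0.8)
        axes[0].set_xlabel("fitted value")
        axes[0].set_ylabel("residual")
        axes[0].set_title(rep.name)
        sps.probplot(rep.fit.residuals, dist="norm", plot=axes[1])
        fig.tight_layout()
        fig.savefig(outdir / f"residuals_{rep.name}.png", dpi=100)
        plt.close(fig)
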