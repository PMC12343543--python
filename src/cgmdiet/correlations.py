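"""Normality-gated correlation study with Bonferroni family-wise control.

The study family comprises 119 tests: glycemic load against each of the 19
windowed CGM metrics over the five postprandial windows (2-6 h, 95 tests),
plus the four daily macronutrients (energy, carbohydrate, fiber, sugar)
against each of the six daily metrics (24 tests). Each pair uses Pearson
correlation when both variables pass a Shapiro-Wilk normality check and
Spearman otherwise; significance is assessed at alpha / 119 = 0.0004.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from cgmdiet.metrics import WINDOWED_METRIC_NAMES, DAILY_METRIC_NAMES, WINDOW_HOURS

MACRONUTRIENTS = ("energy", "carbohydrate", "fiber", "sugar")


@dataclass(frozen=True)
class CorrelationResult:
    """One (variable pair, window) correlation of the study family."""

    x_name: str
    y_name: str
    window: float  # hours; 24.0 for the daily analysis
    method: str  # 'pearson' | 'spearman'
    rho: float
    p_value: float
    significant: bool
    n: int


def bonferroni_alpha(n_tests: int, base_alpha: float = 0.05) -> float:
    """Family-wise corrected significance threshold, base_alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return base_alpha / n_tests


def normality_gate(
    values: np.ndarray | list[float],
    alpha: float = 0.05,
    qq_path: str | Path | None = None,
) -> str:
    """Classify a sample as 'normal' or 'non_normal' by Shapiro-Wilk.

    Constant input is non-normal by convention (the test is undefined).
    When ``qq_path`` is given, a Q-Q plot is written there for visual
    inspection alongside the test.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 3:
        raise ValueError("normality check needs at least 3 values")
    if qq_path is not None:
        _write_qq_plot(arr, qq_path)
    if np.all(arr == arr[0]):
        return "non_normal"
    _, p = stats.shapiro(arr)
    return "normal" if p >= alpha else "non_normal"


def _write_qq_plot(arr: np.ndarray, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    stats.probplot(arr, dist="norm", plot=ax)
    ax.set_title("Q-Q plot")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _correlate_pair(
    x: np.ndarray,
    y: np.ndarray,
    gate_alpha: float,
    force_method: str | None = None,
) -> tuple[str, float, float, int]:
    """Pairwise-complete correlation with the normality-gated method choice."""
    ok = np.isfinite(x) & np.isfinite(y)
    xs, ys = x[ok], y[ok]
    n = int(ok.sum())
    if n < 3:
        return "spearman", math.nan, math.nan, n
    if force_method is not None:
        method = force_method
    else:
        gx = normality_gate(xs, gate_alpha)
        gy = normality_gate(ys, gate_alpha)
        method = "pearson" if gx == "normal" and gy == "normal" else "spearman"
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        return method, math.nan, math.nan, n
    if method == "pearson":
        rho, p = stats.pearsonr(xs, ys)
    else:
        rho, p = stats.spearmanr(xs, ys)
    return method, float(rho), float(p), n


def correlation_family(
    meal_table: pd.DataFrame,
    daily_table: pd.DataFrame,
    base_alpha: float = 0.05,
    gate_alpha: float = 0.05,
    gate_mode: str = "per_pair",
    windows: tuple[float, ...] = WINDOW_HOURS,
) -> list[CorrelationResult]:
    """Run the full correlation family and flag Bonferroni significance.

    ``meal_table`` is the meal x window table (columns ``gl``, ``window_h``
    and the 19 metric names); ``daily_table`` holds the daily macronutrients
    and the six daily metric columns. Rows with missing values are dropped
    pairwise per correlation. ``gate_mode='per_pair'`` gates normality on
    each pair's complete cases (Spearman if either fails);
    ``'per_variable'`` gates each column once over all its values.
    """
    if gate_mode not in ("per_pair", "per_variable"):
        raise ValueError("gate_mode must be 'per_pair' or 'per_variable'")

    n_tests = len(windows) * len(WINDOWED_METRIC_NAMES) + len(MACRONUTRIENTS) * len(
        DAILY_METRIC_NAMES
    )
    family_alpha = bonferroni_alpha(n_tests, base_alpha)

    col_gate: dict[tuple[str, str], str] = {}

    def variable_gate(frame: pd.DataFrame, col: str, key: str) -> str:
        k = (key, col)
        if k not in col_gate:
            vals = frame[col].to_numpy(float)
            vals = vals[np.isfinite(vals)]
            col_gate[k] = normality_gate(vals, gate_alpha) if vals.size >= 3 else "non_normal"
        return col_gate[k]

    results: list[CorrelationResult] = []
    for w in windows:
        sub = meal_table[meal_table["window_h"] == float(w)]
        gl = sub["gl"].to_numpy(float)
        for metric in WINDOWED_METRIC_NAMES:
            y = sub[metric].to_numpy(float)
            force = None
            if gate_mode == "per_variable":
                gx = variable_gate(sub, "gl", f"meal{w}")
                gy = variable_gate(sub, metric, f"meal{w}")
                force = "pearson" if gx == "normal" and gy == "normal" else "spearman"
            method, rho, p, n = _correlate_pair(gl, y, gate_alpha, force)
            results.append(
                CorrelationResult(
                    x_name="gl",
                    y_name=metric,
                    window=float(w),
                    method=method,
                    rho=rho,
                    p_value=p,
                    significant=bool(np.isfinite(p) and p < family_alpha),
                    n=n,
                )
            )

    for macro in MACRONUTRIENTS:
        x = daily_table[macro].to_numpy(float)
        for metric in DAILY_METRIC_NAMES:
            y = daily_table[metric].to_numpy(float)
            force = None
            if gate_mode == "per_variable":
                gx = variable_gate(daily_table, macro, "daily")
                gy = variable_gate(daily_table, metric, "daily")
                force = "pearson" if gx == "normal" and gy == "normal" else "spearman"
            method, rho, p, n = _correlate_pair(x, y, gate_alpha, force)
            results.append(
                CorrelationResult(
                    x_name=macro,
                    y_name=metric,
                    window=24.0,
                    method=method,
                    rho=rho,
                    p_value=p,
                    significant=bool(np.isfinite(p) and p < family_alpha),
                    n=n,
                )
            )
    return results


def results_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    """Long-format results table, one row per correlation."""
    return pd.DataFrame(
        {
            "x_name": [r.x_name for r in results],
            "y_name": [r.y_name for r in results],
            "window_h": [r.window for r in results],
            "method": [r.method for r in results],
            "rho": [r.rho for r in results],
            "p_value": [r.p_value for r in results],
            "significant": [r.significant for r in results],
            "n": [r.n for r in results],
        }
    )


def _star(rho: float, significant: bool) -> str:
    if not np.isfinite(rho):
        return ""
    return f"{rho:.2f}*" if significant else f"{rho:.2f}"


def gl_correlation_grid(results: list[CorrelationResult]) -> pd.DataFrame:
    """Metric x window grid of GL correlations (significance starred)."""
    rows = {}
    for r in results:
        if r.x_name != "gl":
            continue
        rows.setdefault(r.y_name, {})[f"{r.window:g}h" ] = _star(r.rho, r.significant)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "metric"
    return df.loc[[m for m in WINDOWED_METRIC_NAMES if m in df.index]]


def macro_correlation_grid(results: list[CorrelationResult]) -> pd.DataFrame:
    """Daily-metric x macronutrient grid of 24 h correlations."""
    rows = {}
    for r in results:
        if r.x_name == "gl":
            continue
        rows.setdefault(r.y_name, {})[r.x_name] = _star(r.rho, r.significant)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "metric"
    return df.loc[[m for m in DAILY_METRIC_NAMES if m in df.index]]
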