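"""Behavioural statistics and group comparisons computed from run logs.

All per-window frequencies follow the convention
``(absolute count / population size) * 100`` and the neighbour statistic is
``(sum of all neighbouring robots / number of robots) * 100``; both are
evaluated at the metrics sampling interval (default every 10 steps).

Statistical routines delegate to scipy (Pearson product-moment correlation,
Welch two-sample t-test — Welch being R's ``t.test`` default — with a flag
for the pooled-variance Student variant).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "UndefinedMetricError", "action_frequency", "avg_neighbours",
    "prey_food_correlation", "scarcity_tail", "CompareResult",
    "compare_extinction_food", "neighbour_density_map", "run_prey_analysis",
]


class UndefinedMetricError(ValueError):
    """A statistic was requested on inputs where it is mathematically undefined."""


def action_frequency(successful: float, population: int) -> float:
    """Per-window action frequency: (count / population) * 100."""
    if population <= 0:
        raise UndefinedMetricError("action frequency undefined for an empty population")
    if successful < 0:
        raise UndefinedMetricError("negative action count")
    return successful / population * 100.0


def avg_neighbours(neighbour_sum: float, n_robots: int) -> float:
    """Average-neighbour statistic: (sum of all neighbouring robots / robots) * 100."""
    if n_robots <= 0:
        raise UndefinedMetricError("neighbour statistic undefined for an empty population")
    if neighbour_sum < 0:
        raise UndefinedMetricError("negative neighbour sum")
    return neighbour_sum / n_robots * 100.0


def prey_food_correlation(
    prey: Sequence[float], food: Sequence[float]
) -> tuple[float, float]:
    """Pearson r (with two-sided p) between prey frequency and food count series."""
    prey = np.asarray(prey, dtype=float)
    food = np.asarray(food, dtype=float)
    if prey.shape != food.shape:
        raise UndefinedMetricError("series lengths differ")
    if prey.size < 3:
        raise UndefinedMetricError("need at least 3 paired samples")
    if np.ptp(prey) == 0 or np.ptp(food) == 0:
        raise UndefinedMetricError("zero-variance series")
    res = stats.pearsonr(prey, food)
    return float(res.statistic), float(res.pvalue)


def scarcity_tail(frame: pd.DataFrame, food_threshold: float) -> pd.DataFrame:
    """Restrict a metrics frame to the food-scarce tail (food below threshold)."""
    return frame[frame["food"] < food_threshold]


@dataclass(frozen=True)
class CompareResult:
    mean_a: float
    mean_b: float
    t_statistic: float
    p_value: float
    n_a: int
    n_b: int
    welch: bool


def compare_extinction_food(
    sample_a: Sequence[float], sample_b: Sequence[float], welch: bool = True
) -> CompareResult:
    """Two-sample t-test on food-at-extinction (Welch by default)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise UndefinedMetricError("need >= 2 observations per group")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    t = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(t):  # both samples constant and equal: no evidence of difference
        t, p = 0.0, 1.0
    return CompareResult(
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        t_statistic=t, p_value=p, n_a=int(a.size), n_b=int(b.size), welch=welch,
    )


def neighbour_density_map(world, max_class: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell count of robots in the 8 surrounding cells, plus colour classes.

    Returns ``(counts, classes)`` where classes bin counts into
    {0, 1, 2, 3, >=max_class} matching the 0 (dark blue) .. 4 (yellow)
    map colouring.
    """
    from .world import moore_sum  # local import to avoid a cycle at module load

    rc = world.robot_count
    counts = moore_sum(rc, 1, world.torus) - rc  # surrounding cells only
    classes = np.minimum(counts, max_class)
    return counts, classes


def run_prey_analysis(frame: pd.DataFrame, food_threshold: float | None = None
                      ) -> dict:
    """Prey-frequency vs food analysis for one run's metrics frame.

    Computes per-sample prey frequencies, then the Pearson correlation with
    the food series — over the whole run and, when ``food_threshold`` is
    given, over the food-scarce tail only.  Samples with an empty population
    are dropped.  Entries are ``None`` when the correlation is undefined
    (e.g. no preying at all).
    """
    live = frame[frame["population"] > 0]
    freq = live["preys"] / live["population"] * 100.0
    out: dict = {"prey_frequency": freq, "n_samples": int(len(live))}
    for label, sub in (("full", live.assign(freq=freq)),
                       ("tail", None if food_threshold is None else
                        scarcity_tail(live.assign(freq=freq), food_threshold))):
        if sub is None:
            continue
        try:
            r, p = prey_food_correlation(sub["freq"], sub["food"])
        except UndefinedMetricError:
            r, p = None, None
        out[f"r_{label}"] = r
        out[f"p_{label}"] = p
        out[f"n_{label}"] = int(len(sub))
    return out
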