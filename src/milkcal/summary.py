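"""Descriptive statistics, intake bands, convergence checks, reporting.

Simulated intake distributions are summarised by their mean, sample SD
(n-1 denominator) and quartiles.  The quartiles double as scenario
bands: low (LCI, Q1), medium (MCI, Q2 = median) and high caloric intake
(HCI, Q3).  Quantiles use linear interpolation between order statistics
(the common spreadsheet percentile rule); at the default iteration count
the choice of convention shifts quartiles by well under 0.1%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import SimulationDraws

OUTCOMES = ("per_feed", "per_day")
_STATISTICS = ("mean", "sd", "q1", "q2", "q3")


@dataclass(frozen=True)
class IntakeSummary:
    """Summary of one outcome (per_feed or per_day) for one age group."""

    group_label: str
    outcome: str  # "per_feed" | "per_day"
    mean: float
    sd: float
    q1: float
    q2: float
    q3: float
    n_iter: int


@dataclass(frozen=True)
class ConvergenceTrace:
    """Running mean and quartiles at increasing iteration counts."""

    checkpoints: np.ndarray
    running_mean: np.ndarray
    running_q1: np.ndarray
    running_q2: np.ndarray
    running_q3: np.ndarray


def _summarize_vector(x: np.ndarray, group: str, outcome: str) -> IntakeSummary:
    q1, q2, q3 = np.quantile(x, [0.25, 0.5, 0.75])  # linear interpolation
    return IntakeSummary(
        group_label=group,
        outcome=outcome,
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)),
        q1=float(q1),
        q2=float(q2),
        q3=float(q3),
        n_iter=len(x),
    )


def summarize(draws: SimulationDraws) -> tuple[IntakeSummary, IntakeSummary]:
    """Summaries of (per_feed, per_day) for one group's draws."""
    if draws.n_iter < 4:
        raise ValueError(f"need at least 4 draws, got {draws.n_iter}")
    return (
        _summarize_vector(draws.per_feed, draws.group_label, "per_feed"),
        _summarize_vector(draws.per_day, draws.group_label, "per_day"),
    )


def classify(value: float, summary: IntakeSummary) -> str:
    """Band a value against a group's quartiles.

    Convention: value <= Q1 is LCI, value >= Q3 is HCI, otherwise MCI,
    so the three bands partition the real line.
    """
    if value <= summary.q1:
        return "LCI"
    if value >= summary.q3:
        return "HCI"
    return "MCI"


def convergence_trace(
    draws: SimulationDraws, step: int, outcome: str = "per_day"
) -> ConvergenceTrace:
    """Running statistics at iteration counts step, 2*step, ..., n_iter."""
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    if step > draws.n_iter:
        raise ValueError(f"step {step} exceeds n_iter {draws.n_iter}")
    x = getattr(draws, outcome)
    checkpoints = np.arange(step, draws.n_iter + 1, step)
    if checkpoints[-1] != draws.n_iter:
        checkpoints = np.append(checkpoints, draws.n_iter)
    means, q1s, q2s, q3s = [], [], [], []
    for c in checkpoints:
        head = x[:c]
        means.append(np.mean(head))
        q1, q2, q3 = np.quantile(head, [0.25, 0.5, 0.75])
        q1s.append(q1)
        q2s.append(q2)
        q3s.append(q3)
    return ConvergenceTrace(
        checkpoints=checkpoints,
        running_mean=np.array(means),
        running_q1=np.array(q1s),
        running_q2=np.array(q2s),
        running_q3=np.array(q3s),
    )


def is_converged(
    trace: ConvergenceTrace, rel_tol: float = 0.005, window_frac: float = 0.2
) -> tuple[bool, dict]:
    """Stability check on the trailing window of a convergence trace.

    Converged iff the maximum relative change of the running mean and
    each running quartile, within the last ``window_frac`` of the
    checkpoints, does not exceed ``rel_tol``.
    """
    n = len(trace.checkpoints)
    if n < 3:
        raise ValueError("need at least 3 checkpoints")
    start = min(n - 2, int(np.floor(n * (1.0 - window_frac))))
    report: dict[str, float] = {}
    for name, series in (
        ("mean", trace.running_mean),
        ("q1", trace.running_q1),
        ("q2", trace.running_q2),
        ("q3", trace.running_q3),
    ):
        window = series[start:]
        ref = np.abs(window[-1])
        span = float(np.max(window) - np.min(window))
        report[name] = span / ref if ref > 0 else (0.0 if span == 0 else np.inf)
    ok = max(report.values()) <= rel_tol
    return ok, report


# -- reporting ------------------------------------------------------------

_ROW_LABELS = {
    ("mean", "per_feed"): ("Mean", "Kcal/kg/feed"),
    ("mean", "per_day"): ("Mean", "Kcal/kg/day"),
    ("sd", "per_feed"): ("SD", "Kcal/kg/feed"),
    ("sd", "per_day"): ("SD", "Kcal/kg/day"),
    ("q1", "per_feed"): ("LCI (Q1)", "Kcal/kg/feed"),
    ("q1", "per_day"): ("LCI (Q1)", "Kcal/kg/day"),
    ("q2", "per_feed"): ("MCI (Q2)", "Kcal/kg/feed"),
    ("q2", "per_day"): ("MCI (Q2)", "Kcal/kg/day"),
    ("q3", "per_feed"): ("HCI (Q3)", "Kcal/kg/feed"),
    ("q3", "per_day"): ("HCI (Q3)", "Kcal/kg/day"),
}


def to_long_frame(summaries: Sequence[IntakeSummary]) -> pd.DataFrame:
    """Tidy long table: one row per (group, outcome, statistic)."""
    seen = set()
    for s in summaries:
        key = (s.group_label, s.outcome)
        if key in seen:
            raise ValueError(f"duplicate summary for {key}")
        seen.add(key)
    rows = [
        {
            "group": s.group_label,
            "outcome": s.outcome,
            "statistic": stat,
            "value": getattr(s, stat),
        }
        for s in summaries
        for stat in _STATISTICS
    ]
    return pd.DataFrame(rows, columns=["group", "outcome", "statistic", "value"])


def to_table(summaries: Sequence[IntakeSummary], decimals: int = 2) -> pd.DataFrame:
    """Wide report: statistic x outcome rows, age-group columns.

    Ten rows (Mean/SD/LCI/MCI/HCI, each for per-feed and per-day
    intake), values rounded for presentation only.
    """
    if len(summaries) == 0:
        raise ValueError("need at least one summary")
    long = to_long_frame(summaries)
    groups = list(dict.fromkeys(s.group_label for s in summaries))
    index = pd.MultiIndex.from_tuples(
        [_ROW_LABELS[(stat, out)] for stat in _STATISTICS for out in OUTCOMES],
        names=["Statistic", "Outcome"],
    )
    table = pd.DataFrame(index=index, columns=groups, dtype=float)
    for _, row in long.iterrows():
        table.loc[_ROW_LABELS[(row["statistic"], row["outcome"])], row["group"]] = row["value"]
    return table.round(decimals)
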