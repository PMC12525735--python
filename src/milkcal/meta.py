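"""Random-effects pooling of study-level caloric-density measurements.

Studies report the mean and SD of milk caloric density (kcal/dL) in a
sample of n mother–infant pairs.  Per age group, study means are pooled
with inverse-variance weighting under a random-effects model whose
between-study variance tau^2 is estimated by the DerSimonian–Laird
moment method.  Heterogeneity is summarised by Cochran's Q and the I^2
statistic.  Pooled estimates convert to model input distributions: a
normal distribution (pooled mean, SD back-computed from the 95% CI) when
heterogeneity is low, a PERT distribution spanning the CI with the
pooled mean as mode when it is high.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .distributions import DistributionSpec, make_spec

DENSITY_UNITS = "kcal/dL"

#: I^2 above which a pooled density is represented by a PERT rather than
#: a normal distribution ("high heterogeneity", Cochrane convention).
DEFAULT_I2_THRESHOLD_PCT = 75.0


@dataclass(frozen=True)
class StudyRecord:
    """One study's caloric-density summary for one age group."""

    study_id: str
    mean: float
    sd: float
    n: int
    age_group: str

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError(f"study {self.study_id!r}: sd must be > 0, got {self.sd}")
        if self.n < 2:
            raise ValueError(f"study {self.study_id!r}: n must be >= 2, got {self.n}")

    @property
    def se(self) -> float:
        """Standard error of the study mean, sd/sqrt(n)."""
        return self.sd / np.sqrt(self.n)


@dataclass(frozen=True)
class PooledEstimate:
    """Random-effects pooled mean with heterogeneity diagnostics."""

    k: int
    pooled_mean: float
    se: float
    ci_low: float
    ci_high: float
    Q: float
    tau2: float
    i2: float  # percent, 0-100
    weights: tuple[float, ...]  # relative random-effects weights, sum 1


def pool_random_effects(studies: Sequence[StudyRecord], z: float = 1.96) -> PooledEstimate:
    """DerSimonian–Laird random-effects pool of one age group's studies.

    A single study is returned as-is (Q = tau2 = I2 = 0) rather than
    erroring: some age groups rest on very few studies.
    """
    if len(studies) == 0:
        raise ValueError("cannot pool an empty study list")
    groups = {s.age_group for s in studies}
    if len(groups) > 1:
        raise ValueError(f"studies span multiple age groups: {sorted(groups)}")

    x = np.array([s.mean for s in studies], dtype=float)
    se = np.array([s.se for s in studies], dtype=float)
    k = len(studies)

    w = 1.0 / se**2  # fixed-effect weights
    xbar_fixed = float(np.sum(w * x) / np.sum(w))
    Q = float(np.sum(w * (x - xbar_fixed) ** 2))

    if k == 1:
        tau2 = 0.0
        i2 = 0.0
    else:
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (Q - (k - 1)) / denom)
        i2 = max(0.0, (Q - (k - 1)) / Q) * 100.0 if Q > 0 else 0.0

    w_star = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w_star * x) / np.sum(w_star))
    pooled_se = float(1.0 / np.sqrt(np.sum(w_star)))

    return PooledEstimate(
        k=k,
        pooled_mean=pooled,
        se=pooled_se,
        ci_low=pooled - z * pooled_se,
        ci_high=pooled + z * pooled_se,
        Q=Q,
        tau2=float(tau2),
        i2=float(i2),
        weights=tuple(w_star / np.sum(w_star)),
    )


def se_from_ci(ci_low: float, ci_high: float, z: float = 1.96) -> float:
    """Back-compute a standard error from a symmetric confidence interval."""
    if not ci_high > ci_low:
        raise ValueError(f"inverted interval [{ci_low}, {ci_high}]")
    if not z > 0:
        raise ValueError(f"z must be > 0, got {z}")
    return (ci_high - ci_low) / (2.0 * z)


def density_spec_from_pooled(
    est: PooledEstimate,
    i2_threshold_pct: float = DEFAULT_I2_THRESHOLD_PCT,
) -> DistributionSpec:
    """Convert a pooled estimate into a caloric-density distribution.

    Below the heterogeneity threshold: normal(pooled mean, SD from the
    CI half-width).  At or above it: PERT with the CI limits as range
    and the pooled mean as the most likely value.
    """
    if est.i2 < i2_threshold_pct:
        sigma = se_from_ci(est.ci_low, est.ci_high)
        return make_spec("normal", {"mu": est.pooled_mean, "sigma": sigma}, DENSITY_UNITS)
    return make_spec(
        "pert",
        {"a": est.ci_low, "m": est.pooled_mean, "b": est.ci_high},
        DENSITY_UNITS,
    )


def synth_studies(
    true_mean: float,
    tau: float,
    k: int,
    within_sd: float,
    n_per_study: int,
    seed: int,
    age_group: str = "synthetic",
) -> list[StudyRecord]:
    """Generate a synthetic study table for parameter-recovery tests.

    Each study mean is drawn from N(true_mean, tau^2 + within_sd^2/n):
    the true effect varies between studies with SD ``tau`` and each
    study observes its effect with sampling error within_sd/sqrt(n).
    Reported SDs are held at ``within_sd`` so that the pooling stage
    sees the nominal within-study precision.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if not within_sd > 0:
        raise ValueError("within_sd must be > 0")
    rng = np.random.default_rng(seed)
    total_sd = np.sqrt(tau**2 + within_sd**2 / n_per_study)
    means = rng.normal(true_mean, total_sd, size=k)
    return [
        StudyRecord(
            study_id=f"S{i + 1:03d}",
            mean=float(means[i]),
            sd=within_sd,
            n=n_per_study,
            age_group=age_group,
        )
        for i in range(k)
    ]


# -- CSV interfaces -------------------------------------------------------

STUDY_COLUMNS = ["study_id", "age_group", "mean", "sd", "n"]


def read_studies_csv(path: str | Path) -> list[StudyRecord]:
    """Read a study table (columns study_id, age_group, mean, sd, n)."""
    df = pd.read_csv(path)
    missing = set(STUDY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                StudyRecord(
                    study_id=str(row["study_id"]),
                    mean=float(row["mean"]),
                    sd=float(row["sd"]),
                    n=int(row["n"]),
                    age_group=str(row["age_group"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: row {i + 2}: {exc}") from exc
    return records


def pool_by_group(
    studies: Iterable[StudyRecord], z: float = 1.96
) -> dict[str, PooledEstimate]:
    """Pool each age group present in a study table, preserving order."""
    by_group: dict[str, list[StudyRecord]] = {}
    for s in studies:
        by_group.setdefault(s.age_group, []).append(s)
    return {g: pool_random_effects(recs, z=z) for g, recs in by_group.items()}


def pooled_table(pooled: dict[str, PooledEstimate]) -> pd.DataFrame:
    """One row per age group: pooled mean, CI, Q, tau2, I2, k."""
    rows = [
        {
            "age_group": g,
            "k": e.k,
            "pooled_mean": e.pooled_mean,
            "se": e.se,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "Q": e.Q,
            "tau2": e.tau2,
            "i2": e.i2,
        }
        for g, e in pooled.items()
    ]
    return pd.DataFrame(rows, columns=["age_group", "k", "pooled_mean", "se",
                                       "ci_low", "ci_high", "Q", "tau2", "i2"])
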