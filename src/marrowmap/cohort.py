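"""Cohort-level statistics over marrow volume reports.

Ordinary least-squares regressions (slope, intercept, R^2, slope p-value),
paired t-tests between tracer-derived volumes, one-way ANOVA / two-group
comparisons, and the Devine ideal-body-weight covariate. Exercised on
synthetic cohorts; the panel layout follows the usual marrow-volumetry
questions (volumes vs anthropometrics, male/female differences, tracer
agreement).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SubjectRecord",
    "RegressionResult",
    "PairedTResult",
    "GroupCompareResult",
    "least_squares",
    "paired_t_test",
    "group_compare",
    "ideal_body_weight",
    "cohort_panel",
]


@dataclass(frozen=True)
class SubjectRecord:
    """Anthropometrics plus per-tracer volume reports for one subject."""

    id: str
    sex: str
    weight_kg: float
    height_cm: float
    bmi: float | None = None
    ideal_body_weight_kg: float | None = None
    reports: Mapping[str, object] | None = None  # tracer tag -> VolumeReport

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.weight_kg <= 0 or self.height_cm <= 0:
            raise ValueError("weight and height must be positive")
        if self.bmi is not None:
            expected = self.weight_kg / (self.height_cm / 100.0) ** 2
            if abs(self.bmi - expected) > 1e-6 * max(1.0, expected):
                raise ValueError(
                    f"bmi {self.bmi} inconsistent with weight/height (expected {expected:.6f})"
                )

    @property
    def bmi_computed(self) -> float:
        return self.bmi if self.bmi is not None else self.weight_kg / (self.height_cm / 100.0) ** 2


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")


@dataclass(frozen=True)
class PairedTResult:
    t: float
    p: float
    mean_difference: float
    n: int
    undefined: bool = False  # zero-variance differences: t has no value


@dataclass(frozen=True)
class GroupCompareResult:
    statistic: float  # one-way ANOVA F
    p: float
    group_sizes: tuple[int, ...]
    t: float | None = None  # equivalent two-sample t when exactly 2 groups


def least_squares(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least-squares fit of y on x.

    R^2 = 1 - SS_res/SS_tot; the slope p-value is two-sided from the t
    distribution with n-2 degrees of freedom (NaN for n < 3).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    fit = sps.linregress(x, y)
    p = float(fit.pvalue) if x.size >= 3 else math.nan
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        p_value=p,
        n=int(x.size),
    )


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> PairedTResult:
    """Classical paired t-test on the differences a - b, two-sided.

    Zero-variance differences leave t undefined; the result is flagged
    rather than raising, since the mean difference is still meaningful.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D vectors of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    mean_diff = float(diff.mean())
    # zero-variance up to float rounding of the subtraction
    if float(diff.std(ddof=1)) <= 1e-10 * max(1.0, abs(mean_diff)):
        return PairedTResult(t=math.nan, p=math.nan, mean_difference=mean_diff,
                             n=int(a.size), undefined=True)
    t, p = sps.ttest_rel(a, b)
    return PairedTResult(t=float(t), p=float(p), mean_difference=mean_diff, n=int(a.size))


def group_compare(values: Sequence[float], groups: Sequence) -> GroupCompareResult:
    """One-way ANOVA across groups; two groups also report the pooled t.

    With exactly two groups F = t^2, so both views of the same comparison
    are returned.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    labels = [g for g in pd.unique(groups)]
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in labels]
    sizes = tuple(int(s.size) for s in samples)
    if any(n < 2 for n in sizes):
        raise ValueError(f"every group needs at least 2 members, got sizes {sizes}")
    if np.ptp(values) == 0:
        # no variance at all: no between-group signal, F defined as 0
        f, p = 0.0, 1.0
    else:
        f, p = sps.f_oneway(*samples)
    t = None
    if len(samples) == 2:
        if np.ptp(values) == 0:
            t = 0.0
        else:
            t = float(sps.ttest_ind(samples[0], samples[1], equal_var=True).statistic)
    return GroupCompareResult(statistic=float(f), p=float(p), group_sizes=sizes, t=t)


def ideal_body_weight(sex: str, height_cm: float) -> float:
    """Devine ideal body weight in kg.

    M: 50 kg + 0.906 kg/cm over 152.4 cm; F: 45.5 kg + the same increment
    (2.3 kg per inch over five feet). Heights below 152.4 cm floor at the
    sex-specific base.
    """
    if sex not in ("M", "F"):
        raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")
    if height_cm <= 0:
        raise ValueError("height must be positive")
    base = 50.0 if sex == "M" else 45.5
    return base + 0.906 * max(height_cm - 152.4, 0.0)


# -- cohort panel -----------------------------------------------------------

_VOLUME_COLUMNS = ("rbv_ml", "ybv_ml", "ibv_ml", "red_fraction")
_COVARIATES = ("weight_kg", "height_cm", "bmi", "ideal_body_weight_kg")


def cohort_panel(table: pd.DataFrame, subset: pd.Series | None = None) -> dict:
    """Regression / paired-t / ANOVA panel over a cohort table.

    ``table`` has one row per subject per tracer with columns ``id``,
    ``sex``, ``weight_kg``, ``height_cm``, ``tracer`` and the volume-report
    columns (rbv_ml, ybv_ml, ibv_ml, red_fraction, and optionally
    spinal_mean_suv / rob_mean_suv). BMI and ideal body weight are derived
    when absent. ``subset`` is an optional boolean row filter (e.g. males
    only) applied before the regressions and sex comparisons.
    """
    df = table.copy()
    if "bmi" not in df.columns:
        df["bmi"] = df["weight_kg"] / (df["height_cm"] / 100.0) ** 2
    if "ideal_body_weight_kg" not in df.columns:
        df["ideal_body_weight_kg"] = [
            ideal_body_weight(s, h) for s, h in zip(df["sex"], df["height_cm"])
        ]
    if subset is not None:
        df = df[subset]

    panel: dict = {"regressions": {}, "sex_comparisons": {}, "tracer_paired_t": {}}
    for tracer, sub in df.groupby("tracer"):
        reg_block = {}
        for vol in _VOLUME_COLUMNS:
            if vol not in sub.columns:
                continue
            for cov in _COVARIATES:
                rows = sub[[cov, vol]].dropna()
                if (len(rows) >= 3 and np.ptp(rows[cov].to_numpy()) > 0
                        and np.ptp(rows[vol].to_numpy()) > 0):
                    res = least_squares(rows[cov].to_numpy(), rows[vol].to_numpy())
                    reg_block[f"{vol}~{cov}"] = asdict(res)
        panel["regressions"][tracer] = reg_block

        sex_block = {}
        for vol in _VOLUME_COLUMNS + ("spinal_mean_suv", "rob_mean_suv"):
            if vol not in sub.columns:
                continue
            rows = sub[["sex", vol]].dropna()
            sizes = rows["sex"].value_counts()
            if len(sizes) == 2 and sizes.min() >= 2:
                res = group_compare(rows[vol].to_numpy(), rows["sex"].to_numpy())
                sex_block[vol] = asdict(res)
        panel["sex_comparisons"][tracer] = sex_block

    tracers = sorted(df["tracer"].unique())
    for i, ta in enumerate(tracers):
        for tb in tracers[i + 1 :]:
            wide = df.pivot_table(index="id", columns="tracer", values=list(_VOLUME_COLUMNS))
            block = {}
            for vol in _VOLUME_COLUMNS:
                if (vol, ta) in wide.columns and (vol, tb) in wide.columns:
                    pair = wide[[(vol, ta), (vol, tb)]].dropna()
                    if len(pair) >= 2:
                        res = paired_t_test(
                            pair[(vol, ta)].to_numpy(), pair[(vol, tb)].to_numpy()
                        )
                        block[vol] = asdict(res)
            panel["tracer_paired_t"][f"{ta}-vs-{tb}"] = block
    return panel
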