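"""Enzyme-assay and Western-blot statistics.

Fluorometric activities are back-calculated through a linear 4-MU standard
curve, normalized by incubation time and protein mass, and summarized as
mean +/- sample SD per group. Group comparisons use the pooled two-sample
Student t ("two-way" t-test in the figure legends reads as two-tailed; the
one-tailed variant is used for directional Western-blot questions). Band
intensities are normalized lane-by-lane against a loading control.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy import stats

from .containers import AssaySummary, StandardCurve, TTestResult
from .synthetic import AssayPlate

__all__ = [
    "fit_standard_curve", "enzyme_activity", "activities_from_plate",
    "group_summary", "two_sample_t", "t_from_summary", "normalize_bands",
]

MIN_PER_HOUR = 60.0


def fit_standard_curve(x, y) -> StandardCurve:
    """Ordinary least squares line through known amounts vs responses."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct x values")
    res = stats.linregress(x, y)
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         r2=float(res.rvalue ** 2), x=x, y=y)


def enzyme_activity(response: float, curve: StandardCurve,
                    incubation_time_min: float, protein_mass_mg: float,
                    unit: str = "nmol/min/mg") -> float:
    """Back-calculate released 4-MU and normalize to an activity.

    activity = ((response - intercept) / slope) / time / mass. A negative
    back-calculated amount (response below the blank) is clamped to zero
    activity with a warning.
    """
    if curve.slope == 0:
        raise ValueError("standard curve slope must be non-zero")
    if incubation_time_min <= 0 or protein_mass_mg <= 0:
        raise ValueError("incubation time and protein mass must be positive")
    released = curve.inverse(response)
    if released < 0:
        warnings.warn("negative back-calculated 4-MU amount clamped to zero",
                      stacklevel=2)
        released = 0.0
    per_min = released / incubation_time_min / protein_mass_mg
    if unit == "nmol/min/mg":
        return per_min
    if unit == "nmol/h/mg":
        return per_min * MIN_PER_HOUR
    raise ValueError(f"unknown unit {unit!r}")


def activities_from_plate(plate: AssayPlate,
                          unit: str = "nmol/min/mg") -> dict[str, float]:
    """Fit the plate's standards, then back-calculate every unknown well."""
    curve = fit_standard_curve(plate.standards["known_amount"],
                               plate.standards["response"])
    out: dict[str, float] = {}
    for _, row in plate.unknowns.iterrows():
        out[row["well"]] = enzyme_activity(
            row["response"], curve, incubation_time_min=row["time_min"],
            protein_mass_mg=row["protein_mg"], unit=unit)
    return out


def group_summary(values, group: str = "", unit: str = "nmol/min/mg"
                  ) -> AssaySummary:
    """Replicates with mean and sample SD (n-1); n < 2 flags SD undefined."""
    summary = AssaySummary(group=group, values=np.asarray(values, float),
                           unit=unit)
    if summary.n < 2:
        warnings.warn("fewer than 2 replicates: SD undefined", stacklevel=2)
    return summary


def _t_to_p(t: float, df: float, tails: str) -> float:
    if not math.isfinite(t):
        return 0.0
    if tails == "two":
        return float(2.0 * stats.t.sf(abs(t), df))
    return float(stats.t.sf(t, df))   # one-tailed: upper tail of group A


def two_sample_t(values_a, values_b, tails: str = "two",
                 variance: str = "pooled") -> TTestResult:
    """Student t-test of group A vs group B on raw replicate vectors.

    Pooled variance by default (Welch optional). One-tailed mode tests for
    A being larger. Degenerate inputs: zero variance with equal means gives
    t = 0, p = 1; zero variance with unequal means gives an infinite t with
    p = 0 and a flag.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if variance == "pooled":
        return t_from_summary(a.mean(), a.std(ddof=1), a.size,
                              b.mean(), b.std(ddof=1), b.size, tails=tails)
    if variance != "welch":
        raise ValueError(f"unknown variance mode {variance!r}")
    res = stats.ttest_ind(a, b, equal_var=False)
    t = float(res.statistic)
    df = float(res.df)
    return TTestResult(t=t, df=df, p=_t_to_p(t, df, tails), tails=tails,
                       variance="welch")


def t_from_summary(mean_a: float, sd_a: float, n_a: int,
                   mean_b: float, sd_b: float, n_b: int,
                   tails: str = "two") -> TTestResult:
    """Pooled two-sample t from summary statistics (means, SDs, ns).

    Exactly reproduces ``two_sample_t`` on raw vectors with matching
    summaries, which lets printed mean +/- SD values be tested directly.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 observations per group")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be non-negative")
    df = n_a + n_b - 2
    sp2 = ((n_a - 1) * sd_a ** 2 + (n_b - 1) * sd_b ** 2) / df
    se = math.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    diff = mean_a - mean_b
    flag = None
    if se == 0.0:
        if diff == 0.0:
            t = 0.0
        else:
            t = math.copysign(math.inf, diff)
            flag = "zero pooled variance with unequal means"
    else:
        t = diff / se
    if t == 0.0:
        p = 1.0 if tails == "two" else 0.5
    else:
        p = _t_to_p(t, df, tails)
    return TTestResult(t=float(t), df=float(df), p=p, tails=tails,
                       variance="pooled", flag=flag)


def normalize_bands(target_intensities, control_intensities) -> np.ndarray:
    """Per-lane ratio of target band to loading-control band."""
    target = np.asarray(target_intensities, dtype=float)
    control = np.asarray(control_intensities, dtype=float)
    if target.shape != control.shape:
        raise ValueError("target and control must be paired by lane")
    bad = np.where(control <= 0)[0]
    if bad.size:
        raise ValueError(f"non-positive control intensity at lane(s) {bad.tolist()}")
    return target / control
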