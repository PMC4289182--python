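"""Day/night photo-behaviour statistics.

Arm-extension counts (arms visible above the sediment; each animal can
extend at most two) are compared between day and night per light treatment.
The battery per treatment: an F test for variance homogeneity, Shapiro-Wilk
normality on each group, then a pooled-variance unpaired two-tailed t test.
A treatment is scored light-sensitive when day and night means differ at
alpha = 0.05; day-time suppression (day mean below night mean) is the
direction expected for a photonegative, night-feeding animal.

Variance/normality checks annotate the result, they do not gate the verdict;
Welch's correction is available behind a flag.  No multiple-testing
correction is applied across treatments (a documented limitation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .seqcore import InputError

TREATMENTS = ("white", "green", "blue", "red", "none")

DEFAULT_ALPHA = 0.05


@dataclass
class BehaviourDataset:
    """Per-treatment day and night arm counts (observations or daily means)."""

    treatment: str
    day_counts: list[float]
    night_counts: list[float]
    n_animals: int = 18
    n_days: int = 8

    def __post_init__(self):
        if not self.day_counts or not self.night_counts:
            raise InputError("both day and night groups must be non-empty")
        cap = 2 * self.n_animals
        for v in list(self.day_counts) + list(self.night_counts):
            if v < 0 or v > cap:
                raise InputError(
                    f"count {v} outside [0, {cap}] (each animal extends at most two arms)"
                )


@dataclass(frozen=True)
class TestResult:
    treatment: str
    t_statistic: float
    df: float
    p_value: float
    variance_f: float
    variance_p: float
    normality_p_day: float
    normality_p_night: float
    day_mean: float
    night_mean: float
    verdict: str  # sensitive | not_sensitive


def f_test_variances(a, b) -> tuple[float, float]:
    """Variance-ratio F test, two-tailed; F is larger variance over smaller."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InputError("F test needs n >= 2 per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise InputError("F test undefined: both groups have zero variance")
    if va >= vb:
        num_var, den_var, dfn, dfd = va, vb, len(a) - 1, len(b) - 1
    else:
        num_var, den_var, dfn, dfd = vb, va, len(b) - 1, len(a) - 1
    if den_var == 0:
        warnings.warn("one group has zero variance; F is infinite (degenerate)")
        return float("inf"), 0.0
    F = num_var / den_var
    p = min(1.0, 2.0 * stats.f.sf(F, dfn, dfd))
    return float(F), float(p)


def normality_test(x) -> float:
    """Shapiro-Wilk p-value; constant input is flagged as undefined (NaN)."""
    x = np.asarray(x, dtype=float)
    if not 3 <= len(x) <= 50:
        raise InputError("Shapiro-Wilk supported for 3 <= n <= 50 here")
    if np.ptp(x) == 0:
        warnings.warn("constant group; normality undefined")
        return float("nan")
    return float(stats.shapiro(x).pvalue)


def students_t_test(
    day, night, treatment: str = "", alpha: float = DEFAULT_ALPHA,
    welch: bool = False,
) -> TestResult:
    """Unpaired two-tailed t test (pooled variance unless ``welch``)."""
    day = np.asarray(day, dtype=float)
    night = np.asarray(night, dtype=float)
    if len(day) < 2 or len(night) < 2:
        raise InputError("t test needs n >= 2 per group")
    res = stats.ttest_ind(day, night, equal_var=not welch)
    df = res.df if hasattr(res, "df") else len(day) + len(night) - 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            F, pF = f_test_variances(day, night)
        except InputError:
            F, pF = float("nan"), float("nan")
        try:
            p_day = normality_test(day) if 3 <= len(day) <= 50 else float("nan")
        except InputError:
            p_day = float("nan")
        try:
            p_night = (
                normality_test(night) if 3 <= len(night) <= 50 else float("nan")
            )
        except InputError:
            p_night = float("nan")
    p_value = float(res.pvalue)
    if np.isnan(p_value):  # identical constant groups
        t_stat, p_value = 0.0, 1.0
    else:
        t_stat = float(res.statistic)
    return TestResult(
        treatment=treatment,
        t_statistic=t_stat,
        df=float(df),
        p_value=p_value,
        variance_f=F,
        variance_p=pF,
        normality_p_day=p_day,
        normality_p_night=p_night,
        day_mean=float(day.mean()),
        night_mean=float(night.mean()),
        verdict="sensitive" if p_value < alpha else "not_sensitive",
    )


def spectral_verdicts(
    datasets: list[BehaviourDataset], alpha: float = DEFAULT_ALPHA,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-treatment test battery with a day-suppression direction note."""
    rows = []
    for ds in datasets:
        r = students_t_test(ds.day_counts, ds.night_counts, ds.treatment,
                            alpha=alpha, welch=welch)
        rows.append(
            {
                "treatment": r.treatment,
                "day_mean": r.day_mean,
                "night_mean": r.night_mean,
                "t": r.t_statistic,
                "df": r.df,
                "p_value": r.p_value,
                "variance_F": r.variance_f,
                "variance_p": r.variance_p,
                "shapiro_p_day": r.normality_p_day,
                "shapiro_p_night": r.normality_p_night,
                "verdict": r.verdict,
                "day_suppressed": r.day_mean < r.night_mean,
            }
        )
    return pd.DataFrame(rows)


def datasets_from_table(
    table: pd.DataFrame, unit: str = "daily_mean"
) -> list[BehaviourDataset]:
    """Build per-treatment datasets from a tidy count table.

    Expected columns: treatment, phase (day|night), timestamp, arm_count.
    With ``unit='daily_mean'`` (default) observations sharing the day part of
    the timestamp (the text before the first underscore) are averaged before
    testing; ``unit='observation'`` uses raw observations.
    """
    if unit not in ("daily_mean", "observation"):
        raise InputError("unit must be 'daily_mean' or 'observation'")
    datasets = []
    for treatment, sub in table.groupby("treatment", sort=False):
        groups: dict[str, list[float]] = {"day": [], "night": []}
        for phase, psub in sub.groupby("phase"):
            if unit == "daily_mean":
                day_of = psub["timestamp"].astype(str).str.split("_").str[0]
                vals = psub.groupby(day_of)["arm_count"].mean().tolist()
            else:
                vals = psub["arm_count"].tolist()
            groups[phase] = [float(v) for v in vals]
        datasets.append(
            BehaviourDataset(
                treatment=str(treatment),
                day_counts=groups["day"],
                night_counts=groups["night"],
            )
        )
    return datasets
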