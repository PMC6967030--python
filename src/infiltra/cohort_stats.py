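"""Cohort-level statistics: median split, Mann-Whitney / Fisher group
comparisons, Kaplan-Meier + log-rank event-free survival, univariate Cox on
log-transformed ratios, and the characteristics table."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy.stats import mannwhitneyu

from infiltra.errors import FitError, InputError, NoEventsError
from infiltra.hla_assoc import fisher_exact_2x2


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    groups: tuple
    statistic: float
    p: float
    test: str  # "Mann-Whitney" or "Fisher"


@dataclass
class SurvivalFit:
    curves: dict  # group label -> DataFrame(time, at_risk, survival)
    logrank_p: float | None = None
    logrank_stat: float | None = None
    hr: float | None = None
    hr_ci95: tuple | None = None
    cox_p: float | None = None
    log_hr: float | None = None
    log_hr_se: float | None = None


def median_split(values) -> np.ndarray:
    """Dichotomize at the median: strictly above -> HIGH, at or below ->
    LOW (ties and the median value itself go LOW)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InputError("need at least 2 values")
    if np.ptp(v) == 0:
        warnings.warn("all values identical; degenerate split (all LOW)")
    med = np.median(v)
    return np.where(v > med, "HIGH", "LOW")


def compare_continuous(group_a, group_b, variable: str = "", method: str = "auto") -> GroupComparison:
    """Two-sided Mann-Whitney U comparison.

    ``method="auto"`` uses the exact null distribution when both groups have
    n <= 8 and no ties, and the tie-corrected normal approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be non-empty")
    if method == "auto":
        no_ties = len(np.unique(np.concatenate([a, b]))) == a.size + b.size
        method = "exact" if (max(a.size, b.size) <= 8 and no_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        variable=variable,
        groups=("A", "B"),
        statistic=float(res.statistic),
        p=float(min(1.0, res.pvalue)),
        test="Mann-Whitney",
    )


def compare_categorical(table, variable: str = "") -> GroupComparison:
    """Two-sided Fisher exact comparison of a 2x2 table."""
    p = fisher_exact_2x2(table)
    return GroupComparison(variable=variable, groups=("A", "B"), statistic=math.nan, p=p, test="Fisher")


def _km_curve(time, event) -> pd.DataFrame:
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    tab = kmf.event_table
    surv = kmf.survival_function_.iloc[:, 0]
    return pd.DataFrame(
        {
            "time": tab.index.to_numpy(dtype=float),
            "at_risk": tab["at_risk"].to_numpy(dtype=int),
            "survival": surv.reindex(tab.index).to_numpy(dtype=float),
        }
    )


def km_logrank(time, event, labels) -> SurvivalFit:
    """Per-group product-limit estimates plus the two-group log-rank test.

    With zero events overall the KM curves are still estimable (identically
    1) but the log-rank comparison is undefined; a NoEventsError carrying
    the fitted curves is raised.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    labels = np.asarray(labels)
    curves = {}
    for lab in np.unique(labels):
        sel = labels == lab
        curves[str(lab)] = _km_curve(time[sel], event[sel])
    fit = SurvivalFit(curves=curves)
    if not event.any():
        raise NoEventsError("no events observed; log-rank undefined", fit=fit)
    groups = np.unique(labels)
    if groups.size != 2:
        raise InputError("log-rank comparison requires exactly 2 groups")
    sel = labels == groups[0]
    res = logrank_test(time[sel], time[~sel], event_observed_A=event[sel], event_observed_B=event[~sel])
    fit.logrank_p = float(res.p_value)
    fit.logrank_stat = float(res.test_statistic)
    return fit


def cox_univariate_logratio(
    records: pd.DataFrame,
    ratio_col: str = "cd8_ratio",
    time_col: str = "followup_years",
    event_col: str = "event",
) -> SurvivalFit:
    """Univariate Cox partial-likelihood fit on the natural-log ratio.

    Zero ratios are replaced by half the smallest positive ratio in the
    cohort before the log transform. Ties are handled by lifelines' Efron
    approximation. The hazard ratio is per unit natural-log ratio, so it is
    invariant to rescaling the ratio by a constant.
    """
    df = records[[ratio_col, time_col, event_col]].copy()
    if not df[event_col].any():
        raise NoEventsError("no events observed; Cox model undefined")
    ratios = df[ratio_col].to_numpy(dtype=float)
    if np.any(ratios < 0):
        raise InputError("ratios must be >= 0")
    positive = ratios[ratios > 0]
    if positive.size == 0:
        raise InputError("all ratios are 0; log transform impossible")
    ratios = np.where(ratios == 0, positive.min() / 2.0, ratios)
    df["log_ratio"] = np.log(ratios)
    cph = CoxPHFitter()
    try:
        cph.fit(
            df[["log_ratio", time_col, event_col]],
            duration_col=time_col,
            event_col=event_col,
        )
    except ConvergenceError as exc:  # pragma: no cover - degenerate inputs
        raise FitError(f"Cox fit failed to converge: {exc}") from exc
    beta = float(cph.params_["log_ratio"])
    se = float(cph.standard_errors_["log_ratio"])
    return SurvivalFit(
        curves={},
        hr=math.exp(beta),
        hr_ci95=(math.exp(beta - 1.96 * se), math.exp(beta + 1.96 * se)),
        cox_p=float(cph.summary.loc["log_ratio", "p"]),
        log_hr=beta,
        log_hr_se=se,
    )


# ---------------------------------------------------------------------------
# Characteristics table


def _row(variable, level, n_all, n_hi, n_lo, tot_all, tot_hi, tot_lo, p=None):
    return {
        "variable": variable,
        "level": level,
        "all_n": n_all,
        "all_pct": 100.0 * n_all / tot_all,
        "high_n": n_hi,
        "high_pct": 100.0 * n_hi / tot_hi,
        "low_n": n_lo,
        "low_pct": 100.0 * n_lo / tot_lo,
        "p": p,
    }


def build_table1(records: pd.DataFrame, labels) -> pd.DataFrame:
    """Counts and column percentages per stratum with Fisher p per
    categorical row and Mann-Whitney p for follow-up.

    Unknown mutation status is shown but excluded from its Fisher test.
    """
    labels = np.asarray(labels)
    hi = labels == "HIGH"
    lo = labels == "LOW"
    n, n_hi, n_lo = len(records), int(hi.sum()), int(lo.sum())
    rows = []

    def fisher_for(mask: np.ndarray, known: np.ndarray | None = None) -> float:
        keep = known if known is not None else np.ones(n, dtype=bool)
        a = int((mask & hi & keep).sum())
        b = int((~mask & hi & keep).sum())
        c = int((mask & lo & keep).sum())
        d = int((~mask & lo & keep).sum())
        return fisher_exact_2x2([[a, b], [c, d]])

    def add_binary(variable, mask, levels=("yes", "no"), known=None):
        p = fisher_for(mask, known)
        for level, m in zip(levels, (mask, ~mask)):
            if known is not None:
                m = m & known
            rows.append(
                _row(variable, level, int(m.sum()), int((m & hi).sum()), int((m & lo).sum()), n, n_hi, n_lo, p)
            )
            p = None  # print p once per variable

    male = records["sex"].to_numpy() == "male"
    add_binary("sex", male, ("male", "female"))
    ped = records["age_group"].to_numpy() == "pediatric"
    add_binary("age_group", ped, ("pediatric", "adult"))
    extent = records["extent"].to_numpy()
    for level in ("SS", "MS RO-", "MS RO+"):
        mask = extent == level
        rows.append(
            _row("extent", level, int(mask.sum()), int((mask & hi).sum()), int((mask & lo).sum()), n, n_hi, n_lo, fisher_for(mask))
        )
    braf = records["braf"].to_numpy()
    known = braf != "unknown"
    add_binary("braf", braf == "V600E", ("V600E", "WT"), known=known)
    unknown = ~known
    rows.append(
        _row("braf", "unknown", int(unknown.sum()), int((unknown & hi).sum()), int((unknown & lo).sum()), n, n_hi, n_lo)
    )
    if "chemo_fdo" in records.columns:
        add_binary("chemo_fdo", records["chemo_fdo"].to_numpy(dtype=bool))
    fu = records["followup_years"].to_numpy(dtype=float)
    p_fu = compare_continuous(fu[hi], fu[lo]).p
    rows.append(
        {
            "variable": "followup_years",
            "level": "median",
            "all_n": float(np.median(fu)),
            "all_pct": np.nan,
            "high_n": float(np.median(fu[hi])),
            "high_pct": np.nan,
            "low_n": float(np.median(fu[lo])),
            "low_pct": np.nan,
            "p": p_fu,
        }
    )
    return pd.DataFrame(rows)
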