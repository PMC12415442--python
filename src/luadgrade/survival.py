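"""Prognostic validation harness: Kaplan–Meier, log-rank, Cox models.

Stratifies survival records by the grade labels any grading system
produces, estimates product-limit curves per group, tests group separation
with the k-sample log-rank test, and fits uni-/multivariate Cox
proportional-hazards models with the common clinicopathological covariates
(pT, pN, age).  Off-the-shelf survival routines (lifelines) are the
numerical backend; this module contributes the grading-to-survival
plumbing, covariate encodings and report format.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

ENDPOINTS = ("OS", "CSS", "PFS")


@dataclass
class SurvivalRecord:
    """One case's follow-up and clinicopathological covariates.

    time is in months; event 1 = endpoint reached, 0 = censored.
    pN = 2 encodes pN2–pN3 (pooled).
    """

    case_id: str
    endpoint: str
    time: float
    event: int
    pT: int | None = None
    pN: int | None = None
    age: float | None = None
    stage: str | None = None
    cohort: str = ""

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"endpoint must be one of {ENDPOINTS}")
        if self.time <= 0:
            raise ValueError("follow-up time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")
        if self.pT is not None and self.pT not in (1, 2, 3, 4):
            raise ValueError("pT must be in {1,2,3,4}")
        if self.pN is not None and self.pN not in (0, 1, 2):
            raise ValueError("pN must be in {0,1,2} (2 pools pN2-pN3)")


def records_to_frame(records: Iterable[SurvivalRecord]) -> pd.DataFrame:
    rows = [
        {
            "case_id": r.case_id,
            "endpoint": r.endpoint,
            "time": r.time,
            "event": r.event,
            "pT": r.pT,
            "pN": r.pN,
            "age": r.age,
            "stage": r.stage,
            "cohort": r.cohort,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def subset(
    records: Sequence[SurvivalRecord],
    stage: str | None = None,
    pT: int | None = None,
    cohort_in: set[str] | None = None,
    cohort_not_in: set[str] | None = None,
) -> list[SurvivalRecord]:
    """Pure cohort filter (e.g. Stage I, pT1, or merged-cohort selections)."""
    out = records
    if stage is not None:
        out = [r for r in out if r.stage == stage]
    if pT is not None:
        out = [r for r in out if r.pT == pT]
    if cohort_in is not None:
        out = [r for r in out if r.cohort in cohort_in]
    if cohort_not_in is not None:
        out = [r for r in out if r.cohort not in cohort_not_in]
    out = list(out)
    if not out:
        warnings.warn("subset produced an empty record list")
    return out


def km_logrank(
    records: Sequence[SurvivalRecord],
    grade_by_case: Mapping[str, str],
) -> dict:
    """Kaplan–Meier curves per grade group and the k-sample log-rank test.

    Returns per-group fitted curves (step-function coordinates), median
    survival, group sizes and the overall log-rank chi-square with k-1
    degrees of freedom.  Groups with zero events are retained with a
    warning.
    """
    df = records_to_frame(records)
    df["grade"] = df["case_id"].map(grade_by_case)
    df = df.dropna(subset=["grade"])
    groups = sorted(df["grade"].unique())
    if len(groups) < 2:
        raise ValueError("k-sample log-rank needs at least 2 non-empty groups")

    curves, medians, sizes = {}, {}, {}
    for g, sub in df.groupby("grade"):
        if sub["event"].sum() == 0:
            warnings.warn(f"grade group {g!r} has zero events")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(g))
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
        medians[g] = float(kmf.median_survival_time_)
        sizes[g] = int(len(sub))

    lr = multivariate_logrank_test(df["time"], df["grade"], df["event"])
    return {
        "groups": groups,
        "curves": curves,
        "median_survival": medians,
        "n_per_group": sizes,
        "logrank_stat": float(lr.test_statistic),
        "logrank_p": float(lr.p_value),
        "df": len(groups) - 1,
    }


def cox_fit(
    records: Sequence[SurvivalRecord],
    grade_by_case: Mapping[str, str],
    covariates: Sequence[str] = (),
    reference: str | None = None,
    pT_categorical: bool = False,
) -> pd.DataFrame:
    """Cox proportional-hazards fit of grade (categorical) with covariates.

    The grade enters as dummy indicators against the reference level
    (default: lowest grade label in sorted order).  Covariates from
    {pT, pN, age}: pT and pN enter ordinal-as-linear by default (pT can be
    switched to categorical).  Complete-case rows only; the number used is
    attached to the frame as ``fit.attrs['n_used']``.

    Returns one row per model term with hazard ratio, 95% CI and p.
    Non-convergence is flagged, not fatal.
    """
    df = records_to_frame(records)
    df["grade"] = df["case_id"].map(grade_by_case)
    df = df.dropna(subset=["grade"])
    levels = sorted(df["grade"].unique())
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not present")

    X = pd.DataFrame({"time": df["time"], "event": df["event"]})
    for lev in levels:
        if lev != reference:
            X[f"grade_{lev}"] = (df["grade"] == lev).astype(float)
    for cov in covariates:
        if cov not in ("pT", "pN", "age"):
            raise ValueError(f"unsupported covariate {cov!r}")
        if cov == "pT" and pT_categorical:
            for t in (2, 3, 4):
                X[f"pT_{t}"] = (df["pT"] == t).astype(float)
            X.loc[df["pT"].isna(), [f"pT_{t}" for t in (2, 3, 4)]] = np.nan
        else:
            X[cov] = pd.to_numeric(df[cov], errors="coerce")
    n_total = len(X)
    X = X.dropna()

    cph = CoxPHFitter()
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(X, duration_col="time", event_col="event")
        summ = cph.summary
        out = pd.DataFrame(
            {
                "term": summ.index,
                "coef": summ["coef"].to_numpy(),
                "HR": summ["exp(coef)"].to_numpy(),
                "HR_low95": summ["exp(coef) lower 95%"].to_numpy(),
                "HR_high95": summ["exp(coef) upper 95%"].to_numpy(),
                "p": summ["p"].to_numpy(),
            }
        ).reset_index(drop=True)
    except Exception as exc:  # separation / non-convergence
        converged = False
        out = pd.DataFrame(
            {"term": [c for c in X.columns if c not in ("time", "event")]}
        )
        out["coef"] = np.nan
        out["HR"] = np.nan
        out["HR_low95"] = np.nan
        out["HR_high95"] = np.nan
        out["p"] = np.nan
        out["error"] = str(exc)
    out.attrs["n_used"] = int(len(X))
    out.attrs["n_dropped_incomplete"] = int(n_total - len(X))
    out.attrs["reference"] = reference
    out.attrs["converged"] = converged
    return out
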