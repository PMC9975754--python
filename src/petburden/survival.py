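"""Median-split grouping, Kaplan-Meier, log-rank and Cox prognostics.

The cohort is dichotomized at the sample median of a metabolic burden
metric (MTV or TLG); ties at the cut fall in the low group so the high
group is strictly above the cut.  Survival curves use the product-limit
estimator, group separation the two-group log-rank test, and hazard
modeling Cox proportional hazards with Efron tie handling (univariate in
the metric, or multivariable with LDH and ECOG).  Estimation is
delegated to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "KmCurve",
    "CoxFit",
    "median_split",
    "km_fit",
    "logrank",
    "cox_fit",
    "prognosis_report",
]


@dataclass
class KmCurve:
    """One group's product-limit survival curve."""

    group: str
    times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray
    cut_point: float | None = None


@dataclass
class CoxFit:
    """Cox proportional-hazards fit summary (Wald inference)."""

    model: str  # "univariate" | "multivariable"
    coef: dict[str, float]
    hazard_ratio: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    p_value: dict[str, float]
    n: int
    n_events: int
    converged: bool = True


def median_split(values) -> tuple[float, np.ndarray]:
    """Split at the sample median: value > cut → "high", else "low".

    Raises if every value is identical (one group would be empty).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("median split requires n >= 2")
    if np.ptp(values) == 0:
        raise ValueError("all values identical; median split yields an empty group")
    cut = float(np.median(values))
    labels = np.where(values > cut, "high", "low")
    if len(np.unique(labels)) < 2:
        raise ValueError("median split yields an empty group (heavy ties at the median)")
    return cut, labels


def _check_records(records: pd.DataFrame) -> None:
    if (records["time_months"] < 0).any():
        raise ValueError("negative follow-up time")
    if not records["event"].isin([0, 1]).all():
        raise ValueError("event flag must be 0 or 1")


def km_fit(records: pd.DataFrame, groups, cut_point: float | None = None) -> list[KmCurve]:
    """Kaplan-Meier curve per group (columns time_months, event)."""
    _check_records(records)
    groups = np.asarray(groups)
    if len(groups) != len(records):
        raise ValueError("every record needs a group label")
    curves = []
    for g in np.unique(groups):
        sel = groups == g
        if sel.sum() == 0:
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(records.loc[sel, "time_months"], records.loc[sel, "event"], label=str(g))
        tbl = kmf.event_table
        curves.append(KmCurve(
            group=str(g),
            times=tbl.index.to_numpy(dtype=float),
            at_risk=tbl["at_risk"].to_numpy(dtype=float),
            survival=kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float),
            cut_point=cut_point,
        ))
    return curves


def logrank(records: pd.DataFrame, groups) -> tuple[float, float]:
    """Two-group (or k-group) log-rank test: (chi-square, p-value)."""
    _check_records(records)
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValueError("log-rank requires at least two groups")
    if int(records["event"].sum()) == 0:
        raise ValueError("log-rank requires at least one event")
    res = multivariate_logrank_test(records["time_months"], groups, records["event"])
    return float(res.test_statistic), float(res.p_value)


def cox_fit(records: pd.DataFrame, covariates: list[str],
            tie_method: str = "Efron") -> CoxFit:
    """Cox proportional-hazards fit over the named covariate columns.

    Raises on zero events, zero-variance covariates or non-convergence.
    """
    _check_records(records)
    if int(records["event"].sum()) == 0:
        raise ValueError("Cox model requires at least one event")
    for cov in covariates:
        col = records[cov].to_numpy(dtype=float)
        if not np.all(np.isfinite(col)):
            raise ValueError(f"covariate {cov} has non-finite values")
        if np.ptp(col) == 0:
            raise ValueError(f"covariate {cov} has zero variance")
    df = records[["time_months", "event", *covariates]].copy()
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time_months", event_col="event",
                show_progress=False, fit_options={"step_size": 0.5})
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise ValueError(f"Cox fit failed to converge: {exc}") from exc
    summ = cph.summary
    return CoxFit(
        model="univariate" if len(covariates) == 1 else "multivariable",
        coef={c: float(summ.loc[c, "coef"]) for c in covariates},
        hazard_ratio={c: float(summ.loc[c, "exp(coef)"]) for c in covariates},
        ci_low={c: float(summ.loc[c, "exp(coef) lower 95%"]) for c in covariates},
        ci_high={c: float(summ.loc[c, "exp(coef) upper 95%"]) for c in covariates},
        p_value={c: float(summ.loc[c, "p"]) for c in covariates},
        n=len(df),
        n_events=int(df["event"].sum()),
    )


def prognosis_report(measurements: pd.DataFrame, records: pd.DataFrame,
                     metrics: tuple[str, ...] = ("mtv_ml", "tlg_suvml"),
                     readers: tuple[str, ...] = ("M", "A")) -> dict:
    """Full prognostic report: metric × reader median splits, KM, Cox.

    ``measurements`` is the long reader table; ``records`` the survival
    table.  For every metric/reader combination the report holds the
    median cut point, the KM curves of the high/low groups, the log-rank
    chi-square and p, a univariate Cox fit in the continuous metric, and
    a multivariable fit adding LDH and ECOG.  Patients missing from
    either table are reported under ``join_mismatches``.
    """
    report: dict = {"combinations": {}, "join_mismatches": []}
    rec_ids = set(records["patient_id"])
    for reader in readers:
        sub = measurements[measurements["reader"] == reader]
        meas_ids = set(sub["patient_id"])
        mismatches = sorted((meas_ids ^ rec_ids))
        if mismatches:
            report["join_mismatches"].extend(
                {"reader": reader, "patient_id": pid} for pid in mismatches
            )
        joined = sub.merge(records, on="patient_id", how="inner")
        for metric in metrics:
            cut, groups = median_split(joined[metric])
            curves = km_fit(joined, groups, cut_point=cut)
            chi2, p = logrank(joined, groups)
            uni = cox_fit(joined, [metric])
            multi = cox_fit(joined, [metric, "ldh", "ecog"])
            report["combinations"][(metric, reader)] = {
                "cut_point": cut,
                "km_curves": curves,
                "logrank_chi2": chi2,
                "logrank_p": p,
                "cox_univariate": uni,
                "cox_multivariable": multi,
                "n": len(joined),
            }
    return report


def restrict_followup(records: pd.DataFrame, cap_months: float) -> pd.DataFrame:
    """Administrative censoring at ``cap_months`` (e.g. 12 for 1-year PFS).

    Times past the cap are truncated to it and their events cleared.
    """
    if cap_months <= 0:
        raise ValueError("cap_months must be > 0")
    out = records.copy()
    over = out["time_months"] > cap_months
    out.loc[over, "time_months"] = cap_months
    out.loc[over, "event"] = 0
    return out


def report_table(report: dict) -> pd.DataFrame:
    """Flatten a prognosis report into one row per Cox model."""
    rows = []
    for (metric, reader), res in report["combinations"].items():
        for tag in ("cox_univariate", "cox_multivariable"):
            fit: CoxFit = res[tag]
            rows.append({
                "metric": metric,
                "reader": reader,
                "model": fit.model,
                "cut_point": res["cut_point"],
                "logrank_p": res["logrank_p"],
                "hr_metric": fit.hazard_ratio[metric],
                "p_metric": fit.p_value[metric],
                "hr_ldh": fit.hazard_ratio.get("ldh", np.nan),
                "hr_ecog": fit.hazard_ratio.get("ecog", np.nan),
                "n": fit.n,
                "n_events": fit.n_events,
            })
    return pd.DataFrame(rows)
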