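"""Overall-survival analysis.

Kaplan-Meier curves with log-rank tests over median-dichotomized repertoire
metrics (within phenotype strata), and multivariate Cox proportional-hazards
models adjusted for phenotype and stage, optionally with chain-interaction
covariates (elementwise products of transformed metric columns). Ties in the
Cox partial likelihood are handled with Efron's method (lifelines default);
metric covariates enter on the log2(value+1) scale by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from .stats import bh_adjust, log2p1

STAGE_ORDINAL = {"I": 1, "II": 2, "III": 3, "IV": 4}


class NotDichotomizableError(ValueError):
    """All values identical: no median split exists."""


@dataclass
class KMStratum:
    label: str
    times: np.ndarray  # event/censor times in input order of the step function
    survival: np.ndarray  # product-limit estimate after each time
    at_risk: np.ndarray  # number at risk just before each time
    n: int


@dataclass
class KMResult:
    strata: list[KMStratum]
    chi2: float | None = None
    p: float | None = None


@dataclass
class CoxResult:
    covariate: str
    hr: float
    ci_lower: float
    ci_upper: float
    p_raw: float
    p_adj: float = float("nan")
    n: int = 0
    n_events: int = 0
    flagged: bool = False
    reason: str = ""


def dichotomize_by_median(values) -> np.ndarray:
    """Label values <= median "Low" and > median "High" (ties go Low).

    Missing values get None. Raises :class:`NotDichotomizableError` when all
    non-missing values are identical.
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[~np.isnan(arr)]
    if finite.size < 2:
        raise ValueError("need at least 2 non-missing values to dichotomize")
    if np.ptp(finite) == 0:
        raise NotDichotomizableError("all values identical; no median split")
    median = float(np.median(finite))
    labels = np.empty(arr.shape, dtype=object)
    for i, v in enumerate(arr):
        labels[i] = None if np.isnan(v) else ("Low" if v <= median else "High")
    return labels


def km_logrank(
    times, events, labels, at_risk_ticks: Sequence[float] | None = None
) -> KMResult:
    """Product-limit estimates per stratum plus the standard log-rank test.

    With a single stratum only the estimate is returned (no test).
    ``at_risk_ticks``, when given, evaluates the at-risk counts at those
    times instead of at every observed time.
    """
    df = pd.DataFrame({"time": times, "event": events, "label": labels}).dropna()
    if df.empty:
        raise ValueError("no usable observations")
    strata = []
    for label, sub in sorted(df.groupby("label"), key=lambda kv: str(kv[0])):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(label))
        timeline = np.asarray(kmf.survival_function_.index, dtype=float)
        if at_risk_ticks is not None:
            ticks = np.asarray(at_risk_ticks, dtype=float)
        else:
            ticks = timeline
        surv = kmf.survival_function_at_times(ticks).to_numpy()
        observed = sub["time"].to_numpy()
        at_risk = np.array([int((observed >= t).sum()) for t in ticks])
        strata.append(
            KMStratum(
                label=str(label), times=ticks, survival=surv,
                at_risk=at_risk, n=len(sub),
            )
        )
    result = KMResult(strata=strata)
    if df["label"].nunique() >= 2:
        lr = multivariate_logrank_test(df["time"], df["label"], df["event"])
        result.chi2 = float(lr.test_statistic)
        result.p = float(lr.p_value)
    return result


def _code_stage(stage: pd.Series, coding: str) -> pd.DataFrame:
    if coding == "ordinal":
        return pd.DataFrame({"stage": stage.map(STAGE_ORDINAL)})
    if coding == "categorical":
        dummies = pd.get_dummies(stage, prefix="stage", dtype=float)
        return dummies.drop(columns=["stage_I"], errors="ignore")
    raise ValueError(f"unknown stage coding {coding!r}")


def cox_multivariate(
    clinical: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    interactions: Sequence[tuple[str, str]] = (),
    stage_coding: str = "ordinal",
    transform_metrics: bool = True,
    adjust_family: bool = True,
) -> list[CoxResult]:
    """Multivariate Cox PH fit adjusted for phenotype and stage.

    ``clinical`` needs sample_id, phenotype (LSP/HSP), stage, os_days,
    event columns; ``covariates`` is sample-indexed with metric columns
    (entered as log2(value+1) when ``transform_metrics``). Each named
    interaction becomes the elementwise product of the two (transformed)
    columns. Phenotype is coded LSP=1 against the HSP reference, so a
    protective LSP effect appears as HR < 1. P-values are BH-adjusted across
    the fitted battery.
    """
    df = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical.copy()
    design = pd.DataFrame(index=df.index)
    design["phenotype_LSP"] = (df["phenotype"] == "LSP").astype(float)
    design = pd.concat([design, _code_stage(df["stage"], stage_coding)], axis=1)
    if covariates is not None:
        cov = covariates.reindex(df.index).astype(float)
        if transform_metrics:
            cov = cov.apply(lambda s: log2p1(s.to_numpy()), raw=False)
        for a, b in interactions:
            cov[f"{a}:{b}"] = cov[a] * cov[b]
        design = pd.concat([design, cov], axis=1)
    design["os_days"] = df["os_days"].astype(float)
    design["event"] = df["event"].astype(int) if "event" in df.columns else df["vital_status"].astype(int)
    design = design.dropna()
    n_events = int(design["event"].sum())
    if n_events == 0:
        raise ValueError("no events in the data; Cox model is not identifiable")

    fit_cols = [c for c in design.columns if c not in ("os_days", "event")]
    constant = [c for c in fit_cols if design[c].nunique() <= 1]
    results: list[CoxResult] = []
    for c in constant:
        results.append(
            CoxResult(
                covariate=c, hr=1.0, ci_lower=0.0, ci_upper=np.inf,
                p_raw=1.0, n=len(design), n_events=n_events,
                flagged=True, reason="zero variance",
            )
        )
    fit_cols = [c for c in fit_cols if c not in constant]
    if fit_cols:
        cph = CoxPHFitter()  # Efron tie handling (lifelines default)
        try:
            cph.fit(
                design[fit_cols + ["os_days", "event"]],
                duration_col="os_days",
                event_col="event",
            )
        except ConvergenceError as exc:
            for c in fit_cols:
                results.append(
                    CoxResult(
                        covariate=c, hr=float("nan"), ci_lower=float("nan"),
                        ci_upper=float("nan"), p_raw=float("nan"),
                        n=len(design), n_events=n_events,
                        flagged=True, reason=f"non-convergence: {exc}",
                    )
                )
            return results
        summary = cph.summary
        for c in fit_cols:
            row = summary.loc[c]
            results.append(
                CoxResult(
                    covariate=c,
                    hr=float(row["exp(coef)"]),
                    ci_lower=float(row["exp(coef) lower 95%"]),
                    ci_upper=float(row["exp(coef) upper 95%"]),
                    p_raw=float(row["p"]),
                    n=len(design),
                    n_events=n_events,
                )
            )
    if adjust_family:
        ok = [r for r in results if np.isfinite(r.p_raw)]
        if ok:
            adj = bh_adjust([max(r.p_raw, np.nextafter(0, 1)) for r in ok])
            for r, p in zip(ok, adj):
                r.p_adj = float(p)
    return results


def cox_table(results: Sequence[CoxResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "covariate": r.covariate, "hr": r.hr,
                "ci_lower": r.ci_lower, "ci_upper": r.ci_upper,
                "p_raw": r.p_raw, "p_adj": r.p_adj,
                "n": r.n, "n_events": r.n_events,
                "flagged": r.flagged, "reason": r.reason,
            }
            for r in results
        ]
    )


def km_summary(result: KMResult) -> dict:
    """JSON-serialisable summary of a KM analysis."""
    return {
        "logrank_chi2": result.chi2,
        "logrank_p": result.p,
        "strata": [
            {
                "label": s.label,
                "n": s.n,
                "times": [float(t) for t in s.times],
                "survival": [float(v) for v in s.survival],
                "at_risk": [int(v) for v in s.at_risk],
            }
            for s in result.strata
        ],
    }
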