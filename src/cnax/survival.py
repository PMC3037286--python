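"""Survival analysis of signature classes and clinical covariates.

Thin, typed wrappers around lifelines: Kaplan-Meier product-limit curves
with Greenwood confidence bands (read out at 60 months for 5-year
figures), the two-group log-rank test, and Cox proportional-hazards
regression (Efron tie handling, Wald tests, complete-case analysis).
Times are months from diagnosis; event = 1 for relapse/death, 0 censored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = ["KaplanMeierResult", "kaplan_meier", "logrank_test", "cox_fit"]


@dataclass
class KaplanMeierResult:
    times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    max_time: float

    def survival_at(self, t: float) -> tuple[float, tuple[float, float], bool]:
        """S(t) with Greenwood CI; the flag marks an extrapolated read-out
        (t beyond the last observed time, last estimate carried forward)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        idx = max(idx, 0)
        extrapolated = t > self.max_time
        return (
            float(self.survival[idx]),
            (float(self.ci_lower[idx]), float(self.ci_upper[idx])),
            extrapolated,
        )


def _check(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) == 0:
        raise ValueError("no subjects")
    if np.any(time < 0):
        raise ValueError("times must be non-negative")
    if not np.isin(event, [0, 1]).all():
        raise ValueError("event flags must be 0 or 1")
    return time, event


def kaplan_meier(time, event) -> KaplanMeierResult:
    """Product-limit survival estimate with Greenwood confidence band."""
    time, event = _check(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    surv = kmf.survival_function_
    ci = kmf.confidence_interval_
    return KaplanMeierResult(
        times=surv.index.to_numpy(dtype=float),
        survival=surv.iloc[:, 0].to_numpy(dtype=float),
        ci_lower=ci.iloc[:, 0].to_numpy(dtype=float),
        ci_upper=ci.iloc[:, 1].to_numpy(dtype=float),
        max_time=float(time.max()),
    )


def logrank_test(time, event, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    time, event = _check(time, event)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {len(labels)}")
    m = groups == labels[0]
    if m.sum() == 0 or (~m).sum() == 0:
        raise ValueError("a group has no subjects")
    res = _ll_logrank(time[m], time[~m], event_observed_A=event[m], event_observed_B=event[~m])
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    records: pd.DataFrame,
    covariates: list[str],
    multivariate: bool = True,
    time_col: str = "time",
    event_col: str = "event",
) -> pd.DataFrame:
    """Cox proportional-hazards regression (Efron ties, Wald inference).

    Univariate mode fits each covariate alone; multivariate fits them
    jointly. Rows with missing values in the used columns are excluded
    (complete-case). Requires at least one event. Returns a frame
    (covariate, n, hr, ci_low, ci_high, p).
    """
    _check(records[time_col], records[event_col].fillna(-1).astype(int))
    blocks = [covariates] if multivariate else [[c] for c in covariates]
    rows = []
    for block in blocks:
        sub = records[[time_col, event_col] + block].dropna()
        if sub.empty or int(sub[event_col].sum()) == 0:
            raise ValueError("no events among complete cases; cannot fit Cox model")
        cph = CoxPHFitter()
        cph.fit(sub, duration_col=time_col, event_col=event_col)
        summ = cph.summary
        for cov in block:
            rows.append(
                {
                    "covariate": cov,
                    "n": int(len(sub)),
                    "hr": float(summ.loc[cov, "exp(coef)"]),
                    "ci_low": float(summ.loc[cov, "exp(coef) lower 95%"]),
                    "ci_high": float(summ.loc[cov, "exp(coef) upper 95%"]),
                    "p": float(summ.loc[cov, "p"]),
                }
            )
    return pd.DataFrame(rows, columns=["covariate", "n", "hr", "ci_low", "ci_high", "p"])
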