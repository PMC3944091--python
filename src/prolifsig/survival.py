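"""Survival analysis: DMFS encoding, Kaplan-Meier, log-rank, and Cox PH.

The endpoint throughout is distant-metastasis-free survival (DMFS): the
event is distant metastasis or breast-cancer death; death from other
causes, locoregional recurrence, second primaries and contralateral
disease censor at the last follow-up visit.

The Cox model maximizes the partial likelihood by Newton-Raphson with
Breslow tie handling by default (Efron optional); standard errors come
from the observed information, confidence intervals are
exp(coef +/- 1.96*SE), and per-covariate p-values are Wald tests.
Log-rank testing delegates to lifelines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test
from scipy import stats


class CoxConvergenceError(RuntimeError):
    """Raised when the partial-likelihood maximization fails."""


@dataclass
class SurvivalCurve:
    """Kaplan-Meier step function with per-event-time risk/event counts."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")


@dataclass
class CoxResult:
    coefficients: pd.Series
    se: pd.Series
    hr: pd.Series
    ci95: pd.DataFrame  # columns lower, upper
    wald_p: pd.Series
    included: list = field(default_factory=list)
    trace: list = field(default_factory=list)
    loglik: float = float("nan")


def encode_dmfs(clinical: pd.DataFrame) -> pd.DataFrame:
    """Per-sample DMFS time and event indicator from a clinical table.

    Two input dialects are accepted:

    * ``follow_up`` + ``dmfs_event`` columns (already encoded);
    * ``follow_up`` + ``event_type`` (one of ``distant_metastasis``,
      ``breast_cancer_death``, ``other_death``, ``locoregional``,
      ``second_primary``, ``contralateral``, ``none``), optionally with a
      ``recurrence_time`` column. Distant metastasis / breast-cancer
      death are events; everything else censors at last follow-up. A
      confirmed metastasis without a recurrence date is an event at the
      last follow-up visit.
    """
    if "follow_up" not in clinical.columns:
        raise ValueError("clinical table lacks a follow_up column")
    missing = clinical.index[clinical["follow_up"].isna()].tolist()
    if missing:
        raise ValueError(f"missing follow-up times for samples {missing[:10]}")
    if "event_type" in clinical.columns:
        is_event = clinical["event_type"].isin(["distant_metastasis", "breast_cancer_death"])
        time = clinical["follow_up"].astype(float).copy()
        if "recurrence_time" in clinical.columns:
            has_date = is_event & clinical["recurrence_time"].notna()
            time[has_date] = clinical.loc[has_date, "recurrence_time"].astype(float)
        event = is_event.astype(int)
    elif "dmfs_event" in clinical.columns:
        time = clinical["follow_up"].astype(float)
        event = clinical["dmfs_event"].astype(int)
    else:
        raise ValueError("clinical table lacks dmfs_event or event_type columns")
    if (time <= 0).any():
        bad = clinical.index[time <= 0].tolist()
        raise ValueError(f"non-positive follow-up times for samples {bad[:10]}")
    return pd.DataFrame({"time": time, "event": event}, index=clinical.index)


def km_estimate(records: pd.DataFrame) -> SurvivalCurve:
    """Product-limit survival estimate.

    ``records`` has ``time`` and ``event`` columns. Censored observations
    tied with an event time are counted at risk at that time (censoring
    breaks ties after events).
    """
    if len(records) == 0:
        raise ValueError("no survival records")
    time = records["time"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=int)
    event_times = np.unique(time[event == 1])
    at_risk = np.array([(time >= t).sum() for t in event_times])
    events = np.array([((time == t) & (event == 1)).sum() for t in event_times])
    with np.errstate(divide="ignore"):
        survival = np.cumprod(1.0 - events / at_risk)
    return SurvivalCurve(
        event_times=event_times,
        survival=survival,
        at_risk=at_risk,
        events=events,
    )


def survival_at(curve: SurvivalCurve, t: float) -> float:
    """Right-continuous step-function evaluation of the KM curve at time t."""
    if t < 0:
        raise ValueError("time must be non-negative")
    idx = np.searchsorted(curve.event_times, t, side="right") - 1
    return 1.0 if idx < 0 else float(curve.survival[idx])


def logrank_test(groups: list[pd.DataFrame]) -> tuple[float, float]:
    """Log-rank chi-square (k-1 df) and p-value across k groups of records."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(groups):
        if len(g) == 0:
            raise ValueError(f"group {i} has zero records")
    time = np.concatenate([g["time"].to_numpy(dtype=float) for g in groups])
    event = np.concatenate([g["event"].to_numpy(dtype=int) for g in groups])
    label = np.concatenate([np.full(len(g), i) for i, g in enumerate(groups)])
    res = multivariate_logrank_test(time, label, event)
    return float(res.test_statistic), float(res.p_value)


def _cox_loglik_grad_hess(beta, x, time, event, ties):
    """Breslow/Efron partial log-likelihood with gradient and Hessian."""
    n, p = x.shape
    eta = x @ beta
    w = np.exp(eta)
    loglik, grad = 0.0, np.zeros(p)
    hess = np.zeros((p, p))
    for t in np.unique(time[event == 1]):
        risk = time >= t
        dead = (time == t) & (event == 1)
        d = int(dead.sum())
        wr = w[risk]
        xr = x[risk]
        s0 = wr.sum()
        s1 = xr.T @ wr
        s2 = (xr * wr[:, None]).T @ xr
        loglik += eta[dead].sum()
        grad += x[dead].sum(axis=0)
        if ties == "breslow":
            loglik -= d * math.log(s0)
            grad -= d * s1 / s0
            hess -= d * (s2 / s0 - np.outer(s1, s1) / s0**2)
        elif ties == "efron":
            wd = w[dead]
            xd = x[dead]
            s0d = wd.sum()
            s1d = xd.T @ wd
            s2d = (xd * wd[:, None]).T @ xd
            for l in range(d):
                f = l / d
                a0 = s0 - f * s0d
                a1 = s1 - f * s1d
                a2 = s2 - f * s2d
                loglik -= math.log(a0)
                grad -= a1 / a0
                hess -= a2 / a0 - np.outer(a1, a1) / a0**2
        else:
            raise ValueError(f"unknown tie method {ties!r}")
    return loglik, grad, hess


def cox_fit(
    covariates: pd.DataFrame,
    records: pd.DataFrame,
    *,
    ties: str = "breslow",
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxResult:
    """Cox proportional-hazards fit by Newton-Raphson.

    ``covariates`` is a samples x covariates frame aligned with
    ``records`` (``time``/``event``). Raises on constant covariates,
    too few events, non-convergence, or monotone likelihood (complete
    separation, detected as a diverging coefficient).
    """
    x = covariates.to_numpy(dtype=float)
    names = list(covariates.columns)
    time = records["time"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=int)
    if x.shape[0] != len(time):
        raise ValueError("covariates and records must align")
    if any(np.ptp(x[:, j]) == 0 for j in range(x.shape[1])):
        bad = [names[j] for j in range(x.shape[1]) if np.ptp(x[:, j]) == 0]
        raise ValueError(f"constant covariates: {bad}")
    if event.sum() < x.shape[1]:
        raise ValueError("fewer events than covariates")

    beta = np.zeros(x.shape[1])
    loglik = -np.inf
    for _ in range(max_iter):
        loglik, grad, hess = _cox_loglik_grad_hess(beta, x, time, event, ties)
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as err:
            raise CoxConvergenceError(f"singular information matrix: {err}") from err
        # step-halving to keep the likelihood ascending
        for _ in range(30):
            new_beta = beta + step
            new_ll, _, _ = _cox_loglik_grad_hess(new_beta, x, time, event, ties)
            if new_ll >= loglik - 1e-12:
                break
            step = step / 2.0
        beta = beta + step
        if np.any(np.abs(beta) > 30):
            raise CoxConvergenceError(
                "monotone partial likelihood (complete separation suspected)"
            )
        if np.linalg.norm(grad) < tol:
            break
    else:
        raise CoxConvergenceError(
            f"no convergence after {max_iter} iterations; |grad| = {np.linalg.norm(grad):.3g}"
        )

    loglik, grad, hess = _cox_loglik_grad_hess(beta, x, time, event, ties)
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    if not np.all(np.isfinite(se)) or np.any(se > 50):
        raise CoxConvergenceError(
            "unstable fit: standard errors diverge (quasi-complete separation)"
        )
    z = beta / se
    wald_p = 2.0 * stats.norm.sf(np.abs(z))
    coef = pd.Series(beta, index=names)
    se_s = pd.Series(se, index=names)
    return CoxResult(
        coefficients=coef,
        se=se_s,
        hr=np.exp(coef),
        ci95=pd.DataFrame(
            {"lower": np.exp(coef - 1.96 * se_s), "upper": np.exp(coef + 1.96 * se_s)}
        ),
        wald_p=pd.Series(wald_p, index=names),
        included=names,
        loglik=float(loglik),
    )


def cox_forward_wald(
    candidates: pd.DataFrame,
    records: pd.DataFrame,
    p_enter: float = 0.05,
    direction: str = "forward",
    *,
    ties: str = "breslow",
) -> CoxResult:
    """Stepwise Cox model selection by Wald p-values.

    Forward: repeatedly add the candidate with the smallest Wald p-value
    below ``p_enter`` until none qualifies. Backward: start from the full
    model and drop the covariate with the largest Wald p above the
    threshold. The inclusion/removal trace is recorded on the result.
    """
    if candidates.shape[1] == 0:
        raise ValueError("candidate covariate set is empty")
    names = list(candidates.columns)
    trace: list[str] = []
    if direction == "forward":
        included: list[str] = []
        while True:
            best_name, best_p = None, None
            for name in names:
                if name in included:
                    continue
                try:
                    fit = cox_fit(candidates[included + [name]], records, ties=ties)
                except (CoxConvergenceError, ValueError):
                    continue  # separated/degenerate candidate: cannot enter
                p = float(fit.wald_p[name])
                if best_p is None or p < best_p:
                    best_name, best_p = name, p
            if best_name is None or best_p > p_enter:
                break
            included.append(best_name)
            trace.append(f"+{best_name} (p={best_p:.4g})")
        if not included:
            raise CoxConvergenceError(
                f"no candidate reached the entry threshold p<={p_enter}"
            )
    elif direction == "backward":
        included = list(names)
        while len(included) > 1:
            fit = cox_fit(candidates[included], records, ties=ties)
            worst = fit.wald_p.idxmax()
            if float(fit.wald_p[worst]) <= p_enter:
                break
            included.remove(worst)
            trace.append(f"-{worst} (p={float(fit.wald_p[worst]):.4g})")
    else:
        raise ValueError(f"unknown direction {direction!r}")
    final = cox_fit(candidates[included], records, ties=ties)
    final.included = included
    final.trace = trace
    return final


def event_free_percent(events: int, at_risk: int) -> int:
    """Integer event-free percentage, rounded half away from zero.

    ``round(100 * (1 - events/at_risk))`` with .5 rounding away from
    zero, matching how such percentages are conventionally printed.
    """
    if at_risk <= 0:
        raise ValueError("at_risk must be positive")
    if not 0 <= events <= at_risk:
        raise ValueError("events must be between 0 and at_risk")
    value = 100.0 * (1.0 - events / at_risk)
    return int(math.floor(value + 0.5))
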