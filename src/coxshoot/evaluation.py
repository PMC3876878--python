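"""Prediction and selection metrics for fitted Cox models.

Risk scores f(x) = beta'x split patients into high/low-risk groups at a
cutoff (zero by default); group separation is assessed with Kaplan-Meier
curves and the two-sample log-rank test (both via lifelines).  Prediction
accuracy uses the IPCW (inverse probability of censoring weighting)
integrated Brier score: squared error between the predicted survival
probability and the observed at-risk indicator, reweighted by the
Kaplan-Meier estimate of the censoring distribution G fitted on the
TRAINING data, then averaged over [0, t_max] by the trapezoid rule.
Variable-selection quality is summarized by Var / Corr / Incorr counts
against the generating coefficient vector (zeros are bit-exact).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .survival_core import SurvivalDataset


@dataclass
class KMCurve:
    """Product-limit survival step function on the distinct event-time grid."""

    grid_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def at(self, t, left: bool = False) -> np.ndarray:
        """Step-function value S(t) (right-continuous) or left limit S(t-)."""
        t = np.atleast_1d(np.asarray(t, dtype=np.float64))
        if self.grid_times.size == 0:
            return np.ones_like(t)
        side = "left" if left else "right"
        idx = np.searchsorted(self.grid_times, t, side=side) - 1
        return np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])


@dataclass
class BaselineHazard:
    """Breslow cumulative baseline hazard as a right-continuous step function."""

    grid_times: np.ndarray
    cumulative_hazard: np.ndarray

    def cumhaz(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=np.float64))
        idx = np.searchsorted(self.grid_times, t, side="right") - 1
        return np.where(idx < 0, 0.0,
                        self.cumulative_hazard[np.clip(idx, 0, None)])

    def survival(self, t) -> np.ndarray:
        return np.exp(-self.cumhaz(t))


@dataclass
class SelectionMetrics:
    var_count: int
    corr_zeros: int
    incorr_zeros: int


def risk_score(beta, covariates) -> np.ndarray:
    """Linear risk scores f(x) = beta'x, one per row of covariates."""
    beta = np.asarray(beta, dtype=np.float64)
    covariates = np.asarray(covariates, dtype=np.float64)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    return covariates @ beta


def split_groups(scores, cutoff: float = 0.0) -> np.ndarray:
    """High-risk label 1 iff score > cutoff; scores exactly at the cutoff are low-risk."""
    scores = np.asarray(scores, dtype=np.float64)
    return (scores > cutoff).astype(np.int64)


def km_estimator(time, status) -> KMCurve:
    """Kaplan-Meier product-limit estimator, reported at distinct event times."""
    time = np.asarray(time, dtype=np.float64)
    status = np.asarray(status)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=status)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    if len(ev) == 0:
        return KMCurve(np.empty(0), np.empty(0),
                       np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
    grid = ev.index.to_numpy(dtype=np.float64)
    surv = kmf.survival_function_.loc[ev.index, kmf._label].to_numpy(dtype=np.float64)
    return KMCurve(grid_times=grid, survival=surv,
                   at_risk=ev["at_risk"].to_numpy(dtype=np.int64),
                   events=ev["observed"].to_numpy(dtype=np.int64))


def logrank_test(time, status, groups) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its upper-tail p-value."""
    time = np.asarray(time, dtype=np.float64)
    status = np.asarray(status)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError("exactly two groups required")
    a = groups == labels[0]
    res = _ll_logrank(time[a], time[~a], event_observed_A=status[a],
                      event_observed_B=status[~a])
    return float(res.test_statistic), float(res.p_value)


def baseline_survival(data: SurvivalDataset, beta):
    """Breslow baseline: returns a step-function S0(t) = exp(-H0(t)).

    H0(t) = sum over events with t_i <= t of d_i / sum_{j in R_i} exp(eta_j),
    so with beta = 0 it reduces to the Nelson-Aalen estimator.  The returned
    object has ``.cumhaz(t)`` and ``.survival(t)``; subject-level predictions
    are S0(t) ** exp(beta'x) (see :func:`predict_survival`).
    """
    beta = np.asarray(beta, dtype=np.float64)
    eta = np.clip(data.covariates @ beta, -500, 500)
    order = np.argsort(data.time, kind="stable")
    t_s = data.time[order]
    st_s = data.status[order]
    w = np.exp(eta[order] - eta.max())
    W_suffix = np.cumsum(w[::-1])[::-1]
    group_start = np.searchsorted(t_s, t_s, side="left")
    ev = np.flatnonzero(st_s == 1)
    ev_times = np.unique(t_s[ev])
    # Breslow increment at each distinct event time: d / sum_{risk set} e^eta;
    # the max-subtraction scale re-enters as exp(-max) to avoid overflow
    scale = np.exp(-eta.max())
    increments = np.zeros(ev_times.shape[0])
    for i, t in enumerate(ev_times):
        pos = np.searchsorted(t_s, t, side="left")
        d = int(np.sum((t_s == t) & (st_s == 1)))
        increments[i] = d * scale / W_suffix[pos]
    return BaselineHazard(ev_times, np.cumsum(increments))


def predict_survival(train: SurvivalDataset, beta, covariates, times) -> np.ndarray:
    """Predicted S(t|x) = S0(t)^exp(beta'x) on a time grid; rows = subjects."""
    base = baseline_survival(train, beta)
    eta = np.clip(risk_score(beta, covariates), -500, 500)
    H0 = base.cumhaz(times)[None, :]
    return np.exp(-H0 * np.exp(eta)[:, None])


def _censoring_km(train: SurvivalDataset) -> KMCurve:
    """KM of the censoring distribution G (status flipped)."""
    flipped = 1 - train.status
    kmf = KaplanMeierFitter()
    kmf.fit(train.time, event_observed=flipped)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    if len(ev) == 0:
        return KMCurve(np.empty(0), np.empty(0),
                       np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
    grid = ev.index.to_numpy(dtype=np.float64)
    surv = kmf.survival_function_.loc[ev.index, kmf._label].to_numpy(dtype=np.float64)
    return KMCurve(grid, surv, ev["at_risk"].to_numpy(dtype=np.int64),
                   ev["observed"].to_numpy(dtype=np.int64))


def brier_curve(train: SurvivalDataset, test: SurvivalDataset, times,
                beta=None, surv_matrix=None) -> np.ndarray:
    """IPCW Brier score BS(t) at each requested time (Graf weights).

    BS(t) = (1/n) sum_i [ 1{t_i<=t, d_i=1} (0 - S(t|x_i))^2 / G(t_i-)
                        + 1{t_i> t}        (1 - S(t|x_i))^2 / G(t) ].

    Predictions come from the Breslow/Cox model (``beta``) unless an explicit
    n_test x len(times) ``surv_matrix`` is supplied.
    """
    times = np.atleast_1d(np.asarray(times, dtype=np.float64))
    if surv_matrix is None:
        if beta is None:
            raise ValueError("provide beta or surv_matrix")
        surv_matrix = predict_survival(train, beta, test.covariates, times)
    surv_matrix = np.asarray(surv_matrix, dtype=np.float64)
    G = _censoring_km(train)
    G_at_t = G.at(times)
    G_at_ti_minus = G.at(test.time, left=True)
    t_i = test.time[:, None]
    d_i = (test.status == 1)[:, None]
    event_before = (t_i <= times[None, :]) & d_i
    still_atrisk = t_i > times[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        w_event = np.where(event_before, 1.0 / G_at_ti_minus[:, None], 0.0)
        w_risk = np.where(still_atrisk, 1.0 / G_at_t[None, :], 0.0)
    w_event = np.nan_to_num(w_event, nan=0.0, posinf=0.0)
    w_risk = np.nan_to_num(w_risk, nan=0.0, posinf=0.0)
    sq = w_event * surv_matrix ** 2 + w_risk * (1.0 - surv_matrix) ** 2
    return sq.mean(axis=0)


def integrated_brier_score(train: SurvivalDataset, test: SurvivalDataset,
                           beta=None, t_max: float | None = None,
                           surv_matrix_fn=None) -> float:
    """IBS = (1/t_max) * integral_0^t_max BS(t) dt (trapezoid on event grid).

    The grid is {0} + distinct test event times <= t_max + {t_max}.  If the
    censoring KM G vanishes before t_max, t_max is truncated to the last
    usable time with a warning.  ``surv_matrix_fn(times)`` may override the
    Cox predictions (used for oracle / constant predictors in validation).
    """
    if t_max is None:
        t_max = float(np.quantile(test.time, 0.95))
    if t_max > float(test.time.max()):
        raise ValueError("t_max exceeds the largest test follow-up time")
    G = _censoring_km(train)
    if G.grid_times.size:
        zero = G.survival <= 0
        if np.any(zero):
            limit = float(G.grid_times[zero][0])
            if t_max >= limit:
                new_t = float(np.nextafter(limit, 0.0))
                warnings.warn(
                    f"censoring survival reaches 0 at t={limit:g}; "
                    f"truncating t_max from {t_max:g} to {new_t:g}")
                t_max = new_t
    ev_times = np.unique(test.time[(test.status == 1) & (test.time <= t_max)])
    grid = np.unique(np.concatenate(([0.0], ev_times, [t_max])))
    if surv_matrix_fn is not None:
        surv = surv_matrix_fn(grid)
        bs = brier_curve(train, test, grid, surv_matrix=surv)
    else:
        bs = brier_curve(train, test, grid, beta=beta)
    return float(np.trapezoid(bs, grid) / t_max)


def selection_metrics(beta_hat, beta_true) -> SelectionMetrics:
    """Var / Corr / Incorr counts; 'nonzero' means bit-exactly != 0.0."""
    beta_hat = np.asarray(beta_hat, dtype=np.float64)
    beta_true = np.asarray(beta_true, dtype=np.float64)
    if beta_hat.shape != beta_true.shape:
        raise ValueError("beta_hat and beta_true must have the same length")
    hat_zero = beta_hat == 0.0
    true_zero = beta_true == 0.0
    return SelectionMetrics(
        var_count=int(np.sum(~hat_zero)),
        corr_zeros=int(np.sum(true_zero & hat_zero)),
        incorr_zeros=int(np.sum(~true_zero & hat_zero)),
    )
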