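"""Cox partial likelihood, its derivatives, and the Newton linearization.

The Cox proportional-hazards model specifies a hazard
``h(t | x) = h0(t) * exp(beta' x)`` with an unspecified baseline ``h0``.
Inference for ``beta`` uses the partial log-likelihood

    l(beta) = sum_{i: event} [ eta_i - log sum_{j in R_i} exp(eta_j) ],

where ``eta = X beta`` and ``R_i = {j : t_j >= t_i}`` is the risk set at the
i-th event time (Breslow convention for ties: each tied event contributes a
full risk-set term, and subjects censored at an event time are still at risk
at that time).

Penalized estimation proceeds by iteratively linearizing ``-l`` at the
current iterate: the second-order expansion is a least-squares problem whose
normal equations are ``H = hessian(-l)`` and ``b = H beta - grad(-l)``.  We
keep the surrogate in a factored form that never materializes the p x p
Hessian, because

    H = X' diag(d) X - U' U,

with ``d`` a per-subject weight and ``U`` one row per event (the risk-set
mean of the weighted covariates).  The factored form costs O(n p) memory and
supports O(n + n_events) per-coordinate updates, which is what makes the
shooting solvers usable when p is in the thousands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: linear predictors are clipped at +/- this value before exponentiation
LINEAR_PREDICTOR_CLIP = 500.0


@dataclass
class SurvivalDataset:
    """Right-censored survival data: (time, status, covariates) triples.

    Parameters
    ----------
    time : array of positive follow-up times, one per subject.
    status : array of event indicators; 1 = event observed, 0 = censored.
    covariates : n x p design matrix, no missing values.
    feature_names : optional length-p identifiers.
    """

    time: np.ndarray
    status: np.ndarray
    covariates: np.ndarray
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=np.float64)
        self.status = np.asarray(self.status)
        cov = np.asarray(self.covariates, dtype=np.float64)
        if cov.ndim == 1:
            cov = cov[:, None]
        self.covariates = cov
        if self.time.ndim != 1:
            raise ValueError("time must be one-dimensional")
        n = self.time.shape[0]
        if n < 2:
            raise ValueError("need at least 2 subjects")
        if self.status.shape != (n,) or self.covariates.shape[0] != n:
            raise ValueError("time, status and covariates must have matching length")
        if np.any(self.time <= 0) or not np.all(np.isfinite(self.time)):
            raise ValueError("all follow-up times must be positive and finite")
        if not np.all(np.isin(self.status, (0, 1))):
            raise ValueError("status must be 0 (censored) or 1 (event)")
        self.status = self.status.astype(np.int8)
        if not np.all(np.isfinite(self.covariates)):
            raise ValueError("covariate matrix contains missing/non-finite values")
        if self.feature_names is not None:
            self.feature_names = [str(f) for f in self.feature_names]
            if len(self.feature_names) != self.covariates.shape[1]:
                raise ValueError("feature_names length must equal p")

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    def subset(self, idx) -> "SurvivalDataset":
        """Row subset (e.g. a cross-validation fold)."""
        idx = np.asarray(idx)
        return SurvivalDataset(
            self.time[idx], self.status[idx], self.covariates[idx], self.feature_names
        )

    def to_frame(self) -> pd.DataFrame:
        names = self.feature_names or [f"x{j + 1}" for j in range(self.p)]
        df = pd.DataFrame(self.covariates, columns=names)
        df.insert(0, "status", self.status.astype(int))
        df.insert(0, "time", self.time)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurvivalDataset":
        cols = [c for c in df.columns if c not in ("time", "status")]
        return cls(
            df["time"].to_numpy(),
            df["status"].to_numpy(),
            df[cols].to_numpy(dtype=np.float64),
            feature_names=list(cols),
        )


@dataclass
class CoxState:
    """beta together with l(beta), grad(-l) and hessian(-l)."""

    beta: np.ndarray
    loglik: float
    grad: np.ndarray
    hessian: np.ndarray


@dataclass
class QuadraticSurrogate:
    """Least-squares linearization of -l at ``expansion_beta``.

    Represents RSS(beta) = beta' H beta - 2 b' beta + const with
    H = X' diag(d) X - U' U held in factored form.
    """

    X: np.ndarray
    d: np.ndarray
    U: np.ndarray
    b: np.ndarray
    const: float
    expansion_beta: np.ndarray

    @classmethod
    def from_normal_equations(
        cls, H: np.ndarray, b: np.ndarray, const: float = 0.0,
        expansion_beta: np.ndarray | None = None,
    ) -> "QuadraticSurrogate":
        """Build a surrogate from an explicit PSD matrix (mainly for tests).

        Factorizes H = F'F by symmetric eigendecomposition so the factored
        representation (X=F, d=1, U empty) reproduces H exactly.
        """
        H = np.asarray(H, dtype=np.float64)
        b = np.asarray(b, dtype=np.float64)
        p = H.shape[0]
        vals, vecs = np.linalg.eigh(H)
        vals = np.clip(vals, 0.0, None)
        F = np.sqrt(vals)[:, None] * vecs.T
        if expansion_beta is None:
            expansion_beta = np.zeros(p)
        return cls(F, np.ones(p), np.zeros((0, p)), b, float(const), expansion_beta)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def H(self) -> np.ndarray:
        """Materialized p x p Hessian. O(n p^2); avoid for very large p."""
        H = self.X.T @ (self.d[:, None] * self.X)
        if self.U.shape[0]:
            H -= self.U.T @ self.U
        return H

    @property
    def diag(self) -> np.ndarray:
        """H_jj = x_j' x_j of the pseudo-design, per coordinate."""
        h = np.einsum("ij,ij->j", self.X, self.d[:, None] * self.X)
        if self.U.shape[0]:
            h = h - np.einsum("ij,ij->j", self.U, self.U)
        return h

    def matvec(self, beta: np.ndarray) -> np.ndarray:
        """H @ beta without materializing H."""
        out = self.X.T @ (self.d * (self.X @ beta))
        if self.U.shape[0]:
            out -= self.U.T @ (self.U @ beta)
        return out

    def rss(self, beta: np.ndarray) -> float:
        """RSS(beta) = beta'H beta - 2 b'beta + const."""
        return float(beta @ self.matvec(beta) - 2.0 * self.b @ beta + self.const)


def _check_beta(beta: np.ndarray, p: int) -> np.ndarray:
    beta = np.asarray(beta, dtype=np.float64).ravel()
    if beta.shape[0] != p:
        raise ValueError(f"beta has length {beta.shape[0]}, expected {p}")
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta contains NaN/inf")
    return beta


def risk_sets(time, status) -> list[np.ndarray]:
    """Risk set R_i = {j : t_j >= t_i} for each event, in ascending event time.

    Returns 0-based original subject indices; raises if there is no event.
    """
    time = np.asarray(time, dtype=np.float64)
    status = np.asarray(status)
    if time.shape != status.shape:
        raise ValueError("time and status must have the same length")
    if np.any(time <= 0):
        raise ValueError("all times must be positive")
    if not np.any(status == 1):
        raise ValueError("no events")
    event_times = time[status == 1]
    out = []
    for t in np.sort(event_times):
        out.append(np.flatnonzero(time >= t))
    return out


def _risk_quantities(time, status, X, beta):
    """Shared machinery: sorted risk-set sums for l, grad and the factors.

    Returns (loglik, grad(-l), d_in_original_order, U) where
    hessian(-l) = X' diag(d) X - U'U and U has one row per event
    (risk-set weighted covariate mean).
    """
    n, p = X.shape
    order = np.argsort(time, kind="stable")
    t_s = time[order]
    st_s = np.asarray(status)[order]
    X_s = X[order]
    eta = np.clip(X_s @ beta, -LINEAR_PREDICTOR_CLIP, LINEAR_PREDICTOR_CLIP)
    m = eta.max()
    # floor at -700 keeps every risk-set sum strictly positive in floats;
    # relative weights below e^-700 are negligible in every derivative
    w = np.exp(np.maximum(eta - m, -700.0))

    # suffix sums over positions; risk set of an event at time t starts at the
    # first position of its tie group (t_j >= t includes ties)
    W_suffix = np.cumsum(w[::-1])[::-1]
    S_suffix = np.cumsum((w[:, None] * X_s)[::-1], axis=0)[::-1]
    group_start = np.searchsorted(t_s, t_s, side="left")
    group_end = np.searchsorted(t_s, t_s, side="right")

    ev = np.flatnonzero(st_s == 1)
    if ev.size == 0:
        loglik = 0.0
        grad = np.zeros(p)
        d = np.zeros(n)
        U = np.zeros((0, p))
        return loglik, grad, d, U

    W_ev = W_suffix[group_start[ev]]                       # scaled by e^{-m}
    logW = m + np.log(W_ev)
    loglik = float(np.sum(eta[ev] - logW))

    # d_j = w_j * sum over events with t_i <= t_j of 1/W_i (common scale cancels)
    inv_w_at = np.zeros(n)
    inv_w_at[ev] = 1.0 / W_ev
    prefix = np.cumsum(inv_w_at)
    d_s = w * prefix[group_end - 1]

    U = S_suffix[group_start[ev]] / W_ev[:, None]          # risk-set means

    # grad(-l) = sum_events (s_i / W_i - x_i) = X_s' d_s - sum_events x_i
    grad = X_s.T @ d_s - X_s[ev].sum(axis=0)

    d = np.empty(n)
    d[order] = d_s
    return loglik, grad, d, U


def partial_loglik(data: SurvivalDataset, beta) -> float:
    """Breslow partial log-likelihood l(beta); 0 if there are no events."""
    beta = _check_beta(beta, data.p)
    loglik, _, _, _ = _risk_quantities(data.time, data.status, data.covariates, beta)
    return loglik


def gradient_hessian(data: SurvivalDataset, beta) -> CoxState:
    """l(beta), grad(-l) and the materialized hessian(-l).

    The Hessian is a sum over events of within-risk-set covariance matrices
    of the covariates, hence symmetric PSD. O(p^2) memory: for very large p
    use :func:`linearize`, which keeps the factored form.
    """
    beta = _check_beta(beta, data.p)
    loglik, grad, d, U = _risk_quantities(data.time, data.status, data.covariates, beta)
    X = data.covariates
    H = X.T @ (d[:, None] * X)
    if U.shape[0]:
        H -= U.T @ U
    H = 0.5 * (H + H.T)
    return CoxState(beta=beta, loglik=loglik, grad=grad, hessian=H)


def linearize(data: SurvivalDataset, beta) -> QuadraticSurrogate:
    """Quadratic surrogate of 2*(-l) at beta, in normal-equation form.

    H = hessian(-l)(beta), b = H beta - grad(-l)(beta).  The constant is
    chosen so that RSS(beta) equals twice the quadratic model of -l, i.e.
    RSS(expansion_beta) = -2 l(expansion_beta).
    """
    beta = _check_beta(beta, data.p)
    loglik, grad, d, U = _risk_quantities(data.time, data.status, data.covariates, beta)
    sur = QuadraticSurrogate(
        X=data.covariates, d=d, U=U, b=np.zeros(data.p), const=0.0,
        expansion_beta=beta.copy(),
    )
    Hbeta = sur.matvec(beta)
    sur.b = Hbeta - grad
    sur.const = float(-2.0 * loglik + 2.0 * sur.b @ beta - beta @ Hbeta)
    return sur
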