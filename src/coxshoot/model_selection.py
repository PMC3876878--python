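"""Tuning-parameter selection by cross-validated partial likelihood (CVPL).

CVPL(lam) = sum_k [ l_full(beta_hat^(-k)) - l_train(-k)(beta_hat^(-k)) ],
the Verweij & van Houwelingen cross-validated log-likelihood: the fold-k
contribution is the extra partial log-likelihood the held-out subjects add
when the coefficients are estimated without them.  Higher is better; the
selected lambda is the argmax over a log-spaced grid, ties broken toward the
larger (sparser) lambda.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .survival_core import SurvivalDataset, linearize, partial_loglik
from .penalized_solvers import SolverConfig, fit


@dataclass
class CVResult:
    lam_grid: np.ndarray
    cvpl_values: np.ndarray
    lam_best: float
    fold_assignment: np.ndarray
    seed: int


def lambda_grid(data: SurvivalDataset, n_lambda: int = 50,
                ratio: float = 0.01) -> np.ndarray:
    """Log-spaced grid from lambda_max down to ratio*lambda_max.

    lambda_max is the smallest unit-weight L1 penalty that zeroes every
    coordinate in one shooting pass from beta=0 on the first surrogate:
    max_j |S0_j| with S0_j = dRSS/dbeta_j at beta=0, i.e. 2*grad_j(-l)(0).
    """
    if n_lambda < 2:
        raise ValueError("n_lambda must be >= 2")
    if not (0 < ratio < 1):
        raise ValueError("ratio must be in (0, 1)")
    sur = linearize(data, np.zeros(data.p))
    lam_max = float(np.max(np.abs(2.0 * sur.b)))
    if lam_max <= 0:
        raise ValueError("degenerate data: zero gradient at beta=0")
    return np.geomspace(lam_max, ratio * lam_max, n_lambda)


def _stratified_folds(status: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """Fold labels 0..K-1, events and censored subjects spread proportionally."""
    n = status.shape[0]
    folds = np.empty(n, dtype=np.int64)
    for value in (1, 0):
        idx = np.flatnonzero(status == value)
        idx = rng.permutation(idx)
        folds[idx] = np.arange(idx.size) % K
    return folds


def make_folds(data: SurvivalDataset, K: int, seed: int,
               max_retries: int = 10) -> np.ndarray:
    """Seeded event-stratified fold assignment; every training part has an event."""
    if K < 2:
        raise ValueError("K must be >= 2")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        folds = _stratified_folds(data.status, K, rng)
        ok = all(data.status[folds != k].sum() >= 1 for k in range(K))
        if ok:
            return folds
    raise ValueError("could not build folds with events in every training part")


def _cvpl_from_folds(data: SurvivalDataset, method: str, lam: float,
                     folds: np.ndarray, config: SolverConfig,
                     beta_inits: dict | None = None) -> float:
    total = 0.0
    K = int(folds.max()) + 1
    for k in range(K):
        train = data.subset(folds != k)
        init = beta_inits.get(k) if beta_inits is not None else None
        res = fit(train, method, lam, config, beta_init=init)
        if beta_inits is not None:
            beta_inits[k] = res.beta
        total += partial_loglik(data, res.beta) - partial_loglik(train, res.beta)
    return total


def cvpl(data: SurvivalDataset, method: str, lam: float, K: int = 5,
         seed: int = 0, config: SolverConfig | None = None) -> float:
    """CVPL at a single lambda with freshly drawn seeded folds."""
    folds = make_folds(data, K, seed)
    return _cvpl_from_folds(data, method, lam, folds, config or SolverConfig())


def select_lambda(data: SurvivalDataset, method: str, K: int = 5, seed: int = 0,
                  n_lambda: int = 50, ratio: float = 0.01,
                  config: SolverConfig | None = None) -> CVResult:
    """Evaluate CVPL over the lambda grid and pick the argmax.

    Lasso fold fits are warm-started down the grid (largest lambda first):
    the lasso problem is convex, so the warm start only saves time.  The
    adaptive methods always restart from the prescribed all-ones initial
    value — their zero vector is a fixed point of the reweighting (weights
    1/eps), so a warm start from an all-zero solution at a larger lambda
    would poison the rest of the path.  Ties in the argmax go to the larger
    lambda.
    """
    config = config or SolverConfig()
    grid = lambda_grid(data, n_lambda=n_lambda, ratio=ratio)
    folds = make_folds(data, K, seed)
    beta_inits: dict | None = {} if method == "lasso" else None
    values = np.empty(grid.shape[0])
    for i, lam in enumerate(grid):
        values[i] = _cvpl_from_folds(data, method, float(lam), folds, config,
                                     beta_inits=beta_inits)
    best = int(np.argmax(values))  # grid descends, so first max = largest lam
    return CVResult(lam_grid=grid, cvpl_values=values,
                    lam_best=float(grid[best]), fold_assignment=folds,
                    seed=int(seed))
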