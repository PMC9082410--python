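"""Penalized covariate selection: coordinate-descent Lasso, cross-validated
penalty choice, and post-double-selection OLS for the exposure effect.

The Lasso objective is ``(1/2n) ||y - b0 - X beta||^2 + lambda sum_j pf_j
|beta_j|`` with an unpenalized intercept and columns standardized
internally; the 1/2n scaling makes lambda comparable across sample sizes
(note: published lambda values without a stated scaling convention are not
comparable to ours).  The solver is cyclic coordinate descent with
soft-thresholding on the Gram matrix, warm-started along a decreasing
log-spaced penalty grid.

Post-double selection guards the exposure coefficient against moderate
selection mistakes: controls are Lasso-selected once for the outcome and
once for the exposure, and the final OLS regresses the outcome on the
exposure plus the union, with sandwich standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm
from numba import njit

from .errors import DataError, NumericalError

CD_TOL = 1e-8
CD_MAX_SWEEPS = 100_000


# ---------------------------------------------------------------------------
# coordinate-descent kernel


@njit(cache=False)
def _sweep(G, b, lam, penalty, beta, idx):
    """One cyclic pass over the coordinates in idx; returns max |change|."""
    maxdelta = 0.0
    for k in range(idx.shape[0]):
        j = idx[k]
        gjj = G[j, j]
        if gjj <= 0.0:
            continue
        zj = b[j] - np.dot(G[j], beta) + gjj * beta[j]
        thr = lam * penalty[j]
        if zj > thr:
            nb = (zj - thr) / gjj
        elif zj < -thr:
            nb = (zj + thr) / gjj
        else:
            nb = 0.0
        d = nb - beta[j]
        if d != 0.0:
            beta[j] = nb
            if abs(d) > maxdelta:
                maxdelta = abs(d)
    return maxdelta


@njit(cache=False)
def _cd_path(G, b, lambdas, penalty, beta0, tol, max_sweeps):
    """Cyclic coordinate descent over a decreasing lambda path.

    G = X'X/n of centered+scaled columns, b = X'y/n with y centered.
    Soft-threshold updates with warm starts along the path and the usual
    active-set strategy: iterate on the nonzero set to convergence, then
    confirm with a full sweep.  Returns (path, sweeps, last_delta).
    """
    p = b.shape[0]
    L = lambdas.shape[0]
    path = np.zeros((L, p))
    sweeps = np.zeros(L, dtype=np.int64)
    deltas = np.zeros(L)
    beta = beta0.copy()
    all_idx = np.arange(p)
    for li in range(L):
        lam = lambdas[li]
        it = 0
        maxdelta = _sweep(G, b, lam, penalty, beta, all_idx)
        it += 1
        while it < max_sweeps:
            if maxdelta < tol:
                break
            active = np.flatnonzero(beta)
            if active.shape[0] == 0:
                maxdelta = _sweep(G, b, lam, penalty, beta, all_idx)
                it += 1
                continue
            while it < max_sweeps:
                d_act = _sweep(G, b, lam, penalty, beta, active)
                it += 1
                if d_act < tol:
                    break
            maxdelta = _sweep(G, b, lam, penalty, beta, all_idx)
            it += 1
        path[li] = beta
        sweeps[li] = it
        deltas[li] = maxdelta
    return path, sweeps, deltas


def _soft(z, t):
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


def _cd_path_python(G, b, lambdas, penalty, beta0, tol, max_sweeps,
                    X=None, y=None):
    """Pure-python mirror of the kernel that records the objective after
    every sweep (diagnostics / property tests only)."""
    p = b.shape[0]
    beta = beta0.copy()
    path = np.zeros((len(lambdas), p))
    histories = []
    n = len(y) if y is not None else None
    for li, lam in enumerate(lambdas):
        hist = []
        for _ in range(max_sweeps):
            maxdelta = 0.0
            for j in range(p):
                gjj = G[j, j]
                if gjj <= 0:
                    continue
                zj = b[j] - G[j] @ beta + gjj * beta[j]
                nb = _soft(zj, lam * penalty[j]) / gjj
                d = nb - beta[j]
                if d != 0.0:
                    beta[j] = nb
                    maxdelta = max(maxdelta, abs(d))
            if X is not None:
                r = y - X @ beta
                hist.append(0.5 * np.mean(r**2)
                            + lam * np.sum(penalty * np.abs(beta)))
            if maxdelta < tol:
                break
        path[li] = beta
        histories.append(np.asarray(hist))
    return path, histories


# ---------------------------------------------------------------------------
# containers


@dataclass
class DesignMatrix:
    """Outcome, designated exposure and named controls for one fit.

    ``penalty_free`` columns (e.g. fixed-effect blocks the analyst always
    keeps) are never dropped by selection and enter OLS stages unpenalized.
    """

    outcome: np.ndarray
    X: pd.DataFrame  # exposure + controls, numeric
    exposure: str | None = None
    penalty_free: tuple[str, ...] = ()
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.outcome = np.asarray(self.outcome, dtype=float)
        if not isinstance(self.X, pd.DataFrame):
            self.X = pd.DataFrame(self.X)
        if len(self.X) != self.outcome.size:
            raise DataError("outcome and design have different lengths")
        if self.X.isna().to_numpy().any() or not np.all(np.isfinite(self.outcome)):
            raise DataError("design contains missing/non-finite values")
        if self.exposure is not None and self.exposure not in self.X.columns:
            raise DataError(f"exposure column {self.exposure!r} not in design")

    @property
    def controls(self) -> list[str]:
        return [c for c in self.X.columns if c != self.exposure]


@dataclass
class OLSResult:
    params: pd.Series
    se: pd.Series  # heteroskedasticity-robust (HC1)
    adj_r2: float
    r2: float
    n: int
    resid: np.ndarray = field(repr=False, default=None)


@dataclass
class LassoFit:
    lambda_grid: np.ndarray
    coef_path: pd.DataFrame  # standardized scale, (n_lambda, p)
    cv_mean_error: np.ndarray
    cv_se: np.ndarray
    selected_lambda: float
    n_folds: int
    fold_seed: int
    active_set: tuple[str, ...]
    coefficients: pd.Series  # original scale, at selected lambda
    intercept: float


@dataclass
class PostDoubleResult:
    exposure_coefficient: float
    standard_error: float
    selected_controls: tuple[str, ...]
    ols_coefficients: pd.Series
    ols_se: pd.Series
    n_used: int
    step1: LassoFit | None = None
    step2: LassoFit | None = None


# ---------------------------------------------------------------------------
# OLS


def ols_fit(y, X: pd.DataFrame, weights=None, add_const: bool = True) -> OLSResult:
    """OLS (or WLS) with HC1 sandwich standard errors and adjusted R^2.

    Raises a collinearity error listing the dependent columns when the
    design is rank deficient.
    """
    y = np.asarray(y, dtype=float)
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X))
    Xd = X.astype(float)
    if add_const:
        Xd = sm.add_constant(Xd, has_constant="add")
    arr = Xd.to_numpy()
    n, p = arr.shape
    if n <= p:
        raise DataError(f"ols_fit needs n > p (n={n}, p={p})")
    _, R_, piv = scipy.linalg.qr(arr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R_))
    tol = diag.max() * max(n, p) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < p:
        dep = [Xd.columns[i] for i in piv[rank:]]
        raise DataError(f"rank-deficient design; dependent columns: {dep}")
    model = sm.WLS(y, Xd, weights=weights) if weights is not None else sm.OLS(y, Xd)
    res = model.fit(cov_type="HC1")
    return OLSResult(params=res.params, se=res.bse, adj_r2=float(res.rsquared_adj),
                     r2=float(res.rsquared), n=n,
                     resid=np.asarray(y - res.fittedvalues))


# ---------------------------------------------------------------------------
# lasso


def _standardize(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population sd; zero-sd columns flagged by caller
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd_safe, mean, sd, sd_safe


def _prep(design: DesignMatrix):
    X = design.X.to_numpy(dtype=float)
    y = design.outcome
    if np.any(X.std(axis=0) == 0):
        j = int(np.flatnonzero(X.std(axis=0) == 0)[0])
        raise DataError(f"control {design.X.columns[j]!r} has zero variance")
    Xs, mean, sd, sd_safe = _standardize(X)
    ybar = y.mean()
    yc = y - ybar
    penalty = np.array([0.0 if c in design.penalty_free else 1.0
                        for c in design.X.columns])
    return Xs, yc, ybar, mean, sd_safe, penalty


def lasso_fit(design: DesignMatrix, lam: float, tol: float = CD_TOL,
              max_sweeps: int = CD_MAX_SWEEPS) -> tuple[pd.Series, float, pd.Series]:
    """Solve the Lasso at a single penalty.

    Returns ``(coefficients on the original scale, intercept,
    standardized-scale coefficients)``.  Raises on non-convergence,
    reporting the last maximum coefficient change.
    """
    if lam < 0:
        raise DataError("lambda must be non-negative")
    Xs, yc, ybar, mean, sd_safe, penalty = _prep(design)
    n = len(yc)
    G = Xs.T @ Xs / n
    b = Xs.T @ yc / n
    lams = np.array([float(lam)])
    path, sweeps, deltas = _cd_path(G, b, lams, penalty,
                                    np.zeros(len(b)), tol, max_sweeps)
    if sweeps[0] >= max_sweeps and deltas[0] >= tol:
        raise NumericalError(
            f"lasso_fit did not converge: last max coefficient change "
            f"{deltas[0]:.3e} after {max_sweeps} sweeps")
    beta_std = path[0]
    beta = beta_std / sd_safe
    intercept = ybar - float(mean @ beta)
    cols = design.X.columns
    return (pd.Series(beta, index=cols), intercept,
            pd.Series(beta_std, index=cols))


def lambda_max(design: DesignMatrix) -> float:
    """Smallest penalty at which every penalized coefficient is zero."""
    Xs, yc, _, _, _, penalty = _prep(design)
    n = len(yc)
    b = np.abs(Xs.T @ yc / n)
    pen = penalty > 0
    if not pen.any():
        raise DataError("no penalized columns")
    return float(np.max(b[pen] / penalty[pen]))


def cv_select_lambda(design: DesignMatrix, n_folds: int = 10,
                     grid_size: int = 50, fold_seed: int = 0,
                     rule: str = "min", tol: float = CD_TOL,
                     max_sweeps: int = CD_MAX_SWEEPS) -> LassoFit:
    """K-fold cross-validated penalty selection over a log-spaced grid.

    The grid runs from lambda_max down to lambda_max * 1e-4.  Folds are a
    seeded random partition.  ``rule="min"`` picks the out-of-fold-MSE
    minimizer (ties broken toward the larger, sparser penalty);
    ``rule="1se"`` picks the largest penalty within one SE of the minimum.
    """
    Xs, yc, ybar, mean, sd_safe, penalty = _prep(design)
    n, p = Xs.shape
    if n < n_folds:
        raise DataError(f"n={n} smaller than n_folds={n_folds}")
    lmax = lambda_max(design)
    grid = np.geomspace(lmax, lmax * 1e-4, grid_size)

    rng = np.random.default_rng(fold_seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)
    if min(len(f) for f in folds) < 2:
        raise DataError("cross-validation fold with fewer than 2 rows")

    S_full = Xs.T @ Xs
    t_full = Xs.T @ yc
    fold_err = np.empty((n_folds, grid_size))
    for fi, fidx in enumerate(folds):
        Xf, yf = Xs[fidx], yc[fidx]
        ntr = n - len(fidx)
        m_tr = (Xs.sum(axis=0) - Xf.sum(axis=0)) / ntr
        ybar_tr = (yc.sum() - yf.sum()) / ntr
        G = (S_full - Xf.T @ Xf) / ntr - np.outer(m_tr, m_tr)
        b = (t_full - Xf.T @ yf) / ntr - m_tr * ybar_tr
        path, sweeps, deltas = _cd_path(G, b, grid, penalty,
                                        np.zeros(p), tol, max_sweeps)
        pred = ybar_tr + (Xf - m_tr) @ path.T  # (nf, L)
        fold_err[fi] = np.mean((yf[:, None] - pred) ** 2, axis=0)

    cv_mean = fold_err.mean(axis=0)
    cv_se = fold_err.std(axis=0, ddof=1) / np.sqrt(n_folds)
    i_min = int(np.argmin(cv_mean))  # first minimum = largest lambda on ties
    if rule == "min":
        i_sel = i_min
    elif rule == "1se":
        thresh = cv_mean[i_min] + cv_se[i_min]
        i_sel = int(np.flatnonzero(cv_mean <= thresh)[0])
    else:
        raise DataError(f"unknown CV rule {rule!r}")

    G = S_full / n
    b = t_full / n
    full_path, sweeps, deltas = _cd_path(G, b, grid, penalty,
                                         np.zeros(p), tol, max_sweeps)
    if sweeps[-1] >= max_sweeps and deltas[-1] >= tol:
        raise NumericalError(
            f"lasso path did not converge: last max change {deltas[-1]:.3e}")
    beta_std = full_path[i_sel]
    beta = beta_std / sd_safe
    intercept = ybar - float(mean @ beta)
    cols = design.X.columns
    active = tuple(cols[np.abs(beta_std) > 0])
    return LassoFit(
        lambda_grid=grid,
        coef_path=pd.DataFrame(full_path, index=grid, columns=cols),
        cv_mean_error=cv_mean, cv_se=cv_se,
        selected_lambda=float(grid[i_sel]), n_folds=n_folds,
        fold_seed=fold_seed, active_set=active,
        coefficients=pd.Series(beta, index=cols), intercept=intercept,
    )


def post_double_selection(design: DesignMatrix, n_folds: int = 10,
                          grid_size: int = 50, fold_seed: int = 0,
                          rule: str = "min") -> PostDoubleResult:
    """Exposure effect by post-double selection.

    Step 1 Lasso-selects controls for the outcome, step 2 for the
    exposure; the final OLS of outcome on exposure plus the union (and any
    penalty-free columns) carries an HC1 standard error on the exposure.
    """
    if design.exposure is None:
        raise DataError("post_double_selection requires a designated exposure")
    if len(design.X.columns) == 0 or design.outcome.size == 0:
        raise DataError("empty design")
    controls = design.controls
    penalized = [c for c in controls if c not in design.penalty_free]
    step1 = step2 = None
    union: list[str] = []
    if penalized:
        # selection steps penalize everything, including the fixed-effect
        # blocks; the blocks re-enter the final OLS unconditionally
        d1 = DesignMatrix(design.outcome, design.X[controls])
        step1 = cv_select_lambda(d1, n_folds, grid_size, fold_seed, rule)
        d2 = DesignMatrix(design.X[design.exposure].to_numpy(),
                          design.X[controls])
        step2 = cv_select_lambda(d2, n_folds, grid_size, fold_seed + 1, rule)
        sel = (set(step1.active_set) | set(step2.active_set)) - set(design.penalty_free)
        union = [c for c in controls if c in sel]
    final_cols = [design.exposure] + union + [c for c in controls
                                              if c in design.penalty_free]
    ols = ols_fit(design.outcome, design.X[final_cols])
    return PostDoubleResult(
        exposure_coefficient=float(ols.params[design.exposure]),
        standard_error=float(ols.se[design.exposure]),
        selected_controls=tuple(union),
        ols_coefficients=ols.params, ols_se=ols.se,
        n_used=design.outcome.size, step1=step1, step2=step2,
    )
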