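"""Concentration index, concentration curve, Wagstaff decomposition and
horizontal inequity.

The concentration index of an outcome ``y`` with respect to a socioeconomic
ranking variable is ``CI = 2 Cov_w(y, R) / mu``, where ``R`` is the weighted
fractional rank and ``mu`` the weighted mean outcome.  CI > 0 means the
outcome is concentrated among the better-off ("pro-rich"); the concentration
curve then lies below the diagonal.  This is the standard health-economics
convention and is used throughout (see docs/methods.md).

The Wagstaff decomposition writes CI of a linearly modelled outcome as
``CI = sum_k eta_k C_k + GC_eps/mu`` with elasticity ``eta_k = beta_k
x_bar_k / mu`` and ``C_k`` the concentration index of regressor k against
the same ranks.  Horizontal inequity is CI minus the contributions of
"need" factors (demographic/health variables regarded as legitimate
drivers of differences).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DataError
from .scores import quantile_group

logger = logging.getLogger(__name__)

DEFAULT_NEED_FACTORS = ("gender", "education_years", "health_status", "age_sq")


def _as_weights(w, n: int) -> np.ndarray:
    if w is None:
        return np.ones(n, dtype=float)
    w = np.asarray(w, dtype=float)
    if w.shape != (n,):
        raise DataError(f"weights shape {w.shape} does not match n={n}")
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise DataError("weights must be finite and strictly positive")
    return w


def _wmean(x: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * x) / np.sum(w))


def _wcov(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted population covariance (denominator sum of weights)."""
    W = np.sum(w)
    return float(np.sum(w * x * y) / W - (np.sum(w * x) / W) * (np.sum(w * y) / W))


def fractional_rank(ranking_variable, weights=None) -> np.ndarray:
    """Weighted fractional (midpoint) ranks in (0, 1).

    Sorting by the ranking variable, ``R_i = (cumweight before i + w_i/2)/W``;
    every member of a block of tied values receives the block midpoint rank.
    The weighted mean of R is exactly 0.5.
    """
    x = np.asarray(ranking_variable, dtype=float)
    n = x.size
    if n < 2:
        raise DataError("fractional_rank needs at least 2 observations")
    w = _as_weights(weights, n)
    order = np.argsort(x, kind="stable")
    xs, ws = x[order], w[order]
    W = ws.sum()
    cum = np.concatenate([[0.0], np.cumsum(ws)])
    R_sorted = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and xs[j + 1] == xs[i]:
            j += 1
        # midpoint of the tied block [i, j]
        R_sorted[i : j + 1] = (cum[i] + (cum[j + 1] - cum[i]) / 2.0) / W
        i = j + 1
    R = np.empty(n)
    R[order] = R_sorted
    return R


@dataclass(frozen=True)
class ConcentrationResult:
    ci: float
    se: float
    ci95: tuple[float, float]
    curve: np.ndarray  # (m, 2) points (pop share p, outcome share L(p))
    n_used: int
    ranking_name: str = "ranking"
    mean_outcome: float = float("nan")
    p_value: float = float("nan")


def concentration_curve(y, ranking_variable, weights=None) -> np.ndarray:
    """Concentration-curve points from (0, 0) to (1, 1).

    The population is ordered by the ranking variable; each point is the
    cumulative population share against the cumulative outcome share.
    """
    yv = np.asarray(y, dtype=float)
    x = np.asarray(ranking_variable, dtype=float)
    w = _as_weights(weights, yv.size)
    if np.any(yv < 0):
        logger.warning("concentration_curve: negative outcome values; "
                       "cumulative shares may be non-monotone")
    order = np.argsort(x, kind="stable")
    ws, ys = w[order], yv[order]
    p = np.concatenate([[0.0], np.cumsum(ws) / ws.sum()])
    tot = np.sum(ws * ys)
    if tot == 0:
        raise DataError("concentration_curve: total outcome mass is zero")
    L = np.concatenate([[0.0], np.cumsum(ws * ys) / tot])
    p[-1] = 1.0
    L[-1] = 1.0
    return np.column_stack([p, L])


def concentration_index(y, ranking_variable, weights=None,
                        ranking_name: str = "ranking",
                        correction: str | None = None,
                        bounds: tuple[float, float] = (0.0, 32.0)) -> ConcentrationResult:
    """Concentration index with a convenient-regression standard error.

    CI = 2 Cov_w(y, R) / mu.  The SE is the heteroskedasticity-robust SE of
    the slope in the auxiliary regression ``2 var_w(R) (y_i/mu) = a + b R_i``,
    whose WLS slope equals the CI exactly.

    ``correction`` optionally rescales for a bounded outcome:
    ``"erreygers"`` gives 4 mu CI/(b-a); ``"wagstaff"`` gives
    CI (b-a) mu / ((b-mu)(mu-a)).  Default is the plain CI.
    """
    yv = np.asarray(y, dtype=float)
    n = yv.size
    if n < 2:
        raise DataError("concentration_index needs at least 2 observations")
    w = _as_weights(weights, n)
    mu = _wmean(yv, w)
    if mu <= 0:
        raise DataError("concentration_index undefined for non-positive mean outcome")
    R = fractional_rank(ranking_variable, w)
    ci = 2.0 * _wcov(yv, R, w) / mu

    var_R = _wcov(R, R, w)
    lhs = 2.0 * var_R * yv / mu
    X = sm.add_constant(R)
    if var_R > 0:
        res = sm.WLS(lhs, X, weights=w).fit(cov_type="HC1")
        se = float(res.bse[1])
        pval = float(res.pvalues[1])
    else:  # all ranks tied: CI is 0 by construction
        se, pval = float("nan"), float("nan")

    curve = concentration_curve(yv, ranking_variable, w)

    if correction is not None:
        a, b = bounds
        if correction == "erreygers":
            scale = 4.0 * mu / (b - a)
        elif correction == "wagstaff":
            scale = (b - a) * mu / ((b - mu) * (mu - a))
        else:
            raise DataError(f"unknown CI correction {correction!r}")
        ci, se = ci * scale, se * scale

    return ConcentrationResult(
        ci=float(ci), se=se,
        ci95=(float(ci - 1.959963984540054 * se), float(ci + 1.959963984540054 * se)),
        curve=curve, n_used=n, ranking_name=ranking_name,
        mean_outcome=mu, p_value=pval,
    )


@dataclass(frozen=True)
class DecompositionResult:
    """Wagstaff decomposition of a concentration index.

    ``table`` has one row per factor: coefficient, weighted mean,
    elasticity, factor CI, absolute contribution and percent contribution,
    sorted by absolute percent contribution.  The adding-up identity
    ``sum(contributions) + residual == ci`` holds to float precision on
    every run (hard assertion).
    """

    table: pd.DataFrame
    ci: float
    mean_outcome: float
    residual: float
    residual_pct: float
    ranks: np.ndarray = field(repr=False, default=None)

    def grouped(self, groups: dict[str, str]) -> pd.DataFrame:
        """Aggregate rows whose factor maps to a common group label
        (e.g. one-hot fixed-effect blocks); elasticity/CI are summed
        contributions only."""
        tab = self.table.copy()
        tab["group"] = [groups.get(f, f) for f in tab["factor"]]
        agg = tab.groupby("group", sort=False).agg(
            contribution=("contribution", "sum"),
            pct_contribution=("pct_contribution", "sum"),
            elasticity=("elasticity", "sum"),
            n_factors=("factor", "size"),
        ).reset_index()
        return agg.reindex(agg["pct_contribution"].abs()
                           .sort_values(ascending=False).index).reset_index(drop=True)


def wagstaff_decomposition(y, ranking_variable, factors: pd.DataFrame,
                           weights=None) -> DecompositionResult:
    """Decompose the CI of ``y`` into factor contributions.

    A weighted OLS of y on all factors (plus intercept) gives beta_k; the
    contribution of factor k is ``eta_k C_k = 2 beta_k Cov_w(x_k, R)/mu``
    against the same fractional ranks R; the residual is the generalized
    concentration index of the OLS residuals over mu.
    """
    yv = np.asarray(y, dtype=float)
    n = yv.size
    w = _as_weights(weights, n)
    if not isinstance(factors, pd.DataFrame):
        factors = pd.DataFrame(factors)
    if factors.shape[0] != n:
        raise DataError("factors and outcome have different lengths")
    X = factors.to_numpy(dtype=float)
    names = list(factors.columns)
    if np.any(X.std(axis=0) == 0):
        k = names[int(np.flatnonzero(X.std(axis=0) == 0)[0])]
        raise DataError(f"factor {k!r} is constant (collinear with intercept)")
    mu = _wmean(yv, w)
    if mu <= 0:
        raise DataError("decomposition undefined for non-positive mean outcome")
    R = fractional_rank(ranking_variable, w)
    ci = 2.0 * _wcov(yv, R, w) / mu

    Xc = sm.add_constant(X, has_constant="add")
    model = sm.WLS(yv, Xc, weights=w)
    res = model.fit()
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise DataError("decomposition design is rank deficient (collinear factors)")
    beta = res.params[1:]

    rows = []
    contrib_sum = 0.0
    for k, name in enumerate(names):
        xk = X[:, k]
        xbar = _wmean(xk, w)
        cov_k = _wcov(xk, R, w)
        contribution = 2.0 * beta[k] * cov_k / mu
        eta = beta[k] * xbar / mu
        ck = 2.0 * cov_k / xbar if abs(xbar) > 1e-300 else float("nan")
        rows.append({
            "factor": name, "coef": float(beta[k]), "mean": xbar,
            "elasticity": float(eta), "factor_ci": float(ck),
            "contribution": float(contribution),
        })
        contrib_sum += contribution
    residual = ci - contrib_sum

    # independent consistency check: residual equals (2/mu) Cov_w(eps_hat, R)
    eps = yv - res.fittedvalues
    resid_check = 2.0 * _wcov(eps, R, w) / mu
    scale = max(1.0, abs(ci))
    assert abs(residual - resid_check) <= 1e-8 * scale, \
        "decomposition adding-up identity violated"

    tab = pd.DataFrame(rows)
    denom = ci if ci != 0 else np.nan
    tab["pct_contribution"] = tab["contribution"] / denom * 100.0
    residual_pct = residual / denom * 100.0
    tab = tab.reindex(tab["pct_contribution"].abs()
                      .sort_values(ascending=False).index).reset_index(drop=True)
    return DecompositionResult(table=tab, ci=float(ci), mean_outcome=mu,
                               residual=float(residual),
                               residual_pct=float(residual_pct), ranks=R)


@dataclass(frozen=True)
class HorizontalInequity:
    hi: float
    need_factors: tuple[str, ...]
    nonneed_factors: tuple[str, ...]
    need_contribution_total: float
    concentration: DecompositionResult


def horizontal_inequity(decomp: DecompositionResult,
                        need_factors=DEFAULT_NEED_FACTORS) -> HorizontalInequity:
    """HI = CI - sum of need-factor contributions.

    Inequality left after netting out rank-related variation attributable
    to legitimate need (demographics and health status).  HI > 0: pro-rich
    inequity beyond need.
    """
    need = tuple(need_factors)
    known = set(decomp.table["factor"])
    unknown = [f for f in need if f not in known]
    if unknown:
        raise DataError(f"unknown need factor(s): {unknown}")
    mask = decomp.table["factor"].isin(need)
    need_total = float(decomp.table.loc[mask, "contribution"].sum())
    return HorizontalInequity(
        hi=float(decomp.ci - need_total),
        need_factors=need,
        nonneed_factors=tuple(f for f in decomp.table["factor"] if f not in need),
        need_contribution_total=need_total,
        concentration=decomp,
    )


@dataclass(frozen=True)
class StratumResult:
    stratum: object
    n: int
    concentration: ConcentrationResult
    inequity: HorizontalInequity | None
    quartile_means: pd.DataFrame  # outcome mean +/- SD by ranking-variable quartile


def subgroup_inequality(df: pd.DataFrame, stratify_by: str, outcome: str,
                        ranking: str, factors: list[str],
                        need_factors=DEFAULT_NEED_FACTORS,
                        weight_col: str | None = None,
                        min_rows: int = 30) -> list[StratumResult]:
    """Independent CI/HI per stratum, ranks recomputed within stratum.

    Also reports the outcome mean and SD by within-stratum quartile of the
    ranking variable.  Strata below ``min_rows`` are skipped with a warning.
    """
    out = []
    for key, sub in df.groupby(stratify_by, sort=True):
        if len(sub) < min_rows:
            logger.warning("stratum %r skipped: %d rows < floor %d",
                           key, len(sub), min_rows)
            continue
        if sub[ranking].nunique() < 2:
            logger.warning("stratum %r skipped: ranking variable constant", key)
            continue
        w = sub[weight_col].to_numpy() if weight_col else None
        conc = concentration_index(sub[outcome], sub[ranking], w,
                                   ranking_name=ranking)
        hi = None
        usable = [f for f in factors if sub[f].nunique() > 1]
        if usable:
            try:
                decomp = wagstaff_decomposition(sub[outcome], sub[ranking],
                                                sub[usable], w)
                need = [f for f in need_factors if f in usable]
                hi = horizontal_inequity(decomp, need)
            except DataError as exc:  # e.g. collinear factors in a tiny stratum
                logger.warning("stratum %r: HI skipped (%s)", key, exc)
        try:
            q = quantile_group(sub[ranking].to_numpy(), 4)
            qm = (sub.assign(_q=q).groupby("_q")[outcome]
                  .agg(["mean", "std", "size"]).reset_index()
                  .rename(columns={"_q": "quartile", "size": "n"}))
        except DataError:  # fewer than 4 distinct ranking values
            qm = None
        out.append(StratumResult(stratum=key, n=len(sub), concentration=conc,
                                 inequity=hi, quartile_means=qm))
    if not out:
        raise DataError("no stratum met the minimum-size floor")
    return out


def bootstrap_inequality(df: pd.DataFrame, outcome: str, ranking: str,
                         factors: list[str], need_factors,
                         weight_col: str | None = None,
                         n_boot: int = 1000, seed: int = 0) -> dict:
    """Seeded nonparametric bootstrap of CI, HI and decomposition shares.

    Rows are resampled with replacement; every draw recomputes ranks, the
    decomposition OLS and the need subtraction.  Returns bootstrap SEs and
    percentile 95% intervals.
    """
    rng = np.random.default_rng(seed)
    n = len(df)
    cis, his = np.empty(n_boot), np.empty(n_boot)
    shares = {f: np.empty(n_boot) for f in factors}
    arr = df.reset_index(drop=True)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sub = arr.iloc[idx]
        w = sub[weight_col].to_numpy() if weight_col else None
        try:
            dec = wagstaff_decomposition(sub[outcome], sub[ranking],
                                         sub[factors], w)
            hi = horizontal_inequity(dec, need_factors)
        except DataError:  # degenerate resample (e.g. constant factor)
            cis[b], his[b] = np.nan, np.nan
            for f in factors:
                shares[f][b] = np.nan
            continue
        cis[b], his[b] = dec.ci, hi.hi
        row = dec.table.set_index("factor")["contribution"]
        for f in factors:
            shares[f][b] = row[f]

    def summ(x):
        x = x[np.isfinite(x)]
        return {"se": float(np.std(x, ddof=1)),
                "p2.5": float(np.percentile(x, 2.5)),
                "p97.5": float(np.percentile(x, 97.5))}

    return {"n_boot": n_boot, "seed": seed, "ci": summ(cis), "hi": summ(his),
            "contributions": {f: summ(v) for f, v in shares.items()}}
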