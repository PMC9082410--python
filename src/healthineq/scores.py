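"""Outcome and exposure construction.

The outcome is a health-education score: four interviewer items, each an
integer 0-8 (0 = "do not know"), summed to a 0-32 total; a log transform
``ln(1 + total)`` is carried alongside because zero totals occur.

The exposure is a household-consumption composite: the first principal
component of five consumption dimensions (each recorded on a reversed
five-point Likert scale mapped to [0, 1]), min-max standardized to [0, 1]
so a value near 1 means higher consumption.  Internal-consistency
reliability is summarized by Cronbach's alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError

N_ITEMS = 4
ITEM_MIN = 0
ITEM_MAX = 8
TOTAL_MAX = N_ITEMS * ITEM_MAX


@dataclass(frozen=True)
class HealthEducationScore:
    """Per-row item scores, 0-32 total and log(1 + total)."""

    item_scores: np.ndarray  # (n, 4) int
    total: np.ndarray  # (n,) int in [0, 32]
    log_total: np.ndarray  # (n,) float, ln(1 + total)


@dataclass(frozen=True)
class CompositeIndex:
    """First-principal-component consumption index with diagnostics.

    ``loadings`` has unit Euclidean norm and the largest-magnitude loading
    is positive; ``standardized_scores`` is the min-max rescaling of
    ``raw_scores`` onto [0, 1].
    """

    loadings: np.ndarray
    explained_variance_ratio: float
    cronbach_alpha: float
    raw_scores: np.ndarray
    standardized_scores: np.ndarray


def health_education_score(items) -> HealthEducationScore:
    """Validate item responses and build the 0-32 total plus its log.

    Parameters
    ----------
    items : array-like, shape (4,) or (n, 4)
        Integer item scores, each in {0, ..., 8}.
    """
    arr = np.asarray(items)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2 or arr.shape[1] != N_ITEMS:
        raise DataError(f"expected {N_ITEMS} item columns, got shape {arr.shape}")
    flt = arr.astype(float)
    bad = ~np.isfinite(flt) | (flt != np.floor(flt)) | (flt < ITEM_MIN) | (flt > ITEM_MAX)
    if bad.any():
        row = int(np.argwhere(bad.any(axis=1))[0, 0])
        raise DataError(
            f"item score outside integers [{ITEM_MIN}, {ITEM_MAX}] at row {row}: "
            f"{arr[row].tolist()}"
        )
    ints = flt.astype(np.int64)
    total = ints.sum(axis=1)
    return HealthEducationScore(ints, total, np.log1p(total))


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha: K/(K-1) * (1 - sum of item variances / total variance).

    Sample variances use denominator n-1.  Requires at least two items,
    two rows and a non-degenerate total score.
    """
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise DataError("cronbach_alpha needs a 2-D matrix with at least 2 items")
    if X.shape[0] < 2:
        raise DataError("cronbach_alpha needs at least 2 rows")
    if not np.all(np.isfinite(X)):
        raise DataError("cronbach_alpha: missing or non-finite values")
    k = X.shape[1]
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise DataError("cronbach_alpha undefined: total-score variance is zero")
    item_var = X.var(axis=0, ddof=1).sum()
    return k / (k - 1) * (1.0 - item_var / total_var)


def minmax_standardize(values) -> np.ndarray:
    """Rescale to [0, 1] via (v - min) / (max - min); order-preserving."""
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if not hi > lo:
        raise DataError("minmax_standardize: degenerate range (all values equal)")
    return (v - lo) / (hi - lo)


def pca_composite(item_matrix) -> CompositeIndex:
    """First-principal-component composite of the consumption dimensions.

    Columns are z-scored internally, so the eigendecomposition is of the
    correlation matrix; mixing measurement scales is therefore harmless.
    The composite score is the loading-weighted sum of z-scores, min-max
    standardized onto [0, 1].
    """
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, d = X.shape
    if n < d + 1:
        raise DataError(f"pca_composite needs at least D+1={d + 1} rows, got {n}")
    sd = X.std(axis=0, ddof=1)
    const = np.flatnonzero(sd <= 1e-12 * (1.0 + np.abs(X).max(axis=0)))
    if const.size:
        raise DataError(f"pca_composite: constant column at index {int(const[0])}")
    Z = (X - X.mean(axis=0)) / sd
    corr = (Z.T @ Z) / (n - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    loadings = eigvec[:, -1]
    if loadings[np.argmax(np.abs(loadings))] < 0:
        loadings = -loadings
    evr = float(eigval[-1] / d)
    raw = Z @ loadings
    if d == 1:
        # single dimension: composite is the column itself (z-scored)
        raw = Z[:, 0] * loadings[0]
    std = minmax_standardize(raw)
    alpha = cronbach_alpha(X) if d >= 2 else float("nan")
    return CompositeIndex(loadings, evr, alpha, raw, std)


def quantile_group(values, n_groups: int) -> np.ndarray:
    """Assign 1..n_groups labels by empirical quantile cut-points.

    Cut-points are linear-interpolation quantiles of the *distinct* values;
    observations equal to a cut-point go to the lower group (tie-to-lower),
    so group sizes can differ by the number of tied boundary values.
    """
    v = np.asarray(values, dtype=float)
    if n_groups < 2:
        raise DataError("quantile_group: n_groups must be >= 2")
    if v.size < n_groups:
        raise DataError("quantile_group: fewer rows than groups")
    distinct = np.unique(v)
    if distinct.size < n_groups:
        raise DataError(
            f"quantile_group infeasible: {distinct.size} distinct values "
            f"for {n_groups} groups"
        )
    cuts = np.quantile(distinct, np.arange(1, n_groups) / n_groups)
    return 1 + (v[:, None] > cuts[None, :]).sum(axis=1)
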