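"""Canonical correlation analysis with loadings, Wilks' lambda,
surrogate-based variate selection, and permutation p-values.

The solution is computed on column-standardized matrices via the
singular-value decomposition of the whitened cross-correlation matrix;
signs are canonicalized (the largest-magnitude musical loading of each
variate is made positive) so results are deterministic across
linear-algebra backends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from melophys.core import DataError

RIDGE_EPS = 1e-6


@dataclass
class CCAResult:
    x_columns: list
    y_columns: list
    n: int
    correlations: np.ndarray   # r_i, non-increasing, in [0, 1]
    x_weights: np.ndarray      # p x k
    y_weights: np.ndarray      # q x k
    x_scores: np.ndarray       # U = X~ u, n x k, unit variance
    y_scores: np.ndarray       # V = Y~ v
    x_loadings: np.ndarray     # corr(X col, U_i), p x k
    y_loadings: np.ndarray     # corr(Y col, V_i), q x k
    wilks_p: np.ndarray | None = None
    retained: np.ndarray | None = None
    permutation_p: np.ndarray | None = None
    flags: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.correlations)


def _standardize(m, label: str):
    """Column z-scores; zero-variance columns are dropped with a warning."""
    df = pd.DataFrame(m)
    vals = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise DataError(f"{label} contains non-finite values")
    sd = vals.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [str(c) for c, k in zip(df.columns, keep) if not k]
        warnings.warn(f"dropping zero-variance {label} columns: {dropped}", stacklevel=3)
    vals = vals[:, keep]
    z = (vals - vals.mean(axis=0)) / vals.std(axis=0, ddof=1)
    return z, [str(c) for c, k in zip(df.columns, keep) if k]


def _inv_sqrt(corr: np.ndarray, eps: float) -> np.ndarray:
    w, v = np.linalg.eigh(corr + eps * np.eye(len(corr)))
    w = np.maximum(w, 1e-12)
    return v @ np.diag(1.0 / np.sqrt(w)) @ v.T


def fit_cca(x, y, n_components: int | None = None) -> CCAResult:
    """Fit CCA on column-standardized X and Y.

    When n <= p + q the whitening is ridge-regularized (eps = 1e-6 on
    the correlation matrices) and the result is flagged; this keeps
    subject-wise fits on short playlists well-posed.
    """
    xz, x_cols = _standardize(x, "X")
    yz, y_cols = _standardize(y, "Y")
    n, p = xz.shape
    q = yz.shape[1]
    if n != len(yz):
        raise DataError("X and Y row counts differ")
    if n < 3:
        raise DataError("need at least 3 rows")
    ridge = n <= p + q
    if ridge:
        warnings.warn(
            f"n = {n} <= p + q = {p + q}: ridge-regularized whitening engaged", stacklevel=2
        )
    eps = RIDGE_EPS if ridge else 0.0
    rxx = xz.T @ xz / (n - 1)
    ryy = yz.T @ yz / (n - 1)
    rxy = xz.T @ yz / (n - 1)
    wx = _inv_sqrt(rxx, eps)
    wy = _inv_sqrt(ryy, eps)
    u_sv, s, vt_sv = np.linalg.svd(wx @ rxy @ wy)
    k = min(p, q) if n_components is None else min(n_components, p, q)
    corr = np.clip(s[:k], 0.0, 1.0)
    a = wx @ u_sv[:, :k]   # p x k
    b = wy @ vt_sv.T[:, :k]
    us = xz @ a
    vs = yz @ b
    # enforce unit-variance variates (ridge perturbs the normalization)
    for i in range(k):
        for scores, weights in ((us, a), (vs, b)):
            sd = scores[:, i].std(ddof=1)
            if sd > 0:
                scores[:, i] /= sd
                weights[:, i] /= sd

    xl = _corr_with(xz, us)
    yl = _corr_with(yz, vs)
    # sign canonicalization: largest-|loading| musical loading positive
    for i in range(k):
        j = int(np.argmax(np.abs(xl[:, i])))
        if xl[j, i] < 0:
            a[:, i] *= -1
            b[:, i] *= -1
            us[:, i] *= -1
            vs[:, i] *= -1
            xl[:, i] *= -1
            yl[:, i] *= -1

    result = CCAResult(
        x_columns=x_cols, y_columns=y_cols, n=n, correlations=corr,
        x_weights=a, y_weights=b, x_scores=us, y_scores=vs,
        x_loadings=xl, y_loadings=yl, flags={"ridge": ridge},
    )
    result.wilks_p = wilks_test(corr, n, p, q)
    return result


def _corr_with(z: np.ndarray, scores: np.ndarray) -> np.ndarray:
    zs = (scores - scores.mean(axis=0)) / scores.std(axis=0, ddof=1)
    return z.T @ zs / (len(z) - 1)


def loadings(result: CCAResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Canonical loadings (structural coefficients) as labelled tables."""
    cols = [f"variate_{i + 1}" for i in range(result.k)]
    return (
        pd.DataFrame(result.x_loadings, index=result.x_columns, columns=cols),
        pd.DataFrame(result.y_loadings, index=result.y_columns, columns=cols),
    )


def relative_covariance(result: CCAResult) -> np.ndarray:
    """Share of summed squared canonical correlation per variate, in %."""
    r2 = result.correlations**2
    total = r2.sum()
    if total == 0:
        return np.zeros_like(r2)
    return 100.0 * r2 / total


def wilks_test(correlations, n: int, p: int, q: int) -> np.ndarray:
    """Wilks' lambda sequence p-values via Bartlett's chi-square approximation.

    Lambda_k = prod_{i >= k} (1 - r_i^2);
    chi2 = -(n - 1 - (p + q + 1)/2) * ln Lambda_k with
    df = (p - k + 1)(q - k + 1), k = 1..len(r).
    """
    r = np.asarray(correlations, dtype=float)
    pvals = np.ones(len(r))
    factor = n - 1 - (p + q + 1) / 2.0
    for k in range(len(r)):
        lam = float(np.prod(1.0 - r[k:] ** 2))
        if lam <= 0:
            pvals[k] = 0.0
            continue
        chi2 = -factor * np.log(lam)
        df = (p - k) * (q - k)
        pvals[k] = stats.chi2.sf(max(chi2, 0.0), df) if df > 0 else 1.0
    return pvals


def _permuted_correlations(x, y, n_reps: int, seed: int, n_components=None):
    rng = np.random.default_rng(seed)
    y_arr = pd.DataFrame(y).to_numpy(dtype=float)
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_reps):
            perm = rng.permutation(len(y_arr))
            res = fit_cca(x, y_arr[perm], n_components=n_components)
            out.append(res.correlations)
    return np.array(out)


def surrogate_selection(x, y, n_surrogates: int = 100, seed: int = 0,
                        alpha: float = 0.05, result: CCAResult | None = None) -> np.ndarray:
    """Variate retention flags from row-permutation surrogates.

    Surrogates refit the CCA after independently permuting the rows of Y
    (breaking the music-physiology alignment while preserving each set's
    covariance). A variate is retained iff its correlation exceeds the
    maximum over variate positions of the mean surrogate correlation and
    its Wilks p-value is below alpha.
    """
    if n_surrogates < 20:
        raise DataError("need >= 20 surrogates")
    if result is None:
        result = fit_cca(x, y)
    sur = _permuted_correlations(x, y, n_surrogates, seed, n_components=result.k)
    threshold = float(sur.mean(axis=0).max())
    retained = (result.correlations > threshold) & (result.wilks_p < alpha)
    result.retained = retained
    result.flags["surrogate_threshold"] = threshold
    return retained


def permutation_pvalues(x, y, n_perm: int = 999, seed: int = 0,
                        result: CCAResult | None = None) -> np.ndarray:
    """p_i = (1 + #{perm: r_i_perm >= r_i}) / (1 + n_perm)."""
    if result is None:
        result = fit_cca(x, y)
    perm = _permuted_correlations(x, y, n_perm, seed, n_components=result.k)
    exceed = (perm >= result.correlations[None, :]).sum(axis=0)
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    result.permutation_p = pvals
    return pvals


def to_json_dict(result: CCAResult) -> dict:
    xl, yl = loadings(result)
    return dict(
        n=result.n,
        correlations=result.correlations.tolist(),
        relative_covariance_pct=relative_covariance(result).tolist(),
        wilks_p=result.wilks_p.tolist() if result.wilks_p is not None else None,
        retained=[bool(b) for b in result.retained] if result.retained is not None else None,
        permutation_p=(
            result.permutation_p.tolist() if result.permutation_p is not None else None
        ),
        x_loadings=xl.to_dict(),
        y_loadings=yl.to_dict(),
        flags={k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
               for k, v in result.flags.items()},
    )
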