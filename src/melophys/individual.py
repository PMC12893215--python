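"""Individual-level effects: subject-wise CCA, cosine similarity to the
group loading pattern, and generalized additive models relating
similarity to baseline autonomic and demographic predictors with
Benjamini-Hochberg correction."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.gam.api import BSplines, GLMGam
from statsmodels.stats.multitest import multipletests

from melophys.core import DataError
from melophys.cca import fit_cca

#: Predictors entering the GAM as B-spline smooths vs linear terms.
SMOOTH_TERMS = ("pns", "sns", "sys", "dia", "age")
LINEAR_TERMS = ("gender", "musician", "prefers_classical")

MIN_SUBJECT_ROWS = 12
MIN_GAM_SMOOTH_N = 30
SPLINE_DF = 5
SPLINE_DEGREE = 3


def subjectwise_loadings(x, y, variate: int = 0, min_rows: int = MIN_SUBJECT_ROWS):
    """First-variate concatenated (music + physiology) loadings for one
    listener's own matrices; returns ``(vector, reason)`` where the
    vector is None when the listener is skipped (too few rows)."""
    n = len(pd.DataFrame(x))
    if n < min_rows:
        return None, f"only {n} rows (< {min_rows})"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # ridge warning expected on short playlists
        res = fit_cca(x, y)
    if variate >= res.k:
        return None, f"variate {variate + 1} not available (k = {res.k})"
    vec = np.concatenate([res.x_loadings[:, variate], res.y_loadings[:, variate]])
    return vec, None


def cosine_similarity(individual, group, align_sign: bool = True) -> float:
    """cos(a, b); with ``align_sign`` the individual vector is flipped
    when that increases agreement (resolving the CCA sign indeterminacy),
    making the value effectively non-negative."""
    a = np.asarray(individual, dtype=float)
    b = np.asarray(group, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise DataError("zero-norm loading vector")
    c = float(np.dot(a, b) / (na * nb))
    return abs(c) if align_sign else c


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


@dataclass
class GAMReport:
    terms: pd.DataFrame               # term, kind, estimate, p, q
    partial_effects: dict = field(default_factory=dict)  # term -> (grid, effect)
    fallback_linear: bool = False

    def to_dict(self) -> dict:
        return dict(
            fallback_linear=self.fallback_linear,
            terms=self.terms.to_dict(orient="records"),
            partial_effects={
                t: dict(grid=g.tolist(), effect=e.tolist())
                for t, (g, e) in self.partial_effects.items()
            },
        )


def fit_gam(records: pd.DataFrame, response: str = "similarity",
            alpha_smooth: float = 1.0) -> GAMReport:
    """Identity-link Gaussian GAM of similarity on baseline/demographic
    predictors: B-spline smooths (df=5, cubic) for the continuous terms,
    linear terms for the binary ones, per-term p-values and BH q-values.

    With fewer than 30 records every term enters linearly (warned).
    """
    df = records.copy()
    y = df[response].to_numpy(dtype=float)
    smooth = [t for t in SMOOTH_TERMS if t in df.columns]
    linear = [t for t in LINEAR_TERMS if t in df.columns]
    for t in list(smooth) + list(linear):
        if df[t].nunique() < 2:
            warnings.warn(f"dropping constant predictor {t!r}", stacklevel=2)
            smooth = [s for s in smooth if s != t]
            linear = [s for s in linear if s != t]
    df = _encode_binary(df, linear)

    if len(df) < MIN_GAM_SMOOTH_N:
        warnings.warn(
            f"n = {len(df)} < {MIN_GAM_SMOOTH_N}: falling back to linear terms", stacklevel=2
        )
        return _fit_linear(df, y, smooth + linear)

    x_smooth = df[smooth].to_numpy(dtype=float)
    bs = BSplines(x_smooth, df=[SPLINE_DF] * len(smooth), degree=[SPLINE_DEGREE] * len(smooth))
    exog = sm.add_constant(df[linear].to_numpy(dtype=float)) if linear else None
    if exog is not None and np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise DataError(f"singular design among linear terms {linear}")
    model = GLMGam(y, exog=exog, smoother=bs, alpha=[alpha_smooth] * len(smooth))
    res = model.fit()

    rows = []
    partials = {}
    n_linear = exog.shape[1] if exog is not None else 0
    coefs_smooth = np.asarray(res.params)[n_linear:]
    for i, term in enumerate(smooth):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            tt = res.test_significance(i)
        p = float(np.atleast_1d(tt.pvalue)[0])
        mask = np.zeros(len(coefs_smooth), dtype=bool)
        mask[bs.mask[i]] = True
        # summarize the smooth by its first basis coefficient
        est = float(coefs_smooth[mask][0])
        rows.append(dict(term=term, kind="smooth", estimate=est, p=p))
        grid = np.linspace(df[term].min(), df[term].max(), 50)
        xg = np.tile(x_smooth.mean(axis=0), (50, 1))
        xg[:, i] = grid
        basis = bs.transform(xg)
        partials[term] = (grid, basis[:, mask] @ coefs_smooth[mask])
    for j, term in enumerate(linear):
        idx = 1 + j  # after the constant
        rows.append(dict(term=term, kind="linear",
                         estimate=float(np.asarray(res.params)[idx]),
                         p=float(np.asarray(res.pvalues)[idx])))
    terms = pd.DataFrame(rows)
    terms["q"] = bh_adjust(terms["p"])
    return GAMReport(terms=terms, partial_effects=partials)


def _encode_binary(df: pd.DataFrame, linear) -> pd.DataFrame:
    df = df.copy()
    for t in linear:
        col = df[t]
        if col.dtype == object or col.dtype == bool:
            levels = sorted(col.astype(str).unique())
            df[t] = (col.astype(str) == levels[-1]).astype(float)
    return df


def _fit_linear(df: pd.DataFrame, y, terms_list) -> GAMReport:
    x = sm.add_constant(df[list(terms_list)].to_numpy(dtype=float))
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise DataError(f"singular design among terms {list(terms_list)}")
    res = sm.OLS(y, x).fit()
    rows = [
        dict(term=t, kind="linear", estimate=float(res.params[i + 1]),
             p=float(res.pvalues[i + 1]))
        for i, t in enumerate(terms_list)
    ]
    terms = pd.DataFrame(rows)
    terms["q"] = bh_adjust(terms["p"])
    return GAMReport(terms=terms, fallback_linear=True)
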