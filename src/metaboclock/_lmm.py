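"""Internal helpers: random-intercept mixed models fit by ML, with LRTs.

Both the principal-component divergence tests and the per-metabolite
trajectory models are linear mixed models with a single random intercept
for replicate population.  Term p-values come from likelihood-ratio tests
between nested ML fits (chi-square reference, df = difference in fixed
design columns).  REML likelihoods are not comparable across fixed-effect
structures, hence ML throughout.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning


def drop_collinear(exog: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Drop linearly dependent design columns (pivoted QR), keeping order.

    Unbalanced factorials (an age sampled in only one regime) make the full
    dummy expansion rank-deficient; R's fitters silently pivot such columns
    out, and likelihood-ratio df must use the actual rank, so we prune
    explicitly.
    """
    if exog.shape[1] == 0:
        return exog
    from scipy.linalg import qr as sqr

    _, rr, piv = sqr(exog, mode="economic", pivoting=True)
    diag = np.abs(np.diag(rr))
    rank = int((diag > tol * diag[0]).sum()) if diag.size else 0
    keep = sorted(piv[:rank])
    return exog[:, keep]


def fit_ml(endog: np.ndarray, exog: np.ndarray, groups: np.ndarray):
    """Fit a random-intercept MixedLM by ML, tolerating boundary fits.

    The replicate-variance parameter lives on [0, inf); when the optimum is
    at (or near) the boundary the iterative optimizer can stop marginally
    short, so the exact zero-variance candidate (an OLS fit) is evaluated
    too and the higher-likelihood fit is returned.
    """
    from types import SimpleNamespace

    import statsmodels.api as sm

    exog = drop_collinear(exog)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = MixedLM(endog, exog, groups=groups)
        try:
            result = model.fit(reml=False, method="lbfgs", maxiter=200)
        except Exception:
            # fall back to the slower default optimizer before giving up
            result = model.fit(reml=False, maxiter=500)
    ols = sm.OLS(endog, exog).fit()
    if ols.llf > result.llf:
        return SimpleNamespace(
            llf=ols.llf,
            model=SimpleNamespace(exog=exog),
            cov_re=np.array([[0.0]]),
            params=ols.params,
        )
    return result


def lr_test(full, reduced) -> float:
    """Likelihood-ratio p-value for nested ML fits (chi-square)."""
    stat = 2.0 * (full.llf - reduced.llf)
    df = full.model.exog.shape[1] - reduced.model.exog.shape[1]
    if df <= 0:
        raise ValueError("models are not properly nested")
    return float(stats.chi2.sf(max(stat, 0.0), df))


def dummy_columns(values: np.ndarray) -> np.ndarray:
    """Treatment-coded dummy matrix (reference level dropped), levels sorted."""
    levels = np.unique(values)
    return np.column_stack([(values == lv).astype(float) for lv in levels[1:]]) if len(
        levels
    ) > 1 else np.empty((len(values), 0))


def interaction_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All pairwise products of two dummy blocks."""
    if a.shape[1] == 0 or b.shape[1] == 0:
        return np.empty((a.shape[0], 0))
    return np.einsum("ni,nj->nij", a, b).reshape(a.shape[0], -1)
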