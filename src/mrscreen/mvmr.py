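"""Multivariable MR: apportion outcome effects among correlated exposures.

The joint instrument set is the union of per-exposure instruments,
re-clumped at the usual thresholds, with exposure betas for
non-significant variants taken from each exposure's full summary
statistics. Exposure selection uses an L1-penalized version of the same
weighted regression with cross-validated penalty, followed by an
unpenalized refit for inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)


@dataclass
class MVMRInput:
    variant_ids: list[str]
    exposure_ids: list[str]
    B_exp: np.ndarray  # k x m
    se_exp: np.ndarray  # k x m
    beta_out: np.ndarray  # k
    se_out: np.ndarray  # k

    def __post_init__(self) -> None:
        self.B_exp = np.atleast_2d(np.asarray(self.B_exp, dtype=float))
        self.se_exp = np.atleast_2d(np.asarray(self.se_exp, dtype=float))
        self.beta_out = np.asarray(self.beta_out, dtype=float)
        self.se_out = np.asarray(self.se_out, dtype=float)
        k, m = self.B_exp.shape
        if k <= m:
            raise ValueError("multivariable MR requires more instruments than exposures")
        if len(self.exposure_ids) != m or len(self.variant_ids) != k:
            raise ValueError("id lists do not match matrix dimensions")
        if np.any(np.all(self.B_exp == 0, axis=0)):
            raise ValueError("all-zero exposure column")

    @property
    def k(self) -> int:
        return self.B_exp.shape[0]

    @property
    def m(self) -> int:
        return self.B_exp.shape[1]


@dataclass
class MVMRResult:
    exposure_ids: list[str]
    beta: np.ndarray
    se: np.ndarray
    pval: np.ndarray
    k: int
    selected: list[str] = field(default_factory=list)
    conditional_F: np.ndarray | None = None


def _collinear_columns(B: np.ndarray, ids: list[str]) -> list[str]:
    # name exposures involved in near-exact linear dependence
    corr = np.corrcoef(B, rowvar=False)
    bad = set()
    m = B.shape[1]
    for i in range(m):
        for j in range(i + 1, m):
            if abs(corr[i, j]) > 1 - 1e-10:
                bad.update((ids[i], ids[j]))
    return sorted(bad) if bad else list(ids)


def _conditional_f(inp: MVMRInput) -> np.ndarray:
    """Per-exposure conditional instrument strength: mean squared
    standardized residual of each exposure-beta column after weighted
    projection onto the other columns."""
    k, m = inp.k, inp.m
    out = np.empty(m)
    w = 1.0 / inp.se_out**2
    sw = np.sqrt(w)
    for j in range(m):
        target = inp.B_exp[:, j]
        if m == 1:
            resid = target
        else:
            others = np.delete(inp.B_exp, j, axis=1)
            coef, *_ = np.linalg.lstsq(others * sw[:, None], target * sw, rcond=None)
            resid = target - others @ coef
        out[j] = float(np.mean((resid / inp.se_exp[:, j]) ** 2))
    return out


def mvmr_fit(inp: MVMRInput, selected: list[str] | None = None) -> MVMRResult:
    """Weighted least squares of outcome betas on the exposure-beta
    columns, no intercept, weights 1/se_out^2; SEs scaled by
    max(1, residual scale); t p-values on k-m degrees of freedom.
    """
    k, m = inp.k, inp.m
    X = inp.B_exp
    if np.linalg.matrix_rank(X) < m:
        raise ValueError(
            "rank-deficient exposure matrix; collinear exposures: "
            + ", ".join(_collinear_columns(X, inp.exposure_ids))
        )
    w = 1.0 / inp.se_out**2
    XtW = X.T * w
    cov_unscaled = np.linalg.inv(XtW @ X)
    coef = cov_unscaled @ (XtW @ inp.beta_out)
    resid = inp.beta_out - X @ coef
    chi2 = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(chi2 / (k - m)))
    ses = np.sqrt(np.diag(cov_unscaled)) * scale
    pvals = 2.0 * stats.t.sf(np.abs(coef) / ses, df=k - m)
    return MVMRResult(
        exposure_ids=list(inp.exposure_ids),
        beta=coef,
        se=ses,
        pval=pvals,
        k=k,
        selected=list(selected) if selected is not None else list(inp.exposure_ids),
        conditional_F=_conditional_f(inp),
    )


def lasso_select(inp: MVMRInput, seed: int = 0, n_folds: int = 10) -> list[str]:
    """L1-penalized weighted regression with 10-fold cross-validated
    penalty at a fixed seed; returns exposures with nonzero coefficients.

    An empty selection (everything shrunk to zero) is returned with a
    warning, not raised.
    """
    if inp.m < 2:
        raise ValueError("lasso selection requires m >= 2 exposures")
    sw = 1.0 / inp.se_out  # sqrt weights
    Xw = inp.B_exp * sw[:, None]
    yw = inp.beta_out * sw
    cv = KFold(n_splits=min(n_folds, inp.k), shuffle=True, random_state=seed)
    model = LassoCV(fit_intercept=False, cv=cv, random_state=seed, max_iter=50_000)
    model.fit(Xw, yw)
    selected = [eid for eid, c in zip(inp.exposure_ids, model.coef_) if c != 0.0]
    if not selected:
        logger.warning("lasso_select: all coefficients shrunk to zero")
    return selected


def subset_input(inp: MVMRInput, keep: list[str]) -> MVMRInput:
    idx = [inp.exposure_ids.index(e) for e in keep]
    return MVMRInput(
        variant_ids=list(inp.variant_ids),
        exposure_ids=[inp.exposure_ids[i] for i in idx],
        B_exp=inp.B_exp[:, idx],
        se_exp=inp.se_exp[:, idx],
        beta_out=inp.beta_out,
        se_out=inp.se_out,
    )


def lasso_mvmr(inp: MVMRInput, seed: int = 0) -> MVMRResult:
    """Lasso exposure selection followed by an unpenalized refit."""
    selected = lasso_select(inp, seed=seed)
    if not selected:
        res = mvmr_fit(inp)
        res.selected = []
        return res
    res = mvmr_fit(subset_input(inp, selected), selected=selected)
    return res
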