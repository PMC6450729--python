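"""Weighted genetic risk scores and quintile-based logistic regression.

Scores are weighted sums of risk-allele dosages. Cases and controls are
compared across score quantile bins (quintiles by default) with the
lowest bin as reference, optionally adjusting for covariates such as sex,
age and principal components, with per-stratum reruns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054


@dataclass
class CohortMatrix:
    """Individual-level dosage matrix with phenotype, covariates and strata."""

    sample_ids: list[str]
    dosages: pd.DataFrame  # n x k, columns are variant ids, values in [0, 2]
    phenotype: np.ndarray  # 0/1
    covariates: pd.DataFrame | None = None
    strata: dict[str, np.ndarray] = field(default_factory=dict)
    effect_alleles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phenotype = np.asarray(self.phenotype)
        n = len(self.sample_ids)
        if len(self.dosages) != n or len(self.phenotype) != n:
            raise ValueError("sample dimension mismatch")
        if not set(np.unique(self.phenotype)) <= {0, 1}:
            raise ValueError("phenotype must be coded 0/1")
        vals = self.dosages.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    def __len__(self) -> int:
        return len(self.sample_ids)


@dataclass
class QuantileEffect:
    quantile: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    pval: float
    n_cases: int
    n_controls: int


@dataclass
class GRSResult:
    quantile_effects: list[QuantileEffect]  # reference bin has OR 1 by construction
    trend_pval: float
    n_quantiles: int
    adjusted_for: list[str]
    firth_used: bool = False
    strata_results: dict[str, "GRSResult"] = field(default_factory=dict)


def compute_grs(
    cohort: CohortMatrix, weights: dict[str, float], allele_map: dict[str, str] | None = None
) -> np.ndarray:
    """Per-sample weighted dosage sum.

    ``weights`` maps variant id to per-allele weight. When ``allele_map``
    gives the weight's effect allele and it differs from the cohort's
    dosage coding, the dosage is reflected (2 - dosage). Missing dosages
    are mean-imputed per variant. Zero overlapping variants is an error.
    """
    shared = [v for v in weights if v in cohort.dosages.columns]
    if not shared:
        raise ValueError("no overlap between weight variants and dosage columns")
    score = np.zeros(len(cohort))
    for v in shared:
        dos = cohort.dosages[v].to_numpy(dtype=float)
        if np.isnan(dos).any():
            dos = np.where(np.isnan(dos), np.nanmean(dos), dos)
        if allele_map and cohort.effect_alleles and v in allele_map and v in cohort.effect_alleles:
            if allele_map[v] != cohort.effect_alleles[v]:
                dos = 2.0 - dos
        score += dos * weights[v]
    return score


def _quantile_bins(scores: np.ndarray, sample_ids: list[str], q: int) -> np.ndarray:
    """Equal-count bins from whole-sample cut-points; ties resolved by rank
    with deterministic ordering on sample_id."""
    order = np.lexsort((np.asarray(sample_ids, dtype=object), scores))
    ranks = np.empty(len(scores), dtype=int)
    ranks[order] = np.arange(len(scores))
    return (ranks * q) // len(scores)


def _firth_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100):
    """Jeffreys-penalized logistic regression (bias-reduced); used as the
    fallback when ordinary ML shows quasi-separation."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        wdiag = mu * (1.0 - mu)
        XtW = X.T * wdiag
        info = XtW @ X
        cov = np.linalg.pinv(info)
        hat = np.einsum("ij,jk,ik->i", X * wdiag[:, None], cov, X)
        score = X.T @ (y - mu + hat * (0.5 - mu))
        step = cov @ score
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    cov = np.linalg.pinv((X.T * (mu * (1 - mu))) @ X)
    return beta, np.sqrt(np.maximum(np.diag(cov), 0.0))


def _fit_logit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            params, bse = fit.params, fit.bse
            if np.all(np.isfinite(bse)) and np.max(np.abs(params)) < 15:
                return np.asarray(params), np.asarray(bse), False
        except Exception:  # noqa: BLE001 - PerfectSeparation and convergence
            pass
    logger.warning("quasi-separation detected; Firth-penalized fallback used")
    params, bse = _firth_logistic(X, y)
    return params, bse, True


def quintile_logistic(
    scores: np.ndarray,
    cohort: CohortMatrix,
    adjust: list[str] | None = None,
    seed: int = 0,
    n_quantiles: int = 5,
    min_per_bin: int = 50,
    _recurse_strata: bool = True,
) -> GRSResult:
    """Disease regressed on score-quantile membership.

    Cut-points come from the whole analyzed sample; bins 2..q are
    indicator-coded against bin 1 in a logistic model with the requested
    covariate columns. The trend p-value refits with the bin index as a
    single linear term. Each strata label triggers a within-stratum rerun.
    """
    scores = np.asarray(scores, dtype=float)
    adjust = list(adjust or [])
    y = cohort.phenotype.astype(float)
    bins = _quantile_bins(scores, cohort.sample_ids, n_quantiles)
    counts = np.bincount(bins, minlength=n_quantiles)
    if counts.min() < min_per_bin:
        logger.warning("quantile bin with %d samples (< %d recommended)",
                       counts.min(), min_per_bin)

    cov_cols = []
    if adjust:
        if cohort.covariates is None:
            raise ValueError("covariate adjustment requested but cohort has no covariates")
        missing = [c for c in adjust if c not in cohort.covariates.columns]
        if missing:
            raise ValueError(f"unknown covariates: {missing}")
        for c in adjust:
            col = cohort.covariates[c].to_numpy(dtype=float)
            if np.ptp(col) == 0:  # constant within (sub)sample, e.g. sex strata
                logger.warning("covariate %s is constant; dropped from the model", c)
                continue
            cov_cols.append(col)

    indicators = [(bins == q).astype(float) for q in range(1, n_quantiles)]
    X = np.column_stack([np.ones(len(y))] + indicators + cov_cols)
    params, bse, firth = _fit_logit(X, y)

    effects = [
        QuantileEffect(1, 1.0, 1.0, 1.0, float("nan"),
                       int(y[bins == 0].sum()), int((1 - y)[bins == 0].sum()))
    ]
    for q in range(1, n_quantiles):
        b, s = params[q], bse[q]
        p = 2.0 * stats.norm.sf(abs(b) / s) if s > 0 else float("nan")
        effects.append(
            QuantileEffect(
                quantile=q + 1,
                odds_ratio=float(np.exp(b)),
                ci_low=float(np.exp(b - Z95 * s)),
                ci_high=float(np.exp(b + Z95 * s)),
                pval=float(p),
                n_cases=int(y[bins == q].sum()),
                n_controls=int((1 - y)[bins == q].sum()),
            )
        )

    Xt = np.column_stack([np.ones(len(y)), bins.astype(float)] + cov_cols)
    tparams, tbse, _ = _fit_logit(Xt, y)
    trend_p = float(2.0 * stats.norm.sf(abs(tparams[1]) / tbse[1])) if tbse[1] > 0 else float("nan")

    result = GRSResult(
        quantile_effects=effects,
        trend_pval=trend_p,
        n_quantiles=n_quantiles,
        adjusted_for=adjust,
        firth_used=firth,
    )
    if _recurse_strata:
        for label, mask in cohort.strata.items():
            mask = np.asarray(mask, dtype=bool)
            sub = CohortMatrix(
                sample_ids=[s for s, m in zip(cohort.sample_ids, mask) if m],
                dosages=cohort.dosages.loc[mask].reset_index(drop=True),
                phenotype=cohort.phenotype[mask],
                covariates=None
                if cohort.covariates is None
                else cohort.covariates.loc[mask].reset_index(drop=True),
                strata={},
                effect_alleles=cohort.effect_alleles,
            )
            try:
                result.strata_results[label] = quintile_logistic(
                    scores[mask], sub, adjust=adjust, seed=seed,
                    n_quantiles=n_quantiles, min_per_bin=min_per_bin,
                    _recurse_strata=False,
                )
            except Exception as exc:  # pragma: no cover - degenerate strata
                logger.warning("stratum %s skipped: %s", label, exc)
    return result
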