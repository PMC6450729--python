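"""Two-sample causal estimators and sensitivity analyses.

All estimators consume a :class:`~mrscreen.harmonize.HarmonizedSet`. The
inverse-variance-weighted (IVW) estimator defaults to multiplicative
random effects with the residual scale floored at 1; a fixed-effect
variant is available via ``random_effects=False``. Egger p-values use the
t distribution on k-2 degrees of freedom; IVW and weighted-median
p-values use the normal reference distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .harmonize import HarmonizedSet, clump, harmonize, select_instruments
from .sumstats import SumStats, intersect

Z95 = 1.959963984540054  # Phi^{-1}(0.975)

_TINY = float(np.finfo(float).tiny)


def _norm_p(z: float) -> float:
    """Two-sided normal p, floored at the smallest positive float so
    downstream (0, 1] validation survives extreme z-scores."""
    return max(float(2.0 * stats.norm.sf(abs(z))), _TINY)


def _t_p(t: float, df: int) -> float:
    return max(float(2.0 * stats.t.sf(abs(t), df=df)), _TINY)


@dataclass
class MRResult:
    method: str
    beta: float
    se: float
    pval: float
    k: int
    seed: int | None = None

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple[float, float, float]:
        return (
            float(np.exp(self.beta)),
            float(np.exp(self.beta - Z95 * self.se)),
            float(np.exp(self.beta + Z95 * self.se)),
        )

    @property
    def ci(self) -> tuple[float, float]:
        return (self.beta - Z95 * self.se, self.beta + Z95 * self.se)


@dataclass
class HetStats:
    Q: float
    df: int
    Q_pval: float
    I2: float


@dataclass
class SteigerResult:
    r2_exp: float
    r2_out: float
    direction_ok: bool
    z: float
    pval: float


@dataclass
class LeaveOneOut:
    rows: list[tuple[str, MRResult]]
    full: MRResult
    no_single_driver: bool
    flagged: list[str] = field(default_factory=list)


def wald_ratio(beta_exp: float, beta_out: float, se_out: float) -> tuple[float, float]:
    """Single-instrument causal estimate: outcome effect over exposure effect.

    The first-order delta-method standard error ``se_out/|beta_exp|``
    ignores exposure-side sampling noise (NO Measurement Error
    assumption).
    """
    if beta_exp == 0:
        raise ValueError("null instrument: beta_exp must be nonzero")
    return beta_out / beta_exp, se_out / abs(beta_exp)


def _ratios_weights(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    if np.any(h.beta_exp == 0):
        raise ValueError("null instrument: beta_exp must be nonzero")
    ratios = h.beta_out / h.beta_exp
    weights = h.beta_exp**2 / h.se_out**2  # inverse of the delta-method ratio variance
    return ratios, weights


def ivw(h: HarmonizedSet, random_effects: bool = True) -> tuple[MRResult, HetStats]:
    """Inverse-variance-weighted pooled Wald ratio.

    Equivalent to a zero-intercept weighted regression of outcome betas on
    exposure betas. For k>1 and ``random_effects`` the standard error is
    inflated by max(1, sqrt(Q/(k-1))) (multiplicative random effects).
    """
    ratios, w = _ratios_weights(h)
    k = h.k
    beta = float(np.sum(w * ratios) / np.sum(w))
    Q = float(np.sum(w * (ratios - beta) ** 2))
    se = float(np.sqrt(1.0 / np.sum(w)))
    if k > 1 and random_effects:
        se *= max(1.0, np.sqrt(Q / (k - 1)))
    pval = _norm_p(beta / se)
    df = k - 1
    het = HetStats(
        Q=Q,
        df=df,
        Q_pval=float(stats.chi2.sf(Q, df)) if df > 0 else 1.0,
        I2=float(max(0.0, (Q - df) / Q)) if Q > 0 else 0.0,
    )
    return MRResult("ivw", beta, se, float(pval), k), het


def mr_egger(h: HarmonizedSet) -> tuple[MRResult, MRResult]:
    """Egger regression: weighted least squares with a free intercept.

    Inputs are first re-oriented so every exposure beta is nonnegative.
    A nonzero intercept indicates directional horizontal pleiotropy.
    Returns (slope result, intercept result); p-values on t_{k-2}.
    """
    k = h.k
    if k < 3:
        raise ValueError("insufficient instruments for Egger (k >= 3 required)")
    sign = np.where(h.beta_exp < 0, -1.0, 1.0)
    bx = h.beta_exp * sign
    by = h.beta_out * sign
    w = 1.0 / h.se_out**2
    X = np.column_stack([np.ones(k), bx])
    XtW = X.T * w
    cov_unscaled = np.linalg.inv(XtW @ X)
    coef = cov_unscaled @ (XtW @ by)
    resid = by - X @ coef
    chi2 = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(chi2 / (k - 2)))
    ses = np.sqrt(np.diag(cov_unscaled)) * scale
    slope = MRResult("egger_slope", float(coef[1]), float(ses[1]),
                     _t_p(coef[1] / ses[1], k - 2), k)
    intercept = MRResult("egger_intercept", float(coef[0]), float(ses[0]),
                         _t_p(coef[0] / ses[0], k - 2), k)
    return slope, intercept


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    wn = weights[order] / np.sum(weights)
    s = np.cumsum(wn) - 0.5 * wn  # cumulative weight midpoints
    if 0.5 <= s[0]:
        return float(r[0])
    if 0.5 >= s[-1]:
        return float(r[-1])
    j = int(np.searchsorted(s, 0.5, side="right"))
    lo, hi = s[j - 1], s[j]
    return float(r[j - 1] + (r[j] - r[j - 1]) * (0.5 - lo) / (hi - lo))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Weighted median of Wald ratios; consistent with up to half the
    instrument weight invalid.

    The point estimate linearly interpolates the ratio whose cumulative
    weight midpoint crosses 0.5. The standard error comes from a seeded
    parametric bootstrap (betas resampled from normal distributions with
    their reported SEs).
    """
    k = h.k
    if k < 3:
        raise ValueError("insufficient instruments for weighted median (k >= 3 required)")
    ratios, w = _ratios_weights(h)
    beta = _weighted_median_point(ratios, w)

    rng = np.random.default_rng(seed)
    bx = rng.normal(h.beta_exp, h.se_exp, size=(n_boot, k))
    by = rng.normal(h.beta_out, h.se_out, size=(n_boot, k))
    bx[bx == 0] = np.finfo(float).tiny
    est = np.empty(n_boot)
    for b in range(n_boot):
        est[b] = _weighted_median_point(by[b] / bx[b], bx[b] ** 2 / h.se_out**2)
    se = float(np.std(est, ddof=1))
    pval = _norm_p(beta / se) if se > 0 else (_TINY if beta != 0 else 1.0)
    return MRResult("weighted_median", beta, se, pval, k, seed=seed)


def leave_one_out(h: HarmonizedSet, random_effects: bool = True) -> LeaveOneOut:
    """IVW re-estimated k times, each omitting one instrument.

    ``no_single_driver`` is True when every leave-one-out estimate keeps
    the full-set sign and its CI overlaps the full-set estimate.
    """
    if h.k < 2:
        raise ValueError("leave-one-out requires k >= 2")
    full, _ = ivw(h, random_effects=random_effects)
    rows = []
    flagged = []
    ok = True
    for i, vid in enumerate(h.variant_ids):
        mask = np.ones(h.k, dtype=bool)
        mask[i] = False
        res, _ = ivw(h.subset(mask), random_effects=random_effects)
        rows.append((vid, res))
        lo, hi = res.ci
        same_sign = np.sign(res.beta) == np.sign(full.beta) or full.beta == 0
        overlaps = lo <= full.beta <= hi
        if not (same_sign and overlaps):
            ok = False
            flagged.append(vid)
    return LeaveOneOut(rows=rows, full=full, no_single_driver=ok, flagged=flagged)


def _sum_r2(betas: np.ndarray, ses: np.ndarray, n: int) -> float:
    z2 = (betas / ses) ** 2
    return float(np.sum(z2 / (z2 + n - 2)))


def steiger(h: HarmonizedSet, n_exp: int | None = None, n_out: int | None = None) -> SteigerResult:
    """Directionality test: do the instruments explain more variance in the
    exposure than in the outcome?

    Per-instrument variance explained uses r2 = z^2/(z^2 + n - 2) on the
    observed scale, summed per study. The z statistic compares
    Fisher-transformed sqrt(r2) values at the effective sample size
    min(n_exp, n_out).
    """
    n_exp = n_exp if n_exp is not None else h.n_exp
    n_out = n_out if n_out is not None else h.n_out
    if n_exp is None or n_out is None or n_exp <= 0 or n_out <= 0:
        raise ValueError("steiger requires positive sample sizes for both studies")
    r2_exp = min(1.0, _sum_r2(h.beta_exp, h.se_exp, n_exp))
    r2_out = min(1.0, _sum_r2(h.beta_out, h.se_out, n_out))
    n_eff = min(n_exp, n_out)
    z1 = np.arctanh(min(np.sqrt(r2_exp), 1 - 1e-15))
    z2 = np.arctanh(min(np.sqrt(r2_out), 1 - 1e-15))
    z = float((z1 - z2) / np.sqrt(2.0 / max(n_eff - 3, 1)))
    pval = _norm_p(z)
    return SteigerResult(
        r2_exp=r2_exp, r2_out=r2_out, direction_ok=r2_exp > r2_out, z=z, pval=pval
    )


def f_statistic(h: HarmonizedSet) -> float:
    """Mean per-instrument F = mean(beta_exp^2 / se_exp^2); F > 10 is the
    conventional strong-instrument label."""
    return float(np.mean((h.beta_exp / h.se_exp) ** 2))


def is_strong_instrument(f: float) -> bool:
    return f > 10.0


def run_battery(
    h: HarmonizedSet, n_boot: int = 1000, seed: int = 0, random_effects: bool = True
) -> dict:
    """All estimators and sensitivity statistics applicable at the set's k."""
    out: dict = {}
    out["ivw"], out["het"] = ivw(h, random_effects=random_effects)
    out["f_stat"] = f_statistic(h)
    if h.k >= 3:
        out["egger_slope"], out["egger_intercept"] = mr_egger(h)
        out["weighted_median"] = weighted_median(h, n_boot=n_boot, seed=seed)
    if h.k >= 2:
        out["loo"] = leave_one_out(h, random_effects=random_effects)
    if h.n_exp and h.n_out:
        out["steiger"] = steiger(h)
    return out


def reverse_mr(
    outcome_as_exposure: SumStats,
    exposure_as_outcome: SumStats,
    ld=None,
    p_thresh: float = 5e-8,
    min_snps: int = 2,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Run the estimator battery in the reverse direction.

    The nominal outcome's genome-wide-significant loci (clumped when an LD
    panel is supplied) instrument the nominal exposure. Nonsignificant
    reverse estimates support forward causality.
    """
    sel = select_instruments(outcome_as_exposure, p_thresh=p_thresh, min_snps=min_snps)
    if not sel.eligible:
        raise ValueError(
            f"reverse MR needs >= {min_snps} genome-wide-significant loci; "
            f"found {len(sel.records)}"
        )
    instruments = clump(sel.records, ld) if ld is not None else sel.records
    inst_ss = SumStats(
        trait_id=outcome_as_exposure.trait_id,
        records=instruments,
        trait_type=outcome_as_exposure.trait_type,
        n=outcome_as_exposure.n,
    )
    pairs = intersect(inst_ss, exposure_as_outcome)
    if not pairs:
        raise ValueError("no harmonizable instruments")
    h = harmonize(
        [p[0] for p in pairs],
        [p[1] for p in pairs],
        exposure_id=outcome_as_exposure.trait_id,
        outcome_id=exposure_as_outcome.trait_id,
        n_exp=outcome_as_exposure.n,
        n_out=exposure_as_outcome.n,
    )
    return run_battery(h, n_boot=n_boot, seed=seed)
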