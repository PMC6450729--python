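"""LD-score regression: heritability and bivariate genetic correlation.

Chi-squared statistics (or z-score products) are regressed on LD scores
with a free intercept; the slope, rescaled by M over the sample sizes,
estimates the observed-scale heritability (or genetic covariance). All
uncertainties come from a delete-one-block jackknife over contiguous
genome blocks.

Heritability is computed by the *same* covariance routine applied to a
trait against itself, so a trait's genetic correlation with itself is
exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_N_BLOCKS = 200


@dataclass
class LDScoreTable:
    """Per-variant LD scores plus the reference panel size M used as the
    regression denominator."""

    variant_id: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ldscore: np.ndarray
    M: int

    def __post_init__(self) -> None:
        self.ldscore = np.asarray(self.ldscore, dtype=float)
        if np.any(self.ldscore < 0):
            raise ValueError("LD scores must be nonnegative")
        if self.M <= 0:
            raise ValueError("M must be positive")

    def __len__(self) -> int:
        return len(self.variant_id)

    @classmethod
    def read(cls, path, m_path=None) -> "LDScoreTable":
        """Read the conventional ldscore layout: TSV with columns CHR, SNP,
        BP, L2 and a sidecar ``.M`` file holding the denominator."""
        df = pd.read_csv(path, sep=r"\s+")
        if m_path is None:
            m_path = str(path) + ".M"
        M = int(float(Path(m_path).read_text().split()[0]))
        return cls(
            variant_id=[str(v) for v in df["SNP"]],
            chrom=df["CHR"].to_numpy(),
            pos=df["BP"].to_numpy(),
            ldscore=df["L2"].to_numpy(dtype=float),
            M=M,
        )

    def write(self, path, m_path=None) -> None:
        pd.DataFrame(
            {"CHR": self.chrom, "SNP": self.variant_id, "BP": self.pos,
             "L2": [f"{v:.10g}" for v in self.ldscore]}
        ).to_csv(path, sep="\t", index=False)
        if m_path is None:
            m_path = str(path) + ".M"
        Path(m_path).write_text(f"{self.M}\n")


@dataclass
class RGResult:
    h2_1: float
    h2_1_se: float
    h2_2: float
    h2_2_se: float
    gencov: float
    gencov_se: float
    rg: float
    rg_se: float
    rg_pval: float
    intercept_1: float
    intercept_1_se: float
    intercept_2: float
    intercept_2_se: float
    intercept_biv: float
    intercept_biv_se: float
    n_blocks: int
    reason: str | None = None  # set when rg is undefined (h2 <= 0)

    @property
    def defined(self) -> bool:
        return self.reason is None


def _wls_from_sums(S, Sx, Sxx, Sy, Sxy):
    denom = S * Sxx - Sx * Sx
    slope = (S * Sxy - Sx * Sy) / denom
    icpt = (Sy - slope * Sx) / S
    return slope, icpt


def _wls(y, x, w):
    return _wls_from_sums(
        np.sum(w), np.sum(w * x), np.sum(w * x * x), np.sum(w * y), np.sum(w * x * y)
    )


class _CovFit:
    """One LD-score regression of y (chi2 or z1*z2) on LD scores, with the
    iterated heteroskedasticity weights and delete-one-block machinery."""

    def __init__(self, y, lds: LDScoreTable, n_blocks: int, n_iter: int = 2):
        y = np.asarray(y, dtype=float)
        x = lds.ldscore
        if len(y) != len(x):
            raise ValueError("statistics and LD-score table are not aligned")
        if len(y) < 2 * n_blocks:
            raise ValueError(
                f"only {len(y)} variants for {n_blocks} jackknife blocks; "
                "reduce n_blocks to at most half the variant count"
            )
        xw = np.maximum(x, 1.0)
        slope, icpt = _wls(y, x, np.ones_like(x))
        for _ in range(n_iter):
            fitted = icpt + slope * x
            w = 1.0 / (xw * np.maximum(1.0, np.abs(fitted)) ** 2)
            slope, icpt = _wls(y, x, w)
        self.slope, self.icpt, self.w = slope, icpt, w
        # per-block sufficient statistics for O(n_blocks) delete-block fits
        bounds = np.linspace(0, len(y), n_blocks + 1).astype(int)
        stats_ = np.stack([w, w * x, w * x * x, w * y, w * x * y])
        self.block_sums = np.stack(
            [stats_[:, a:b].sum(axis=1) for a, b in zip(bounds[:-1], bounds[1:])]
        )  # (n_blocks, 5)
        self.totals = self.block_sums.sum(axis=0)
        self.n_blocks = n_blocks

    def delete_block_fits(self) -> tuple[np.ndarray, np.ndarray]:
        part = self.totals[None, :] - self.block_sums
        slope, icpt = _wls_from_sums(*(part[:, i] for i in range(5)))
        return slope, icpt


def _jackknife_se(values: np.ndarray) -> float:
    b = len(values)
    return float(np.sqrt((b - 1) / b * np.sum((values - values.mean()) ** 2)))


def _mean_n(n, size) -> float:
    n = np.asarray(n, dtype=float)
    if n.ndim == 0:
        return float(n)
    if len(n) != size:
        raise ValueError("sample-size vector is not aligned")
    return float(n.mean())


def ldsc_h2(
    z, n, lds: LDScoreTable, n_blocks: int = DEFAULT_N_BLOCKS
) -> tuple[float, float, float, float]:
    """Observed-scale heritability from a z-score vector aligned to ``lds``.

    Returns (h2, h2_se, intercept, intercept_se); SEs by delete-one-block
    jackknife over ``n_blocks`` contiguous blocks.
    """
    z = np.asarray(z, dtype=float)
    nbar = _mean_n(n, len(z))
    fit = _CovFit(z * z, lds, n_blocks)
    scale = lds.M / nbar
    slopes, icpts = fit.delete_block_fits()
    return (
        fit.slope * scale,
        _jackknife_se(slopes * scale),
        fit.icpt,
        _jackknife_se(icpts),
    )


def ldsc_rg(
    z1,
    z2,
    n1,
    n2,
    lds: LDScoreTable,
    n_blocks: int = DEFAULT_N_BLOCKS,
    overlap_n: int | None = None,
) -> RGResult:
    """Bivariate genetic correlation from two aligned z-score vectors.

    The cross-trait regression of z1*z2 on LD scores has a free intercept
    that absorbs sample overlap (``overlap_n`` is accepted for provenance
    but not used in estimation). The rg standard error comes from
    delete-one-block jackknife over the joint (h2_1, h2_2, gencov)
    pseudo-estimates. When either heritability estimate is nonpositive,
    rg is reported undefined with a reason code.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if z1.shape != z2.shape:
        raise ValueError("z-score vectors are not aligned")
    n1bar, n2bar = _mean_n(n1, len(z1)), _mean_n(n2, len(z2))

    fit1 = _CovFit(z1 * z1, lds, n_blocks)
    fit2 = _CovFit(z2 * z2, lds, n_blocks)
    fitx = _CovFit(z1 * z2, lds, n_blocks)

    s1, s2 = lds.M / n1bar, lds.M / n2bar
    sx = lds.M / np.sqrt(n1bar * n2bar)
    h2_1, h2_2 = fit1.slope * s1, fit2.slope * s2
    gencov = fitx.slope * sx

    sl1, ic1 = fit1.delete_block_fits()
    sl2, ic2 = fit2.delete_block_fits()
    slx, icx = fitx.delete_block_fits()
    h2_1_se = _jackknife_se(sl1 * s1)
    h2_2_se = _jackknife_se(sl2 * s2)
    gencov_se = _jackknife_se(slx * sx)

    reason = None
    if h2_1 <= 0 or h2_2 <= 0:
        reason = "h2_nonpositive"
        rg = rg_se = rg_pval = float("nan")
    else:
        rg = gencov / np.sqrt(h2_1 * h2_2)
        prod = (sl1 * s1) * (sl2 * s2)
        valid = prod > 0
        rg_blocks = np.where(valid, (slx * sx) / np.sqrt(np.where(valid, prod, 1.0)), rg)
        rg_se = _jackknife_se(rg_blocks)
        if rg_se > 0:
            rg_pval = max(float(2.0 * stats.norm.sf(abs(rg) / rg_se)), np.finfo(float).tiny)
        else:  # degenerate jackknife (e.g. a trait against itself)
            rg_pval = np.finfo(float).tiny if rg != 0 else 1.0

    return RGResult(
        h2_1=h2_1, h2_1_se=h2_1_se,
        h2_2=h2_2, h2_2_se=h2_2_se,
        gencov=gencov, gencov_se=gencov_se,
        rg=float(rg), rg_se=float(rg_se), rg_pval=float(rg_pval),
        intercept_1=fit1.icpt, intercept_1_se=_jackknife_se(ic1),
        intercept_2=fit2.icpt, intercept_2_se=_jackknife_se(ic2),
        intercept_biv=fitx.icpt, intercept_biv_se=_jackknife_se(icx),
        n_blocks=n_blocks, reason=reason,
    )
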