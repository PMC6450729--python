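"""Bayesian colocalization via Wakefield approximate Bayes factors.

For one region and two traits, posterior probabilities are computed for
the five hypotheses: H0 no association, H1/H2 association with one trait
only, H3 two distinct causal variants, H4 one shared causal variant —
under the single-causal-variant-per-locus assumption. All accumulation is
done in log space so extreme z-scores survive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 1e-5
PRIOR_SD_BINARY = 0.20
PRIOR_SD_QUANT = 0.15
PPH4_STRONG = 0.95


@dataclass
class RegionPanel:
    """Aligned per-variant summary statistics for two traits in one region."""

    region_id: str
    chrom: str
    start: int
    end: int
    variant_ids: list[str]
    beta1: np.ndarray
    se1: np.ndarray
    beta2: np.ndarray
    se2: np.ndarray
    trait_type1: str = "quantitative"
    trait_type2: str = "binary"
    case_fraction1: float | None = None
    case_fraction2: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("region start must precede end")
        self.beta1 = np.asarray(self.beta1, dtype=float)
        self.se1 = np.asarray(self.se1, dtype=float)
        self.beta2 = np.asarray(self.beta2, dtype=float)
        self.se2 = np.asarray(self.se2, dtype=float)
        k = len(self.variant_ids)
        for v in (self.beta1, self.se1, self.beta2, self.se2):
            if v.shape != (k,):
                raise ValueError("panel vectors must share length")
        if np.any(self.se1 <= 0) or np.any(self.se2 <= 0):
            raise ValueError("standard errors must be strictly positive")

    def __len__(self) -> int:
        return len(self.variant_ids)


@dataclass
class ColocResult:
    region_id: str
    pph: np.ndarray  # (PPH0, PPH1, PPH2, PPH3, PPH4)
    per_variant_h4: np.ndarray
    top_variant: str
    top_variant_h4: float
    n_variants: int
    colocalized: bool = field(init=False)

    def __post_init__(self) -> None:
        self.colocalized = bool(self.pph[4] > PPH4_STRONG)


def wakefield_abf(beta: float, se: float, prior_sd: float) -> float:
    """Log approximate Bayes factor for one association.

    With z = beta/se, V = se^2, W = prior_sd^2 and shrinkage
    r = W/(V+W): log-ABF = 0.5*log(1-r) + 0.5*z^2*r.
    """
    if np.any(np.asarray(se) <= 0):
        raise ValueError("se must be positive")
    V = np.asarray(se, dtype=float) ** 2
    z = np.asarray(beta, dtype=float) / se
    r = prior_sd**2 / (V + prior_sd**2)
    return 0.5 * np.log(1.0 - r) + 0.5 * z**2 * r


def _prior_sd(trait_type: str) -> float:
    return PRIOR_SD_BINARY if trait_type == "binary" else PRIOR_SD_QUANT


def coloc_region(
    panel: RegionPanel,
    p1: float = DEFAULT_P1,
    p2: float = DEFAULT_P2,
    p12: float = DEFAULT_P12,
    prior_sd1: float | None = None,
    prior_sd2: float | None = None,
) -> ColocResult:
    """Posterior probabilities of the five colocalization hypotheses.

    Per-variant priors: p1, p2 for trait-specific causality, p12 for a
    shared causal variant. The H3 term excludes same-variant pairs. A
    single-variant panel cannot support H3; it is reported as 0 with a
    warning.
    """
    if prior_sd1 is None:
        prior_sd1 = _prior_sd(panel.trait_type1)
    if prior_sd2 is None:
        prior_sd2 = _prior_sd(panel.trait_type2)

    lbf1 = wakefield_abf(panel.beta1, panel.se1, prior_sd1)
    lbf2 = wakefield_abf(panel.beta2, panel.se2, prior_sd2)
    lsum1 = logsumexp(lbf1)
    lsum2 = logsumexp(lbf2)
    lsum12 = logsumexp(lbf1 + lbf2)

    lh = np.empty(5)
    lh[0] = 0.0
    lh[1] = np.log(p1) + lsum1
    lh[2] = np.log(p2) + lsum2
    k = len(panel)
    if k < 2:
        logger.warning("coloc_region(%s): single-variant panel, H3 undefined -> 0",
                       panel.region_id)
        lh[3] = -np.inf
    elif k <= 4096:
        # exact pairwise sum over ordered (i, j), i != j; avoids the
        # catastrophic cancellation of the subtraction form when a single
        # variant dominates both traits
        pairs = lbf1[:, None] + lbf2[None, :]
        np.fill_diagonal(pairs, -np.inf)
        lh[3] = np.log(p1) + np.log(p2) + logsumexp(pairs)
    else:
        both = lsum1 + lsum2
        diff = -np.expm1(lsum12 - both)
        lh[3] = np.log(p1) + np.log(p2) + both + (np.log(diff) if diff > 0 else -np.inf)
    lh[4] = np.log(p12) + lsum12

    pph = np.exp(lh - logsumexp(lh))
    per_variant = np.exp((lbf1 + lbf2) - lsum12)
    top = int(np.argmax(per_variant))
    return ColocResult(
        region_id=panel.region_id,
        pph=pph,
        per_variant_h4=per_variant,
        top_variant=panel.variant_ids[top],
        top_variant_h4=float(per_variant[top]),
        n_variants=len(panel),
    )


def extract_region(
    exposure, outcome, index_variant_id: str, flank_bp: int = 1_000_000, region_id=None
) -> RegionPanel:
    """Build a RegionPanel around an index variant: every variant within
    ``flank_bp`` of it that is present in both summary-statistics tables,
    harmonized to the exposure's effect allele."""
    from .harmonize import harmonize
    from .sumstats import intersect

    idx = exposure.by_id().get(index_variant_id)
    if idx is None or idx.pos is None:
        raise ValueError(f"index variant {index_variant_id} not positioned in exposure")
    lo, hi = idx.pos - flank_bp, idx.pos + flank_bp
    from .sumstats import SumStats

    sub = SumStats(
        trait_id=exposure.trait_id,
        records=[
            r
            for r in exposure.records
            if r.chrom == idx.chrom and r.pos is not None and lo <= r.pos <= hi
        ],
        trait_type=exposure.trait_type,
        n=exposure.n,
    )
    pairs = intersect(sub, outcome)
    if not pairs:
        raise ValueError("no shared variants in region")
    h = harmonize([p[0] for p in pairs], [p[1] for p in pairs])
    return RegionPanel(
        region_id=region_id or f"{idx.chrom}:{lo}-{hi}",
        chrom=idx.chrom,
        start=lo,
        end=hi,
        variant_ids=h.variant_ids,
        beta1=h.beta_exp,
        se1=h.se_exp,
        beta2=h.beta_out,
        se2=h.se_out,
        trait_type1=exposure.trait_type,
        trait_type2=outcome.trait_type,
    )
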