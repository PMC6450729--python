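"""Synthetic GWAS inputs with a recorded truth ledger.

Summary statistics are drawn directly from their asymptotic sampling
distributions (genotype-free, desk-scale): with standardized genotypes
and phenotypes, a study of size n yields marginal effect estimates

    beta_hat ~ Normal(R b_true, R / n)   per LD block,

where R is the block LD correlation matrix. Sample overlap between two
studies induces cross-correlated sampling noise. A small genotype-level
path backs the risk-score analyses with real dosage matrices.

Every generator is a pure function of its config (which includes the
seed); sub-streams are derived deterministically per component.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .coloc import RegionPanel
from .harmonize import LDMatrix
from .ldsc import LDScoreTable
from .sumstats import SumStats, VariantAssoc

# allele pairs assigned to synthetic variants; non-palindromic by default so
# harmonization is lossless and tests stay deterministic
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
_PALINDROMIC_PAIRS = [("A", "T"), ("C", "G")]


@dataclass
class SimConfig:
    """Knobs for all synthetic generators. Unused fields are ignored by
    generators that do not need them."""

    seed: int = 0
    m_variants: int = 100
    ld_block_size: int = 1
    ld_rho: float = 0.0  # within-block correlation
    maf_range: tuple[float, float] = (0.05, 0.5)
    # exposure model
    k_instruments: int = 50
    effect_sd: float = 0.1
    n_exp: int = 100_000
    # outcome model
    theta: float = 0.0  # causal effect of exposure on outcome
    k_outcome_loci: int = 0  # loci acting directly on the outcome only
    outcome_effect_sd: float = 0.1
    n_out: int = 100_000
    case_fraction: float | None = None
    pleiotropy: str = "none"  # none | balanced | directional
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    invalid_fraction: float = 1.0  # fraction of instruments carrying pleiotropy
    overlap_fraction: float = 0.0
    palindromic_fraction: float = 0.0
    # LDSC model
    M: int = 20_000
    h2_1: float = 0.3
    h2_2: float = 0.3
    rg: float = 0.0
    n1: int = 50_000
    n2: int = 50_000
    intercept_overlap: float | None = None  # derived from overlap_fraction if None
    # coloc model
    coloc_mode: str = "shared"  # shared | distinct | single1 | single2 | none
    coloc_effect: float = 0.08
    # GRS genotype-level model
    n_samples: int = 2_000
    grs_effect: float = 0.0

    def validate(self) -> None:
        if not (0 <= self.overlap_fraction <= 1):
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if not (0 <= self.invalid_fraction <= 1):
            raise ValueError("invalid_fraction must lie in [0, 1]")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy model {self.pleiotropy!r}")
        if self.n_exp <= 0 or self.n_out <= 0 or self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("sample sizes must be positive")
        for h2 in (self.h2_1, self.h2_2):
            if not (0 <= h2 <= 1):
                raise ValueError("h2 must lie in [0, 1]")
        if not (-1 <= self.rg <= 1):
            raise ValueError("rg must lie in [-1, 1]")
        if self.k_instruments > self.m_variants:
            raise ValueError("more instruments requested than variants")
        if self.k_instruments * self.effect_sd**2 > 1.0:
            raise ValueError("infeasible exposure model: expected h2 exceeds 1")


@dataclass
class TruthLedger:
    """Immutable record of what a simulation planted; sufficient to score
    every estimator against its estimand."""

    seed: int
    theta: float | None = None
    pleiotropy_mean: float | None = None
    instrument_ids: list[str] = field(default_factory=list)
    invalid_ids: list[str] = field(default_factory=list)
    rg: float | None = None
    h2_1: float | None = None
    h2_2: float | None = None
    intercept_biv: float | None = None
    causal_variant_ids: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _rng(cfg: SimConfig, component: str) -> np.random.Generator:
    # stable per-component sub-stream (zlib.crc32 is process-independent,
    # unlike the built-in str hash)
    tag = zlib.crc32(component.encode())
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, tag]))


def _block_chol(block: int, rho: float) -> np.ndarray:
    R = np.full((block, block), rho)
    np.fill_diagonal(R, 1.0)
    return np.linalg.cholesky(R)


def _ld_matrix(cfg: SimConfig, ids: list[str], chroms, poss) -> LDMatrix:
    m = len(ids)
    r = np.eye(m)
    if cfg.ld_block_size > 1:
        for start in range(0, m, cfg.ld_block_size):
            end = min(start + cfg.ld_block_size, m)
            r[start:end, start:end] = cfg.ld_rho
            np.fill_diagonal(r[start:end, start:end], 1.0)
    positions = {v: (str(c), int(p)) for v, c, p in zip(ids, chroms, poss)}
    return LDMatrix(ids, r, positions)


def _variant_frame(cfg: SimConfig, rng: np.random.Generator, m: int):
    ids = [f"rs{i + 1}" for i in range(m)]
    block = max(cfg.ld_block_size, 1)
    n_blocks = -(-m // block)
    # blocks separated far beyond the clump window; one chromosome per 50 blocks
    chroms = np.repeat(np.arange(n_blocks) // 50 + 1, block)[:m].astype(str)
    poss = np.array(
        [(b % 50) * 50_000_000 + 1_000 * (i % block) + 1
         for b, i in zip(np.repeat(np.arange(n_blocks), block)[:m], range(m))]
    )
    maf = rng.uniform(*cfg.maf_range, size=m)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    alleles = [_ALLELE_PAIRS[i] for i in pair_idx]
    if cfg.palindromic_fraction > 0:
        pal = rng.random(m) < cfg.palindromic_fraction
        for i in np.flatnonzero(pal):
            alleles[i] = _PALINDROMIC_PAIRS[int(rng.integers(0, 2))]
    return ids, chroms, poss, maf, alleles


def _p_from_z(z: np.ndarray) -> np.ndarray:
    from scipy import stats

    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.maximum(p, np.finfo(float).tiny)


def _records(ids, chroms, poss, alleles, maf, beta, se, n) -> list[VariantAssoc]:
    pvals = _p_from_z(beta / se)
    return [
        VariantAssoc(
            variant_id=v, chrom=str(c), pos=int(p),
            effect_allele=a[0], other_allele=a[1],
            eaf=float(f), beta=float(b), se=float(s), pval=float(pv), n=int(n),
        )
        for v, c, p, a, f, b, s, pv in zip(ids, chroms, poss, alleles, maf, beta, se, pvals)
    ]


def simulate_two_sample(
    cfg: SimConfig,
) -> tuple[SumStats, SumStats, LDMatrix, TruthLedger]:
    """Paired exposure/outcome summary statistics with known causal effect.

    The first ``k_instruments`` blocks each carry one true instrument
    (the block's first variant); remaining variants are null for the
    exposure. The outcome's true effect at variant j is
    theta * b_j + pleiotropy_j. Overlap correlates the two studies'
    sampling noise.
    """
    cfg.validate()
    rng = _rng(cfg, "two_sample")
    m = cfg.m_variants
    ids, chroms, poss, maf, alleles = _variant_frame(cfg, rng, m)
    block = max(cfg.ld_block_size, 1)

    b_true = np.zeros(m)
    inst_idx = np.arange(cfg.k_instruments) * block
    inst_idx = inst_idx[inst_idx < m][: cfg.k_instruments]
    signs = rng.choice([-1.0, 1.0], size=len(inst_idx))
    b_true[inst_idx] = signs * np.abs(rng.normal(cfg.effect_sd, cfg.effect_sd / 5, len(inst_idx)))

    alpha = np.zeros(m)
    invalid_ids: list[str] = []
    if cfg.pleiotropy != "none":
        n_invalid = int(round(cfg.invalid_fraction * len(inst_idx)))
        chosen = rng.choice(inst_idx, size=n_invalid, replace=False)
        mean = cfg.pleiotropy_mean if cfg.pleiotropy == "directional" else 0.0
        alpha[chosen] = rng.normal(mean, cfg.pleiotropy_sd, size=n_invalid)
        invalid_ids = [ids[i] for i in np.sort(chosen)]

    # directional pleiotropy is coded on the exposure-increasing allele, so
    # its mean survives re-orientation of instruments to positive exposure
    # effects (as the Egger intercept assumes)
    theta_out = cfg.theta * b_true + np.where(b_true != 0, np.sign(b_true), 1.0) * alpha

    # loci acting on the outcome directly (not through the exposure); placed
    # in blocks after the instrument blocks so panels stay disjoint
    outcome_loci: list[str] = []
    if cfg.k_outcome_loci > 0:
        start_block = len(inst_idx)
        loci_idx = (start_block + np.arange(cfg.k_outcome_loci)) * block
        loci_idx = loci_idx[loci_idx < m]
        theta_out[loci_idx] += rng.choice([-1.0, 1.0], len(loci_idx)) * np.abs(
            rng.normal(cfg.outcome_effect_sd, cfg.outcome_effect_sd / 5, len(loci_idx))
        )
        outcome_loci = [ids[i] for i in loci_idx]

    se_exp = np.full(m, 1.0 / np.sqrt(cfg.n_exp))
    phi = cfg.case_fraction
    out_scale = 1.0 if phi is None else 1.0 / np.sqrt(phi * (1.0 - phi))
    se_out = np.full(m, out_scale / np.sqrt(cfg.n_out))

    c_overlap = cfg.overlap_fraction
    mean_exp = np.empty(m)
    mean_out = np.empty(m)
    noise_exp = np.empty(m)
    noise_out = np.empty(m)
    L = _block_chol(block, cfg.ld_rho) if block > 1 else None
    for start in range(0, m, block):
        end = min(start + block, m)
        bsize = end - start
        e1 = rng.standard_normal(bsize)
        e2 = c_overlap * e1 + np.sqrt(max(0.0, 1 - c_overlap**2)) * rng.standard_normal(bsize)
        if L is not None and bsize == block:
            R = L @ L.T
            mean_exp[start:end] = R @ b_true[start:end]
            mean_out[start:end] = R @ theta_out[start:end]
            noise_exp[start:end] = L @ e1
            noise_out[start:end] = L @ e2
        else:
            mean_exp[start:end] = b_true[start:end]
            mean_out[start:end] = theta_out[start:end]
            noise_exp[start:end] = e1
            noise_out[start:end] = e2
    beta_exp = mean_exp + noise_exp * se_exp
    beta_out = mean_out + noise_out * se_out

    exposure = SumStats(
        trait_id="sim_exposure",
        records=_records(ids, chroms, poss, alleles, maf, beta_exp, se_exp, cfg.n_exp),
        trait_type="quantitative",
        n=cfg.n_exp,
    )
    outcome = SumStats(
        trait_id="sim_outcome",
        records=_records(ids, chroms, poss, alleles, maf, beta_out, se_out, cfg.n_out),
        trait_type="binary" if phi is not None else "quantitative",
        n=cfg.n_out,
    )
    ld = _ld_matrix(cfg, ids, chroms, poss)
    ledger = TruthLedger(
        seed=cfg.seed,
        theta=cfg.theta,
        pleiotropy_mean=cfg.pleiotropy_mean if cfg.pleiotropy == "directional" else 0.0,
        instrument_ids=[ids[i] for i in inst_idx],
        invalid_ids=invalid_ids,
        extra={
            "overlap_fraction": c_overlap,
            "pleiotropy": cfg.pleiotropy,
            "outcome_loci": outcome_loci,
        },
    )
    return exposure, outcome, ld, ledger


def simulate_ldsc(
    cfg: SimConfig,
) -> tuple[np.ndarray, np.ndarray, int, int, LDScoreTable, TruthLedger]:
    """Z-scores for two traits under the LD-score-regression model.

    E[z1 z2] = sqrt(n1 n2) * gencov * l / M + intercept, with the
    bivariate intercept induced by the configured sample-overlap fraction
    (phenotypic correlation 1 among shared samples).
    """
    cfg.validate()
    rng = _rng(cfg, "ldsc")
    M = cfg.M
    ell = 1.0 + rng.gamma(shape=4.0, scale=10.0, size=M)
    gencov = cfg.rg * np.sqrt(cfg.h2_1 * cfg.h2_2)
    ic = (
        cfg.intercept_overlap
        if cfg.intercept_overlap is not None
        else cfg.overlap_fraction * min(cfg.n1, cfg.n2) / np.sqrt(cfg.n1 * cfg.n2)
    )
    v1 = 1.0 + cfg.n1 * cfg.h2_1 * ell / M
    v2 = 1.0 + cfg.n2 * cfg.h2_2 * ell / M
    cv = np.sqrt(cfg.n1 * cfg.n2) * gencov * ell / M + ic
    cv = np.clip(cv, -np.sqrt(v1 * v2) * 0.999, np.sqrt(v1 * v2) * 0.999)
    e1 = rng.standard_normal(M)
    e2 = rng.standard_normal(M)
    z1 = np.sqrt(v1) * e1
    rho = cv / np.sqrt(v1 * v2)
    z2 = np.sqrt(v2) * (rho * e1 + np.sqrt(1.0 - rho**2) * e2)

    ids = [f"rs{i + 1}" for i in range(M)]
    lds = LDScoreTable(
        variant_id=ids,
        chrom=np.ones(M, dtype=int),
        pos=np.arange(1, M + 1) * 1000,
        ldscore=ell,
        M=M,
    )
    ledger = TruthLedger(
        seed=cfg.seed, rg=cfg.rg, h2_1=cfg.h2_1, h2_2=cfg.h2_2, intercept_biv=float(ic)
    )
    return z1, z2, cfg.n1, cfg.n2, lds, ledger


def simulate_coloc_region(cfg: SimConfig) -> tuple[RegionPanel, TruthLedger]:
    """One region of block-correlated variants with a configurable causal
    architecture: a shared causal variant, two distinct causals placed in
    different LD blocks, a single-trait causal, or no causal."""
    cfg.validate()
    rng = _rng(cfg, "coloc")
    m = cfg.m_variants
    block = max(cfg.ld_block_size, 1)
    b1 = np.zeros(m)
    b2 = np.zeros(m)
    causal: list[int] = []
    if cfg.coloc_mode == "shared":
        i = int(rng.integers(0, m))
        b1[i] = cfg.coloc_effect
        b2[i] = cfg.coloc_effect
        causal = [i]
    elif cfg.coloc_mode == "distinct":
        i = int(rng.integers(0, max(1, m // 2)))
        j = int(rng.integers(m // 2, m))
        if block > 1:  # force different LD blocks
            j = min(m - 1, (j // block) * block) if j // block != i // block else m - 1
        b1[i] = cfg.coloc_effect
        b2[j] = cfg.coloc_effect
        causal = [i, j]
    elif cfg.coloc_mode in ("single1", "single2"):
        i = int(rng.integers(0, m))
        (b1 if cfg.coloc_mode == "single1" else b2)[i] = cfg.coloc_effect
        causal = [i]
    elif cfg.coloc_mode != "none":
        raise ValueError(f"unknown coloc_mode {cfg.coloc_mode!r}")

    se1 = np.full(m, 1.0 / np.sqrt(cfg.n1))
    se2 = np.full(m, 1.0 / np.sqrt(cfg.n2))
    beta1 = np.empty(m)
    beta2 = np.empty(m)
    L = _block_chol(block, cfg.ld_rho) if block > 1 else None
    for start in range(0, m, block):
        end = min(start + block, m)
        bsize = end - start
        if L is not None and bsize == block:
            R = L @ L.T
            beta1[start:end] = R @ b1[start:end] + (L @ rng.standard_normal(bsize)) * se1[start:end]
            beta2[start:end] = R @ b2[start:end] + (L @ rng.standard_normal(bsize)) * se2[start:end]
        else:
            beta1[start:end] = b1[start:end] + rng.standard_normal(bsize) * se1[start:end]
            beta2[start:end] = b2[start:end] + rng.standard_normal(bsize) * se2[start:end]

    ids = [f"rs{i + 1}" for i in range(m)]
    panel = RegionPanel(
        region_id="sim_region",
        chrom="1",
        start=1,
        end=m * 1000 + 1,
        variant_ids=ids,
        beta1=beta1,
        se1=se1,
        beta2=beta2,
        se2=se2,
        trait_type1="quantitative",
        trait_type2="quantitative",
    )
    ledger = TruthLedger(
        seed=cfg.seed,
        causal_variant_ids=[ids[i] for i in causal],
        extra={"coloc_mode": cfg.coloc_mode},
    )
    return panel, ledger


def simulate_cohort(
    cfg: SimConfig, weights: dict[str, float] | None = None
):
    """Genotype-level cohort for risk-score analyses: dosages from
    binomial(2, maf), binary phenotype from a logistic liability on the
    weighted score, plus sex/age/PC covariates and subtype strata."""
    from .grs import CohortMatrix

    cfg.validate()
    rng = _rng(cfg, "cohort")
    n, k = cfg.n_samples, cfg.k_instruments
    maf = rng.uniform(*cfg.maf_range, size=k)
    ids = [f"rs{i + 1}" for i in range(k)]
    dos = rng.binomial(2, maf, size=(n, k)).astype(float)
    if weights is None:
        weights = {v: float(w) for v, w in zip(ids, rng.normal(0.0, 0.05, size=k))}
    w = np.array([weights.get(v, 0.0) for v in ids])
    score = dos @ w
    zscore = (score - score.mean()) / (score.std() if score.std() > 0 else 1.0)
    sex = rng.integers(0, 2, size=n).astype(float)
    age = rng.normal(60, 10, size=n)
    pcs = rng.normal(0, 1, size=(n, 20))
    logit = -0.5 + cfg.grs_effect * zscore
    pheno = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(int)
    cov = pd.DataFrame({"sex": sex, "age": age})
    for i in range(20):
        cov[f"PC{i + 1}"] = pcs[:, i]
    strata = {
        "male": sex == 1,
        "female": sex == 0,
        "sporadic": rng.random(n) < 0.9,
    }
    cohort = CohortMatrix(
        sample_ids=[f"S{i + 1}" for i in range(n)],
        dosages=pd.DataFrame(dos, columns=ids),
        phenotype=pheno,
        covariates=cov,
        strata=strata,
        effect_alleles={v: "A" for v in ids},
    )
    ledger = TruthLedger(seed=cfg.seed, extra={"grs_effect": cfg.grs_effect})
    return cohort, weights, ledger


def simulate_screen_library(
    n_null: int,
    n_causal: int,
    seed: int = 0,
    theta: float = 0.3,
    k_instruments: int = 30,
    n_per_study: int = 50_000,
    effect_sd: float = 0.1,
):
    """A trait library for end-to-end screening: ``n_null + n_causal``
    exposures over disjoint variant panels and one shared outcome that
    carries theta-scaled effects at the causal traits' instruments.

    Causal traits alternate cohort tags (published/ukbb) so the
    category-level replication rule is exercised; null traits are split
    evenly. Returns (TraitLibrary, TruthLedger).
    """
    from .screen import TraitLibrary

    rng = np.random.default_rng(np.random.SeedSequence([seed, 777]))
    n_traits = n_null + n_causal
    causal_flags = [True] * n_causal + [False] * n_null
    se = 1.0 / np.sqrt(n_per_study)
    out_records: list[VariantAssoc] = []
    traits = []
    causal_ids = []
    vcounter = 0
    for t in range(n_traits):
        is_causal = causal_flags[t]
        tid = f"trait{t + 1}_{'causal' if is_causal else 'null'}"
        tag = ("published", "ukbb")[t % 2]
        k = k_instruments
        ids = [f"rs{vcounter + i + 1}" for i in range(k)]
        vcounter += k
        maf = rng.uniform(0.1, 0.5, size=k)
        alleles = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), size=k)]
        chroms = np.full(k, str(t + 1))
        poss = (np.arange(k) + 1) * 20_000_000
        b = rng.choice([-1, 1], k) * np.abs(rng.normal(effect_sd, effect_sd / 5, k))
        bx = b + rng.standard_normal(k) * se
        theta_t = theta if is_causal else 0.0
        by = theta_t * b + rng.standard_normal(k) * se
        exp_ss = SumStats(
            trait_id=tid,
            records=_records(ids, chroms, poss, alleles, maf, bx, np.full(k, se), n_per_study),
            n=n_per_study,
        )
        traits.append((tid, exp_ss, tag))
        out_records.extend(
            _records(ids, chroms, poss, alleles, maf, by, np.full(k, se), n_per_study)
        )
        if is_causal:
            causal_ids.append(tid)
    outcome = SumStats(trait_id="sim_outcome", records=out_records, n=n_per_study)
    lib = TraitLibrary(traits=traits, outcome=outcome)
    ledger = TruthLedger(seed=seed, theta=theta, extra={"causal_traits": causal_ids})
    return lib, ledger
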