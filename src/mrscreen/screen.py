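"""Orchestration of the two screening designs over a trait library.

Design 1: per-trait genetic correlation against the outcome with
Benjamini-Hochberg FDR over all traits with a defined estimate.

Design 2: a two-phase MR screen — phase-1 IVW gate, then Egger and
weighted-median sensitivity gates, then cross-cohort replication. No
multiplicity correction is applied within the MR phase (replication
across independent cohort classes stands in for it); BH-adjusted IVW
p-values are reported in a side column for transparency.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .harmonize import LDMatrix, clump, harmonize, select_instruments
from .ldsc import LDScoreTable, ldsc_rg
from .mr import run_battery
from .sumstats import SumStats, intersect

logger = logging.getLogger(__name__)


def fdr_bh(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and significance mask.

    Adjusted values are p*(m/rank) with monotonicity enforced from the
    largest p downward; the mask marks adjusted p <= alpha. Empty input
    yields empty outputs.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out, out <= alpha


@dataclass
class TraitLibrary:
    """Exposure traits (with cohort tags) plus the single outcome."""

    traits: list[tuple[str, SumStats, str]]  # (trait_id, sumstats, cohort_tag)
    outcome: SumStats

    def __post_init__(self) -> None:
        ids = [t[0] for t in self.traits]
        if len(ids) != len(set(ids)):
            raise ValueError("trait_ids must be unique")


@dataclass
class ScreenConfig:
    p_instrument: float = 5e-8
    min_snps: int = 2
    clump_r2: float = 0.001
    clump_window_kb: int = 10_000
    phase1_alpha: float = 0.05
    sensitivity_alpha: float = 0.05
    fdr_alpha: float = 0.05
    h2_bounds: tuple[float, float] = (0.0, 1.0)  # exclusive lower, inclusive upper
    replication: str = "category"  # "category" or "strict"
    n_boot: int = 1000
    seed: int = 0
    random_effects: bool = True

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class ScreenReport:
    rows: pd.DataFrame
    final_causal_set: list[str]
    config: ScreenConfig
    kind: str  # "mr" or "ldsc"
    manifest: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.rows.to_csv(out / f"{self.kind}_screen.tsv", sep="\t", index=False)
        with open(out / f"{self.kind}_manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def _mr_trait_row(trait_id, cohort_tag, exp, outcome, ld, cfg) -> dict:
    row: dict = {
        "trait_id": trait_id,
        "cohort_tag": cohort_tag,
        "status": "ok",
        "n_instruments": 0,
    }
    sel = select_instruments(exp, p_thresh=cfg.p_instrument, min_snps=cfg.min_snps)
    if not sel.eligible:
        row["status"] = "ineligible_too_few_instruments"
        row["n_selected"] = len(sel.records)
        return row
    instruments = clump(sel.records, ld, r2_thresh=cfg.clump_r2, window_kb=cfg.clump_window_kb)
    inst_ss = SumStats(trait_id=trait_id, records=instruments, n=exp.n)
    pairs = intersect(inst_ss, outcome)
    if len(pairs) < cfg.min_snps:
        row["status"] = "ineligible_missing_in_outcome"
        return row
    try:
        h = harmonize(
            [p[0] for p in pairs], [p[1] for p in pairs],
            exposure_id=trait_id, outcome_id=outcome.trait_id,
            n_exp=exp.n, n_out=outcome.n,
        )
    except ValueError as exc:
        row["status"] = f"harmonization_failed: {exc}"
        return row
    res = run_battery(h, n_boot=cfg.n_boot, seed=cfg.seed, random_effects=cfg.random_effects)
    row["n_instruments"] = h.k
    row["ivw_beta"] = res["ivw"].beta
    row["ivw_se"] = res["ivw"].se
    row["ivw_p"] = res["ivw"].pval
    row["Q"] = res["het"].Q
    row["I2"] = res["het"].I2
    row["f_stat"] = res["f_stat"]
    if "egger_slope" in res:
        row["egger_beta"] = res["egger_slope"].beta
        row["egger_p"] = res["egger_slope"].pval
        row["egger_intercept"] = res["egger_intercept"].beta
        row["egger_intercept_p"] = res["egger_intercept"].pval
        row["wm_beta"] = res["weighted_median"].beta
        row["wm_p"] = res["weighted_median"].pval
        row["wm_seed"] = cfg.seed
    if "steiger" in res:
        row["steiger_ok"] = res["steiger"].direction_ok
    if "loo" in res:
        row["no_single_driver"] = res["loo"].no_single_driver
    return row


def run_mr_screen(lib: TraitLibrary, cfg: ScreenConfig | None = None,
                  ld: LDMatrix | None = None) -> ScreenReport:
    """Instrument selection, harmonization, the estimator battery, and the
    gate cascade for every trait in the library.

    Gates (evaluated in order, each logged with its inputs):
    pass_phase1: IVW p <= phase1_alpha; pass_sensitivity: additionally
    Egger p and weighted-median p <= sensitivity_alpha; replicated:
    additionally a sensitivity-passing, IVW-sign-concordant trait exists
    in the other cohort class. The final causal set is the replicated
    traits. Ineligible traits stay in the report with a status.
    """
    cfg = cfg or ScreenConfig()
    rows = [
        _mr_trait_row(tid, tag, exp, lib.outcome, ld, cfg) for tid, exp, tag in lib.traits
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return ScreenReport(df, [], cfg, "mr", {"n_traits": 0, "config": cfg.to_dict()})

    ok = df["status"] == "ok" if "status" in df else pd.Series(dtype=bool)
    df["pass_phase1"] = False
    df["pass_sensitivity"] = False
    df["replicated"] = False
    if ok.any():
        df.loc[ok, "pass_phase1"] = df.loc[ok, "ivw_p"] <= cfg.phase1_alpha
        has_sens = ok & df.get("egger_p", pd.Series(np.nan, index=df.index)).notna()
        df.loc[has_sens, "pass_sensitivity"] = (
            df.loc[has_sens, "pass_phase1"]
            & (df.loc[has_sens, "egger_p"] <= cfg.sensitivity_alpha)
            & (df.loc[has_sens, "wm_p"] <= cfg.sensitivity_alpha)
        )
        # BH side column over traits with a defined IVW p (transparency only)
        adj = np.full(len(df), np.nan)
        idx = np.flatnonzero(ok.to_numpy())
        adj_vals, _ = fdr_bh(df.loc[ok, "ivw_p"].to_numpy())
        adj[idx] = adj_vals
        df["ivw_p_bh"] = adj
        # replication across cohort classes
        for i in df.index[df["pass_sensitivity"]]:
            tag_i = df.at[i, "cohort_tag"]
            sign_i = np.sign(df.at[i, "ivw_beta"])
            partners = df[
                df["pass_sensitivity"]
                & (df["cohort_tag"] != tag_i)
                & (np.sign(df["ivw_beta"].fillna(0)) == sign_i)
            ]
            if cfg.replication == "strict":
                partners = partners[partners["trait_id"] == df.at[i, "trait_id"]]
            df.at[i, "replicated"] = len(partners) > 0
    final = sorted(df.loc[df["replicated"], "trait_id"].tolist())
    manifest = {
        "n_traits": len(df),
        "config": cfg.to_dict(),
        "final_causal_set": final,
        "version": __version__,
    }
    return ScreenReport(df, final, cfg, "mr", manifest)


def _zvec(ss: SumStats, lds: LDScoreTable) -> np.ndarray | None:
    by_id = {r.variant_id: r.beta / r.se for r in ss.records}
    z = np.array([by_id.get(v, np.nan) for v in lds.variant_id])
    return None if np.isnan(z).any() else z


def run_ldsc_screen(
    lib: TraitLibrary, lds: LDScoreTable, cfg: ScreenConfig | None = None,
    n_blocks: int = 200,
) -> ScreenReport:
    """Per-trait genetic correlation with the outcome, heritability-bounds
    filter, and BH-FDR over the family of traits with defined estimates.

    Traits with undefined rg (nonpositive heritability) remain in the
    report with a status and are excluded from the FDR family; the family
    size is recorded in the manifest.
    """
    cfg = cfg or ScreenConfig()
    z_out = _zvec(lib.outcome, lds)
    if z_out is None:
        raise ValueError("outcome summary statistics do not cover the LD-score panel")
    rows = []
    for tid, ss, tag in lib.traits:
        row: dict = {"trait_id": tid, "cohort_tag": tag, "status": "ok"}
        z = _zvec(ss, lds)
        if z is None:
            row["status"] = "missing_variants"
            rows.append(row)
            continue
        res = ldsc_rg(z, z_out, ss.n or lds.M, lib.outcome.n or lds.M, lds, n_blocks=n_blocks)
        row["h2"] = res.h2_1
        row["h2_se"] = res.h2_1_se
        lo, hi = cfg.h2_bounds
        if not res.defined:
            row["status"] = f"rg_undefined:{res.reason}"
        elif not (lo < res.h2_1 <= hi):
            row["status"] = "h2_out_of_bounds"
        else:
            row.update(
                rg=res.rg, rg_se=res.rg_se, rg_p=res.rg_pval,
                gencov=res.gencov, intercept_biv=res.intercept_biv,
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    defined = df["status"] == "ok"
    df["fdr_p"] = np.nan
    df["significant"] = False
    if defined.any():
        adj, mask = fdr_bh(df.loc[defined, "rg_p"].to_numpy(), alpha=cfg.fdr_alpha)
        df.loc[defined, "fdr_p"] = adj
        df.loc[defined, "significant"] = mask
    final = sorted(df.loc[df["significant"], "trait_id"].tolist())
    manifest = {
        "n_traits": len(df),
        "fdr_family_size": int(defined.sum()),
        "config": cfg.to_dict(),
        "significant": final,
        "version": __version__,
    }
    return ScreenReport(df, final, cfg, "ldsc", manifest)
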