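"""Instrument selection, LD clumping, proxy substitution, and allele harmonization.

The output of this stage is a :class:`HarmonizedSet`: exposure and outcome
effect vectors expressed on a common effect-allele orientation, ready for
the causal estimators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .sumstats import SumStats, VariantAssoc

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROMIC_PAIRS = ({"A", "T"}, {"C", "G"})

GENOME_WIDE_P = 5e-8
DEFAULT_CLUMP_R2 = 0.001
DEFAULT_CLUMP_WINDOW_KB = 10_000
DEFAULT_PROXY_R2 = 0.8
DEFAULT_PALINDROME_MAF_BAND = 0.42


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in PALINDROMIC_PAIRS


def _complement_allele(a: str) -> str | None:
    if all(ch in COMPLEMENT for ch in a):
        return "".join(COMPLEMENT[ch] for ch in a)
    return None  # indel or ambiguous base: no strand flip possible


@dataclass
class LDMatrix:
    """Signed LD correlations over a variant panel."""

    variant_ids: list[str]
    r: np.ndarray
    positions: dict[str, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.variant_ids)
        if self.r.shape != (k, k):
            raise ValueError("LD matrix shape does not match panel size")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-6):
            raise ValueError("LD matrix must have unit diagonal")
        if np.any(np.abs(self.r) > 1.0 + 1e-8):
            raise ValueError("LD correlations must lie in [-1, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def corr(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]])

    def r2(self, a: str, b: str) -> float:
        return self.corr(a, b) ** 2

    @classmethod
    def from_triplets(cls, triplet_path, panel_path) -> "LDMatrix":
        """Build from a TSV triplet list (id_a, id_b, r) plus a panel table
        (id, chrom, pos)."""
        panel = pd.read_csv(panel_path, sep=r"\s+")
        ids = [str(v) for v in panel.iloc[:, 0]]
        positions = {
            str(row[0]): (str(row[1]), int(row[2])) for row in panel.itertuples(index=False)
        }
        idx = {v: i for i, v in enumerate(ids)}
        r = np.eye(len(ids))
        trip = pd.read_csv(triplet_path, sep=r"\s+")
        for a, b, val in trip.itertuples(index=False):
            i, j = idx[str(a)], idx[str(b)]
            r[i, j] = r[j, i] = float(val)
        return cls(ids, r, positions)

    @classmethod
    def from_square(cls, matrix_path, panel_path) -> "LDMatrix":
        """Build from a square-matrix TSV (header row of ids) plus a panel table."""
        panel = pd.read_csv(panel_path, sep=r"\s+")
        positions = {
            str(row[0]): (str(row[1]), int(row[2])) for row in panel.itertuples(index=False)
        }
        mat = pd.read_csv(matrix_path, sep=r"\s+", index_col=0)
        ids = [str(c) for c in mat.columns]
        return cls(ids, mat.to_numpy(dtype=float), positions)


@dataclass
class InstrumentSelection:
    """Genome-wide-significant records plus an eligibility flag."""

    records: list[VariantAssoc]
    eligible: bool
    p_thresh: float
    min_snps: int


@dataclass
class HarmonizedSet:
    """Matched exposure/outcome effects on a common effect-allele orientation."""

    exposure_id: str
    outcome_id: str
    variant_ids: list[str]
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    eaf_exp: np.ndarray | None = None
    n_exp: int | None = None
    n_out: int | None = None
    flips: int = 0
    dropped_palindromes: int = 0
    proxies_used: dict[str, str] = field(default_factory=dict)
    pairs: list[tuple[VariantAssoc, VariantAssoc]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beta_exp = np.asarray(self.beta_exp, dtype=float)
        self.se_exp = np.asarray(self.se_exp, dtype=float)
        self.beta_out = np.asarray(self.beta_out, dtype=float)
        self.se_out = np.asarray(self.se_out, dtype=float)
        k = len(self.variant_ids)
        for v in (self.beta_exp, self.se_exp, self.beta_out, self.se_out):
            if v.shape != (k,):
                raise ValueError("harmonized vectors must share length k")
        if k < 1:
            raise ValueError("harmonized set must contain at least one instrument")
        if np.any(self.se_exp <= 0) or np.any(self.se_out <= 0):
            raise ValueError("standard errors must be strictly positive")

    @property
    def k(self) -> int:
        return len(self.variant_ids)

    def subset(self, mask: np.ndarray) -> "HarmonizedSet":
        idx = np.flatnonzero(mask)
        return HarmonizedSet(
            exposure_id=self.exposure_id,
            outcome_id=self.outcome_id,
            variant_ids=[self.variant_ids[i] for i in idx],
            beta_exp=self.beta_exp[idx],
            se_exp=self.se_exp[idx],
            beta_out=self.beta_out[idx],
            se_out=self.se_out[idx],
            eaf_exp=None if self.eaf_exp is None else np.asarray(self.eaf_exp)[idx],
            n_exp=self.n_exp,
            n_out=self.n_out,
            proxies_used=dict(self.proxies_used),
            pairs=[self.pairs[i] for i in idx] if self.pairs else [],
        )


def select_instruments(
    exp: SumStats, p_thresh: float = GENOME_WIDE_P, min_snps: int = 2
) -> InstrumentSelection:
    """Keep records below the significance threshold.

    Exposures yielding fewer than ``min_snps`` hits are flagged ineligible
    (a status, not an exception) so a screen can carry them in its report.
    """
    if not (0.0 < p_thresh < 1.0) and p_thresh != 1.0:
        raise ValueError("p_thresh must lie in (0, 1]")
    hits = [r for r in exp.records if r.pval < p_thresh or p_thresh == 1.0]
    return InstrumentSelection(
        records=hits, eligible=len(hits) >= min_snps, p_thresh=p_thresh, min_snps=min_snps
    )


def clump(
    records: list[VariantAssoc],
    ld: LDMatrix | None,
    r2_thresh: float = DEFAULT_CLUMP_R2,
    window_kb: int = DEFAULT_CLUMP_WINDOW_KB,
    strict: bool = False,
) -> list[VariantAssoc]:
    """Greedy p-value-priority LD pruning.

    Repeatedly keep the best remaining record (ascending p, ties broken
    by variant_id) and discard records on the same chromosome within
    +/- window_kb whose r-squared with it meets ``r2_thresh``. Records
    absent from the LD panel are kept with a warning (dropped under
    ``strict=True``). Output is sorted by (chrom, pos).
    """
    if not (0.0 < r2_thresh <= 1.0):
        raise ValueError("r2_thresh must lie in (0, 1]")
    window_bp = window_kb * 1000

    resolvable, unresolvable = [], []
    for rec in records:
        if ld is not None and rec.variant_id in ld:
            resolvable.append(rec)
        else:
            unresolvable.append(rec)
    if unresolvable and ld is not None:
        logger.warning("clump: %d records not in LD panel (%s)",
                       len(unresolvable), "dropped" if strict else "kept unclumped")
        if strict:
            unresolvable = []

    remaining = sorted(resolvable, key=lambda r: (r.pval, r.variant_id))
    kept: list[VariantAssoc] = []
    while remaining:
        index = remaining.pop(0)
        kept.append(index)
        survivors = []
        for rec in remaining:
            same_chrom = (
                index.chrom is not None and rec.chrom is not None and rec.chrom == index.chrom
            )
            in_window = (
                same_chrom
                and index.pos is not None
                and rec.pos is not None
                and abs(rec.pos - index.pos) <= window_bp
            )
            if in_window and ld.r2(index.variant_id, rec.variant_id) >= r2_thresh:
                continue
            survivors.append(rec)
        remaining = survivors

    out = kept + unresolvable
    return sorted(out, key=lambda r: (r.chrom or "", r.pos or 0, r.variant_id))


def proxy_lookup(
    missing: VariantAssoc,
    outcome: SumStats,
    ld: LDMatrix,
    r2_min: float = DEFAULT_PROXY_R2,
) -> tuple[VariantAssoc, VariantAssoc] | None:
    """Find an LD proxy in the outcome for an instrument the outcome lacks.

    Returns ``(re_signed_exposure_record, outcome_proxy_record)`` for the
    outcome record with maximal r2 >= r2_min, or None. When the LD
    correlation r is negative the exposure beta is sign-flipped (and eaf
    complemented) so the proxy's allele dosage tracks the instrument.
    """
    if missing.variant_id not in ld:
        return None
    best: tuple[float, VariantAssoc] | None = None
    for rec in outcome.records:
        if rec.variant_id == missing.variant_id or rec.variant_id not in ld:
            continue
        r2 = ld.r2(missing.variant_id, rec.variant_id)
        if r2 >= r2_min and (best is None or r2 > best[0]):
            best = (r2, rec)
    if best is None:
        return None
    proxy = best[1]
    r = ld.corr(missing.variant_id, proxy.variant_id)
    exp_rec = missing
    if r < 0:
        exp_rec = replace(
            missing,
            beta=-missing.beta,
            eaf=None if missing.eaf is None else 1.0 - missing.eaf,
        )
    exp_rec = replace(
        exp_rec,
        variant_id=proxy.variant_id,
        effect_allele=proxy.effect_allele,
        other_allele=proxy.other_allele,
        chrom=proxy.chrom,
        pos=proxy.pos,
    )
    return exp_rec, proxy


def _orient_pair(
    e: VariantAssoc, o: VariantAssoc, band: float
) -> tuple[VariantAssoc | None, str]:
    """Align one outcome record to the exposure's effect allele.

    Returns (aligned outcome record or None, action tag), where the tag is
    one of kept/flipped/dropped_palindrome/dropped_incompatible.
    """
    ea, oa = e.effect_allele, e.other_allele

    if _is_palindromic(ea, oa):
        if {o.effect_allele, o.other_allele} != {ea, oa}:
            return None, "dropped_incompatible"
        if e.eaf is None or o.eaf is None:
            return None, "dropped_palindrome"
        lo, hi = band, 1.0 - band
        if lo <= e.eaf <= hi or lo <= o.eaf <= hi:
            return None, "dropped_palindrome"
        # nominal orientation by labels, then frequency agreement decides
        if o.effect_allele == ea:
            cand, flipped = o, False
        else:
            cand, flipped = _swap_alleles(o), True
        if (e.eaf - 0.5) * ((cand.eaf if cand.eaf is not None else 0.5) - 0.5) < 0:
            cand, flipped = _swap_alleles_keep_labels(cand), not flipped
        return cand, ("flipped" if flipped else "kept")

    # non-palindromic: try direct, swapped, then strand-complemented forms
    if {o.effect_allele, o.other_allele} == {ea, oa}:
        aligned = o if o.effect_allele == ea else _swap_alleles(o)
        return aligned, ("kept" if o.effect_allele == ea else "flipped")

    cea, coa = _complement_allele(o.effect_allele), _complement_allele(o.other_allele)
    if cea is not None and coa is not None and {cea, coa} == {ea, oa}:
        o2 = replace(o, effect_allele=cea, other_allele=coa)
        aligned = o2 if o2.effect_allele == ea else _swap_alleles(o2)
        return aligned, ("kept" if o2.effect_allele == ea else "flipped")

    return None, "dropped_incompatible"


def _swap_alleles(o: VariantAssoc) -> VariantAssoc:
    return replace(
        o,
        effect_allele=o.other_allele,
        other_allele=o.effect_allele,
        beta=-o.beta,
        eaf=None if o.eaf is None else 1.0 - o.eaf,
    )


def _swap_alleles_keep_labels(o: VariantAssoc) -> VariantAssoc:
    # palindromic strand flip: labels already match the exposure, only the
    # effect direction and frequency change
    return replace(o, beta=-o.beta, eaf=None if o.eaf is None else 1.0 - o.eaf)


def harmonize(
    exp_records: list[VariantAssoc],
    out_records: list[VariantAssoc],
    palindrome_maf_band: float = DEFAULT_PALINDROME_MAF_BAND,
    exposure_id: str = "exposure",
    outcome_id: str = "outcome",
    n_exp: int | None = None,
    n_out: int | None = None,
    proxies_used: dict[str, str] | None = None,
) -> HarmonizedSet:
    """Align paired exposure/outcome records to a common effect allele.

    ``exp_records`` and ``out_records`` must be paired positionally by
    variant_id. Palindromic variants are resolved by allele-frequency
    agreement when both frequencies fall outside
    [band, 1-band]; otherwise they are dropped and counted.

    Raises ``ValueError`` when no pair survives.
    """
    if len(exp_records) != len(out_records):
        raise ValueError("exposure and outcome record lists must be paired")
    ids, bx, sx, by, sy, fx = [], [], [], [], [], []
    pairs: list[tuple[VariantAssoc, VariantAssoc]] = []
    flips = dropped_pal = dropped_bad = 0
    for e, o in zip(exp_records, out_records):
        if e.variant_id != o.variant_id:
            raise ValueError(f"record pair mismatch: {e.variant_id} vs {o.variant_id}")
        aligned, action = _orient_pair(e, o, palindrome_maf_band)
        if aligned is None:
            if action == "dropped_palindrome":
                dropped_pal += 1
            else:
                dropped_bad += 1
            continue
        if action == "flipped":
            flips += 1
        ids.append(e.variant_id)
        bx.append(e.beta)
        sx.append(e.se)
        by.append(aligned.beta)
        sy.append(aligned.se)
        fx.append(np.nan if e.eaf is None else e.eaf)
        pairs.append((e, aligned))
    if dropped_bad:
        logger.warning("harmonize: dropped %d incompatible allele pairs", dropped_bad)
    if not ids:
        raise ValueError("no harmonizable instruments")
    return HarmonizedSet(
        exposure_id=exposure_id,
        outcome_id=outcome_id,
        variant_ids=ids,
        beta_exp=np.array(bx),
        se_exp=np.array(sx),
        beta_out=np.array(by),
        se_out=np.array(sy),
        eaf_exp=np.array(fx),
        n_exp=n_exp,
        n_out=n_out,
        flips=flips,
        dropped_palindromes=dropped_pal,
        proxies_used=dict(proxies_used or {}),
        pairs=pairs,
    )
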