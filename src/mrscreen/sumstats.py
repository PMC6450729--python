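"""GWAS summary-statistics data model and I/O.

Tables are headered, tab- or whitespace-delimited, one row per variant.
Coordinates are 1-based inclusive; the genome build is carried as metadata
only (default GRCh37). Alleles are upper-cased on read; indel alleles are
kept verbatim. Multi-allelic records are not representable: each record
carries exactly two alleles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default header-name -> field mapping accepted by :func:`read_sumstats`.
DEFAULT_COLUMN_MAP = {
    "SNP": "variant_id",
    "CHR": "chrom",
    "BP": "pos",
    "A1": "effect_allele",
    "A2": "other_allele",
    "FRQ": "eaf",
    "EAF": "eaf",
    "BETA": "beta",
    "SE": "se",
    "P": "pval",
    "N": "n",
}

MANDATORY_FIELDS = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pval")


@dataclass(frozen=True)
class VariantAssoc:
    """One variant's association summary in one GWAS.

    ``beta`` is a per-allele log-odds ratio for binary traits and a
    per-unit effect for quantitative traits.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    n: int | None = None

    def is_valid(self) -> bool:
        """Check the record-level invariants."""
        if not np.isfinite(self.beta) or not np.isfinite(self.se) or self.se <= 0:
            return False
        if not (0.0 < self.pval <= 1.0):
            return False
        if self.effect_allele == self.other_allele:
            return False
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            return False
        return True

    @property
    def zscore(self) -> float:
        return self.beta / self.se


@dataclass
class SumStats:
    """A full summary-statistics table for one trait."""

    trait_id: str
    records: list[VariantAssoc] = field(default_factory=list)
    trait_type: str = "quantitative"  # "binary" or "quantitative"
    n: int | None = None
    n_cases: int | None = None
    n_controls: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "quantitative"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        self.metadata.setdefault("build", "GRCh37")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_id(self) -> dict[str, VariantAssoc]:
        return {r.variant_id: r for r in self.records}

    def sample_size(self, rec: VariantAssoc) -> int | None:
        """Per-row n takes precedence over the trait-level n."""
        if rec.n is not None:
            return rec.n
        if self.n is not None:
            return self.n
        if self.n_cases is not None and self.n_controls is not None:
            return self.n_cases + self.n_controls
        return None


def _coerce_row(row: dict) -> VariantAssoc | None:
    try:
        eaf = row.get("eaf")
        eaf = None if eaf is None or pd.isna(eaf) else float(eaf)
        n = row.get("n")
        n = None if n is None or pd.isna(n) else int(n)
        pos = row.get("pos")
        pos = None if pos is None or pd.isna(pos) else int(pos)
        chrom = row.get("chrom")
        chrom = None if chrom is None or pd.isna(chrom) else str(chrom)
        rec = VariantAssoc(
            variant_id=str(row["variant_id"]),
            chrom=chrom,
            pos=pos,
            effect_allele=str(row["effect_allele"]).upper(),
            other_allele=str(row["other_allele"]).upper(),
            eaf=eaf,
            beta=float(row["beta"]),
            se=float(row["se"]),
            pval=float(row["pval"]),
            n=n,
        )
    except (TypeError, ValueError):
        return None
    return rec if rec.is_valid() else None


def read_sumstats(
    path,
    column_map: dict[str, str] | None = None,
    trait_meta: dict | None = None,
) -> SumStats:
    """Read a summary-statistics table into a validated :class:`SumStats`.

    Rows violating record invariants (se<=0, p outside (0,1], identical
    alleles, eaf outside [0,1], unparseable numbers) are dropped and
    tallied in ``metadata["dropped_rows"]``. Duplicate variant ids keep
    the row with the smallest p-value.

    Raises
    ------
    ValueError
        If any mandatory column (variant_id, effect_allele, other_allele,
        beta, se, pval) cannot be located in the header.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    meta = dict(trait_meta or {})

    df = pd.read_csv(path, sep=r"\s+")
    rename = {c: cmap[c] for c in df.columns if c in cmap}
    df = df.rename(columns=rename)
    for col in MANDATORY_FIELDS:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column: {col}")

    records: list[VariantAssoc] = []
    dropped = 0
    for row in df.to_dict("records"):
        rec = _coerce_row(row)
        if rec is None:
            dropped += 1
        else:
            records.append(rec)

    # dedup on variant_id, keeping smallest p-value
    best: dict[str, VariantAssoc] = {}
    order: list[str] = []
    for rec in records:
        cur = best.get(rec.variant_id)
        if cur is None:
            best[rec.variant_id] = rec
            order.append(rec.variant_id)
        elif rec.pval < cur.pval:
            dropped += 1
            best[rec.variant_id] = rec
        else:
            dropped += 1
    records = [best[v] for v in order]

    ss = SumStats(
        trait_id=str(meta.pop("trait_id", "trait")),
        records=records,
        trait_type=meta.pop("trait_type", "quantitative"),
        n=meta.pop("n", None),
        n_cases=meta.pop("n_cases", None),
        n_controls=meta.pop("n_controls", None),
        metadata=meta,
    )
    ss.metadata["dropped_rows"] = str(dropped)
    if dropped:
        logger.info("read_sumstats(%s): dropped %d invalid/duplicate rows", path, dropped)
    return ss


def write_sumstats(ss: SumStats, path) -> None:
    """Write a SumStats back to the TSV dialect read_sumstats consumes.

    Floats carry >=10 significant digits so read/write round-trips are
    lossless for every retained field.
    """
    rows = []
    for r in ss.records:
        rows.append(
            {
                "SNP": r.variant_id,
                "CHR": r.chrom if r.chrom is not None else "NA",
                "BP": r.pos if r.pos is not None else "NA",
                "A1": r.effect_allele,
                "A2": r.other_allele,
                "EAF": "NA" if r.eaf is None else f"{r.eaf:.12g}",
                "BETA": f"{r.beta:.12g}",
                "SE": f"{r.se:.12g}",
                "P": f"{r.pval:.12g}",
                "N": r.n if r.n is not None else "NA",
            }
        )
    pd.DataFrame(
        rows, columns=["SNP", "CHR", "BP", "A1", "A2", "EAF", "BETA", "SE", "P", "N"]
    ).to_csv(path, sep="\t", index=False)


def intersect(a: SumStats, b: SumStats) -> list[tuple[VariantAssoc, VariantAssoc]]:
    """Pair records present in both tables, matched on variant_id.

    Order follows ``a``. No allele logic is applied here; harmonization
    is a separate step. An empty intersection returns an empty list.
    """
    b_ids = b.by_id()
    return [(ra, b_ids[ra.variant_id]) for ra in a.records if ra.variant_id in b_ids]


def rescale(rec: VariantAssoc, **changes) -> VariantAssoc:
    """Return a copy of ``rec`` with the given fields replaced."""
    return replace(rec, **changes)
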