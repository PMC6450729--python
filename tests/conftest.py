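import numpy as np
import pytest

from mrscreen import HarmonizedSet, SumStats, VariantAssoc


def make_variant(vid="rs1", ea="A", oa="G", beta=0.1, se=0.02, pval=1e-9,
                 chrom="1", pos=1000, eaf=0.3, n=10_000):
    return VariantAssoc(
        variant_id=vid, chrom=chrom, pos=pos, effect_allele=ea, other_allele=oa,
        eaf=eaf, beta=beta, se=se, pval=pval, n=n,
    )


def make_hset(beta_exp, beta_out, se_out, se_exp=None, n_exp=100_000, n_out=100_000):
    beta_exp = np.asarray(beta_exp, dtype=float)
    k = len(beta_exp)
    return HarmonizedSet(
        exposure_id="exp", outcome_id="out",
        variant_ids=[f"rs{i + 1}" for i in range(k)],
        beta_exp=beta_exp,
        se_exp=np.full(k, 0.01) if se_exp is None else np.asarray(se_exp, dtype=float),
        beta_out=np.asarray(beta_out, dtype=float),
        se_out=np.asarray(se_out, dtype=float),
        n_exp=n_exp, n_out=n_out,
    )


@pytest.fixture
def sumstats_file(tmp_path):
    """Write a small well-formed sumstats TSV and return its path."""

    def _write(rows, name="sumstats.tsv", header=None):
        header = header or ["SNP", "CHR", "BP", "A1", "A2", "EAF", "BETA", "SE", "P", "N"]
        lines = ["\t".join(header)]
        for row in rows:
            lines.append("\t".join(str(x) for x in row))
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture
def five_row_table(sumstats_file):
    rows = [
        [f"rs{i}", 1, 1000 * i, "A", "G", 0.3, 0.1 * i, 0.02, 1e-5, 5000]
        for i in range(1, 6)
    ]
    return sumstats_file(rows)


def make_sumstats(records, trait_id="trait", n=10_000, trait_type="quantitative"):
    return SumStats(trait_id=trait_id, records=list(records), n=n, trait_type=trait_type)
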