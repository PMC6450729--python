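import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrscreen import LDMatrix, clump, harmonize, ivw, proxy_lookup, select_instruments
from mrscreen.harmonize import DEFAULT_PALINDROME_MAF_BAND

from conftest import make_sumstats, make_variant


def ld_from(ids, r, positions=None):
    positions = positions or {v: ("1", 1000 * (i + 1)) for i, v in enumerate(ids)}
    return LDMatrix(list(ids), np.asarray(r, dtype=float), positions)


class TestSelectInstruments:
    def test_threshold_count(self):
        recs = [make_variant(vid=f"sig{i}", pval=1e-9) for i in range(3)]
        recs += [make_variant(vid=f"weak{i}", pval=1e-4) for i in range(100)]
        sel = select_instruments(make_sumstats(recs), p_thresh=5e-8)
        assert len(sel.records) == 3
        assert sel.eligible

    def test_single_hit_is_ineligible(self):
        recs = [make_variant(vid="rs1", pval=1e-9), make_variant(vid="rs2", pval=1e-3)]
        sel = select_instruments(make_sumstats(recs))
        assert not sel.eligible
        assert len(sel.records) == 1

    def test_p_thresh_one_returns_all(self):
        recs = [make_variant(vid=f"rs{i}", pval=0.5) for i in range(5)]
        sel = select_instruments(make_sumstats(recs), p_thresh=1.0)
        assert len(sel.records) == 5

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            select_instruments(make_sumstats([make_variant()]), p_thresh=2.0)


def brute_force_clump(records, ld, r2_thresh, window_kb):
    """Independent p-value-priority reference: repeatedly take the smallest-p
    remaining record and delete its in-window LD partners."""
    window_bp = window_kb * 1000
    pool = {r.variant_id: r for r in records}
    kept = []
    while pool:
        best = min(pool.values(), key=lambda r: (r.pval, r.variant_id))
        kept.append(best)
        del pool[best.variant_id]
        for vid in list(pool):
            r = pool[vid]
            if (
                r.chrom == best.chrom
                and abs(r.pos - best.pos) <= window_bp
                and vid in ld
                and best.variant_id in ld
                and ld.r2(best.variant_id, vid) >= r2_thresh
            ):
                del pool[vid]
    return sorted(kept, key=lambda r: (r.chrom or "", r.pos or 0, r.variant_id))


class TestClump:
    def test_two_correlated_variants_keep_best_p(self):
        a = make_variant(vid="rs1", pos=1000, pval=1e-10)
        b = make_variant(vid="rs2", pos=2000, pval=1e-8)
        ld = ld_from(["rs1", "rs2"], [[1, 0.94868], [0.94868, 1]])  # r2 = 0.9
        kept = clump([a, b], ld, r2_thresh=0.001)
        assert [r.variant_id for r in kept] == ["rs1"]

    def test_window_is_intra_chromosomal(self):
        a = make_variant(vid="rs1", chrom="1", pos=1000, pval=1e-10)
        b = make_variant(vid="rs2", chrom="2", pos=1000, pval=1e-8)
        ld = ld_from(["rs1", "rs2"], [[1, 0.995], [0.995, 1]])
        kept = clump([a, b], ld)
        assert len(kept) == 2

    def test_independent_variants_all_kept(self):
        recs = [make_variant(vid=f"rs{i}", pos=1000 * i, pval=10**-(9 + i)) for i in range(1, 6)]
        ld = ld_from([r.variant_id for r in recs], np.eye(5))
        assert len(clump(recs, ld)) == 5

    def test_bad_r2(self):
        with pytest.raises(ValueError):
            clump([make_variant()], None, r2_thresh=0.0)

    def test_unresolvable_records_kept(self):
        a = make_variant(vid="rs1", pos=1000, pval=1e-10)
        b = make_variant(vid="zz9", pos=2000, pval=1e-8)  # not in panel
        ld = ld_from(["rs1"], [[1.0]])
        assert len(clump([a, b], ld)) == 2

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for trial in range(20):
            k = int(rng.integers(2, 13))
            ids = [f"rs{i}" for i in range(k)]
            pos = np.sort(rng.integers(1, 5_000_000, size=k))
            chol = rng.normal(size=(k, k))
            cov = chol @ chol.T + np.eye(k)
            d = np.sqrt(np.diag(cov))
            r = cov / np.outer(d, d)
            ld = ld_from(ids, r, {v: ("1", int(p)) for v, p in zip(ids, pos)})
            recs = [
                make_variant(vid=v, pos=int(p), pval=float(pv))
                for v, p, pv in zip(ids, pos, rng.uniform(1e-12, 1e-6, k))
            ]
            got = clump(recs, ld, r2_thresh=0.1, window_kb=10_000)
            want = brute_force_clump(recs, ld, 0.1, 10_000)
            assert [g.variant_id for g in got] == [w.variant_id for w in want]

    @given(st.permutations(list(range(8))))
    @settings(max_examples=25, deadline=None)
    def test_order_invariance(self, perm):
        rng = np.random.default_rng(7)
        ids = [f"rs{i}" for i in range(8)]
        pos = list(range(1000, 9000, 1000))
        r = np.eye(8)
        r[0, 1] = r[1, 0] = 0.9
        r[2, 3] = r[3, 2] = -0.8
        ld = ld_from(ids, r, {v: ("1", p) for v, p in zip(ids, pos)})
        pvals = rng.uniform(1e-10, 1e-7, 8)
        recs = [make_variant(vid=v, pos=p, pval=float(pv)) for v, p, pv in zip(ids, pos, pvals)]
        base = [x.variant_id for x in clump(recs, ld, r2_thresh=0.5)]
        shuffled = [x.variant_id for x in clump([recs[i] for i in perm], ld, r2_thresh=0.5)]
        assert base == shuffled


class TestProxyLookup:
    def _setup(self, r12, r13):
        ids = ["rs1", "rs2", "rs3"]
        r = np.eye(3)
        r[0, 1] = r[1, 0] = r12
        r[0, 2] = r[2, 0] = r13
        ld = ld_from(ids, r)
        missing = make_variant(vid="rs1", beta=0.2)
        outcome = make_sumstats(
            [make_variant(vid="rs2", pos=2000), make_variant(vid="rs3", pos=3000)]
        )
        return missing, outcome, ld

    def test_argmax_over_candidates(self):
        missing, outcome, ld = self._setup(np.sqrt(0.95), np.sqrt(0.85))
        result = proxy_lookup(missing, outcome, ld)
        assert result is not None
        assert result[1].variant_id == "rs2"

    def test_below_threshold_none(self):
        missing, outcome, ld = self._setup(np.sqrt(0.5), np.sqrt(0.4))
        assert proxy_lookup(missing, outcome, ld) is None

    def test_negative_r_flips_exposure_sign(self):
        missing, outcome, ld = self._setup(-0.95, 0.0)
        exp_rec, proxy = proxy_lookup(missing, outcome, ld)
        assert proxy.variant_id == "rs2"
        assert exp_rec.beta == pytest.approx(-0.2)
        assert exp_rec.variant_id == "rs2"


class TestHarmonize:
    def test_same_orientation_kept(self):
        e = make_variant(ea="A", oa="G", beta=0.1)
        o = make_variant(ea="A", oa="G", beta=0.05)
        h = harmonize([e], [o])
        assert h.beta_out[0] == pytest.approx(0.05)
        assert h.flips == 0

    def test_swapped_alleles_negated(self):
        e = make_variant(ea="A", oa="G", beta=0.1)
        o = make_variant(ea="G", oa="A", beta=0.05, eaf=0.7)
        h = harmonize([e], [o])
        assert h.beta_out[0] == pytest.approx(-0.05)
        assert h.flips == 1

    def test_strand_complement_resolved(self):
        e = make_variant(ea="A", oa="G", beta=0.1)
        o = make_variant(ea="T", oa="C", beta=0.05)
        h = harmonize([e], [o])
        assert h.beta_out[0] == pytest.approx(0.05)

    def test_strand_complement_and_swap(self):
        e = make_variant(ea="A", oa="G", beta=0.1)
        o = make_variant(ea="C", oa="T", beta=0.05, eaf=0.7)
        h = harmonize([e], [o])
        assert h.beta_out[0] == pytest.approx(-0.05)

    def test_ambiguous_palindrome_dropped(self):
        # all four orientation hypotheses are indistinguishable at eaf 0.5
        e = make_variant(vid="rs1", ea="A", oa="T", eaf=0.50)
        o = make_variant(vid="rs1", ea="A", oa="T", eaf=0.50)
        keeper_e = make_variant(vid="rs2", ea="A", oa="G")
        keeper_o = make_variant(vid="rs2", ea="A", oa="G")
        h = harmonize([e, keeper_e], [o, keeper_o])
        assert h.dropped_palindromes == 1
        assert h.variant_ids == ["rs2"]

    def test_palindrome_resolved_by_frequency(self):
        e = make_variant(ea="A", oa="T", eaf=0.10, beta=0.1)
        o = make_variant(ea="A", oa="T", eaf=0.12, beta=0.05)
        h = harmonize([e], [o])
        assert h.beta_out[0] == pytest.approx(0.05)
        # disagreeing frequency implies the other strand: effect flips
        o2 = make_variant(ea="A", oa="T", eaf=0.88, beta=0.05)
        h2 = harmonize([e], [o2])
        assert h2.beta_out[0] == pytest.approx(-0.05)

    def test_incompatible_alleles_dropped(self):
        e = make_variant(vid="rs1", ea="A", oa="G")
        o = make_variant(vid="rs1", ea="A", oa="C")
        keeper_e = make_variant(vid="rs2")
        keeper_o = make_variant(vid="rs2")
        h = harmonize([e, keeper_e], [o, keeper_o])
        assert h.variant_ids == ["rs2"]

    def test_no_survivors_raises(self):
        e = make_variant(ea="A", oa="T", eaf=0.5)
        o = make_variant(ea="A", oa="T", eaf=0.5)
        with pytest.raises(ValueError, match="no harmonizable"):
            harmonize([e], [o])

    def test_idempotent(self):
        exps = [
            make_variant(vid="rs1", ea="A", oa="G", beta=0.1),
            make_variant(vid="rs2", ea="C", oa="T", beta=-0.2, eaf=0.2),
            make_variant(vid="rs3", ea="A", oa="T", eaf=0.1, beta=0.3),
        ]
        outs = [
            make_variant(vid="rs1", ea="G", oa="A", beta=0.05, eaf=0.7),
            make_variant(vid="rs2", ea="G", oa="A", beta=0.02),
            make_variant(vid="rs3", ea="T", oa="A", eaf=0.85, beta=0.01),
        ]
        h1 = harmonize(exps, outs)
        aligned_out = [p[1] for p in h1.pairs]
        aligned_exp = [p[0] for p in h1.pairs]
        h2 = harmonize(aligned_exp, aligned_out)
        assert h2.flips == 0
        np.testing.assert_allclose(h1.beta_out, h2.beta_out)
        np.testing.assert_allclose(h1.beta_exp, h2.beta_exp)

    def test_orientation_gauge_invariance(self):
        # flipping both studies' allele labels for one variant leaves the
        # downstream estimate unchanged
        exps = [make_variant(vid=f"rs{i}", beta=0.1 * i, pval=1e-9, pos=i * 1000)
                for i in range(1, 4)]
        outs = [make_variant(vid=f"rs{i}", beta=0.02 * i, pos=i * 1000)
                for i in range(1, 4)]
        h1 = harmonize(exps, outs)
        flip = lambda v: make_variant(
            vid=v.variant_id, ea=v.other_allele, oa=v.effect_allele,
            beta=-v.beta, eaf=1 - v.eaf, pos=v.pos,
        )
        h2 = harmonize([flip(exps[0])] + exps[1:], [flip(outs[0])] + outs[1:])
        r1, _ = ivw(h1)
        r2, _ = ivw(h2)
        assert r1.beta == pytest.approx(r2.beta, rel=1e-12)
        assert r1.se == pytest.approx(r2.se, rel=1e-12)

    def test_band_boundary(self):
        lo = DEFAULT_PALINDROME_MAF_BAND
        e = make_variant(ea="A", oa="T", eaf=lo - 0.01)
        o = make_variant(ea="A", oa="T", eaf=lo - 0.01)
        assert harmonize([e], [o]).dropped_palindromes == 0


class TestLDMatrix:
    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError):
            LDMatrix(["a", "b"], np.array([[1.0, 0.5], [0.2, 1.0]]))

    def test_rejects_bad_diagonal(self):
        with pytest.raises(ValueError):
            LDMatrix(["a", "b"], np.array([[2.0, 0.0], [0.0, 1.0]]))

    def test_triplet_roundtrip(self, tmp_path):
        trip = tmp_path / "trip.tsv"
        trip.write_text("id_a\tid_b\tr\nrs1\trs2\t0.5\n")
        panel = tmp_path / "panel.tsv"
        panel.write_text("id\tchrom\tpos\nrs1\t1\t100\nrs2\t1\t200\n")
        ld = LDMatrix.from_triplets(trip, panel)
        assert ld.r2("rs1", "rs2") == pytest.approx(0.25)
        assert ld.positions["rs2"] == ("1", 200)
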