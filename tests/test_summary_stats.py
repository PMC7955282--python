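"""Parsing, validation, harmonization, clumping and filtering."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrmed import (ConfigurationError, LDInfo, ValidationError, clump,
                   harmonize, is_palindromic, read_ld_matrix,
                   read_summary_stats, rescale_to_sd, select_instruments,
                   write_summary_stats)
from mrmed.summary_stats import VariantAssociation, two_sided_p

from conftest import make_assoc


# ---------------------------------------------------------------------------
# VariantAssociation and file IO
# ---------------------------------------------------------------------------

class TestVariantAssociation:
    def test_identity_parse(self, tmp_path):
        p = tmp_path / "stats.tsv"
        p.write_text("snp\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tn\n"
                     "rs1\tA\tG\t0.3\t0.10\t0.01\t1e-20\t100000\n")
        (a,) = read_summary_stats(p)
        assert (a.variant_id, a.effect_allele, a.other_allele) == ("rs1", "A", "G")
        assert (a.eaf, a.beta, a.se, a.pvalue, a.n) == (0.3, 0.10, 0.01, 1e-20, 100000)

    def test_duplicate_id_raises(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("snp\teffect_allele\tother_allele\tbeta\tse\n"
                     "rs1\tA\tG\t0.1\t0.01\nrs1\tA\tG\t0.2\t0.01\n")
        with pytest.raises(ValidationError, match="rs1"):
            read_summary_stats(p)

    def test_nonpositive_se_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("snp\teffect_allele\tother_allele\tbeta\tse\n"
                     "rs9\tA\tG\t0.1\t0.0\n")
        with pytest.raises(ValidationError):
            read_summary_stats(p)
        with pytest.raises(ValidationError):
            make_assoc(se=0.0)

    def test_missing_column_is_configuration_error(self, tmp_path):
        p = tmp_path / "noc.tsv"
        p.write_text("snp\teffect_allele\tbeta\tse\nrs1\tA\t0.1\t0.01\n")
        with pytest.raises(ConfigurationError, match="other_allele"):
            read_summary_stats(p)

    def test_column_map_and_missing_rows_dropped(self, tmp_path):
        p = tmp_path / "mapped.tsv"
        p.write_text("rsid\tA1\tA2\tb\tstderr\n"
                     "rs1\tA\tG\t0.1\t0.01\n"
                     "rs2\tT\tC\t\t0.01\n")
        recs = read_summary_stats(p, column_map={
            "snp": "rsid", "effect_allele": "A1", "other_allele": "A2",
            "beta": "b", "se": "stderr"})
        assert [a.variant_id for a in recs] == ["rs1"]

    def test_missing_p_recomputed_two_sided_normal(self):
        a = make_assoc(beta=0.1, se=0.05)
        assert a.pvalue == pytest.approx(two_sided_p(0.1, 0.05))
        assert a.pvalue == pytest.approx(0.0455, abs=1e-4)

    def test_inconsistent_p_rejected(self):
        # z = 10 implies p ~ 1.5e-23; p = 0.5 is wildly inconsistent
        with pytest.raises(ValidationError, match="inconsistent"):
            make_assoc(beta=0.1, se=0.01, pvalue=0.5)

    def test_invalid_alleles_rejected(self):
        with pytest.raises(ValidationError):
            make_assoc(ea="N")
        with pytest.raises(ValidationError):
            make_assoc(ea="A", oa="A")

    def test_roundtrip(self, tmp_path):
        recs = [make_assoc("rs1", beta=0.2, se=0.03, eaf=0.4, n=1000),
                make_assoc("rs2", "T", "C", beta=-0.1, se=0.02)]
        p = tmp_path / "out.tsv"
        write_summary_stats(recs, p)
        back = read_summary_stats(p)
        assert [(a.variant_id, a.beta, a.se) for a in back] == \
               [(a.variant_id, a.beta, a.se) for a in recs]


@pytest.mark.parametrize("a1,a2,expected", [
    ("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
    ("A", "G", False), ("A", "C", False), ("T", "G", False), ("C", "T", False),
])
def test_is_palindromic(a1, a2, expected):
    assert is_palindromic(a1, a2) is expected


def test_is_palindromic_rejects_bad_bases():
    with pytest.raises(ValidationError):
        is_palindromic("A", "N")
    with pytest.raises(ValidationError):
        is_palindromic("A", "A")


# ---------------------------------------------------------------------------
# instrument selection
# ---------------------------------------------------------------------------

class TestSelectInstruments:
    def _mk(self, pvals):
        # betas chosen so each beta/se implies the stated p-value
        from scipy import stats
        out = []
        for i, p in enumerate(pvals):
            z = stats.norm.isf(p / 2)
            out.append(make_assoc(f"rs{i+1}", beta=z * 0.01, se=0.01, pvalue=p))
        return out

    def test_strict_inequality_at_threshold(self):
        recs = self._mk([1e-9, 4.9e-8, 5e-8, 1e-3])
        kept = select_instruments(recs, 5e-8)
        assert [a.variant_id for a in kept] == ["rs1", "rs2"]

    def test_none_significant(self):
        assert select_instruments(self._mk([0.5, 0.5]), 5e-8) == []

    def test_threshold_one_keeps_all(self):
        recs = self._mk([0.5, 0.9, 1e-3])
        assert select_instruments(recs, 1.0) == recs


# ---------------------------------------------------------------------------
# clumping
# ---------------------------------------------------------------------------

def _ld(ids, r2):
    return LDInfo(tuple(ids), np.asarray(r2, dtype=float))


class TestClump:
    def test_greedy_rule(self):
        recs = [make_assoc("v1", beta=0.13, se=0.02, pvalue=1e-10),
                make_assoc("v2", beta=0.12, se=0.02, pvalue=1e-9),
                make_assoc("v3", beta=0.115, se=0.02, pvalue=1e-8)]
        ld = _ld(["v1", "v2", "v3"],
                 [[1, 0.5, 0], [0.5, 1, 0], [0, 0, 1]])
        kept = clump(recs, ld, 0.001)
        assert sorted(a.variant_id for a in kept) == ["v1", "v3"]

    def test_identity_ld_keeps_all(self):
        recs = [make_assoc(f"rs{i}", beta=0.1, se=0.01) for i in range(5)]
        kept = clump(recs, LDInfo.identity([a.variant_id for a in recs]), 0.001)
        assert len(kept) == 5

    def test_single_block_keeps_lowest_p(self):
        # 20 variants in one LD block: exactly one survivor, the best p
        n = 20
        ids = [f"rs{i:02d}" for i in range(n)]
        r2 = np.full((n, n), 0.9)
        np.fill_diagonal(r2, 1.0)
        recs = [make_assoc(ids[i], beta=0.1 + 0.001 * i, se=0.01)
                for i in range(n)]
        best = min(recs, key=lambda a: (a.pvalue, a.variant_id))
        kept = clump(recs, _ld(ids, r2), 0.001)
        assert [a.variant_id for a in kept] == [best.variant_id]

    def test_retained_pairs_below_threshold_brute_force(self, rng):
        # oracle: directly assert the pairwise-r2 guarantee and greedy
        # maximality on random LD structures
        for _ in range(10):
            n = 12
            ids = [f"rs{i:02d}" for i in range(n)]
            a = rng.uniform(0, 1, size=(n, n))
            r2 = (a + a.T) / 2
            np.fill_diagonal(r2, 1.0)
            r2[r2 < 0.3] = 0.0  # sparsify
            recs = [make_assoc(ids[i], beta=rng.uniform(0.05, 0.2), se=0.01)
                    for i in range(n)]
            thr = 0.3
            kept = clump(recs, _ld(ids, r2), thr)
            pos = {v: i for i, v in enumerate(ids)}
            for x, y in itertools.combinations(kept, 2):
                assert r2[pos[x.variant_id], pos[y.variant_id]] < thr
            # greedy maximality: every discarded variant is in LD with a
            # better-ranked retained one
            kept_ids = {a.variant_id for a in kept}
            for rec in recs:
                if rec.variant_id in kept_ids:
                    continue
                assert any(
                    r2[pos[rec.variant_id], pos[k.variant_id]] >= thr
                    and (k.pvalue, k.variant_id) < (rec.pvalue, rec.variant_id)
                    for k in kept)

    def test_order_invariance(self, rng):
        n = 10
        ids = [f"rs{i}" for i in range(n)]
        a = rng.uniform(0, 1, size=(n, n))
        r2 = (a + a.T) / 2
        np.fill_diagonal(r2, 1.0)
        recs = [make_assoc(ids[i], beta=rng.uniform(0.05, 0.2), se=0.01)
                for i in range(n)]
        ld = _ld(ids, r2)
        kept1 = clump(recs, ld, 0.4)
        kept2 = clump(list(reversed(recs)), ld, 0.4)
        assert [a.variant_id for a in kept1] == [a.variant_id for a in kept2]

    def test_rank_p_override(self):
        recs = [make_assoc("v1", beta=0.10, se=0.01),
                make_assoc("v2", beta=0.12, se=0.01)]
        ld = _ld(["v1", "v2"], [[1, 0.9], [0.9, 1]])
        # v2 has the lower own p, but rank_p promotes v1
        kept = clump(recs, ld, 0.001, rank_p={"v1": 1e-30, "v2": 1e-20})
        assert [a.variant_id for a in kept] == ["v1"]

    def test_missing_variant_in_ld_raises(self):
        recs = [make_assoc("v1"), make_assoc("vX")]
        with pytest.raises(ValidationError, match="vX"):
            clump(recs, LDInfo.identity(["v1"]), 0.001)


def test_ld_matrix_validation_and_io(tmp_path):
    with pytest.raises(ValidationError):
        LDInfo(("a", "b"), np.array([[1.0, 0.5], [0.4, 1.0]]))  # asymmetric
    with pytest.raises(ValidationError):
        LDInfo(("a", "b"), np.array([[1.0, 0.5], [0.5, 0.9]]))  # diagonal
    ld = LDInfo(("a", "b"), np.array([[1.0, 0.25], [0.25, 1.0]]))
    import pandas as pd
    pd.DataFrame(ld.r2, index=ld.variant_ids,
                 columns=ld.variant_ids).to_csv(tmp_path / "ld.tsv", sep="\t")
    back = read_ld_matrix(tmp_path / "ld.tsv")
    assert back.variant_ids == ld.variant_ids
    assert np.allclose(back.r2, ld.r2)


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

class TestHarmonize:
    def test_allele_swap_flips_outcome(self):
        exp = [make_assoc("rs1", "A", "G", beta=0.1, se=0.01)]
        out = [make_assoc("rs1", "G", "A", beta=0.05, se=0.02, eaf=0.7)]
        h = harmonize({"x": exp}, out)
        assert h.outcome_betas[0] == pytest.approx(-0.05)
        assert h.effect_alleles == ("A",)

    def test_palindromic_excluded_by_default(self):
        exp = [make_assoc("rs1", "A", "G", beta=0.1, se=0.01),
               make_assoc("rs2", "A", "T", beta=0.1, se=0.01)]
        out = [make_assoc("rs1", "A", "G", beta=0.05, se=0.02),
               make_assoc("rs2", "A", "T", beta=0.05, se=0.02)]
        h = harmonize({"x": exp}, out)
        assert h.variant_ids == ("rs1",)
        h2 = harmonize({"x": exp}, out, drop_palindromic=False)
        assert h2.variant_ids == ("rs1", "rs2")
        assert list(h2.palindromic_flags) == [False, True]

    def test_allele_mismatch_dropped_and_logged(self, caplog):
        exp = [make_assoc("rs3", "A", "G", beta=0.1, se=0.01),
               make_assoc("rs4", "A", "G", beta=0.1, se=0.01)]
        out = [make_assoc("rs3", "A", "C", beta=0.05, se=0.02),
               make_assoc("rs4", "A", "G", beta=0.05, se=0.02)]
        import logging
        with caplog.at_level(logging.INFO, logger="mrmed"):
            h = harmonize({"x": exp}, out)
        assert h.variant_ids == ("rs4",)
        assert any("mismatched" in r.message for r in caplog.records)

    def test_empty_intersection_raises(self):
        with pytest.raises(ValidationError):
            harmonize({"x": [make_assoc("rs1")]}, [make_assoc("rs2")])

    def test_intersection_across_all_traits(self):
        exp1 = [make_assoc("rs1"), make_assoc("rs2")]
        exp2 = [make_assoc("rs2")]
        out = [make_assoc("rs1"), make_assoc("rs2")]
        h = harmonize({"a": exp1, "b": exp2}, out)
        assert h.variant_ids == ("rs2",)
        assert h.n_exposures == 2

    def test_idempotent(self, rng):
        exp = [make_assoc(f"rs{i}", "A", "G", beta=rng.normal(0, 0.1),
                          se=0.01) for i in range(8)]
        # outcome on a randomly swapped allele orientation per variant
        out = []
        for i in range(8):
            if rng.random() < 0.5:
                out.append(make_assoc(f"rs{i}", "A", "G",
                                      beta=rng.normal(), se=0.02))
            else:
                out.append(make_assoc(f"rs{i}", "G", "A",
                                      beta=rng.normal(), se=0.02))
        h1 = harmonize({"x": exp}, out)
        exp2, out2 = h1.to_assoc_lists()
        h2 = harmonize(exp2, out2)
        assert h1.variant_ids == h2.variant_ids
        assert np.allclose(h1.exposure_betas, h2.exposure_betas)
        assert np.allclose(h1.outcome_betas, h2.outcome_betas)

    @given(st.lists(st.tuples(st.floats(-0.5, 0.5), st.floats(0.01, 0.1),
                              st.booleans()),
                    min_size=1, max_size=10))
    def test_sign_flip_equivariance(self, rows):
        # expressing an input trait on the opposite allele leaves the
        # harmonized set unchanged
        exp, out, out_flipped = [], [], []
        for i, (beta, se, flip) in enumerate(rows):
            vid = f"rs{i}"
            exp.append(make_assoc(vid, "A", "G", beta=0.1, se=0.01))
            rec = make_assoc(vid, "A", "G", beta=beta, se=se)
            out.append(rec)
            out_flipped.append(rec.flipped() if flip else rec)
        h1 = harmonize({"x": exp}, out)
        h2 = harmonize({"x": exp}, out_flipped)
        assert h1.variant_ids == h2.variant_ids
        assert np.allclose(h1.outcome_betas, h2.outcome_betas)


# ---------------------------------------------------------------------------
# per-SD rescaling
# ---------------------------------------------------------------------------

class TestRescaleToSD:
    def _hset(self):
        exp = [make_assoc("rs1", beta=0.02, se=0.004)]
        out = [make_assoc("rs1", beta=0.01, se=0.005)]
        return harmonize({"sbp": exp}, out)

    def test_identity_at_sd_one(self):
        h = self._hset()
        h2 = rescale_to_sd(h, [1.0])
        assert np.allclose(h2.exposure_betas, h.exposure_betas)
        assert np.allclose(h2.exposure_ses, h.exposure_ses)

    def test_per_mmhg_to_per_sd(self):
        # systolic blood pressure SD of 18.68 mmHg
        h2 = rescale_to_sd(self._hset(), [18.68])
        assert h2.exposure_betas[0, 0] == pytest.approx(0.3736)
        assert h2.exposure_ses[0, 0] == pytest.approx(0.004 * 18.68)
        assert h2.outcome_betas[0] == pytest.approx(0.01)  # outcome untouched

    def test_zero_sd_rejected(self):
        with pytest.raises(ValidationError):
            rescale_to_sd(self._hset(), [0.0])
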