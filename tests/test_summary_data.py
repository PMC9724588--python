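"""Instrument selection, clumping, and harmonization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrpipe import (
    GwasRecord,
    InstrumentSet,
    LDTable,
    MRError,
    clump,
    f_statistic,
    find_proxy,
    harmonize,
    is_palindromic,
    read_gwas_table,
    select_instruments,
    simulate_two_sample,
    SimulationConfig,
    strength_summary,
    variance_explained,
    write_gwas_table,
)


def rec(snp, beta=0.1, se=0.02, pval=1e-9, ea="A", oa="G", chrom="1", pos=1000,
        eaf=0.3, n=10000):
    return GwasRecord(snp_id=snp, chrom=chrom, pos=pos, effect_allele=ea,
                      other_allele=oa, eaf=eaf, beta=beta, se=se, pval=pval, n=n)


# ---------------------------------------------------------------- reading

class TestReadGwasTable:
    def test_well_formed_rows_all_kept(self, tmp_path):
        path = tmp_path / "t.tsv"
        write_gwas_table([rec("rs1"), rec("rs2"), rec("rs3")], path)
        records, rejections = read_gwas_table(path)
        assert len(records) == 3 and rejections == []

    def test_nonpositive_se_rejected_with_reason(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("SNP\tEA\tOA\tBETA\tSE\tP\nrs1\tA\tG\t0.1\t0\t0.5\nrs2\tA\tG\t0.1\t0.02\t0.5\n")
        records, rejections = read_gwas_table(path)
        assert [r.snp_id for r in records] == ["rs2"]
        assert rejections == [("rs1", "nonpositive se")]

    def test_missing_required_column_is_fatal(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("SNP\tEA\tOA\tBETA\tSE\nrs1\tA\tG\t0.1\t0.02\n")
        with pytest.raises(MRError, match="pval"):
            read_gwas_table(path)

    def test_zero_valid_rows_is_fatal(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("SNP\tEA\tOA\tBETA\tSE\tP\nrs1\tA\tA\t0.1\t0.02\t0.5\n")
        with pytest.raises(MRError, match="zero valid"):
            read_gwas_table(path)

    def test_simulator_output_round_trips(self, tmp_path):
        study = simulate_two_sample(SimulationConfig(seed=5, n_snp=500))
        path = tmp_path / "exp.tsv"
        write_gwas_table(study.exposure_table, path)
        records, rejections = read_gwas_table(path)
        assert rejections == []
        assert records == study.exposure_table  # field-for-field


# ---------------------------------------------------------------- selection

class TestSelectInstruments:
    @pytest.mark.parametrize("threshold,expected", [(5e-8, 1), (1e-5, 2)])
    def test_strict_threshold(self, threshold, expected):
        records = [rec("rs1", pval=1e-9), rec("rs2", pval=1e-7)]
        kept = select_instruments(records, threshold)
        assert len(kept) == expected

    def test_no_survivors_names_threshold(self):
        with pytest.raises(MRError, match="5e-08"):
            select_instruments([rec("rs1", pval=0.5)], 5e-8)

    def test_recovers_true_instruments_at_large_n(self):
        study = simulate_two_sample(
            SimulationConfig(seed=7, n_snp=50, n_exposure_sample=5_000_000)
        )
        kept = select_instruments(study.exposure_table, 5e-8)
        strong = {
            s for s, g, p in zip(
                study.truth["snp_ids"], study.truth["gamma"], study.truth["eaf"]
            )
            # comfortably detectable: |gamma|/se_x > 8
            if abs(g) * np.sqrt(2 * p * (1 - p) * 5_000_000) > 8
        }
        assert strong and strong <= set(kept.snp_ids)


# ---------------------------------------------------------------- clumping

def brute_force_clump(records, ld, r2_max, window_bp):
    """Independent re-statement of greedy clumping over explicit pair checks."""
    chosen = []
    for cand in sorted(records, key=lambda r: (r.pval, r.snp_id)):
        ok = True
        for acc in chosen:
            if cand.chrom == acc.chrom and abs(cand.pos - acc.pos) <= window_bp:
                r2 = ld.get(cand.snp_id, acc.snp_id)
                if r2 is None or r2 >= r2_max:
                    ok = False
        if ok:
            chosen.append(cand)
    return sorted(r.snp_id for r in chosen)


class TestClump:
    def test_outside_window_both_kept(self):
        ld = LDTable()
        ld.add("rs1", "rs2", 0.99)
        inst = InstrumentSet("x", [rec("rs1", pos=1), rec("rs2", pos=2_000_002, pval=1e-8)], 1e-5)
        out = clump(inst, ld, 0.001, 1_000_000)
        assert sorted(out.snp_ids) == ["rs1", "rs2"]

    def test_correlated_within_window_keeps_lower_p(self):
        ld = LDTable()
        ld.add("rs1", "rs2", 0.5)
        inst = InstrumentSet(
            "x", [rec("rs1", pos=1, pval=1e-12), rec("rs2", pos=500_000, pval=1e-8)], 1e-5
        )
        out = clump(inst, ld, 0.001, 1_000_000)
        assert out.snp_ids == ["rs1"]

    def test_absent_pair_within_window_treated_dependent(self):
        inst = InstrumentSet(
            "x", [rec("rs1", pos=1, pval=1e-12), rec("rs2", pos=500_000, pval=1e-8)], 1e-5
        )
        out = clump(inst, None, 0.001, 1_000_000)
        assert out.snp_ids == ["rs1"]

    def test_matches_brute_force_on_block_ld(self, rng):
        ids = [f"rs{i:03d}" for i in range(50)]
        records = [
            rec(ids[i], chrom=str(i // 10 + 1), pos=int(rng.integers(1, 3_000_000)),
                pval=float(rng.uniform(1e-30, 1e-8)))
            for i in range(50)
        ]
        ld = LDTable()
        for i in range(50):
            for k in range(i + 1, 50):
                if rng.random() < 0.5:
                    ld.add(ids[i], ids[k], float(rng.random()))
        inst = InstrumentSet("x", records, 1e-5)
        out = clump(inst, ld, 0.1, 1_000_000)
        assert sorted(out.snp_ids) == brute_force_clump(records, ld, 0.1, 1_000_000)

    def test_order_invariance(self, rng):
        records = [
            rec(f"rs{i}", chrom="1", pos=int(rng.integers(1, 2_000_000)),
                pval=float(rng.uniform(1e-20, 1e-8)))
            for i in range(20)
        ]
        inst_a = InstrumentSet("x", records, 1e-5)
        inst_b = InstrumentSet("x", records[::-1], 1e-5)
        assert clump(inst_a, None).snp_ids == clump(inst_b, None).snp_ids


# ---------------------------------------------------------------- palindromes & proxies

@pytest.mark.parametrize(
    "ea,oa,expected",
    [("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
     ("A", "G", False), ("C", "T", False), ("a", "t", True)],
)
def test_is_palindromic(ea, oa, expected):
    assert is_palindromic(ea, oa) is expected


class TestFindProxy:
    def setup_method(self):
        self.ld = LDTable()
        self.ld.add("rs1", "rsA", 0.95)
        self.ld.add("rs1", "rsB", 0.7)
        self.ld.add("rs2", "rsC", 0.75)
        self.ld.add("rs3", "rsD", 0.85)
        self.ld.add("rs3", "rsE", 0.92)

    def test_single_partner_above_threshold(self):
        assert find_proxy("rs1", ["rsA", "rsB"], self.ld) == "rsA"

    def test_all_below_threshold_returns_none(self):
        assert find_proxy("rs2", ["rsC"], self.ld) is None

    def test_highest_r2_wins(self):
        assert find_proxy("rs3", ["rsD", "rsE"], self.ld) == "rsE"

    def test_partner_must_be_outcome_present(self):
        assert find_proxy("rs3", ["rsD"], self.ld) == "rsD"


# ---------------------------------------------------------------- harmonization

class TestHarmonize:
    def base_sets(self):
        exp = InstrumentSet(
            "exp",
            [rec("rs1", beta=0.1), rec("rs2", beta=-0.2), rec("rs3", beta=0.15),
             rec("rs4", beta=0.12)],
            5e-8,
        )
        out = [rec("rs1", beta=0.05, pval=0.3), rec("rs2", beta=0.02, pval=0.4),
               rec("rs3", beta=-0.01, pval=0.6), rec("rs4", beta=0.03, pval=0.5)]
        return exp, out

    def test_swapped_alleles_flip_outcome_beta(self):
        exp, out = self.base_sets()
        out[0] = rec("rs1", beta=0.1, pval=0.3, ea="G", oa="A")
        h = harmonize(exp, out)
        assert h.beta_out[h.snp_ids.index("rs1")] == pytest.approx(-0.1)

    def test_outcome_significant_snp_excluded(self):
        exp, out = self.base_sets()
        out[1] = rec("rs2", pval=1e-9)
        h = harmonize(exp, out, outcome_sig_threshold=5e-8)
        assert "rs2" not in h.snp_ids
        assert ("rs2", "outcome-significant") in h.exclusions

    def test_palindromic_dropped(self):
        exp, out = self.base_sets()
        exp.records[2] = rec("rs3", ea="A", oa="T")
        h = harmonize(exp, out)
        assert ("rs3", "palindromic") in h.exclusions

    def test_missing_in_outcome_logged(self):
        exp, out = self.base_sets()
        h = harmonize(exp, out[:3])
        assert ("rs4", "missing-in-outcome") in h.exclusions

    def test_counts_conserved(self):
        exp, out = self.base_sets()
        exp.records[0] = rec("rs1", ea="A", oa="T")
        out[1] = rec("rs2", pval=1e-9)
        h = harmonize(exp, out, min_snps=1)
        assert h.n_snp + len(h.exclusions) == len(exp.records)
        excluded = [e[0] for e in h.exclusions]
        assert len(set(excluded)) == len(excluded)  # one reason each

    def test_idempotence(self):
        exp, out = self.base_sets()
        h1 = harmonize(exp, out)
        exp2 = InstrumentSet(
            "exp",
            [r for r in exp.records if r.snp_id in h1.snp_ids],
            5e-8,
        )
        h2 = harmonize(exp2, out)
        assert h2.snp_ids == h1.snp_ids
        np.testing.assert_array_equal(h2.beta_out, h1.beta_out)
        np.testing.assert_array_equal(h2.beta_exp, h1.beta_exp)

    def test_allele_flip_involution(self):
        exp, out = self.base_sets()
        h1 = harmonize(exp, out)
        flipped = InstrumentSet(
            "exp",
            [GwasRecord(r.snp_id, r.other_allele, r.effect_allele, -r.beta, r.se,
                        r.pval, r.chrom, r.pos,
                        None if r.eaf is None else 1 - r.eaf, r.n)
             for r in exp.records],
            5e-8,
        )
        h2 = harmonize(flipped, out)
        assert h2.snp_ids == h1.snp_ids
        np.testing.assert_array_equal(h2.beta_exp, h1.beta_exp)
        np.testing.assert_array_equal(h2.beta_out, h1.beta_out)
        # 1-(1-eaf) round-trips only to float precision
        np.testing.assert_allclose(h2.eaf, h1.eaf, atol=1e-15)

    def test_too_few_survivors_fatal(self):
        exp, out = self.base_sets()
        with pytest.raises(MRError, match=">= 3"):
            harmonize(exp, out[:2])

    def test_self_harmonization_of_simulator_output(self):
        study = simulate_two_sample(
            SimulationConfig(seed=9, n_snp=30, n_palindromic=3)
        )
        exp = InstrumentSet("exp", study.exposure_table, 1.0)
        h = harmonize(exp, study.outcome_table, outcome_sig_threshold=0.0)
        reasons = {r for _, r in h.exclusions}
        assert reasons == {"palindromic"} and len(h.exclusions) == 3

    def test_swapped_simulator_labels_recovered(self):
        study = simulate_two_sample(
            SimulationConfig(seed=9, n_snp=30, swap_fraction=0.5)
        )
        exp = InstrumentSet("exp", study.exposure_table, 1.0)
        h = harmonize(exp, study.outcome_table, outcome_sig_threshold=0.0)
        # after harmonization betas must match the generator's orientation
        order = {s: i for i, s in enumerate(study.truth["snp_ids"])}
        for j, snp in enumerate(h.snp_ids):
            truth_gamma = study.truth["big_gamma"][order[snp]]
            assert abs(h.beta_out[j] - truth_gamma) < 6 * h.se_out[j]

    def test_proxy_substitution(self):
        exp, out = self.base_sets()
        ld = LDTable()
        ld.add("rs4", "rs9", 0.9)
        out[3] = rec("rs9", beta=0.07, pval=0.5)
        h = harmonize(exp, out, ld=ld, use_proxies=True)
        assert "rs4" in h.snp_ids
        assert ("rs4", "proxy-substituted:rs9") in h.exclusions
        assert h.beta_out[h.snp_ids.index("rs4")] == pytest.approx(0.07)


# ---------------------------------------------------------------- strength

class TestStrength:
    @pytest.mark.parametrize(
        "beta,se,expected",
        [(0.1, 0.02, 25.0), (0.0, 0.5, 0.0), (-0.37, 0.0037, 10000.0)],
    )
    def test_f_statistic(self, beta, se, expected):
        assert f_statistic(beta, se) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "eaf,beta,expected",
        [(0.5, 0.2, 0.02), (0.0, 0.2, 0.0), (1.0, 0.2, 0.0)],
    )
    def test_variance_explained(self, eaf, beta, expected):
        assert variance_explained(eaf, beta) == pytest.approx(expected)

    def test_variance_explained_inverts_printed_share(self):
        # a SNP with beta −0.37 explaining 4.7% of variance implies
        # eaf ≈ 0.2201 from 2p(1−p)·0.37² = 0.047
        eaf = (1 - np.sqrt(1 - 2 * 0.047 / 0.37**2)) / 2
        assert eaf == pytest.approx(0.22009, abs=1e-4)
        assert variance_explained(eaf, -0.37) == pytest.approx(0.047, rel=1e-6)

    @given(st.floats(0.0, 1.0), st.floats(-1, 1))
    def test_r2_sign_and_eaf_symmetry(self, eaf, beta):
        assert variance_explained(eaf, beta) == pytest.approx(
            variance_explained(1 - eaf, -beta)
        )

    def test_strength_summary_single_and_additive(self):
        one = InstrumentSet("x", [rec("rs1", beta=0.1, se=0.02, eaf=0.5)], 1e-5)
        s1 = strength_summary(one)
        assert s1.mean_f == pytest.approx(25.0)
        assert s1.total_r2 == pytest.approx(0.005)
        two = InstrumentSet(
            "x",
            [rec("rs1", beta=0.1, se=0.02, eaf=0.5), rec("rs2", beta=0.1, se=0.02, eaf=0.5)],
            1e-5,
        )
        s2 = strength_summary(two)
        assert s2.mean_f == pytest.approx(25.0)
        assert s2.total_r2 == pytest.approx(0.01)

    def test_total_r2_tracks_configured_heritability(self):
        study = simulate_two_sample(SimulationConfig(seed=13, n_snp=100))
        inst = InstrumentSet("exp", study.exposure_table, 1.0)
        s = strength_summary(inst)
        # estimated beta inflates R2 by the sampling noise, negligible at this N
        assert s.total_r2 == pytest.approx(study.truth["exposure_r2"], rel=0.15)

    def test_missing_eaf_excluded_from_r2(self):
        inst = InstrumentSet(
            "x",
            [rec("rs1", beta=0.1, se=0.02, eaf=0.5), rec("rs2", beta=0.1, se=0.02, eaf=None)],
            1e-5,
        )
        s = strength_summary(inst)
        assert s.total_r2 == pytest.approx(0.005)
        assert s.n_missing_eaf == 1
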