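import numpy as np
import pandas as pd
import pytest

from kumquatpop import synth
from kumquatpop.introgression import (DEFAULT_BLOCK, SsmSet, UndefinedStatistic,
                                      d_statistic, derived_freq_table,
                                      f_branch, fd_genomewide, fd_windows,
                                      identify_ssms, introgression_dosage,
                                      _jackknife_ratio, _block_ids, _patterns)
from kumquatpop.vcfio import PopulationMap, polarize

from conftest import matrix_from_arrays

TREE = "(((WILDSEX1,WILDSEX2),WILDAPO),(CULAPO,CULSEX));"


def _ft(freqs, pos=None):
    """Frequency table from a list of (p1,p2,p3,p4) tuples."""
    arr = np.asarray(freqs, float)
    n = len(arr)
    return pd.DataFrame({
        "chrom": ["chr1"] * n,
        "pos": np.asarray(pos) if pos is not None else np.arange(1, n + 1),
        "P1": arr[:, 0], "P2": arr[:, 1], "P3": arr[:, 2], "O": arr[:, 3],
    })


class TestDStatistic:
    def test_pure_abba_site(self):
        ft = _ft([(0, 1, 1, 0)] * 4, pos=[1, 2, 10_000_001, 10_000_002])
        r = d_statistic(ft, "P1", "P2", "P3", "O", block_bp=5_000_000)
        assert r.D == pytest.approx(1.0)

    def test_hand_computed_mixture(self):
        ft = _ft([(0, 1, 1, 0), (1, 0, 1, 0), (0, 0.5, 1, 0),
                  (0, 1, 1, 0), (1, 0, 1, 0), (0, 0.5, 1, 0)],
                 pos=[1, 2, 3, 6_000_001, 6_000_002, 6_000_003])
        r = d_statistic(ft, "P1", "P2", "P3", "O", block_bp=5_000_000)
        assert r.abba_sum == pytest.approx(3.0)
        assert r.baba_sum == pytest.approx(2.0)
        assert r.D == pytest.approx(0.2)

    def test_swapping_p1_p2_negates_d(self):
        rng = np.random.default_rng(3)
        ft = _ft(rng.random((50, 4)), pos=np.arange(1, 51) * 300_000)
        a = d_statistic(ft, "P1", "P2", "P3", "O", block_bp=5_000_000)
        b = d_statistic(ft, "P2", "P1", "P3", "O", block_bp=5_000_000)
        assert a.D == pytest.approx(-b.D, abs=1e-12)

    def test_zero_denominator_is_error(self):
        ft = _ft([(0, 0, 0, 0)] * 4, pos=[1, 2, 6_000_001, 6_000_002])
        with pytest.raises(UndefinedStatistic):
            d_statistic(ft, "P1", "P2", "P3", "O")

    def test_jackknife_se_matches_naive_loop(self):
        rng = np.random.default_rng(4)
        ft = _ft(rng.random((200, 4)), pos=np.arange(1, 201) * 100_000)
        r = d_statistic(ft, "P1", "P2", "P3", "O", block_bp=5_000_000)
        # independent leave-one-block-out recomputation
        p1, p2, p3, p4 = (ft[c].to_numpy() for c in ("P1", "P2", "P3", "O"))
        abba, baba = _patterns(p1, p2, p3, p4)
        blocks = _block_ids(ft["chrom"].to_numpy(), ft["pos"].to_numpy(),
                            5_000_000)
        B = blocks.max() + 1
        loo = []
        for b in range(B):
            m = blocks != b
            loo.append((abba[m] - baba[m]).sum() / (abba[m] + baba[m]).sum())
        loo = np.array(loo)
        se = np.sqrt((B - 1) / B * ((loo - loo.mean()) ** 2).sum())
        assert r.se == pytest.approx(se, abs=1e-12)
        assert r.n_blocks == B


class TestFd:
    def test_complete_replacement_gives_one(self):
        # P2 copies P3 everywhere -> f_d = 1 in every informative window
        rng = np.random.default_rng(5)
        p3 = rng.random(100)
        ft = pd.DataFrame({"chrom": ["chr1"] * 100,
                           "pos": np.arange(1, 101) * 1000,
                           "P1": 0.0, "P2": p3, "P3": p3, "O": 0.0})
        df = fd_windows(ft, "P1", "P2", "P3", "O", window_bp=25_000)
        vals = df["value"].dropna()
        assert len(vals) > 0
        assert np.allclose(vals, 1.0)

    def test_planted_tracts_recovered_genomewide(self, intro_cohort):
        gm, pm, truth = intro_cohort
        gm = polarize(gm, pm)
        ft = derived_freq_table(gm, pm, ["WILDSEX1", "WILDAPO", "CULAPO",
                                         "OUTGROUP"])
        fd = fd_genomewide(ft, "WILDSEX1", "WILDAPO", "CULAPO", "OUTGROUP")
        assert fd == pytest.approx(0.25, abs=0.05)

    def test_negative_d_windows_masked_by_default(self):
        rng = np.random.default_rng(6)
        ft = pd.DataFrame({"chrom": ["chr1"] * 200,
                           "pos": np.arange(1, 201) * 500,
                           "P1": rng.random(200), "P2": rng.random(200) * 0.3,
                           "P3": rng.random(200), "O": 0.0})
        masked = fd_windows(ft, "P1", "P2", "P3", "O", window_bp=25_000)
        signed = fd_windows(ft, "P1", "P2", "P3", "O", window_bp=25_000,
                            mask_negative_d=False)
        neg = signed["value"] < 0
        assert neg.any()  # construction produces some negative-D windows
        assert masked["value"][neg].isna().all()
        pos = signed["value"] > 0
        np.testing.assert_allclose(masked["value"][pos], signed["value"][pos])


class TestFBranch:
    def test_fhat_is_one_when_b_equals_c_rows(self):
        rng = np.random.default_rng(7)
        p3 = rng.random(60)
        ft = pd.DataFrame({"chrom": ["chr1"] * 60,
                           "pos": np.arange(1, 61) * 200_000,
                           "A": rng.random(60) * 0.2, "B": p3, "C": p3,
                           "O": 0.0})
        from kumquatpop.introgression import _fhat
        v, se, nb = _fhat(ft, "A", "B", "C", "O", 5_000_000)
        assert v == pytest.approx(1.0, abs=1e-12)

    def test_planted_flow_flags_recipient_not_sister(self, intro_cohort):
        gm, pm, truth = intro_cohort
        gm = polarize(gm, pm)
        groups = ["WILDSEX1", "WILDSEX2", "WILDAPO", "CULAPO", "CULSEX",
                  "OUTGROUP"]
        ft = derived_freq_table(gm, pm, groups)
        res = f_branch(ft, TREE, "OUTGROUP", block_bp=500_000)
        cell = lambda br, dn: res[(res.branch == br) & (res.donor == dn)].iloc[0]
        hit = cell("WILDAPO", "CULAPO")
        assert hit["f_b"] > 0.1 and hit["significant"]
        quiet = cell("WILDSEX1", "CULAPO")
        assert quiet["f_b"] < 0.05

    def test_null_cohorts_quiet(self):
        # star-like no-flow cohorts: equal drift, no apomict pools
        fb_vals, sig = [], []
        drift = {g: 0.05 for g in synth.GROUPS}
        for seed in range(15):
            cfg = synth.CohortConfig(n_sites=8000, drift=drift,
                                     apomict_groups=())
            gm, pm, _ = synth.simulate_cohort(cfg, seed=200 + seed)
            gm = polarize(gm, pm)
            ft = derived_freq_table(gm, pm, ["WILDSEX1", "WILDSEX2", "WILDAPO",
                                             "CULAPO", "CULSEX", "OUTGROUP"])
            res = f_branch(ft, TREE, "OUTGROUP", block_bp=500_000)
            ok = res["f_b"].dropna()
            fb_vals.extend(ok.tolist())
            sig.extend(res.loc[ok.index, "significant"].tolist())
        assert np.mean(fb_vals) < 0.02
        assert np.mean(sig) < 0.05

    def test_too_few_groups_rejected(self):
        ft = _ft([(0, 1, 1, 0)])
        with pytest.raises(ValueError):
            f_branch(ft, "(P1,P2);", "O")


class TestSsm:
    def _gm(self, cul, wild, og, anc=None):
        gt = np.array([cul, cul, wild, wild, og, og], dtype=np.int8).reshape(6, 1)
        gm = matrix_from_arrays(gt, anc=anc)
        pm = PopulationMap({"s0": "CUL", "s1": "CUL", "s2": "WILD",
                            "s3": "WILD", "s4": "OUTGROUP", "s5": "OUTGROUP"})
        return gm, pm

    def test_definition_case(self):
        gm, pm = self._gm(2, 0, 0)
        s = identify_ssms(gm, pm, "CUL", "WILD")
        assert len(s) == 1
        assert s.diag_allele[0] == 1
        assert s.polarity[0]  # alt diagnostic, REF ancestral -> derived

    def test_het_cultivated_call_disqualifies(self):
        gm, pm = self._gm(2, 0, 0)
        gm.gt[0, 0] = 1
        assert len(identify_ssms(gm, pm, "CUL", "WILD")) == 0

    def test_polymorphic_outgroup_disqualifies(self):
        gm, pm = self._gm(2, 0, 0)
        gm.gt[5, 0] = 2
        assert len(identify_ssms(gm, pm, "CUL", "WILD")) == 0

    def test_overlapping_groups_rejected(self, default_cohort):
        gm, pm, _ = default_cohort
        with pytest.raises(ValueError):
            identify_ssms(gm, pm, ["CULAPO", "WILDSEX1"], "WILDSEX1")

    def test_truth_jaccard(self, intro_cohort):
        gm, pm, truth = intro_cohort
        s = identify_ssms(gm, pm, ["CULAPO", "CULSEX"], "WILDSEX1")
        found, planted = set(s.site_idx), set(truth.diagnostic_sites)
        jacc = len(found & planted) / len(found | planted)
        assert jacc >= 0.95


class TestDosage:
    def test_hand_count(self):
        # 20 SSMs; sample het at 10, hom-nondiagnostic elsewhere
        gt = np.zeros((1, 20), dtype=np.int8)
        gt[0, :10] = 1
        gm = matrix_from_arrays(gt)
        ssm = SsmSet(site_idx=np.arange(20), chrom=gm.chrom, pos=gm.pos,
                     diag_allele=np.ones(20, dtype=np.int8),
                     polarity=np.ones(20, dtype=bool))
        res = introgression_dosage(gm, ssm, ["s0"])
        row = res.iloc[0]
        assert row["proportion"] == pytest.approx(0.25)
        assert row["n_het_sites"] == 10 and row["n_hom_sites"] == 0

    def test_pure_cultivated_sample_is_one(self, intro_cohort):
        gm, pm, _ = intro_cohort
        s = identify_ssms(gm, pm, ["CULAPO", "CULSEX"], "WILDSEX1")
        res = introgression_dosage(gm, s, pm.samples_of("CULAPO")[:2])
        assert np.allclose(res["proportion"], 1.0)

    def test_dosage_identity(self, intro_cohort):
        gm, pm, _ = intro_cohort
        s = identify_ssms(gm, pm, ["CULAPO", "CULSEX"], "WILDSEX1")
        res = introgression_dosage(gm, s, pm.samples_of("WILDAPO"))
        num = res["proportion"] * 2 * res["n_genotyped"]
        np.testing.assert_allclose(num, res["n_het_sites"] + 2 * res["n_hom_sites"])
        assert ((res["proportion"] >= 0) & (res["proportion"] <= 1)).all()

    def test_planted_fraction_recovered(self, intro_cohort):
        gm, pm, truth = intro_cohort
        s = identify_ssms(gm, pm, ["CULAPO", "CULSEX"], "WILDSEX1")
        res = introgression_dosage(gm, s, pm.samples_of("WILDAPO"))
        assert res["proportion"].mean() == pytest.approx(0.25, abs=0.02)
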