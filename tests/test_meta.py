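import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import multigwas as mg
from multigwas.meta import classify_i2

from .conftest import make_assoc
from .oracles import (dl_tau2_literal, ivw_literal, random_effects_literal,
                      stouffer_literal)


class TestHarmonize:
    def test_identical_tables_no_flips(self):
        t = make_assoc(["a", "b"], 1, [100, 200], [0.1, -0.2], [0.05, 0.05])
        h = mg.harmonize([t, t.copy()])
        assert (h.n_studies_per_snp == 2).all()
        assert np.allclose(h.b[:, 0], h.b[:, 1])
        assert h.n_dropped == 0

    def test_swapped_alleles_flip_back(self):
        t1 = make_assoc(["a", "b"], 1, [100, 200], [0.1, -0.2], [0.05, 0.05],
                        freq=0.3)
        t2 = t1.copy()
        t2["A1"], t2["A2"] = t1["A2"], t1["A1"]
        t2["B"] = -t1["B"]
        t2["Z"] = -t1["Z"]
        t2["FREQ"] = 1 - t1["FREQ"]
        h = mg.harmonize([t1, t2])
        assert np.allclose(h.b[:, 0], h.b[:, 1])
        assert np.allclose(h.freq[:, 0], h.freq[:, 1])

    def test_irreconcilable_alleles_dropped_and_counted(self):
        t1 = make_assoc(["a", "b"], 1, [100, 200], [0.1, 0.2], [0.05, 0.05])
        t2 = t1.copy()
        t2.loc[0, "A2"] = "C"  # G/A vs G/C cannot be aligned
        h = mg.harmonize([t1, t2])
        assert h.n_dropped == 1
        assert list(h.info["SNP"]) == ["b"]

    def test_duplicate_ids_rejected(self):
        t = make_assoc(["a", "a"], 1, [100, 200], [0.1, 0.2], [0.05, 0.05])
        with pytest.raises(ValueError, match="duplicate"):
            mg.harmonize([t])

    def test_partial_overlap_keeps_singleton_snps(self):
        t1 = make_assoc(["a", "b"], 1, [100, 200], [0.1, 0.2], [0.05, 0.05])
        t2 = make_assoc(["a"], 1, [100], [0.15], [0.05])
        h = mg.harmonize([t1, t2])
        assert list(h.n_studies_per_snp) == [2, 1]


class TestStoufferZ:
    def test_single_study_is_identity(self):
        z, p = mg.stouffer_z(p=[[0.04]], b=[[-0.2]], n=[[50]])
        from scipy import stats
        assert z[0] == pytest.approx(-stats.norm.isf(0.02))
        assert p[0] == pytest.approx(0.04)

    def test_equal_n_equal_z_hand_value(self):
        from scipy import stats
        p196 = 2 * stats.norm.sf(1.96)
        z, _ = mg.stouffer_z(p=[[p196, p196]], b=[[1.0, 1.0]], n=[[400, 400]])
        assert z[0] == pytest.approx(1.96 * np.sqrt(2), rel=1e-6)

    def test_opposite_directions_cancel(self):
        from scipy import stats
        p2 = 2 * stats.norm.sf(2.0)
        z, p = mg.stouffer_z(p=[[p2, p2]], b=[[1.0, -1.0]], n=[[100, 100]])
        assert z[0] == pytest.approx(0.0, abs=1e-12)
        assert p[0] == pytest.approx(1.0)

    def test_matches_literal_formula_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            k = rng.integers(2, 6)
            p = rng.uniform(1e-6, 1, k)
            sign = rng.choice([-1.0, 1.0], k)
            n = rng.integers(50, 3000, k)
            z, _ = mg.stouffer_z(p=p[None], b=sign[None], n=n[None].astype(float))
            z_o, _ = stouffer_literal(p, sign, n)
            assert z[0] == pytest.approx(z_o, rel=1e-10)


class TestIvw:
    def test_hand_evaluated_two_study_case(self):
        beta, v, chi2, p, q, i2 = mg.ivw([[0.2, 0.4]], [[0.1, 0.1]])
        assert beta[0] == pytest.approx(0.3)
        assert v[0] == pytest.approx(0.005)
        assert q[0] == pytest.approx(2.0)
        assert i2[0] == pytest.approx(50.0)

    def test_identical_studies_have_no_heterogeneity(self):
        beta, _, _, _, q, i2 = mg.ivw([[0.25, 0.25, 0.25]], [[0.1, 0.1, 0.1]])
        assert beta[0] == pytest.approx(0.25)
        assert q[0] == pytest.approx(0.0, abs=1e-12)
        assert i2[0] == 0.0

    def test_single_study_edge(self):
        beta, _, _, _, q, i2 = mg.ivw([[0.4]], [[0.2]])
        assert beta[0] == pytest.approx(0.4)
        assert q[0] == pytest.approx(0.0, abs=1e-12)
        assert i2[0] == 0.0

    def test_combined_variance_below_every_study(self):
        rng = np.random.default_rng(1)
        se = rng.uniform(0.05, 0.5, size=(50, 4))
        b = rng.normal(size=(50, 4))
        _, v, *_ = mg.ivw(b, se)
        assert np.all(v <= (se ** 2).min(axis=1) + 1e-15)

    def test_i2_invariant_under_common_rescaling(self):
        b = np.array([[0.2, -0.1, 0.4]])
        se = np.array([[0.1, 0.2, 0.15]])
        *_, i2a = mg.ivw(b, se)
        *_, i2b = mg.ivw(10 * b, 10 * se)
        assert i2a[0] == pytest.approx(i2b[0], abs=1e-10)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            mg.ivw([[0.1, 0.2]], [[0.0, 0.1]])

    def test_i2_bands(self):
        assert classify_i2(10) == "none"
        assert classify_i2(30) == "moderate"
        assert classify_i2(60) == "high"
        assert classify_i2(90) == "very high"


class TestDlTau2:
    def test_hand_evaluated_value(self):
        # Q=2, N=2, w=(100,100): tau2 = 1 / (200 - 20000/200) = 0.01
        tau2 = mg.dl_tau2([[0.2, 0.4]], [[0.1, 0.1]])
        assert tau2[0] == pytest.approx(0.01)

    def test_truncated_at_zero(self):
        tau2 = mg.dl_tau2([[0.3, 0.3]], [[0.1, 0.1]])
        assert tau2[0] == 0.0

    def test_single_study_flagged_zero(self):
        assert mg.dl_tau2([[0.3]], [[0.1]])[0] == 0.0

    def test_permutation_invariant(self):
        a = mg.dl_tau2([[0.1, 0.5, -0.2]], [[0.1, 0.2, 0.3]])
        b = mg.dl_tau2([[-0.2, 0.1, 0.5]], [[0.3, 0.1, 0.2]])
        assert a[0] == pytest.approx(b[0], rel=1e-12)


class TestHanEskin:
    def test_zero_tau2_equals_ivw(self):
        rng = np.random.default_rng(2)
        b = rng.normal(size=(30, 4))
        se = rng.uniform(0.05, 0.3, size=(30, 4))
        _, _, chi2, _, _, _ = mg.ivw(b, se)
        beta_ivw = mg.ivw(b, se)[0]
        s_fe, s_het, s_rand, beta_star, _ = mg.han_eskin(b, se, tau2=np.zeros(30))
        assert np.allclose(s_het, 0.0, atol=1e-10)
        assert np.allclose(s_rand, chi2, atol=1e-10)
        assert np.allclose(beta_star, beta_ivw, atol=1e-10)

    def test_s_fe_equals_ivw_chi2(self):
        rng = np.random.default_rng(3)
        b = rng.normal(size=(40, 3))
        se = rng.uniform(0.05, 0.3, size=(40, 3))
        chi2 = mg.ivw(b, se)[2]
        s_fe = mg.han_eskin(b, se)[0]
        assert np.allclose(s_fe, chi2, atol=1e-8)

    def test_heterogeneous_case_beats_fixed_effects(self):
        s_fe, s_het, s_rand, _, _ = mg.han_eskin([[0.5, -0.5]], [[0.1, 0.1]])
        o_fe, o_het, o_rand, _ = random_effects_literal([0.5, -0.5], [0.1, 0.1])
        assert s_rand[0] > s_fe[0]
        assert s_fe[0] == pytest.approx(o_fe, rel=1e-10)
        assert s_het[0] == pytest.approx(o_het, rel=1e-10)
        assert s_rand[0] == pytest.approx(o_rand, rel=1e-10)

    def test_decomposition_identity_on_random_inputs(self):
        """S_rand recomputed from the literal displayed decomposition matches
        the implementation, and equals S_FE + S_Het."""
        rng = np.random.default_rng(4)
        for _ in range(50):
            k = rng.integers(2, 6)
            b = rng.normal(scale=0.3, size=k)
            se = rng.uniform(0.05, 0.4, size=k)
            s_fe, s_het, s_rand, _, _ = mg.han_eskin(b[None], se[None])
            assert s_rand[0] == pytest.approx(s_fe[0] + s_het[0], abs=1e-8)
            _, _, o_rand, _ = random_effects_literal(b, se,
                                                     dl_tau2_literal(b, se))
            assert s_rand[0] == pytest.approx(o_rand, abs=1e-8)

    def test_negative_tau2_rejected(self):
        with pytest.raises(ValueError):
            mg.han_eskin([[0.1, 0.2]], [[0.1, 0.1]], tau2=np.array([-0.1]))


class TestZToBetaSe:
    def test_hand_values(self):
        b, se = mg.z_to_beta_se(0.0, 0.5, 100)
        assert b == pytest.approx(0.0)
        assert se == pytest.approx(1 / np.sqrt(50))
        b, se = mg.z_to_beta_se(2.0, 0.5, 100)
        assert b == pytest.approx(2 / np.sqrt(52))
        assert se == pytest.approx(1 / np.sqrt(52))

    @given(st.floats(-30, 30), st.floats(0.01, 0.99), st.integers(2, 10 ** 6))
    @settings(max_examples=200, deadline=None)
    def test_ratio_identity(self, z, p, n):
        b, se = mg.z_to_beta_se(z, p, n)
        assert b / se == pytest.approx(z, abs=1e-12)

    def test_degenerate_frequency_rejected(self):
        with pytest.raises(ValueError):
            mg.z_to_beta_se(1.0, 0.0, 100)


class TestRunMeta:
    def test_identical_tables_reduce_to_inputs(self):
        t = make_assoc([f"s{i}" for i in range(5)], 1, np.arange(5) * 1000 + 1,
                       [0.1, -0.2, 0.0, 0.3, 0.05], [0.05] * 5)
        out = mg.run_meta([t, t.copy()], method="ivw")
        assert np.allclose(out["BETA_IVW"], t["B"])
        assert np.allclose(out["Q"], 0.0, atol=1e-12)
        assert (out["DIRECTIONS"] == ["++", "--", "++", "++", "++"]).all()

    def test_method_selects_p_column(self):
        t1 = make_assoc(["a"], 1, [100], [0.3], [0.1], n=500)
        t2 = make_assoc(["a"], 1, [100], [0.25], [0.12], n=400)
        for method, col in (("zscore", "P_ZSCORE"), ("ivw", "P_IVW"),
                            ("random", "P_RAND")):
            out = mg.run_meta([t1, t2], method=method)
            assert out["P"].iloc[0] == pytest.approx(out[col].iloc[0])

    def test_needs_two_tables(self):
        t = make_assoc(["a"], 1, [100], [0.3], [0.1])
        with pytest.raises(ValueError):
            mg.run_meta([t])

    def test_matches_metafor_oracle(self, tmp_path):
        """IVW beta/Q/I2 and DL tau2 agree with R metafor on a toy case."""
        b = [0.42, 0.11, -0.08, 0.25]
        se = [0.1, 0.08, 0.15, 0.12]
        script = tmp_path / "meta.R"
        script.write_text(
            "library(metafor)\n"
            f"yi <- c({','.join(map(str, b))}); vi <- c({','.join(str(s**2) for s in se)})\n"
            "fe <- rma(yi, vi, method='FE'); dl <- rma(yi, vi, method='DL')\n"
            "cat(coef(fe), fe$QE, dl$I2, dl$tau2, sep='\\n')\n")
        res = subprocess.run(["Rscript", "--vanilla", str(script)],
                             capture_output=True, text=True, check=True)
        beta_r, q_r, i2_r, tau2_r = map(float, res.stdout.strip().split("\n"))
        beta, _, _, _, q, i2 = mg.ivw([b], [se])
        tau2 = mg.dl_tau2([b], [se])
        assert beta[0] == pytest.approx(beta_r, rel=1e-6)
        assert q[0] == pytest.approx(q_r, rel=1e-6)
        assert tau2[0] == pytest.approx(tau2_r, rel=1e-4, abs=1e-8)
        # metafor's I2 is tau2-based, not the Q-based index; both must agree
        # on the absence/presence of heterogeneity for this effect pattern
        assert (i2[0] > 25) == (i2_r > 25)

    def test_null_unrelated_simulation_is_calibrated(self):
        """With no QTL, no polygenic signal and unrelated populations, all
        three meta p-value sets have lambda near 1 (mean over seeds)."""
        lams = {"z": [], "ivw": [], "re": []}
        for seed in range(5):
            cfg = mg.SimConfig(pop_sizes=[200, 200], n_snps=1500, n_chroms=3,
                               fst=0.01, h2_poly=0.0, n_pool_haplotypes=2000,
                               seed=seed)
            panel, phen = mg.simulate_panel(cfg)
            tables = []
            for pop in ("POP1", "POP2"):
                sub = panel.subset(samples=panel.populations == pop)
                sub = sub.drop_monomorphic()
                grm = mg.compute_grm(sub)
                tables.append(mg.mlma_scan(sub, phen, grm))
            out = mg.run_meta(tables, method="ivw")
            lams["z"].append(mg.genomic_lambda(p=out["P_ZSCORE"].to_numpy()).lam)
            lams["ivw"].append(mg.genomic_lambda(p=out["P_IVW"].to_numpy()).lam)
            lams["re"].append(mg.genomic_lambda(
                components=(out["S_FE"].to_numpy(), out["S_HET"].to_numpy())).lam)
        for key, vals in lams.items():
            assert 0.9 < np.mean(vals) < 1.1, (key, vals)
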