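import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microbiability import (AbundanceDesign, ModelSpec, RelationshipMatrix,
                            SimConfig, backsolve_effects, backsolve_pvalues,
                            backsolve_variances, blup_solve, build_A,
                            build_microbial_relationship, gao_effective_tests,
                            mwas_backsolve, mwas_single_regression,
                            simulate_dataset)
from conftest import FIXED


def _identity_A(ids):
    return RelationshipMatrix(ids=list(ids), matrix=np.eye(len(ids)),
                              kind="pedigree")


def _centered_design(n, k, seed=0):
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, k))
    z = (z - z.mean(0)) / z.std(0, ddof=1)
    return AbundanceDesign([f"s{i}" for i in range(n)],
                           [f"o{j}" for j in range(k)], z)


class TestSingleOtuRegression:
    def test_planted_effect_recovered(self):
        design = _centered_design(80, 10, seed=1)
        rng = np.random.default_rng(2)
        y = 2.0 * design.z3[:, 3] + rng.standard_normal(80) * 0.01
        pheno = pd.DataFrame({"id": design.sample_ids, "trait": y})
        res = mwas_single_regression(
            "trait", pheno, _identity_A(design.sample_ids), design,
            {"sigma2_a": 1e-6, "sigma2_e": 1.0}, fixed_effects=[])
        best = res.loc[res["p_value"].idxmin()]
        assert best["otu_id"] == "o3"
        assert res["effect"].iloc[3] == pytest.approx(2.0, abs=0.02)
        assert best["p_value"] < 1e-6

    def test_ols_limit(self):
        # A = I with sigma2_a -> 0: the animal term vanishes and the
        # coefficient equals ordinary least squares
        design = _centered_design(50, 5, seed=3)
        rng = np.random.default_rng(4)
        y = 0.7 * design.z3[:, 2] + rng.standard_normal(50)
        pheno = pd.DataFrame({"id": design.sample_ids, "trait": y})
        res = mwas_single_regression(
            "trait", pheno, _identity_A(design.sample_ids), design,
            {"sigma2_a": 1e-10, "sigma2_e": 1.0}, fixed_effects=[])
        X = np.column_stack([np.ones(50), design.z3[:, 2]])
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0][1]
        assert res["effect"].iloc[2] == pytest.approx(beta_ols, abs=1e-6)

    def test_null_pvalues_uniform(self):
        # permutation-style null: independent OTU columns, pure-noise trait
        design = _centered_design(60, 400, seed=5)
        rng = np.random.default_rng(6)
        y = rng.standard_normal(60)
        pheno = pd.DataFrame({"id": design.sample_ids, "trait": y})
        res = mwas_single_regression(
            "trait", pheno, _identity_A(design.sample_ids), design,
            {"sigma2_a": 1e-10, "sigma2_e": 1.0}, fixed_effects=[])
        ks = stats.kstest(res["p_value"], "uniform")
        assert ks.pvalue > 0.01

    def test_collinear_otu_flagged(self):
        design = _centered_design(30, 3, seed=7)
        z = design.z3.copy()
        z[:, 1] = 0.0  # constant column, collinear with the intercept
        design = AbundanceDesign(design.sample_ids, design.otu_ids, z)
        rng = np.random.default_rng(8)
        pheno = pd.DataFrame({"id": design.sample_ids,
                              "trait": rng.standard_normal(30)})
        res = mwas_single_regression(
            "trait", pheno, _identity_A(design.sample_ids), design,
            {"sigma2_a": 0.5, "sigma2_e": 1.0}, fixed_effects=[])
        assert res["flag"].iloc[1] == "aliased"
        assert res["p_value"].iloc[1] == 1.0

    def test_reml_refit_close_to_plugin(self):
        design = _centered_design(60, 4, seed=9)
        rng = np.random.default_rng(10)
        y = 0.5 * design.z3[:, 0] + rng.standard_normal(60)
        pheno = pd.DataFrame({"id": design.sample_ids, "trait": y})
        A = _identity_A(design.sample_ids)
        v = {"sigma2_a": 0.3, "sigma2_e": 1.0}
        plug = mwas_single_regression("trait", pheno, A, design, v,
                                      fixed_effects=[], otu_indices=[0])
        reml = mwas_single_regression("trait", pheno, A, design, v,
                                      fixed_effects=[], otu_indices=[0],
                                      refit_variances=True)
        assert reml["effect"].iloc[0] == pytest.approx(plug["effect"].iloc[0],
                                                       rel=0.15)


class TestBacksolve:
    def test_zero_mhat_zero_effects(self):
        design = _centered_design(20, 30, seed=11)
        M = build_microbial_relationship(design)
        eff = backsolve_effects(np.zeros(20), design, M)
        np.testing.assert_allclose(eff, 0.0)

    def test_exact_inverse_case(self):
        # uncentered square invertible Z3: OTU_hat = Z3^-1 m_hat exactly
        rng = np.random.default_rng(12)
        z = rng.standard_normal((15, 15)) + 0.1
        design = AbundanceDesign([f"s{i}" for i in range(15)],
                                 [f"o{j}" for j in range(15)], z)
        M = build_microbial_relationship(design)
        m_hat = rng.standard_normal(15)
        eff = backsolve_effects(m_hat, design, M)
        np.testing.assert_allclose(eff, np.linalg.solve(z, m_hat), atol=1e-8)

    def test_projection_identity(self):
        # m_hat in range(Z3): reconstruction Z3 @ OTU_hat == m_hat
        design = _centered_design(20, 50, seed=13)
        M = build_microbial_relationship(design)
        rng = np.random.default_rng(14)
        m_hat = M.matrix @ rng.standard_normal(20)
        eff = backsolve_effects(m_hat, design, M)
        np.testing.assert_allclose(design.z3 @ eff, m_hat, atol=1e-8)

    def test_variances_against_monte_carlo_pev(self):
        # Eq-style analytic variances of back-solved effects match the
        # empirical variance over simulated phenotype replicates at the same
        # fixed design and variance components
        n, k = 12, 18
        design = _centered_design(n, k, seed=15)
        M = build_microbial_relationship(design)
        s2m, s2e = 0.8, 0.5
        spec = ModelSpec(traits=["trait"], include_genetic=False,
                         include_microbiome=True, intercept=True)
        rng = np.random.default_rng(16)
        wM, QM = np.linalg.eigh(M.matrix)
        wM = np.clip(wM, 0, None)
        reps = []
        for _ in range(4000):
            m = QM @ (np.sqrt(wM * s2m) * rng.standard_normal(n))
            y = 0.3 + m + rng.standard_normal(n) * np.sqrt(s2e)
            pheno = pd.DataFrame({"id": design.sample_ids, "trait": y})
            sol = blup_solve(spec, pheno, None, M,
                             {"sigma2_m": s2m, "sigma2_e": s2e})
            reps.append(backsolve_effects(sol.m.to_numpy(), design, M))
        emp_var = np.var(np.array(reps), axis=0, ddof=1)
        pheno = pd.DataFrame({"id": design.sample_ids,
                              "trait": np.zeros(n)})
        sol = blup_solve(spec, pheno, None, M,
                         {"sigma2_m": s2m, "sigma2_e": s2e}, compute_cmm=True)
        ana_var = backsolve_variances(design, M, sol.cmm, s2m, s2e)
        # compare in aggregate and per OTU
        assert ana_var.sum() == pytest.approx(emp_var.sum(), rel=0.05)
        np.testing.assert_allclose(ana_var, emp_var, rtol=0.25)

    def test_variances_shrink_with_more_noise(self):
        # less information in m_hat (larger residual variance) means smaller
        # variance of the back-solved estimates
        n, k = 15, 25
        design = _centered_design(n, k, seed=17)
        M = build_microbial_relationship(design)
        spec = ModelSpec(traits=["trait"], include_genetic=False,
                         include_microbiome=True, intercept=True)
        pheno = pd.DataFrame({"id": design.sample_ids, "trait": np.zeros(n)})
        out = []
        for s2e in (0.5, 1.0, 2.0):
            sol = blup_solve(spec, pheno, None, M,
                             {"sigma2_m": 0.8, "sigma2_e": s2e},
                             compute_cmm=True)
            out.append(backsolve_variances(design, M, sol.cmm, 0.8, s2e))
        assert (out[1] <= out[0] + 1e-12).all()
        assert (out[2] <= out[1] + 1e-12).all()

    def test_no_data_limit_zero_variances(self):
        # without phenotypic information var(m_hat) = 0, so OTU variances 0:
        # M*s2m - C^mm*s2e with C^mm -> M/lambda recovers exactly zero
        n, k = 10, 14
        design = _centered_design(n, k, seed=18)
        M = build_microbial_relationship(design)
        s2m, s2e = 0.6, 1.1
        C_mm = M.matrix * s2m / s2e  # prior-only inverse block
        var = backsolve_variances(design, M, C_mm, s2m, s2e)
        np.testing.assert_allclose(var, 0.0, atol=1e-10)

    def test_pvalue_conventions(self):
        res = backsolve_pvalues(np.array([0.0, 1.959964 * 2.0]),
                                np.array([1.0, 4.0]))
        assert res["p_value"].iloc[0] == pytest.approx(1.0)
        assert res["p_value"].iloc[1] == pytest.approx(0.05, abs=1e-6)
        assert (res["z_score"] == res["effect"] / res["se"]).all()

    def test_null_pvalues_uniform(self):
        # data simulated under the model at the plug-in variances: the
        # analytic var(OTU_hat) is the marginal estimator variance, so
        # Z-scores are standard normal and p-values uniform
        n, k = 40, 60
        design = _centered_design(n, k, seed=19)
        M = build_microbial_relationship(design)
        rng = np.random.default_rng(20)
        s2m, s2e = 0.5, 1.0
        wM, QM = np.linalg.eigh(M.matrix)
        wM = np.clip(wM, 0, None)
        pvals = []
        for _ in range(40):
            m = QM @ (np.sqrt(wM * s2m) * rng.standard_normal(n))
            y = m + rng.standard_normal(n) * np.sqrt(s2e)
            pheno = pd.DataFrame({"id": design.sample_ids, "trait": y})
            res = mwas_backsolve("trait", pheno, None, M, design,
                                 {"sigma2_m": s2m, "sigma2_e": s2e})
            pvals.extend(res["p_value"])
        ks = stats.kstest(np.array(pvals), "uniform")
        assert ks.pvalue > 0.01


class TestGaoThresholds:
    def test_rank_one_two_correlated_columns(self):
        rng = np.random.default_rng(21)
        x = rng.standard_normal(30)
        z = np.column_stack([x, x])
        z = (z - z.mean(0)) / z.std(0, ddof=1)
        design = AbundanceDesign([f"s{i}" for i in range(30)], ["a", "b"], z)
        thr = gao_effective_tests(design)
        assert thr.m_eff == 1
        assert thr.threshold_5 == pytest.approx(-np.log10(0.05), abs=1e-10)
        np.testing.assert_allclose(sorted(thr.eigenvalues), [0, 2], atol=1e-10)

    def test_equal_eigenvalue_orthogonal_case(self):
        # exactly orthonormal columns: all eigenvalues 1, so
        # m_eff = ceil(0.995 * k)
        n, k = 210, 200
        rng = np.random.default_rng(22)
        q, _ = np.linalg.qr(rng.standard_normal((n, k)))
        z = q * np.sqrt(n - 1)
        design = AbundanceDesign([f"s{i}" for i in range(n)],
                                 [f"o{j}" for j in range(k)], z)
        thr = gao_effective_tests(design)
        assert thr.m_eff == int(np.ceil(0.995 * k))

    def test_printed_threshold_formulas(self):
        from microbiability.mwas import SignificanceThresholds
        thr = SignificanceThresholds.from_m_eff(428)
        assert thr.threshold_5 == pytest.approx(-np.log10(0.05 / 428))
        assert thr.threshold_10 == pytest.approx(-np.log10(0.10 / 428))
        assert thr.threshold_5 > thr.threshold_10

    def test_scale_invariance_n_vs_n_minus_1(self):
        # eigenvalue ratios are scale invariant, so m_eff is unchanged by
        # the Gram denominator
        design = _centered_design(40, 25, seed=23)
        thr1 = gao_effective_tests(design)
        scaled = AbundanceDesign(design.sample_ids, design.otu_ids,
                                 design.z3 * np.sqrt(39 / 40))
        thr2 = gao_effective_tests(scaled)
        assert thr1.m_eff == thr2.m_eff

    def test_wide_design_consistent_with_direct_eigh(self):
        design = _centered_design(15, 40, seed=24)
        thr = gao_effective_tests(design)
        R = np.corrcoef(design.z3, rowvar=False)
        ev = np.sort(np.linalg.eigvalsh(R))[::-1]
        cum = np.cumsum(np.clip(ev, 0, None))
        m_eff = int(np.searchsorted(cum, 0.995 * ev.sum()) + 1)
        assert thr.m_eff == m_eff


@pytest.fixture(scope="module")
def planted_sim():
    cfg = SimConfig(n_phenotyped=400, n_otu=200, n_founders=40, seed=42,
                    sigma2_a=0.25, sigma2_m=0.25, sigma2_e=0.5,
                    n_planted=1, planted_effect=0.3, n_cg=6)
    sim = simulate_dataset(cfg)
    A = build_A(sim.pedigree)
    M = build_microbial_relationship(sim.design)
    v = {"sigma2_a": 0.25, "sigma2_m": 0.25, "sigma2_e": 0.5}
    single = mwas_single_regression("trait", sim.phenotypes, A,
                                    sim.design, v, fixed_effects=FIXED)
    back = mwas_backsolve("trait", sim.phenotypes, A, M, sim.design, v,
                          fixed_effects=FIXED)
    return sim, single, back


class TestMethodConcordance:

    def test_methods_concordant_independent_otu(self):
        # with uncorrelated OTU columns the marginal (single-regression) and
        # joint (back-solving) estimands coincide and p-value ranks agree
        cfg = SimConfig(n_phenotyped=400, n_otu=200, n_founders=40, seed=42,
                        sigma2_a=0.25, sigma2_m=0.25, sigma2_e=0.5,
                        n_factors=0, n_planted=1, planted_effect=0.3, n_cg=6)
        sim = simulate_dataset(cfg)
        A = build_A(sim.pedigree)
        M = build_microbial_relationship(sim.design)
        v = {"sigma2_a": 0.25, "sigma2_m": 0.25, "sigma2_e": 0.5}
        single = mwas_single_regression("trait", sim.phenotypes, A,
                                        sim.design, v, fixed_effects=FIXED)
        back = mwas_backsolve("trait", sim.phenotypes, A, M, sim.design, v,
                              fixed_effects=FIXED)
        rho = stats.spearmanr(single["neg_log10_p"], back["neg_log10_p"])[0]
        assert rho > 0.8
        assert single["p_value"].idxmin() == back["p_value"].idxmin()

    def test_methods_broadly_concordant_correlated_otu(self, planted_sim):
        # under the correlated (factor-structured) default generator the
        # marginal and joint methods diverge in null ranks but remain
        # broadly concordant
        sim, single, back = planted_sim
        rho = stats.spearmanr(single["neg_log10_p"], back["neg_log10_p"])[0]
        assert rho > 0.5

    def test_top_hit_shared_and_is_planted(self, planted_sim):
        sim, single, back = planted_sim
        planted = np.flatnonzero(np.abs(sim.truth.otu_effects) > 0.1)
        top_single = single["p_value"].idxmin()
        top_back = back["p_value"].idxmin()
        assert top_single == top_back
        assert top_single in planted

    def test_backsolve_shrinks_effects(self, planted_sim):
        _, single, back = planted_sim
        assert np.mean(np.abs(back["effect"])) < np.mean(np.abs(single["effect"]))


class TestPowerAndError:
    def test_planted_otu_detected_and_null_fwer_controlled(self):
        # power: the planted large-effect OTU clears the 5% family-wise
        # threshold in most seeds; with no planted effects the family-wise
        # error at that threshold stays low
        hits, false_alarms, n_seeds = 0, 0, 5
        for seed in range(n_seeds):
            cfg = SimConfig(n_phenotyped=500, n_otu=150, n_founders=40,
                            seed=500 + seed, sigma2_a=0.25, sigma2_m=0.25,
                            sigma2_e=0.5, n_planted=1, planted_effect=0.4,
                            n_cg=6)
            sim = simulate_dataset(cfg)
            A = build_A(sim.pedigree)
            v = {"sigma2_a": 0.25, "sigma2_m": 0.25, "sigma2_e": 0.5}
            thr = gao_effective_tests(sim.design)
            res = mwas_single_regression("trait", sim.phenotypes, A,
                                         sim.design, v, fixed_effects=FIXED)
            planted = int(np.flatnonzero(
                np.abs(sim.truth.otu_effects) > 0.2)[0])
            if res["neg_log10_p"].iloc[planted] > thr.threshold_5:
                hits += 1

            null_cfg = SimConfig(n_phenotyped=500, n_otu=150, n_founders=40,
                                 seed=600 + seed, sigma2_a=0.25, sigma2_m=0.0,
                                 sigma2_e=0.75, n_cg=6)
            null_sim = simulate_dataset(null_cfg)
            A0 = build_A(null_sim.pedigree)
            thr0 = gao_effective_tests(null_sim.design)
            res0 = mwas_single_regression("trait", null_sim.phenotypes, A0,
                                          null_sim.design,
                                          {"sigma2_a": 0.25, "sigma2_e": 0.75},
                                          fixed_effects=FIXED)
            if (res0["neg_log10_p"] > thr0.threshold_5).any():
                false_alarms += 1
        assert hits >= 4
        assert false_alarms <= 1
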