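"""Animal-model EBV/reliability, deregression and BayesA weight estimation."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from ssblup.mme import ModelSpec
from ssblup.pedigree import UNKNOWN, inbreeding_and_a_inverse, tabular_a, validate_and_sort
from ssblup.weights import (
    BayesAConfig, animal_model_ebv_and_reliability, bayesa_gibbs,
    bayesa_prior_scale, deregress, weights_from_variances, _garrick_information,
)
from conftest import G0_2TRAIT, R0_2TRAIT, make_random_pedigree


@pytest.fixture
def ped_and_spec():
    ped = validate_and_sort(make_random_pedigree(20, 6, seed=3))
    spec = ModelSpec(G0_2TRAIT, R0_2TRAIT)
    return ped, inbreeding_and_a_inverse(ped), spec


class TestAnimalModel:
    def test_no_phenotypes_errors(self, ped_and_spec):
        ped, kin, spec = ped_and_spec
        phen = pd.DataFrame({"animal": [], "trait1": [], "trait2": []})
        with pytest.raises(ValueError, match="no phenotype"):
            animal_model_ebv_and_reliability(ped, phen, kin, spec)

    def test_unconnected_founder_zero_ebv_and_reliability(self, ped_and_spec):
        ped, kin, spec = ped_and_spec
        # give records only to founders without offspring links to founder 0
        rng = np.random.default_rng(0)
        others = ped.labels[5:]
        phen = pd.DataFrame({"animal": others,
                             "trait1": rng.standard_normal(others.size),
                             "trait2": rng.standard_normal(others.size)})
        ebv, rel = animal_model_ebv_and_reliability(ped, phen, kin, spec)
        # a founder with no record and no descendants among the recorded set
        a = tabular_a(ped)
        recorded = ped.position_of(others)
        isolated = [i for i in range(5)
                    if np.allclose(a[i, recorded], 0) and i not in recorded]
        for i in isolated:
            assert np.allclose(ebv[i], 0.0, atol=1e-10)
            assert np.allclose(rel[i], 0.0, atol=1e-8)

    def test_matches_gls_oracle(self, ped_and_spec):
        # independent route: BLUP from the joint covariance (GLS + conditional mean)
        ped, kin, spec = ped_and_spec
        rng = np.random.default_rng(1)
        phen = pd.DataFrame({"animal": ped.labels,
                             "trait1": rng.standard_normal(ped.n),
                             "trait2": rng.standard_normal(ped.n)})
        ebv, rel = animal_model_ebv_and_reliability(ped, phen, kin, spec)

        a = tabular_a(ped)
        t = 2
        g = np.kron(a, spec.g0)                       # Var(u), level-major
        w = np.eye(ped.n * t)                         # one record per animal, both traits
        r = np.kron(np.eye(ped.n), spec.r0)
        x = np.tile(np.eye(t), (ped.n, 1))
        y = phen[["trait1", "trait2"]].to_numpy().ravel()
        v = w @ g @ w.T + r
        vi = np.linalg.inv(v)
        beta = np.linalg.solve(x.T @ vi @ x, x.T @ vi @ y)
        u = g @ w.T @ vi @ (y - x @ beta)
        assert np.abs(ebv.ravel() - u).max() < 1e-8

    def test_reliability_matches_independent_mme_inverse(self, ped_and_spec):
        ped, kin, spec = ped_and_spec
        rng = np.random.default_rng(2)
        phen = pd.DataFrame({"animal": ped.labels,
                             "trait1": rng.standard_normal(ped.n),
                             "trait2": rng.standard_normal(ped.n)})
        _, rel = animal_model_ebv_and_reliability(ped, phen, kin, spec)
        # independently assembled dense MME (pedigree order, trait-minor)
        t = 2
        n = ped.n
        a_inv = kin.a_inverse.toarray()
        rinv = np.linalg.inv(spec.r0)
        wtrw = np.kron(np.eye(n), rinv) + np.kron(a_inv, spec.g0_inv)
        xtrw = np.tile(rinv, (1, n))
        cmat = np.block([[n * rinv, xtrw], [xtrw.T, wtrw]])
        cinv = np.linalg.inv(cmat)
        pev = np.diagonal(cinv)[t:].reshape(n, t)
        expected = 1.0 - pev / ((1.0 + kin.F)[:, None] * np.diag(spec.g0)[None, :])
        assert np.abs(rel - np.clip(expected, 0, 1)).max() < 1e-8


class TestDeregression:
    def test_high_reliability_limit_recovers_ebv(self):
        l_i, _ = _garrick_information(1.0 - 1e-9, 0.0, lam=7 / 3)
        # DRP = (−2λ·PA + (l_i + 2λ)·EBV)/l_i → EBV as l_i → ∞
        assert l_i > 1e6

    def test_scalar_oracle(self):
        # independent route: solve the reliability equations numerically
        lam = (1 - 0.3) / 0.3
        r2_i, r2_pa = 0.5, 0.0

        def equations(v):
            l_i, l_pa = v
            c = np.array([[l_pa + 4 * lam, -2 * lam], [-2 * lam, l_i + 2 * lam]])
            ci = np.linalg.inv(c)
            return [1 - 2 * lam * ci[0, 0] - r2_pa, 1 - lam * ci[1, 1] - r2_i]

        sol = optimize.fsolve(equations, [1.0, 1.0], full_output=False)
        l_i_num, l_pa_num = sol
        l_i, l_pa = _garrick_information(r2_i, r2_pa, lam)
        assert l_i == pytest.approx(l_i_num, rel=1e-6)
        assert l_pa == pytest.approx(l_pa_num, rel=1e-6, abs=1e-6)
        # with parent EBV 0 and offspring EBV 1: DRP from the closed form
        drp = (-2 * lam * 0.0 + (l_i + 2 * lam) * 1.0) / l_i
        assert drp > 1.0  # deregression removes shrinkage

    def test_pipeline_excludes_no_data_animals(self):
        ped = validate_and_sort(make_random_pedigree(15, 5, seed=1))
        spec = ModelSpec(G0_2TRAIT, R0_2TRAIT)
        kin = inbreeding_and_a_inverse(ped)
        rng = np.random.default_rng(0)
        # last animal gets no record; ensure it also has no progeny
        recorded = ped.labels[:-1]
        phen = pd.DataFrame({"animal": recorded,
                             "trait1": rng.standard_normal(recorded.size),
                             "trait2": rng.standard_normal(recorded.size)})
        ebv, rel = animal_model_ebv_and_reliability(ped, phen, kin, spec)
        recs = deregress(ebv, rel, ped, phen, spec)
        last_label = ped.labels[-1]
        has_progeny = (ped.sire == ped.n - 1).any() or (ped.dam == ped.n - 1).any()
        if not has_progeny:
            assert all(r.animal != last_label for r in recs)
        assert all(r.weight > 0 for r in recs)


class TestBayesA:
    def test_null_data_weights_near_one(self):
        rng = np.random.default_rng(0)
        n, m = 120, 60
        z = rng.integers(0, 3, (n, m)).astype(float) - 1.0
        y = rng.standard_normal(n)
        cfg = BayesAConfig(scale=bayesa_prior_scale(0.3, m * 0.5), chain=2000,
                           burn_in=500, seed=4)
        sig2, _ = bayesa_gibbs(y, np.ones(n), z, cfg, use_numba=False)
        w = weights_from_variances(sig2)
        # no marker stands out under the null
        assert abs(w.mean() - 1.0) < 1e-12
        assert w.max() < 5.0

    def test_single_large_qtl_gets_max_variance(self):
        rng = np.random.default_rng(1)
        n, m = 200, 200
        z = rng.binomial(2, 0.5, (n, m)).astype(float)
        z -= z.mean(axis=0)
        beta = np.zeros(m)
        beta[37] = 1.0
        g = z @ beta
        y = g + rng.standard_normal(n) * g.std()  # QTL explains ~50% of variance
        cfg = BayesAConfig(scale=bayesa_prior_scale(g.var(), m * 0.5), chain=1500,
                           burn_in=300, seed=5)
        sig2, _ = bayesa_gibbs(y, np.ones(n), z, cfg)
        assert np.argmax(sig2) == 37

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(2)
        z = rng.binomial(2, 0.4, (50, 30)).astype(float)
        y = rng.standard_normal(50)
        cfg = BayesAConfig(scale=1e-3, chain=300, burn_in=50, seed=9)
        s1, g1 = bayesa_gibbs(y, np.ones(50), z, cfg)
        s2, g2 = bayesa_gibbs(y, np.ones(50), z, cfg)
        assert np.array_equal(s1, s2) and np.array_equal(g1, g2)

    def test_chain_shorter_than_burnin_rejected(self):
        with pytest.raises(ValueError, match="burn-in"):
            BayesAConfig(chain=100, burn_in=100)

    def test_sparse_architecture_weight_recovery(self):
        # 10 of 300 markers carry ~80% of the genetic variance
        rng = np.random.default_rng(3)
        n, m = 250, 300
        z = rng.binomial(2, 0.5, (n, m)).astype(float)
        z -= z.mean(axis=0)
        causal = rng.choice(m, 10, replace=False)
        beta = np.zeros(m)
        beta[causal] = rng.standard_normal(10) * 1.0
        bg = np.setdiff1d(np.arange(m), causal)
        beta[bg] = rng.standard_normal(bg.size) * np.sqrt(
            0.25 * (beta[causal] ** 2 * 0.5).sum() / (bg.size * 0.5))
        g = z @ beta
        y = g + rng.standard_normal(n) * g.std() * 0.8
        cfg = BayesAConfig(scale=bayesa_prior_scale(g.var(), m * 0.5), chain=1500,
                           burn_in=300, seed=6)
        sig2, _ = bayesa_gibbs(y, np.ones(n), z, cfg)
        w = weights_from_variances(sig2)
        assert w[causal].mean() > w[bg].mean()


class TestWeightsFromVariances:
    def test_constant_variances(self):
        assert np.allclose(weights_from_variances(np.full(5, 0.2)), 1.0)

    def test_two_values(self):
        assert np.allclose(weights_from_variances(np.array([1.0, 3.0])), [0.5, 1.5])

    def test_rank_preserved(self):
        rng = np.random.default_rng(0)
        s = rng.gamma(1, 1, 50)
        w = weights_from_variances(s)
        rho = stats.spearmanr(s, w).statistic
        assert rho == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            weights_from_variances(np.zeros(3))
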