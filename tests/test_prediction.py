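"""Tests for the six GEBV methods and their supporting linear algebra."""

import numpy as np
import pandas as pd
import pytest

from caprigen import evaluation as ev, prediction as pr, quantgen as qg
from .conftest import random_pedigree


def hwe_genotypes(rng, n, m, lo=0.1, hi=0.9):
    p = rng.uniform(lo, hi, m)
    return rng.binomial(2, p, size=(n, m)).astype(float)


class TestGRM:
    def test_single_locus_hand_example(self):
        g = pr.build_grm(np.array([[0.0], [1.0], [2.0]]))
        assert g.denom == pytest.approx(0.5)
        assert np.allclose(g.G, [[2, 0, -2], [0, 0, 0], [-2, 0, 2]])

    def test_mean_diagonal_near_one_under_hwe(self, rng):
        X = hwe_genotypes(rng, 400, 5000)
        g = pr.build_grm(X)
        assert 0.95 < np.diag(g.G).mean() < 1.05

    def test_duplicated_individuals_give_identical_rows(self, rng):
        X = hwe_genotypes(rng, 20, 100)
        X2 = np.vstack([X, X[:1]])
        g = pr.build_grm(X2)
        assert np.allclose(g.G[0], g.G[-1])

    def test_monomorphic_panel_rejected(self):
        with pytest.raises(ValueError):
            pr.build_grm(np.full((5, 4), 2.0))


class TestGBLUP:
    def test_equivalent_to_rr_blup_with_matched_variances(self, rng):
        """Kernel-form GBLUP == explicit ridge MME on a 50 x 200 instance."""
        n, m, h2 = 50, 200, 0.4
        X = hwe_genotypes(rng, n, m)
        y = rng.normal(0, 1, n)
        est = pr.GBLUP(h2=h2).fit(X, y)
        p = X.mean(0) / 2
        Zc = X - 2 * p
        lam = 2 * np.sum(p * (1 - p)) * (1 - h2) / h2
        C = np.block([[np.array([[float(n)]]), Zc.sum(0)[None, :]],
                      [Zc.sum(0)[:, None], Zc.T @ Zc + lam * np.eye(m)]])
        sol = np.linalg.solve(C, np.concatenate([[y.sum()], Zc.T @ y]))
        Xv = hwe_genotypes(rng, 30, m)
        assert np.max(np.abs(est.predict(Xv) - (Xv - 2 * p) @ sol[1:])) <= 1e-6

    def test_matches_joint_G_mixed_model(self, rng):
        """Marker-effect predictions equal the G-based animal-model solve."""
        n, m, h2 = 40, 300, 0.3
        X = hwe_genotypes(rng, n, m)
        y = rng.normal(0, 1, n)
        est = pr.GBLUP(h2=h2).fit(X, y)
        G = pr.build_grm(X).G
        lam = (1 - h2) / h2
        Ginv = np.linalg.inv(G + 1e-8 * np.eye(n))
        C = np.block([[np.array([[float(n)]]), np.ones((1, n))],
                      [np.ones((n, 1)), np.eye(n) + lam * Ginv]])
        sol = np.linalg.solve(C, np.concatenate([[y.sum()], y]))
        assert np.max(np.abs(est.predict(X) - sol[1:])) < 1e-4

    def test_permutation_equivariance(self, rng):
        X = hwe_genotypes(rng, 30, 80)
        y = rng.normal(0, 1, 30)
        est = pr.GBLUP(h2=0.34).fit(X, y)
        perm = rng.permutation(30)
        assert np.allclose(est.predict(X)[perm], est.predict(X[perm]))

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            pr.GBLUP(h2=0.34).fit(np.empty((0, 5)), np.empty(0))

    def test_sklearn_param_interface(self):
        est = pr.GBLUP(h2=0.11, blend=0.05)
        assert est.get_params()["h2"] == 0.11
        est.set_params(h2=0.34)
        assert est.h2 == 0.34


class TestSSGBLUP:
    def _setup(self, seed=4, n_founders=16, n_offspring=120):
        ped = random_pedigree(n_founders, n_offspring, seed=seed)
        rng = np.random.default_rng(seed)
        n = len(ped)
        y = pd.Series(rng.normal(0, 1, n), index=ped["id"])
        X = pd.DataFrame(hwe_genotypes(rng, n, 200),
                         index=pd.Index(ped["id"], name="id"))
        return ped, y, X, rng

    def test_reduces_to_pedigree_blup_when_G_equals_A(self):
        ped, y, X, _ = self._setup()
        A = qg.relationship_matrix(ped)
        res = pr.ssgblup(y, ped, X, 0.3, G=A)
        ebv, _ = qg.pedigree_blup(y.to_numpy(), ped, 0.3)
        assert np.max(np.abs(res.gebv.to_numpy() - ebv)) <= 1e-6

    def test_full_blend_reduces_to_pedigree_blup(self):
        ped, y, X, _ = self._setup()
        est = pr.SSGBLUP(h2=0.3, blend=1.0).fit(ped, y, X)
        ebv, _ = qg.pedigree_blup(y.to_numpy(), ped, 0.3)
        assert np.max(np.abs(est.gebv_.to_numpy() - ebv)) <= 1e-6

    def test_ungenotyped_dam_receives_information(self):
        ped = pd.DataFrame({"id": [1, 2, 3, 4], "sire": [0, 0, 1, 1],
                            "dam": [0, 0, 2, 2]})
        rng = np.random.default_rng(0)
        y = pd.Series([0.5, np.nan, 1.0, -0.3], index=[1, 2, 3, 4])
        X = pd.DataFrame(hwe_genotypes(rng, 3, 50), index=[1, 3, 4])
        res = pr.ssgblup(y, ped, X, 0.3)
        assert res.gebv.loc[2] != 0.0

    def test_genotyped_animal_missing_from_pedigree_rejected(self):
        ped, y, X, _ = self._setup()
        X_bad = X.copy()
        X_bad.index = [99999] + list(X.index[1:])
        with pytest.raises(KeyError):
            pr.ssgblup(y, ped, X_bad, 0.3)


class TestBayesSamplers:
    def test_constant_phenotype_gives_null_effects(self, rng):
        X = hwe_genotypes(rng, 50, 40)
        y = np.full(50, 3.7)
        est = pr.BayesB(n_iter=800, burn_in=200, thin=2, random_state=1).fit(X, y)
        assert np.max(np.abs(est.effects_)) < 0.01
        assert est.mu_ == pytest.approx(3.7, abs=0.05)

    def test_brr_fixed_variances_matches_ridge(self, rng):
        """Conjugate BRR with known variances == closed-form ridge posterior."""
        n, m = 30, 100
        X = hwe_genotypes(rng, n, m)
        y = X @ rng.normal(0, 0.05, m) + rng.normal(0, 0.5, n)
        sg, se = 0.01, 0.25
        est = pr.BayesRR(n_iter=20000, burn_in=4000, thin=1,
                         fixed_marker_var=sg, fixed_resid_var=se,
                         random_state=11).fit(X, y)
        p = X.mean(0) / 2
        Zc = X - 2 * p
        C = np.block([[np.array([[float(n)]]), Zc.sum(0)[None, :]],
                      [Zc.sum(0)[:, None], Zc.T @ Zc + (se / sg) * np.eye(m)]])
        sol = np.linalg.solve(C, np.concatenate([[y.sum()], Zc.T @ y]))
        rms = np.sqrt(np.mean((est.effects_ - sol[1:]) ** 2))
        assert rms <= 0.02

    def test_bayesa_and_brr_agree_on_polygenic_data(self, rng):
        """Near-infinitesimal architecture: corr(GEBV_A, GEBV_RR) > 0.95."""
        n, m = 500, 1000
        X = hwe_genotypes(rng, n, m)
        p = X.mean(0) / 2
        b = rng.normal(0, 1, m)
        g = (X - 2 * p) @ b
        g = g / g.std() * np.sqrt(0.5)
        y = g + rng.normal(0, np.sqrt(0.5), n)
        kw = dict(h2=0.5, n_iter=2000, burn_in=500, thin=5)
        ga = pr.BayesA(random_state=1, **kw).fit(X, y).predict(X)
        gr = pr.BayesRR(random_state=2, **kw).fit(X, y).predict(X)
        assert np.corrcoef(ga, gr)[0, 1] > 0.95
        assert np.corrcoef(ga, g)[0, 1] > 0.5

    def test_residual_variance_recovered_within_posterior_sd(self, rng):
        """Posterior se2 within 3 posterior SDs of the simulating value."""
        n, m = 300, 50
        X = hwe_genotypes(rng, n, m)
        p = X.mean(0) / 2
        denom = 2 * np.sum(p * (1 - p))
        b = rng.normal(0, np.sqrt(0.3 / denom), m)
        se_true = 0.7
        y = (X - 2 * p) @ b + rng.normal(0, np.sqrt(se_true), n)
        est = pr.BayesRR(h2=0.3, n_iter=3000, burn_in=1000, thin=2,
                         random_state=7).fit(X, y)
        assert abs(est.resid_var_ - se_true) < 3 * est.resid_var_sd_

    @pytest.mark.parametrize("bad", [dict(n_iter=0), dict(n_iter=100, burn_in=100)])
    def test_invalid_chain_settings_rejected(self, bad, rng):
        X = hwe_genotypes(rng, 10, 5)
        with pytest.raises(ValueError):
            pr.BayesA(**bad).fit(X, np.zeros(10))


class TestPredictGebv:
    def _posterior(self, effects, p):
        return pr.MarkerEffectPosterior(
            method="BayesA", effects=np.asarray(effects, dtype=float),
            marker_vars=np.ones(len(effects)), inclusion=np.ones(len(effects)),
            mu=0.0, resid_var=1.0, resid_var_sd=0.1,
            allele_freqs=np.asarray(p, dtype=float), nu=4.2, S=0.01, pi=0.0)

    def test_zero_effects_give_zero_gebv(self):
        post = self._posterior([0.0, 0.0], [0.3, 0.6])
        X = pd.DataFrame([[0, 1], [2, 2]], index=[1, 2])
        res = pr.predict_gebv(post, X)
        assert np.allclose(res.gebv, 0.0)

    def test_single_marker_closed_form(self):
        post = self._posterior([1.0], [0.3])
        X = pd.DataFrame([[0], [1], [2]], index=[1, 2, 3])
        res = pr.predict_gebv(post, X)
        assert np.allclose(res.gebv, np.array([0, 1, 2]) - 0.6)

    def test_panel_mismatch_rejected(self):
        post = self._posterior([1.0, 2.0], [0.3, 0.4])
        with pytest.raises(ValueError):
            pr.predict_gebv(post, pd.DataFrame([[0]], index=[1]))

    def test_predict_is_idempotent_on_reference(self, rng):
        X = hwe_genotypes(rng, 40, 60)
        y = rng.normal(0, 1, 40)
        est = pr.BayesLasso(n_iter=600, burn_in=200, thin=2,
                            random_state=3).fit(X, y)
        assert np.allclose(est.predict(X), est.predict(X.copy()))


def test_all_methods_positively_correlated_with_tbv(micro_recent):
    """Every method's GEBV correlates positively with TBV across replicate
    reference/validation splits of a simulated population (h2 = 0.34)."""
    chain = dict(n_iter=600, burn_in=200, thin=2)
    accs = {m: [] for m in ev.ALL_METHODS}
    for rep in range(10):
        rng = np.random.default_rng(1000 + rep)
        sc = ev.make_scenario(micro_recent, 300, 150, rng)
        for method in ev.ALL_METHODS:
            gebv = ev.fit_method(method, sc, seed=rep, chain_kwargs=chain)
            accs[method].append(
                ev.compute_accuracy(gebv, sc.tbv.loc[sc.val_ids]))
    for method, vals in accs.items():
        assert np.mean(vals) > 0, f"{method} mean accuracy not positive"
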