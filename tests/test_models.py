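import numpy as np
import pytest

import gsel
from gsel.models import (
    center_dosages,
    fit_sampler_fixed_variances,
    reml_variance_components,
    ridge_solution,
)


def _split(g, y, n_test):
    n = g.n_samples
    tr, te = np.arange(n - n_test), np.arange(n - n_test, n)
    g_tr, g_te = g.take_samples(tr), g.take_samples(te)
    y_tr = gsel.standardize(
        gsel.TraitVector(y.trait_name, [y.sample_ids[i] for i in tr], y.values[tr])
    )
    return g_tr, y_tr, g_te, y.values[te]


@pytest.fixture(scope="module")
def sim_data():
    cfg = gsel.SimConfig(
        n_samples=220,
        n_markers=400,
        n_chromosomes=5,
        chromosome_length_bp=800_000,
        ld_decay_bp=40_000,
        n_qtl=20,
        target_h2=0.6,
        seed=51,
    )
    g = gsel.sim_genotypes(cfg)
    y, truth = gsel.sim_phenotype(g, cfg)
    return g, gsel.standardize(y), truth


class TestKinship:
    def test_duplicated_individuals_share_relationship(self, toy):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(4, 60))
        d[1] = d[0]
        K = gsel.kinship(toy(d)).values
        assert K[0, 1] == pytest.approx(K[0, 0], abs=1e-10)
        assert K[0, 1] == pytest.approx(K[1, 1], abs=1e-10)

    def test_two_by_two_hand_computed(self, toy):
        d = np.array([[0, 2], [2, 0]])
        K = gsel.kinship(toy(d)).values
        # centred dosages are +/-1, so ZZ' = [[2,-2],[-2,2]]; mean diag -> 1
        np.testing.assert_allclose(K, [[1, -1], [-1, 1]], atol=1e-10)

    def test_mean_diagonal_is_one_and_psd(self, sim_data):
        g, _, _ = sim_data
        K = gsel.kinship(g).values
        assert np.mean(np.diag(K)) == pytest.approx(1.0, abs=1e-12)
        assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_unrelated_individuals_near_zero_offdiagonal(self):
        cfg = gsel.SimConfig(
            n_samples=60,
            n_markers=5000,
            n_chromosomes=5000,
            chromosome_length_bp=1000,
            seed=5,
        )
        g = gsel.sim_genotypes(cfg)
        K = gsel.kinship(g).values
        off = K[~np.eye(60, dtype=bool)]
        # centring by estimated frequencies forces mean off-diagonal to
        # -1/(n-1) exactly; it vanishes with n, and individual entries are
        # near zero for unrelated samples
        assert off.mean() == pytest.approx(-1 / 59, abs=1e-6)
        assert np.abs(off).max() < 0.2


class TestREMLAndLinearFamilies:
    def test_rrblup_equals_gblup_train_and_test(self, sim_data):
        g, y, _ = sim_data
        g_tr, y_tr, g_te, _ = _split(g, y, 40)
        f_rr = gsel.fit(gsel.ModelSpec("rrblup"), g_tr, y_tr)
        f_gb = gsel.fit(gsel.ModelSpec("gblup"), g_tr, y_tr)
        np.testing.assert_allclose(
            f_rr.fitted_gebv, f_gb.fitted_gebv, atol=1e-6
        )
        np.testing.assert_allclose(
            gsel.predict_gebv(f_rr, g_te), gsel.predict_gebv(f_gb, g_te),
            atol=1e-6,
        )
        assert f_rr.sigma2_a == pytest.approx(f_gb.sigma2_a, rel=1e-8)

    def test_noiseless_trait_fits_nearly_exactly(self, sim_data):
        g, _, truth = sim_data
        gv = truth.genetic_values
        y = gsel.standardize(
            gsel.TraitVector("pure", list(g.samples), gv)
        )
        f = gsel.fit(gsel.ModelSpec("rrblup"), g, y)
        r = np.corrcoef(f.fitted_gebv, y.values)[0, 1]
        assert r > 0.999

    def test_training_prediction_reproduces_fitted(self, sim_data):
        g, y, _ = sim_data
        for family in ("rrblup", "gblup", "rkhs"):
            f = gsel.fit(gsel.ModelSpec(family), g, y)
            np.testing.assert_allclose(
                gsel.predict_gebv(f, g), f.fitted_gebv, atol=1e-8
            )

    def test_intercept_absorbs_phenotype_shift(self, sim_data):
        g, y, _ = sim_data
        g_tr, y_tr, g_te, _ = _split(g, y, 40)
        shifted = gsel.TraitVector(
            "shift", y_tr.sample_ids, y_tr.values + 3.7
        )
        with pytest.warns(UserWarning, match="standardized"):
            f0 = gsel.fit(gsel.ModelSpec("rrblup"), g_tr, gsel.TraitVector(
                "raw", y_tr.sample_ids, y_tr.values))
            f1 = gsel.fit(gsel.ModelSpec("rrblup"), g_tr, shifted)
        np.testing.assert_allclose(
            gsel.predict_gebv(f1, g_te),
            gsel.predict_gebv(f0, g_te) + 3.7,
            atol=1e-8,
        )

    def test_marker_effect_gebv_identity(self, sim_data):
        g, y, _ = sim_data
        f = gsel.fit(gsel.ModelSpec("rrblup"), g, y)
        Z, _ = center_dosages(g.dosages.astype(float), f.train_freqs)
        np.testing.assert_allclose(
            f.fitted_gebv, Z @ f.alpha + f.intercept, atol=1e-10
        )

    def test_reml_recovers_variance_ratio_on_gaussian_data(self):
        # y = u + e with Var(u) = 2K, Var(e) = 1: REML at n=400 should land
        # near the truth
        rng = np.random.default_rng(9)
        n = 400
        A = rng.standard_normal((n, 800)) / np.sqrt(800)
        K = A @ A.T
        K *= n / np.trace(K)
        L = np.linalg.cholesky(K + 1e-10 * np.eye(n))
        y = L @ rng.standard_normal(n) * np.sqrt(2.0) + rng.standard_normal(n)
        res = reml_variance_components(K, y)
        assert res.sigma2_g == pytest.approx(2.0, rel=0.35)
        assert res.sigma2_e == pytest.approx(1.0, rel=0.35)


class TestSamplers:
    def test_brr_fixed_variances_matches_ridge_closed_form(self, sim_data):
        g, y, _ = sim_data
        s2a, s2e = 2e-3, 0.5
        f = fit_sampler_fixed_variances(
            gsel.ModelSpec("brr", iterations=8000, burn_in=1000, seed=4),
            g, y, s2a, s2e,
        )
        Z, _ = center_dosages(g.dosages.astype(float))
        mu, alpha = ridge_solution(Z, y.values, s2e / s2a)
        r = np.corrcoef(f.alpha, alpha)[0, 1]
        assert r > 0.99
        assert f.intercept == pytest.approx(mu, abs=0.05)

    def test_bayesb_with_pi_one_matches_bayesa(self):
        cfg = gsel.SimConfig(
            n_samples=200,
            n_markers=300,
            n_chromosomes=5,
            chromosome_length_bp=500_000,
            ld_decay_bp=30_000,
            n_qtl=5,
            target_h2=0.7,
            seed=61,
        )
        g = gsel.sim_genotypes(cfg)
        y, _ = gsel.sim_phenotype(g, cfg)
        ys = gsel.standardize(y)
        chain = dict(iterations=10_000, burn_in=2_000, thin=5)
        fa = gsel.fit(gsel.ModelSpec("bayesA", seed=1, **chain), g, ys)
        fb = gsel.fit(gsel.ModelSpec("bayesB", pi=1.0, seed=2, **chain), g, ys)
        r = np.corrcoef(fa.alpha, fb.alpha)[0, 1]
        assert r > 0.98

    def test_bayesb_sparsity_recovers_large_qtl(self):
        found = []
        for seed in range(10):
            cfg = gsel.SimConfig(
                n_samples=250,
                n_markers=400,
                n_chromosomes=5,
                chromosome_length_bp=500_000,
                ld_decay_bp=30_000,
                n_qtl=5,
                qtl_effect_dist="equal",
                target_h2=0.7,
                seed=300 + seed,
            )
            g = gsel.sim_genotypes(cfg)
            y, truth = gsel.sim_phenotype(g, cfg)
            f = gsel.fit(
                gsel.ModelSpec(
                    "bayesB", pi=0.05, iterations=2500, burn_in=500, seed=seed
                ),
                g,
                gsel.standardize(y),
            )
            top5 = np.argsort(-np.abs(f.alpha))[:5]
            D = g.dosages.astype(float)
            n_linked = 0
            for t in top5:
                for q in truth.qtl_indices:
                    if abs(np.corrcoef(D[:, t], D[:, q])[0, 1]) >= 0.9:
                        n_linked += 1
                        break
            found.append(n_linked)
        assert np.mean(found) >= 4

    def test_brr_posterior_interval_covers_true_residual_variance(self):
        # data simulated from the BRR prior itself; the 95% credible
        # interval for sigma2_e should cover the truth at ~95%
        rng = np.random.default_rng(13)
        n, m = 120, 150
        covered = 0
        reps = 40
        for rep in range(reps):
            X = rng.integers(0, 3, size=(n, m)).astype(float)
            Z, _ = center_dosages(X)
            s2a_true, s2e_true = 0.5 / m * 2, 0.5
            alpha = rng.normal(0, np.sqrt(s2a_true), m)
            y = Z @ alpha + rng.normal(0, np.sqrt(s2e_true), n)
            g = gsel.GenotypeMatrix(
                [f"s{i}" for i in range(n)],
                [gsel.MarkerRecord(f"m{j}", "1", j + 1) for j in range(m)],
                X.astype(int),
                sort=False,
            )
            t = gsel.TraitVector("t", list(g.samples), y)
            f = gsel.fit(
                gsel.ModelSpec("brr", iterations=2000, burn_in=500, seed=rep),
                g,
                gsel.standardize(t),
            )
            # standardization rescales variances by 1/var(y)
            scale = np.var(y)
            lo, hi = np.percentile(f.chains["sigma2_e"] * scale, [2.5, 97.5])
            covered += lo <= s2e_true <= hi
        assert covered >= 0.85 * reps

    def test_chain_validation(self):
        with pytest.raises(ValueError):
            gsel.ModelSpec("bayesB", iterations=100, burn_in=200)
        with pytest.raises(ValueError):
            gsel.ModelSpec("bayesC", pi=0.0)
        with pytest.raises(ValueError):
            gsel.ModelSpec("nope")


class TestPredictErrors:
    def test_missing_marker_in_new_panel(self, sim_data):
        g, y, _ = sim_data
        f = gsel.fit(gsel.ModelSpec("rrblup"), g, y)
        g_sub = g.take_markers(range(10))
        with pytest.raises(KeyError, match="absent"):
            gsel.predict_gebv(f, g_sub)
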