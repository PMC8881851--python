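import numpy as np
import pytest
from scipy import stats

import gsel


class TestSplits:
    def test_test_size_rounding(self):
        plan = gsel.make_splits(346, 0.9, repeats=3, seed=0)
        for train, test in plan.splits:
            assert len(test) == 35  # round(0.1 * 346)
            assert len(train) == 311

    def test_same_seed_reproduces_plan(self):
        a = gsel.make_splits(100, 0.7, repeats=5, seed=9)
        b = gsel.make_splits(100, 0.7, repeats=5, seed=9)
        for (ta, sa), (tb, sb) in zip(a.splits, b.splits):
            np.testing.assert_array_equal(ta, tb)
            np.testing.assert_array_equal(sa, sb)

    def test_partition_set_algebra(self):
        plan = gsel.make_splits(57, 0.5, repeats=10, seed=3)
        universe = set(range(57))
        for train, test in plan.splits:
            assert set(train) | set(test) == universe
            assert set(train) & set(test) == set()

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            gsel.make_splits(100, 0.999, repeats=2, seed=0)
        with pytest.raises(ValueError):
            gsel.make_splits(5, 0.5)


class TestAccuracy:
    def test_perfect_and_affine(self):
        obs = np.array([1.0, 3.0, 2.0, 5.0])
        assert gsel.accuracy(obs, obs) == pytest.approx(1.0)
        assert gsel.accuracy(2.5 * obs + 1, obs) == pytest.approx(1.0)

    def test_hand_computed_four_pairs(self):
        assert gsel.accuracy(
            np.array([1.0, 2, 3, 4]), np.array([2.0, 1, 4, 3])
        ) == pytest.approx(0.6)

    def test_constant_side_flagged_missing(self):
        assert np.isnan(gsel.accuracy(np.ones(4), np.array([1.0, 2, 3, 4])))

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            gsel.accuracy(np.ones(2), np.ones(2))


class TestFTest:
    def test_identical_samples_give_f_one(self):
        a = np.array([1.0, 2, 3, 4, 5])
        F, p = gsel.f_test_two_variances(a, a)
        assert F == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_fourfold_variance_matches_f_distribution(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(10)
        a = (a - a.mean()) / a.std(ddof=1) * 2.0  # variance exactly 4
        b = rng.standard_normal(10)
        b = (b - b.mean()) / b.std(ddof=1)  # variance exactly 1
        F, p = gsel.f_test_two_variances(a, b)
        assert F == pytest.approx(4.0)
        d = stats.f(9, 9)
        assert p == pytest.approx(2 * min(d.sf(4.0), d.cdf(4.0)))

    def test_swap_inverts_f_and_preserves_p(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal(8), 2 * rng.standard_normal(12)
        F1, p1 = gsel.f_test_two_variances(a, b)
        F2, p2 = gsel.f_test_two_variances(b, a)
        assert F2 == pytest.approx(1 / F1)
        assert p2 == pytest.approx(p1)

    def test_zero_denominator_variance(self):
        with pytest.raises(ZeroDivisionError):
            gsel.f_test_two_variances([1.0, 2.0], [3.0, 3.0])


class TestRunCV:
    def test_marker_order_invariance(self, ld_panel, oligo_trait):
        _, g = ld_panel
        y, _ = oligo_trait
        plan = gsel.make_splits(g.n_samples, 0.9, repeats=2, seed=1)
        spec = gsel.ModelSpec("rrblup")
        base = gsel.run_cv(g, y, spec, gsel.full_panel(g), plan)
        rng = np.random.default_rng(2)
        perm = rng.permutation(g.n_markers)
        g_perm = gsel.GenotypeMatrix(
            g.samples,
            [g.markers[j] for j in perm],
            g.dosages[:, perm],
            sort=False,
        )
        permuted = gsel.run_cv(g_perm, y, spec, gsel.full_panel(g_perm), plan)
        np.testing.assert_allclose(
            base["accuracy"], permuted["accuracy"], atol=1e-10
        )

    def test_accuracy_increases_with_heritability(self):
        """Higher-h2 traits predict better: the core heritability-accuracy
        relationship, at reduced problem size."""
        cfg0 = gsel.SimConfig(
            n_samples=300,
            n_markers=500,
            n_chromosomes=5,
            chromosome_length_bp=800_000,
            ld_decay_bp=40_000,
            n_qtl=50,
            seed=81,
        )
        g = gsel.sim_genotypes(cfg0)
        plan = gsel.make_splits(g.n_samples, 0.9, repeats=5, seed=7)
        means = []
        for h2 in (0.2, 0.5, 0.8):
            cfg = gsel.SimConfig(**{**cfg0.__dict__, "target_h2": h2})
            y, _ = gsel.sim_phenotype(g, cfg)
            res = gsel.run_cv(
                g, gsel.standardize(y), gsel.ModelSpec("rrblup"),
                gsel.full_panel(g), plan,
            )
            means.append(res["accuracy"].mean())
        assert means[0] < means[1] < means[2]

    def test_excluding_qtl_linked_markers_lowers_accuracy(
        self, ld_panel, oligo_trait
    ):
        _, g = ld_panel
        y, truth = oligo_trait
        D = g.dosages.astype(float)
        R = np.corrcoef(D.T)
        linked = set()
        for q in truth.qtl_indices:
            linked |= set(np.flatnonzero(np.abs(R[q]) >= 0.5))
        keep = tuple(j for j in range(g.n_markers) if j not in linked)
        stripped = gsel.MarkerSubset("no_qtl", keep)
        plan = gsel.make_splits(g.n_samples, 0.9, repeats=5, seed=5)
        spec = gsel.ModelSpec("rrblup")
        full = gsel.run_cv(g, y, spec, gsel.full_panel(g), plan)
        crippled = gsel.run_cv(g, y, spec, stripped, plan)
        assert crippled["accuracy"].mean() < full["accuracy"].mean()

    def test_records_training_h2_when_asked(self, ld_panel, oligo_trait):
        _, g = ld_panel
        y, _ = oligo_trait
        plan = gsel.make_splits(g.n_samples, 0.7, repeats=2, seed=0)
        res = gsel.run_cv(
            g, y, gsel.ModelSpec("rrblup"), gsel.full_panel(g), plan,
            record_h2=True,
        )
        assert res["h2_train"].between(0, 1).all()

    def test_leakage_safe_mode_ignores_test_phenotypes(
        self, ld_panel, oligo_trait
    ):
        _, g = ld_panel
        y, _ = oligo_trait
        plan = gsel.make_splits(g.n_samples, 0.9, repeats=1, seed=2)
        train, test = plan.splits[0]

        def builder(g_tr, y_tr):
            scan = gsel.mlm_scan(g_tr, y_tr, gsel.kinship(g_tr))
            return gsel.subset_by_pvalue(scan, 0.05)

        y2_vals = y.values.copy()
        y2_vals[test[0]] += 100.0  # perturb a testing-only phenotype
        y2 = gsel.TraitVector("perturbed", y.sample_ids, y2_vals)

        def artifacts(trait):
            g_tr = g.take_samples(train)
            y_tr = gsel.standardize(
                gsel.TraitVector(
                    "t", [trait.sample_ids[i] for i in train],
                    trait.values[train],
                )
            )
            sub = builder(g_tr, y_tr)
            f = gsel.fit(gsel.ModelSpec("rrblup"), g_tr, y_tr, sub)
            return sub, gsel.predict_gebv(f, g.take_samples(test))

        sub1, pred1 = artifacts(y)
        sub2, pred2 = artifacts(y2)
        assert sub1.indices == sub2.indices
        np.testing.assert_allclose(pred1, pred2, atol=1e-12)


class TestBenchmarkGrid:
    def test_grid_cardinality_and_aggregation(self, ld_panel, oligo_trait):
        _, g = ld_panel
        y, _ = oligo_trait
        models = [gsel.ModelSpec("rrblup"), gsel.ModelSpec("gblup")]
        subsets = [
            gsel.full_panel(g),
            gsel.MarkerSubset("half", tuple(range(0, g.n_markers, 2))),
        ]
        grid = gsel.benchmark_grid(
            g, y, models, subsets, proportions=[0.9], repeats=2, seed=0
        )
        assert len(grid.records) == 2 * 2 * 1 * 2
        agg = grid.aggregate()
        for _, row in agg.iterrows():
            sub = grid.records[
                (grid.records["model"] == row["model"])
                & (grid.records["subset"] == row["subset"])
            ]
            assert row["accuracy"] == pytest.approx(sub["accuracy"].mean())
        assert 0.9 in grid.tables
        assert grid.tables[0.9].shape == (2, 2)

    def test_rerun_with_same_seed_is_identical(self, ld_panel, oligo_trait):
        _, g = ld_panel
        y, _ = oligo_trait
        kwargs = dict(
            models=[gsel.ModelSpec("rrblup")],
            subsets=[gsel.full_panel(g)],
            proportions=[0.5],
            repeats=2,
            seed=4,
        )
        a = gsel.benchmark_grid(g, y, **kwargs)
        b = gsel.benchmark_grid(g, y, **kwargs)
        np.testing.assert_array_equal(
            a.records["accuracy"], b.records["accuracy"]
        )
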