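import numpy as np
import pytest
from scipy import stats

import gsel


def _noise_trait(g, seed, standardized=True):
    rng = np.random.default_rng(seed)
    t = gsel.TraitVector("noise", list(g.samples), rng.standard_normal(g.n_samples))
    return gsel.standardize(t) if standardized else t


class TestMlmScan:
    def test_reduces_to_ols_when_additive_variance_is_zero(
        self, ld_panel, oligo_trait
    ):
        _, g = ld_panel
        y, _ = oligo_trait
        K = gsel.kinship(g)
        fixed = gsel.mlm_scan(g, y, K, variance_components=(0.0, 1.0))
        # OLS oracle per marker
        for j in (0, 123, 599):
            x = g.dosages[:, j].astype(float)
            slope, _, _, p, _ = stats.linregress(x, y.values)
            row = fixed.table.iloc[j]
            assert row["effect"] == pytest.approx(slope, abs=1e-6)
            assert row["p"] == pytest.approx(p, abs=1e-6)

    def test_null_pvalues_uniform(self):
        # independent markers (one per chromosome), pure-noise trait,
        # identity-scaled kinship: p-values should be Uniform(0,1)
        cfg = gsel.SimConfig(
            n_samples=250,
            n_markers=200,
            n_chromosomes=200,
            chromosome_length_bp=10_000,
            seed=23,
        )
        g = gsel.sim_genotypes(cfg)
        K = gsel.KinshipMatrix(np.eye(g.n_samples))
        ks_crit_1pct = 1.63 / np.sqrt(g.n_markers)
        passed = 0
        for seed in range(10):
            scan = gsel.mlm_scan(g, _noise_trait(g, 100 + seed), K)
            ks = stats.kstest(scan.p, "uniform").statistic
            passed += ks < ks_crit_1pct
        assert passed >= 9

    def test_planted_qtl_is_top_hit_or_tightly_linked(self):
        cfg = gsel.SimConfig(
            n_samples=300,
            n_markers=400,
            n_chromosomes=4,
            chromosome_length_bp=800_000,
            ld_decay_bp=50_000,
            n_qtl=1,
            target_h2=0.5,
            seed=31,
        )
        g = gsel.sim_genotypes(cfg)
        y, truth = gsel.sim_phenotype(g, cfg)
        scan = gsel.mlm_scan(g, gsel.standardize(y), gsel.kinship(g))
        top = int(np.argmin(scan.p))
        qtl = int(truth.qtl_indices[0])
        r = np.corrcoef(
            g.dosages[:, top].astype(float), g.dosages[:, qtl].astype(float)
        )[0, 1]
        assert top == qtl or abs(r) >= 0.9

    def test_singular_design_rejected(self, ld_panel, oligo_trait):
        _, g = ld_panel
        y, _ = oligo_trait
        bad_cov = np.ones((g.n_samples, 1))  # collinear with the intercept
        with pytest.raises(ValueError, match="singular"):
            gsel.mlm_scan(g, y, covariates=bad_cov)

    def test_kinship_dimension_mismatch(self, ld_panel, oligo_trait):
        _, g = ld_panel
        y, _ = oligo_trait
        with pytest.raises(ValueError, match="dimension"):
            gsel.mlm_scan(g, y, gsel.KinshipMatrix(np.eye(5)))


class TestFarmCPU:
    def test_zero_qtl_trait_gives_empty_pseudo_set(self, ld_panel):
        _, g = ld_panel
        scan = gsel.farmcpu_scan(g, _noise_trait(g, 77))
        assert scan.metadata["pseudo_qtns"] == []
        assert scan.metadata["converged"]

    def test_two_independent_qtl_recovered(self):
        hits = 0
        for seed in range(10):
            cfg = gsel.SimConfig(
                n_samples=400,
                n_markers=500,
                n_chromosomes=5,
                chromosome_length_bp=500_000,
                ld_decay_bp=20_000,
                n_qtl=2,
                qtl_effect_dist="equal",
                target_h2=0.6,
                seed=200 + seed,
            )
            g = gsel.sim_genotypes(cfg)
            y, truth = gsel.sim_phenotype(g, cfg)
            chrom_of = lambda j: g.markers[j].chromosome
            if chrom_of(truth.qtl_indices[0]) == chrom_of(truth.qtl_indices[1]):
                hits += 1  # same-chromosome draw: not this example's regime
                continue
            scan = gsel.farmcpu_scan(g, gsel.standardize(y))
            found = 0
            for q in truth.qtl_indices:
                xq = g.dosages[:, q].astype(float)
                for p in scan.metadata["pseudo_qtns"]:
                    r = np.corrcoef(xq, g.dosages[:, p].astype(float))[0, 1]
                    if abs(r) >= 0.7:
                        found += 1
                        break
            hits += found == 2
        assert hits >= 8

    def test_single_marker_panel_reduces_to_mlm(self, ld_panel, oligo_trait):
        _, g = ld_panel
        y, _ = oligo_trait
        g1 = g.take_markers([0])
        a = gsel.farmcpu_scan(g1, y)
        b = gsel.mlm_scan(g1, y)
        assert a.p[0] == pytest.approx(b.p[0], abs=1e-12)


class TestSubsets:
    def test_partition_and_nesting(self, ld_panel, oligo_trait):
        _, g = ld_panel
        y, _ = oligo_trait
        scan = gsel.mlm_scan(g, y, gsel.kinship(g))
        s5 = gsel.subset_by_pvalue(scan, 0.5)
        s1 = gsel.subset_by_pvalue(scan, 0.1)
        s05 = gsel.subset_by_pvalue(scan, 0.05)
        ns = gsel.complement(scan, 0.05)
        assert (s5.name, s1.name, s05.name, ns.name) == (
            "SNP_5",
            "SNP_1",
            "SNP_05",
            "SNP_NS",
        )
        assert set(s05).issubset(s1) and set(s1).issubset(s5)
        assert len(s05) + len(ns) == g.n_markers
        assert set(s05).isdisjoint(ns)

    def test_sweep_is_nested_and_ends_with_full_panel(
        self, ld_panel, oligo_trait
    ):
        _, g = ld_panel
        y, _ = oligo_trait
        scan = gsel.mlm_scan(g, y, gsel.kinship(g))
        subsets = gsel.significance_sweep(scan)
        for a, b in zip(subsets, subsets[1:]):
            assert set(a).issubset(set(b))
        assert len(subsets[-1]) == g.n_markers
        single = gsel.significance_sweep(scan, [0.05])
        assert single[0].indices == gsel.subset_by_pvalue(scan, 0.05).indices

    def test_unsorted_thresholds_rejected(self, ld_panel, oligo_trait):
        _, g = ld_panel
        y, _ = oligo_trait
        scan = gsel.mlm_scan(g, y)
        with pytest.raises(ValueError, match="increasing"):
            gsel.significance_sweep(scan, [0.1, 0.05])

    def test_permutation_calibration(self, ld_panel, oligo_trait):
        """Permuting phenotype labels leaves ~5% of markers below p=0.05."""
        _, g = ld_panel
        y, _ = oligo_trait
        K = gsel.kinship(g)
        rng = np.random.default_rng(0)
        fracs = []
        for _ in range(10):
            perm = gsel.TraitVector(
                "perm", y.sample_ids, rng.permutation(y.values),
                standardized=True,
            )
            scan = gsel.mlm_scan(g, perm, K)
            fracs.append(len(gsel.subset_by_pvalue(scan, 0.05)) / g.n_markers)
        assert 0.03 <= np.mean(fracs) <= 0.07
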