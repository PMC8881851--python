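"""Simulate a genotype panel, damage it, and run QC + LD-kNNi imputation.

Builds a 200 x 500 dosage matrix with soybean-like slow LD decay, masks 5%
of cells and knocks out a few markers, then applies the standard filters
(missing rate > 10%, MAF <= 5%, monomorphic) and imputes what remains.
"""

import numpy as np

import gsel

cfg = gsel.SimConfig(
    n_samples=200,
    n_markers=500,
    n_chromosomes=5,
    chromosome_length_bp=1_000_000,
    ld_decay_bp=150_000,
    seed=42,
)
g = gsel.sim_genotypes(cfg)
print(f"simulated panel: {g.n_samples} samples x {g.n_markers} markers")

# damage: random missingness plus two heavily missing markers
rng = np.random.default_rng(42)
d = g.dosages.copy()
d[rng.random(d.shape) < 0.05] = gsel.MISSING
d[: int(0.3 * g.n_samples), :2] = gsel.MISSING
damaged = gsel.GenotypeMatrix(g.samples, g.markers, d, sort=False)

filtered, report = gsel.apply_qc(damaged, maf_threshold=0.05, missing_threshold=0.10)
print(
    f"QC: {report.n_input} in -> {report.n_retained} retained "
    f"({report.n_missing_removed} missing-rate, "
    f"{report.n_monomorphic_removed} monomorphic, "
    f"{report.n_maf_removed} low-MAF)"
)

imputed = gsel.impute_ldknni(filtered, k_neighbors=5, l_markers=20)
holes = filtered.missing_mask()
truth = g.take_markers(
    [g.marker_ids.index(m) for m in filtered.marker_ids]
)
concordance = (imputed.dosages[holes] == truth.dosages[holes]).mean()
print(
    f"imputed {int(holes.sum())} cells; concordance with the masked truth = "
    f"{concordance:.3f}"
)
print("(values near 1 mean local LD carries enough information to restore")
print(" the hidden genotypes; the mode-imputation baseline sits far lower)")
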