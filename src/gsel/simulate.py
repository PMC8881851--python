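"""Synthetic genotypes with tunable LD decay and additive traits.

Genotypes come from a first-order Markov process along each chromosome: a
latent Gaussian AR(1) field per haplotype, thresholded at each marker to a
biallelic allele at that marker's target frequency, with the two haplotypes
summed to a dosage.  The AR step correlation is calibrated numerically
(via bivariate-normal orthant probabilities, averaged over the simulated
allele-frequency spectrum) so that the expected dosage r² between markers
separated by ``ld_decay_bp`` bases equals 0.25 — mirroring the contrast
between a fast-decaying maize-like genome (~1 kb to r² = 0.25) and a
slow-decaying soybean-like genome (~150 kb).

Traits are strictly additive: a chosen number of QTL drawn uniformly among
markers, effect sizes from a configurable distribution, and residual noise
scaled (and orthogonalized against the genetic values) so the realized
narrow-sense heritability equals the target.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .containers import GenotypeMatrix, MarkerRecord, TraitVector


@dataclass(frozen=True)
class SimConfig:
    n_samples: int = 300
    n_markers: int = 2000
    n_chromosomes: int = 10
    chromosome_length_bp: int = 3_000_000
    ld_decay_bp: float = 150_000.0  # distance at which expected r2 = 0.25
    maf_min: float = 0.05
    n_qtl: int = 50
    qtl_effect_dist: str = "gaussian"  # gaussian | laplace | equal
    target_h2: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_markers, self.n_chromosomes) < 1:
            raise ValueError("counts must be positive")
        if not 0 < self.maf_min < 0.5:
            raise ValueError("maf_min must be in (0, 0.5)")
        if not 0 <= self.target_h2 < 1:
            raise ValueError("target_h2 must be in [0, 1)")
        if self.qtl_effect_dist not in ("gaussian", "laplace", "equal"):
            raise ValueError("qtl_effect_dist must be gaussian/laplace/equal")
        if self.ld_decay_bp <= 0:
            raise ValueError("ld_decay_bp must be positive")


@dataclass
class SimTruth:
    """Ground truth of a simulated trait."""

    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    genetic_values: np.ndarray
    realized_h2: float


# ---------------------------------------------------------------------------
# LD calibration: latent AR(1) step -> dosage r2
# ---------------------------------------------------------------------------

def _binary_corr(rho: float, q1: float, q2: float) -> float:
    """Pearson correlation of two thresholded standard normals."""
    t1, t2 = stats.norm.ppf(q1), stats.norm.ppf(q2)
    p11 = stats.multivariate_normal.cdf(
        [t1, t2], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
    )
    denom = math.sqrt(q1 * (1 - q1) * q2 * (1 - q2))
    return (p11 - q1 * q2) / denom


@lru_cache(maxsize=None)
def _latent_rho_for_r2(maf_min: float, target_r2: float = 0.25) -> float:
    """Latent correlation giving mean dosage r2 = target over the MAF band.

    Dosages are sums of two independent haplotypes, so the dosage
    correlation equals the haplotype-allele correlation; the expectation is
    taken over a quadrature grid of allele frequencies in (maf_min, 0.5).
    """
    grid = maf_min + (0.5 - maf_min) * (np.arange(5) + 0.5) / 5.0

    def mean_r2(rho: float) -> float:
        # alternate alleles sit on either side of 0.5 with equal chance, so
        # average same-side and opposite-side threshold pairs
        vals = [
            0.5 * _binary_corr(rho, q1, q2) ** 2
            + 0.5 * _binary_corr(rho, q1, 1.0 - q2) ** 2
            for q1 in grid
            for q2 in grid
        ]
        return float(np.mean(vals))

    return float(
        brentq(lambda r: mean_r2(r) - target_r2, 0.05, 0.999, xtol=1e-4)
    )


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def sim_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Simulate dosage genotypes with the configured LD decay and MAF band."""
    rng = np.random.default_rng(cfg.seed)
    per_chrom = _split_markers(cfg.n_markers, cfg.n_chromosomes)
    rho_star = _latent_rho_for_r2(round(cfg.maf_min, 6))
    # latent correlation at distance d: exp(-d / L); at ld_decay_bp it is rho*
    L = cfg.ld_decay_bp / (-math.log(rho_star))
    n_hap = 2 * cfg.n_samples

    markers: list[MarkerRecord] = []
    columns: list[np.ndarray] = []
    for c, m_c in enumerate(per_chrom, start=1):
        if m_c == 0:
            continue
        if m_c > cfg.chromosome_length_bp:
            raise ValueError(
                "n_markers exceeds available positions on a chromosome"
            )
        pos = np.sort(
            rng.choice(cfg.chromosome_length_bp, size=m_c, replace=False) + 1
        )
        z = np.empty((n_hap, m_c))
        z[:, 0] = rng.standard_normal(n_hap)
        for k in range(1, m_c):
            step = math.exp(-(pos[k] - pos[k - 1]) / L)
            z[:, k] = step * z[:, k - 1] + math.sqrt(
                max(1.0 - step * step, 1e-12)
            ) * rng.standard_normal(n_hap)
        freqs = rng.uniform(cfg.maf_min, 0.5, size=m_c)
        flip = rng.random(m_c) < 0.5  # let the alternate allele be major too
        freqs = np.where(flip, 1.0 - freqs, freqs)
        dos = _threshold_to_dosages(z, freqs)
        dos = _enforce_maf(dos, z, freqs, cfg.maf_min, rng)
        for k in range(m_c):
            markers.append(MarkerRecord(f"m{c}_{k + 1}", str(c), int(pos[k])))
        columns.append(dos)
    dosages = np.hstack(columns)
    samples = [f"s{i + 1:04d}" for i in range(cfg.n_samples)]
    return GenotypeMatrix(samples, markers, dosages, sort=False)


def _split_markers(n_markers: int, n_chromosomes: int) -> list[int]:
    base = n_markers // n_chromosomes
    extra = n_markers % n_chromosomes
    return [base + (1 if c < extra else 0) for c in range(n_chromosomes)]


def _threshold_to_dosages(z: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    thresh = stats.norm.ppf(freqs)
    alleles = (z < thresh[None, :]).astype(np.int8)
    return alleles[0::2] + alleles[1::2]


def _enforce_maf(
    dos: np.ndarray,
    z: np.ndarray,
    freqs: np.ndarray,
    maf_min: float,
    rng: np.random.Generator,
    max_rounds: int = 10,
) -> np.ndarray:
    """Re-threshold markers whose empirical MAF fell below the floor."""
    freqs = freqs.copy()
    for round_ in range(max_rounds):
        p = dos.mean(axis=0) / 2.0
        bad = np.minimum(p, 1 - p) < maf_min
        if not bad.any():
            return dos
        lo = min(0.5, max(2.0 * maf_min, 0.2)) if round_ < max_rounds - 1 else 0.5
        freqs[bad] = rng.uniform(lo, 0.5, size=int(bad.sum()))
        dos[:, bad] = _threshold_to_dosages(z[:, bad], freqs[bad])
    return dos


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def sim_phenotype(
    g: GenotypeMatrix, cfg: SimConfig, trait_name: str = "sim_trait"
) -> tuple[TraitVector, SimTruth]:
    """Additive trait y = sum_j x_j alpha_j + e at the target heritability.

    The residual is orthogonalized against the genetic values and scaled so
    the realized h2 (Var(g)/Var(y)) matches ``target_h2`` exactly in-sample.
    """
    if cfg.n_qtl > g.n_markers:
        raise ValueError("n_qtl exceeds the number of markers")
    if cfg.n_qtl == 0 and cfg.target_h2 > 0:
        raise ValueError("target_h2 > 0 requires at least one QTL")
    rng = np.random.default_rng(cfg.seed + 104729)  # decoupled from genotypes
    n = g.n_samples
    e_raw = rng.standard_normal(n)

    if cfg.n_qtl == 0:
        y = e_raw - e_raw.mean()
        truth = SimTruth(
            np.empty(0, dtype=int), np.empty(0), np.zeros(n), 0.0
        )
        return TraitVector(trait_name, list(g.samples), y), truth

    qtl = np.sort(rng.choice(g.n_markers, size=cfg.n_qtl, replace=False))
    effects = _draw_effects(cfg, rng)
    X = g.dosages[:, qtl].astype(np.float64)
    gvals = (X - X.mean(axis=0)) @ effects
    var_g = float(np.var(gvals))
    if cfg.target_h2 == 0 or var_g == 0:
        if cfg.target_h2 > 0:
            raise ValueError("all QTL are monomorphic; genetic variance is zero")
        warnings.warn(
            "target_h2 = 0 with QTL present: noise dominates, genetic "
            "values retained in the truth only",
            stacklevel=2,
        )
        y = e_raw - e_raw.mean()
        return (
            TraitVector(trait_name, list(g.samples), y),
            SimTruth(qtl, effects, gvals, 0.0),
        )
    # orthogonalize the residual against [1, g] and scale exactly
    basis = np.column_stack([np.ones(n), gvals])
    coef, *_ = np.linalg.lstsq(basis, e_raw, rcond=None)
    e = e_raw - basis @ coef
    var_e_target = var_g * (1.0 - cfg.target_h2) / cfg.target_h2
    e *= math.sqrt(var_e_target / np.var(e))
    y = gvals + e
    realized = var_g / float(np.var(y))
    return (
        TraitVector(trait_name, list(g.samples), y),
        SimTruth(qtl, effects, gvals, realized),
    )


def _draw_effects(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.qtl_effect_dist == "gaussian":
        return rng.standard_normal(cfg.n_qtl)
    if cfg.qtl_effect_dist == "laplace":
        return rng.laplace(0.0, 1.0, size=cfg.n_qtl)
    return rng.choice([-1.0, 1.0], size=cfg.n_qtl)  # equal magnitudes


# ---------------------------------------------------------------------------
# crop-shaped fixture bundles
# ---------------------------------------------------------------------------

#: Shapes and LD/heritability profiles emulating the three crop panels:
#: sample count x marker count, decay distance to r2 = 0.25, and two traits
#: of contrasting heritability per bundle.  Genome sizes are chosen so the
#: marker spacing makes the configured decay measurable from the data.
PRESETS = {
    "soybean-like": dict(
        n_samples=350,
        n_markers=2000,
        n_chromosomes=10,
        chromosome_length_bp=3_000_000,
        ld_decay_bp=150_000.0,
        n_qtl=20,
        h2_pair=(0.8, 0.6),
    ),
    "maize-like": dict(
        n_samples=280,
        n_markers=3000,
        n_chromosomes=10,
        chromosome_length_bp=150_000,
        ld_decay_bp=1_000.0,
        n_qtl=150,
        h2_pair=(0.85, 0.65),
    ),
    "rice-like": dict(
        n_samples=350,
        n_markers=2200,
        n_chromosomes=10,
        chromosome_length_bp=2_500_000,
        ld_decay_bp=123_000.0,
        n_qtl=60,
        h2_pair=(0.8, 0.55),
    ),
}


@dataclass
class FixtureBundle:
    name: str
    genotypes: GenotypeMatrix
    traits: list  # two TraitVector of contrasting h2
    truths: list  # matching SimTruth
    config: SimConfig


def make_fixture(preset: str, seed: int = 0) -> FixtureBundle:
    """One crop-shaped bundle: genotypes plus two traits of contrasting h2."""
    if preset not in PRESETS:
        raise KeyError(f"unknown preset {preset!r}; one of {sorted(PRESETS)}")
    p = dict(PRESETS[preset])
    h2_pair = p.pop("h2_pair")
    cfg = SimConfig(seed=seed, target_h2=h2_pair[0], **p)
    g = sim_genotypes(cfg)
    traits, truths = [], []
    for t, h2 in enumerate(h2_pair):
        cfg_t = replace(cfg, target_h2=h2, seed=seed + 7919 * (t + 1))
        tv, truth = sim_phenotype(g, cfg_t, trait_name=f"trait_h{int(h2 * 100)}")
        traits.append(tv)
        truths.append(truth)
    return FixtureBundle(preset, g, traits, truths, cfg)


def make_paper_like_fixtures(
    seed: int = 0, out_dir: Optional[str] = None
) -> dict[str, FixtureBundle]:
    """All three crop-shaped bundles; optionally written as CSV files."""
    bundles = {name: make_fixture(name, seed=seed) for name in PRESETS}
    if out_dir is not None:
        from .io import write_dosage_csv, write_phenotypes

        os.makedirs(out_dir, exist_ok=True)
        for name, b in bundles.items():
            stem = os.path.join(out_dir, name.replace("-like", ""))
            write_dosage_csv(b.genotypes, stem + "_genotypes.csv")
            write_phenotypes(b.traits, stem + "_phenotypes.csv")
            _write_truth(b, stem + "_truth.tsv")
    return bundles


def _write_truth(bundle: FixtureBundle, path: str) -> None:
    import pandas as pd

    rows = []
    for trait, truth in zip(bundle.traits, bundle.truths):
        for j, eff in zip(truth.qtl_indices, truth.qtl_effects):
            rows.append(
                {
                    "trait": trait.trait_name,
                    "qtl_marker": bundle.genotypes.marker_ids[j],
                    "effect": eff,
                    "realized_h2": truth.realized_h2,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
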