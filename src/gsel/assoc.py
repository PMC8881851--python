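"""Single-trait GWAS scans and significance-based marker subsets.

Two scans are provided:

* :func:`mlm_scan` — kinship-corrected mixed-linear-model scan.  Variance
  components are estimated once on the null (marker-free) model and reused
  for every marker test (the population-parameters-previously-determined
  shortcut), after which each marker is a generalized-least-squares t-test.
* :func:`farmcpu_scan` — a simplified iterative fixed/random scan in the
  FarmCPU spirit: alternate a fixed-effect scan (pseudo-QTN markers as
  covariates) with re-selection of pseudo-QTNs by p-value under a
  Bonferroni entry rule and mutual-LD de-duplication, until the set
  stabilizes.  This is a deliberately simplified re-implementation, not the
  published algorithm.

Subsets follow the nominal-threshold convention: SNP_5 / SNP_1 / SNP_05 at
p < 0.5 / 0.1 / 0.05, and SNP_NS the p >= 0.05 complement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, MarkerSubset, TraitVector
from .models import KinshipMatrix, center_dosages, reml_variance_components

_SUBSET_NAMES = {0.5: "SNP_5", 0.1: "SNP_1", 0.05: "SNP_05"}


@dataclass
class GWASResult:
    """Per-marker scan results aligned with the scanned panel's columns."""

    table: pd.DataFrame  # id, chromosome, position, effect, se, stat, p
    method: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = self.table["p"].to_numpy()
        if np.any(p <= 0) or np.any(p > 1):
            raise ValueError("p-values must lie in (0, 1]")

    @property
    def p(self) -> np.ndarray:
        return self.table["p"].to_numpy()

    @property
    def n_markers(self) -> int:
        return len(self.table)


def _weighted_marker_tests(
    Zstar: np.ndarray,
    ystar: np.ndarray,
    Xstar: np.ndarray,
    w: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """GLS t-tests of each marker given rotated data and weights.

    Per-marker residual variance is re-estimated (weighted RSS / df), so
    with unit weights this reduces exactly to the OLS t-test.
    """
    n, q = Xstar.shape
    WX = Xstar * w[:, None]
    XtWX = WX.T @ Xstar
    XtWy = WX.T @ ystar
    C = np.linalg.inv(XtWX)
    beta0 = C @ XtWy
    yWy = float(np.sum(w * ystar * ystar))
    rss0 = yWy - float(beta0 @ XtWy)

    A = WX.T @ Zstar  # q x m
    G = C @ A
    zWz = np.einsum("ij,ij->j", Zstar * w[:, None], Zstar)
    zWy = Zstar.T @ (w * ystar)
    denom = zWz - np.einsum("ij,ij->j", A, G)
    num = zWy - G.T @ XtWy
    df = n - q - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        effect = np.where(denom > 1e-12, num / denom, 0.0)
        rss = rss0 - effect * num
        rss = np.clip(rss, 1e-300, None)
        sigma2 = rss / df
        se = np.sqrt(np.where(denom > 1e-12, sigma2 / denom, np.inf))
        tstat = np.where(np.isfinite(se) & (se > 0), effect / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return effect, se, tstat, p


def mlm_scan(
    g: GenotypeMatrix,
    y: TraitVector,
    kinship: Optional[KinshipMatrix] = None,
    covariates: Optional[np.ndarray] = None,
    variance_components: Optional[tuple[float, float]] = None,
) -> GWASResult:
    """Kinship-corrected single-marker scan (Wald/t tests).

    ``variance_components`` = (sigma2_a, sigma2_e) overrides the null-model
    REML estimates; (0, 1) makes every test an ordinary least-squares
    t-test.  ``kinship=None`` also degenerates to OLS.
    """
    if g.samples != y.sample_ids:
        raise ValueError("samples of genotypes and phenotype are not aligned")
    if g.missing_mask().any():
        raise ValueError("scan requires a fully imputed matrix")
    yv = y.values.astype(np.float64)
    if np.isnan(yv).any():
        raise ValueError("phenotype contains missing values")
    n = g.n_samples
    X = np.ones((n, 1))
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
        if cov.shape[0] != n:
            cov = cov.T
        X = np.hstack([X, cov])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular fixed-effects design")

    Z = g.dosages.astype(np.float64)
    meta: dict = {"kinship": kinship is not None, "n_covariates": X.shape[1] - 1}
    if kinship is None:
        s = np.zeros(n)
        U = np.eye(n)
        sg, se_ = 0.0, 1.0
    else:
        if kinship.n != n:
            raise ValueError("kinship dimension mismatch")
        s, U = np.linalg.eigh(kinship.values)
        s = np.clip(s, 0.0, None)
        if variance_components is None:
            null = reml_variance_components(
                kinship.values, yv, X=X, eig=(s, U)
            )
            sg, se_ = null.sigma2_g, null.sigma2_e
        else:
            sg, se_ = variance_components
        meta["sigma2_a"], meta["sigma2_e"] = sg, se_
    w = 1.0 / (sg * s + se_)
    ystar = U.T @ yv
    Xstar = U.T @ X
    Zstar = U.T @ Z
    effect, se, tstat, p = _weighted_marker_tests(Zstar, ystar, Xstar, w)
    table = pd.DataFrame(
        {
            "id": g.marker_ids,
            "chromosome": [m.chromosome for m in g.markers],
            "position": g.positions,
            "effect": effect,
            "se": se,
            "stat": tstat,
            "p": p,
        }
    )
    return GWASResult(table=table, method="mlm", metadata=meta)


def farmcpu_scan(
    g: GenotypeMatrix,
    y: TraitVector,
    max_iterations: int = 10,
    entry_alpha: float = 0.01,
    dedup_r: float = 0.7,
) -> GWASResult:
    """Simplified FarmCPU-style iterative scan (see module docstring)."""
    m = g.n_markers
    bonferroni = entry_alpha / m
    scan = mlm_scan(g, y)  # iteration 1: plain fixed-effect scan
    pseudo: list[int] = []
    converged = False
    it = 0
    D = g.dosages.astype(np.float64)
    for it in range(1, max_iterations + 1):
        new_pseudo = _select_pseudo_qtns(scan.p, D, bonferroni, dedup_r)
        if set(new_pseudo) == set(pseudo) and it > 1:
            converged = True
            break
        pseudo = new_pseudo
        if not pseudo:
            converged = True
            break
        scan = _scan_with_pseudo_qtns(g, y, pseudo)
    else:
        warnings.warn(
            f"pseudo-QTN set did not stabilize in {max_iterations} iterations",
            stacklevel=2,
        )
    scan.metadata.update(
        {
            "pseudo_qtns": list(pseudo),
            "converged": converged,
            "iterations": it,
            "entry_rule": f"p < {entry_alpha}/m, |r| < {dedup_r} de-dup",
        }
    )
    scan.method = "farmcpu"
    return scan


def _select_pseudo_qtns(
    p: np.ndarray, D: np.ndarray, threshold: float, dedup_r: float
) -> list[int]:
    cand = np.flatnonzero(p < threshold)
    cand = cand[np.argsort(p[cand], kind="stable")]
    kept: list[int] = []
    for j in cand:
        ok = True
        for kj in kept:
            cj = np.corrcoef(D[:, j], D[:, kj])[0, 1]
            if np.isnan(cj) or abs(cj) >= dedup_r:
                ok = False
                break
        if ok:
            kept.append(int(j))
    return kept


def _scan_with_pseudo_qtns(
    g: GenotypeMatrix, y: TraitVector, pseudo: list[int]
) -> GWASResult:
    D = g.dosages.astype(np.float64)
    cov_all, _ = center_dosages(D[:, pseudo])
    scan = mlm_scan(g, y, covariates=cov_all)
    # a pseudo-QTN cannot be a covariate in its own test: refit those few
    # markers with the covariate set excluding themselves
    table = scan.table
    for k, j in enumerate(pseudo):
        others = [jj for jj in pseudo if jj != j]
        cov = center_dosages(D[:, others])[0] if others else None
        sub = g.take_markers([j])
        one = mlm_scan(sub, y, covariates=cov)
        table.iloc[j, table.columns.get_loc("effect")] = one.table["effect"].iloc[0]
        table.iloc[j, table.columns.get_loc("se")] = one.table["se"].iloc[0]
        table.iloc[j, table.columns.get_loc("stat")] = one.table["stat"].iloc[0]
        table.iloc[j, table.columns.get_loc("p")] = one.table["p"].iloc[0]
    return GWASResult(table=table, method="mlm+pseudoQTN", metadata=scan.metadata)


# ---------------------------------------------------------------------------
# subsetting by significance
# ---------------------------------------------------------------------------

def subset_by_pvalue(
    scan: GWASResult, p_threshold: float, name: Optional[str] = None
) -> MarkerSubset:
    """Markers with p < threshold (SNP_5 / SNP_1 / SNP_05 naming)."""
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must be in (0, 1)")
    idx = np.flatnonzero(scan.p < p_threshold)
    if name is None:
        name = _SUBSET_NAMES.get(p_threshold, f"SNP_p{p_threshold:g}")
    return MarkerSubset(
        name,
        tuple(int(i) for i in idx),
        provenance=f"{scan.method} scan, p < {p_threshold:g}",
    )


def complement(scan: GWASResult, p_threshold: float = 0.05) -> MarkerSubset:
    """Non-significant markers: p >= threshold (the SNP_NS set)."""
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must be in (0, 1)")
    idx = np.flatnonzero(scan.p >= p_threshold)
    return MarkerSubset(
        "SNP_NS",
        tuple(int(i) for i in idx),
        provenance=f"{scan.method} scan, p >= {p_threshold:g}",
    )


DEFAULT_SWEEP = (
    0.001,
    0.0025,
    0.005,
    0.0075,
    0.01,
    0.025,
    0.05,
    0.075,
    0.1,
    0.25,
    0.5,
    0.75,
)


def significance_sweep(
    scan: GWASResult, thresholds: Sequence[float] = DEFAULT_SWEEP
) -> list[MarkerSubset]:
    """Nested subsets at increasing thresholds, plus the complete panel."""
    thresholds = list(thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    subsets = [
        subset_by_pvalue(scan, t, name=f"SNP_p{t:g}") for t in thresholds
    ]
    subsets.append(
        MarkerSubset(
            "Com", tuple(range(scan.n_markers)), provenance="complete panel"
        )
    )
    return subsets


def write_scan_tsv(scan: GWASResult, path: str) -> None:
    scan.table.to_csv(path, sep="\t", index=False)
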