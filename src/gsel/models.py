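"""Whole-genome prediction models behind a single fit/predict contract.

Families
--------
``rrblup``
    Ridge-regression BLUP: REML variance components by profile likelihood on
    the eigendecomposition of the centred marker cross-product, marker
    effects by ridge with shrinkage ratio sigma2_e / sigma2_alpha.
``gblup``
    The same mixed model in breeding-value space: Var(u) = sigma2_a * K with
    K the genomic relationship matrix; held-out samples predicted through
    the train-test relationship block.  Numerically equivalent to rrblup
    when K is built from the same centred marker matrix.
``brr, bayesA, bayesB, bayesC, bayesian_lasso``
    The Bayesian alphabet via Gibbs sampling (see :mod:`gsel._gibbs`).
    bayesB/bayesC place prior inclusion probability ``pi`` (default 0.05) on
    each marker having a non-null effect.
``rkhs``
    Gaussian-kernel reproducing-kernel Hilbert space regression:
    K(i, j) = exp(-d_ij^2 / (h * mean(d^2))) plugged into the GBLUP
    machinery.

Phenotypes are expected standardized (zero mean, unit variance); a warning
is emitted otherwise.  Dosages are centred by the training-set allele
frequency and test-set centring reuses the training statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar

from . import _gibbs
from .containers import GenotypeMatrix, MarkerSubset, TraitVector, full_panel

FAMILIES = (
    "rrblup",
    "gblup",
    "brr",
    "bayesA",
    "bayesB",
    "bayesC",
    "bayesian_lasso",
    "rkhs",
)
_SAMPLER_CODE = {
    "brr": _gibbs.FAM_BRR,
    "bayesA": _gibbs.FAM_BAYESA,
    "bayesB": _gibbs.FAM_BAYESB,
    "bayesC": _gibbs.FAM_BAYESC,
    "bayesian_lasso": _gibbs.FAM_BL,
}


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

@dataclass
class KinshipMatrix:
    """n x n genomic relationship matrix, mean diagonal scaled to 1."""

    values: np.ndarray
    normalization: str = "mean_diag_1"

    def __post_init__(self) -> None:
        K = np.asarray(self.values, dtype=np.float64)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("kinship must be square")
        if not np.allclose(K, K.T, atol=1e-8):
            raise ValueError("kinship must be symmetric")
        self.values = 0.5 * (K + K.T)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def center_dosages(
    X: np.ndarray, freqs: Optional[np.ndarray] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Centre dosage columns by twice the allele frequency.

    Returns (Z, freqs); pass training ``freqs`` to centre new data with the
    training statistics.
    """
    X = np.asarray(X, dtype=np.float64)
    if freqs is None:
        freqs = X.mean(axis=0) / 2.0
    return X - 2.0 * freqs, freqs


def kinship(g: GenotypeMatrix, method: str = "vanraden") -> KinshipMatrix:
    """Genomic relationship matrix from centred dosages.

    ``vanraden`` divides the centred cross-product by 2*sum(p(1-p));
    ``cross_product`` divides by its mean diagonal.  Either way the result
    is rescaled so the mean diagonal is exactly 1.
    """
    if g.missing_mask().any():
        raise ValueError("kinship requires a fully imputed matrix")
    Z, p = center_dosages(g.dosages)
    if np.all((p == 0) | (p == 1)):
        raise ValueError("kinship undefined for an all-monomorphic panel")
    G = Z @ Z.T
    if method == "vanraden":
        denom = 2.0 * np.sum(p * (1.0 - p))
        G = G / denom
    elif method != "cross_product":
        raise ValueError(f"unknown kinship method {method!r}")
    scale = np.trace(G) / G.shape[0]
    return KinshipMatrix(G / scale)


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------

@dataclass
class REMLResult:
    sigma2_g: float
    sigma2_e: float
    beta: np.ndarray
    delta: float  # sigma2_e / sigma2_g at the optimum
    loglik: float
    boundary: bool
    eigvals: np.ndarray = field(repr=False, default=None)
    eigvecs: np.ndarray = field(repr=False, default=None)


_LOG_DELTA_LO, _LOG_DELTA_HI = np.log(1e-6), np.log(1e6)


def reml_variance_components(
    K: np.ndarray,
    y: np.ndarray,
    X: Optional[np.ndarray] = None,
    eig: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> REMLResult:
    """Single-kernel REML by profile likelihood over delta = s2e/s2g.

    Model: y = X beta + u + e, Var(u) = sigma2_g K, Var(e) = sigma2_e I.
    The likelihood is profiled on the eigendecomposition K = U S U'; the
    scalar search runs on log(delta) in [log 1e-6, log 1e6].
    """
    y = np.asarray(y, dtype=np.float64)
    n = y.shape[0]
    if X is None:
        X = np.ones((n, 1))
    q = X.shape[1]
    if eig is None:
        s, U = np.linalg.eigh(np.asarray(K, dtype=np.float64))
    else:
        s, U = eig
    s = np.clip(s, 0.0, None)
    ystar = U.T @ y
    Xstar = U.T @ X

    def neg_remll(log_delta: float) -> float:
        delta = np.exp(log_delta)
        w = 1.0 / (s + delta)
        XtWX = (Xstar * w[:, None]).T @ Xstar
        XtWy = Xstar.T @ (w * ystar)
        beta = np.linalg.solve(XtWX, XtWy)
        r = ystar - Xstar @ beta
        rwr = float(np.sum(r * r * w))
        nq = n - q
        sign, logdet_x = np.linalg.slogdet(XtWX)
        if sign <= 0 or rwr <= 0:
            return np.inf
        return 0.5 * (
            nq * np.log(rwr / nq) + np.sum(np.log(s + delta)) + logdet_x + nq
        )

    res = minimize_scalar(
        neg_remll,
        bounds=(_LOG_DELTA_LO, _LOG_DELTA_HI),
        method="bounded",
        options={"xatol": 1e-12, "maxiter": 500},
    )
    log_delta = float(res.x)
    boundary = (
        log_delta - _LOG_DELTA_LO < 1e-3 or _LOG_DELTA_HI - log_delta < 1e-3
    )
    delta = float(np.exp(log_delta))
    w = 1.0 / (s + delta)
    XtWX = (Xstar * w[:, None]).T @ Xstar
    XtWy = Xstar.T @ (w * ystar)
    beta = np.linalg.solve(XtWX, XtWy)
    r = ystar - Xstar @ beta
    sigma2_g = float(np.sum(r * r * w) / (n - q))
    sigma2_e = delta * sigma2_g
    return REMLResult(
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        beta=beta,
        delta=delta,
        loglik=-float(res.fun),
        boundary=boundary,
        eigvals=s,
        eigvecs=U,
    )


# ---------------------------------------------------------------------------
# model specification and fit
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Configuration for one prediction-model family.

    ``pi`` is the prior probability of a marker having a non-null effect
    (bayesB/bayesC; default 0.05).  ``h2_prior`` sets the sampler prior
    scales: the share of phenotypic variance assumed genomic a priori.
    ``bandwidth`` is the Gaussian-kernel width multiplier for rkhs on the
    mean-squared-distance-normalized kernel.
    """

    family: str
    pi: float = 0.05
    df_prior: float = 5.0
    h2_prior: float = 0.5
    bandwidth: float = 1.0
    iterations: int = 12_000
    burn_in: int = 2_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; one of {FAMILIES}")
        if not 0 < self.pi <= 1:
            raise ValueError("pi must be in (0, 1]")
        if not self.iterations > self.burn_in >= 0:
            raise ValueError("need iterations > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class ModelFit:
    """A fitted prediction model with everything needed to predict."""

    spec: ModelSpec
    intercept: float
    alpha: Optional[np.ndarray]  # per-marker effects (marker families)
    sigma2_a: float
    sigma2_e: float
    fitted_gebv: np.ndarray  # training samples
    train_freqs: np.ndarray  # allele freqs used for centring
    marker_ids: list
    subset_name: str
    u: Optional[np.ndarray] = None  # per-sample genetic values (kernel fams)
    chains: Optional[dict] = None
    inclusion_prob: Optional[np.ndarray] = None
    boundary: bool = False
    # kernel-family prediction state
    _Z_train: Optional[np.ndarray] = field(default=None, repr=False)
    _w: Optional[np.ndarray] = field(default=None, repr=False)
    _kernel_scale: Optional[float] = None  # c for gblup, h*mean_d2 for rkhs


def _check_standardized(y: TraitVector) -> np.ndarray:
    v = y.values
    if np.isnan(v).any():
        raise ValueError("phenotype contains missing values; drop or impute first")
    if not y.standardized:
        warnings.warn(
            "phenotype is not flagged standardized; models assume z-scored "
            "phenotypes",
            stacklevel=3,
        )
    return v.astype(np.float64)


def fit(
    spec: ModelSpec,
    g_train: GenotypeMatrix,
    y_train: TraitVector,
    subset: Optional[MarkerSubset] = None,
) -> ModelFit:
    """Fit one model family on the training samples over a marker subset."""
    if subset is None:
        subset = full_panel(g_train)
    subset.validate_against(g_train)
    if len(subset) == 0:
        raise ValueError("marker subset is empty")
    if g_train.samples != y_train.sample_ids:
        raise ValueError("samples of genotypes and phenotype are not aligned")
    y = _check_standardized(y_train)
    idx = np.asarray(subset.indices, dtype=int)
    X = g_train.dosages[:, idx].astype(np.float64)
    if np.any(X < 0):
        raise ValueError("missing dosages in training matrix; impute first")
    Z, freqs = center_dosages(X)
    ids = [g_train.marker_ids[i] for i in idx]

    if spec.family in ("rrblup", "gblup"):
        return _fit_linear_kernel(spec, Z, y, freqs, ids, subset.name)
    if spec.family == "rkhs":
        return _fit_rkhs(spec, Z, y, freqs, ids, subset.name)
    return _fit_sampler(spec, Z, y, freqs, ids, subset.name)


def _fit_linear_kernel(spec, Z, y, freqs, ids, subset_name) -> ModelFit:
    n = Z.shape[0]
    G = Z @ Z.T
    c = np.trace(G) / n
    if c <= 0:
        raise ValueError("marker panel is constant; cannot fit")
    K = G / c
    res = reml_variance_components(K, y)
    mu = float(res.beta[0])
    r = y - mu
    U, s = res.eigvecs, res.eigvals
    vinv_r = U @ ((U.T @ r) / (res.sigma2_g * s + res.sigma2_e))
    w = res.sigma2_g * vinv_r  # u_hat = K w_dir; kept for kernel prediction
    if spec.family == "rrblup":
        alpha = (res.sigma2_g / c) * (Z.T @ vinv_r)
        fitted = Z @ alpha + mu
        return ModelFit(
            spec=spec,
            intercept=mu,
            alpha=alpha,
            sigma2_a=res.sigma2_g,
            sigma2_e=res.sigma2_e,
            fitted_gebv=fitted,
            train_freqs=freqs,
            marker_ids=ids,
            subset_name=subset_name,
            boundary=res.boundary,
        )
    u = K @ w
    fitted = u + mu
    return ModelFit(
        spec=spec,
        intercept=mu,
        alpha=None,
        sigma2_a=res.sigma2_g,
        sigma2_e=res.sigma2_e,
        fitted_gebv=fitted,
        train_freqs=freqs,
        marker_ids=ids,
        subset_name=subset_name,
        u=u,
        boundary=res.boundary,
        _Z_train=Z,
        _w=w,
        _kernel_scale=float(c),
    )


def _gaussian_kernel(D2: np.ndarray, scale: float) -> np.ndarray:
    return np.exp(-D2 / scale)


def _fit_rkhs(spec, Z, y, freqs, ids, subset_name) -> ModelFit:
    from scipy.spatial.distance import cdist

    D2 = cdist(Z, Z, metric="sqeuclidean")
    n = Z.shape[0]
    off = D2[~np.eye(n, dtype=bool)]
    mean_d2 = float(off.mean())
    if mean_d2 <= 0:
        raise ValueError("all training samples identical; rkhs kernel degenerate")
    scale = spec.bandwidth * mean_d2
    K = _gaussian_kernel(D2, scale)
    res = reml_variance_components(K, y)
    mu = float(res.beta[0])
    r = y - mu
    U, s = res.eigvecs, res.eigvals
    w = res.sigma2_g * (U @ ((U.T @ r) / (res.sigma2_g * s + res.sigma2_e)))
    u = K @ w
    return ModelFit(
        spec=spec,
        intercept=mu,
        alpha=None,
        sigma2_a=res.sigma2_g,
        sigma2_e=res.sigma2_e,
        fitted_gebv=u + mu,
        train_freqs=freqs,
        marker_ids=ids,
        subset_name=subset_name,
        u=u,
        boundary=res.boundary,
        _Z_train=Z,
        _w=w,
        _kernel_scale=scale,
    )


def _fit_sampler(
    spec,
    Z,
    y,
    freqs,
    ids,
    subset_name,
    fix_variances: bool = False,
    sigma2_a_fix: float = 0.0,
    sigma2_e_fix: float = 0.0,
) -> ModelFit:
    n, m = Z.shape
    var_y = float(np.var(y))
    sum2pq = float(np.sum(Z.var(axis=0)))
    if sum2pq <= 0:
        raise ValueError("marker panel is constant; cannot fit")
    nu = spec.df_prior
    mode_a = spec.h2_prior * var_y / sum2pq
    if spec.family in ("bayesB", "bayesC"):
        mode_a = mode_a / spec.pi
    S2_a = mode_a * (nu + 2.0) / nu
    nu_e = spec.df_prior
    S2_e = (1.0 - spec.h2_prior) * var_y * (nu_e + 2.0) / nu_e
    alpha, mu, incl, s2e_chain, s2a_chain = _gibbs.gibbs_chain(
        np.ascontiguousarray(Z),
        np.ascontiguousarray(y),
        _SAMPLER_CODE[spec.family],
        float(spec.pi),
        float(nu),
        float(S2_a),
        float(nu_e),
        float(S2_e),
        int(spec.iterations),
        int(spec.burn_in),
        int(spec.thin),
        int(spec.seed) & 0x7FFFFFFF,
        fix_variances,
        float(sigma2_a_fix),
        float(sigma2_e_fix),
    )
    fitted = Z @ alpha + mu
    g_hat = Z @ alpha
    return ModelFit(
        spec=spec,
        intercept=float(mu),
        alpha=alpha,
        sigma2_a=float(np.var(g_hat)),
        sigma2_e=float(np.mean(s2e_chain)),
        fitted_gebv=fitted,
        train_freqs=freqs,
        marker_ids=ids,
        subset_name=subset_name,
        chains={"sigma2_e": s2e_chain, "marker_variance": s2a_chain},
        inclusion_prob=incl if spec.family in ("bayesB", "bayesC") else None,
    )


def fit_sampler_fixed_variances(
    spec: ModelSpec,
    g_train: GenotypeMatrix,
    y_train: TraitVector,
    sigma2_alpha: float,
    sigma2_e: float,
    subset: Optional[MarkerSubset] = None,
) -> ModelFit:
    """Sampler fit with both variance components held fixed.

    With the BRR family this targets the conditional posterior whose mean is
    the closed-form ridge solution with shrinkage sigma2_e / sigma2_alpha —
    the sampler's correctness oracle.
    """
    if subset is None:
        subset = full_panel(g_train)
    idx = np.asarray(subset.indices, dtype=int)
    X = g_train.dosages[:, idx].astype(np.float64)
    Z, freqs = center_dosages(X)
    y = _check_standardized(y_train)
    ids = [g_train.marker_ids[i] for i in idx]
    return _fit_sampler(
        spec,
        Z,
        y,
        freqs,
        ids,
        subset.name,
        fix_variances=True,
        sigma2_a_fix=sigma2_alpha,
        sigma2_e_fix=sigma2_e,
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict_gebv(fit_result: ModelFit, g_new: GenotypeMatrix) -> np.ndarray:
    """Predict GEBVs (incl. intercept) for new samples.

    ``g_new`` must carry the fitted markers (looked up by id); centring
    reuses the training allele frequencies.
    """
    index = {mid: j for j, mid in enumerate(g_new.marker_ids)}
    missing = [mid for mid in fit_result.marker_ids if mid not in index]
    if missing:
        raise KeyError(f"marker(s) absent from new panel: {missing[:5]}")
    cols = [index[mid] for mid in fit_result.marker_ids]
    X = g_new.dosages[:, cols].astype(np.float64)
    if np.any(X < 0):
        raise ValueError("missing dosages in prediction matrix; impute first")
    Z, _ = center_dosages(X, fit_result.train_freqs)
    if fit_result.alpha is not None:
        return Z @ fit_result.alpha + fit_result.intercept
    if fit_result.spec.family == "gblup":
        K_nt = (Z @ fit_result._Z_train.T) / fit_result._kernel_scale
        return K_nt @ fit_result._w + fit_result.intercept
    # rkhs
    from scipy.spatial.distance import cdist

    D2 = cdist(Z, fit_result._Z_train, metric="sqeuclidean")
    K_nt = _gaussian_kernel(D2, fit_result._kernel_scale)
    return K_nt @ fit_result._w + fit_result.intercept


def ridge_solution(
    Z: np.ndarray, y: np.ndarray, lam: float
) -> tuple[float, np.ndarray]:
    """Closed-form ridge oracle: intercept + (Z'Z + lam I)^-1 Z'(y - mu)."""
    mu = float(y.mean())
    m = Z.shape[1]
    alpha = np.linalg.solve(Z.T @ Z + lam * np.eye(m), Z.T @ (y - mu))
    return mu, alpha
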