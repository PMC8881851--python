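"""LD-kNNi genotype imputation.

Missing dosages are filled one marker at a time.  For a target marker the
``l`` markers in highest LD with it (|Pearson r| over pairwise-complete
samples) define a local distance: the mean absolute dosage difference
between two samples over those markers, computed on their shared non-missing
cells.  The ``k`` nearest samples that carry an observed genotype at the
target marker then vote with weight 1/distance, and the weighted mean vote
is rounded to the nearest of {0, 1, 2}.  Ties in distance are broken by
lower sample index.  Observed cells are never altered.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


class ImputationError(RuntimeError):
    pass


def impute_ldknni(
    g: GenotypeMatrix, k_neighbors: int = 5, l_markers: int = 20
) -> GenotypeMatrix:
    """Impute all missing dosages; returns a new matrix with none missing.

    Raises :class:`ImputationError` for a marker with no observed genotype.
    Falls back to the marker's modal dosage (logged) when no usable
    neighbour exists for a cell.
    """
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    if l_markers < 1:
        raise ValueError("l_markers must be >= 1")
    miss = g.missing_mask()
    if not miss.any():
        return g

    X = g.dosages_float()  # NaN at missing
    n, m = X.shape
    all_missing = np.flatnonzero(np.isnan(X).all(axis=0))
    if all_missing.size:
        raise ImputationError(
            f"marker(s) with no observed genotype: "
            f"{[g.marker_ids[j] for j in all_missing[:5]]}"
        )

    r = _pairwise_complete_corr(X)
    out = g.dosages.copy()
    for j in np.flatnonzero(miss.any(axis=0)):
        ld = np.abs(r[:, j]).copy()
        ld[j] = -np.inf
        ld[np.isnan(ld)] = -np.inf
        n_panel = min(l_markers, m - 1)
        panel = np.argpartition(-ld, n_panel - 1)[:n_panel]
        panel = panel[np.isfinite(ld[panel])]
        if panel.size == 0:  # no informative marker at all
            panel = np.asarray([jj for jj in range(m) if jj != j][:l_markers])
        observed = np.flatnonzero(~np.isnan(X[:, j]))
        P = X[:, panel]
        for i in np.flatnonzero(np.isnan(X[:, j])):
            d = _mean_abs_distance(P[i], P[observed])
            usable = np.isfinite(d)
            if not usable.any():
                out[i, j] = _marker_mode(X[:, j])
                logger.info(
                    "marker %s sample %s: no comparable neighbour, used mode",
                    g.marker_ids[j],
                    g.samples[i],
                )
                continue
            cand = observed[usable]
            dist = d[usable]
            order = np.lexsort((cand, dist))  # distance, then lower index
            top = order[: min(k_neighbors, order.size)]
            if top.size < k_neighbors:
                logger.info(
                    "marker %s sample %s: only %d neighbours available",
                    g.marker_ids[j],
                    g.samples[i],
                    top.size,
                )
            w = 1.0 / (dist[top] + 1e-9)
            vote = float(np.sum(w * X[cand[top], j]) / np.sum(w))
            out[i, j] = int(np.clip(np.rint(vote), 0, 2))
    imputed = GenotypeMatrix(g.samples, g.markers, out, sort=False)
    assert not imputed.missing_mask().any()
    return imputed


def impute_mode(g: GenotypeMatrix) -> GenotypeMatrix:
    """Baseline: fill each missing cell with its marker's modal dosage."""
    X = g.dosages_float()
    out = g.dosages.copy()
    for j in np.flatnonzero(np.isnan(X).any(axis=0)):
        if np.isnan(X[:, j]).all():
            raise ImputationError(f"marker {g.marker_ids[j]} has no observed genotype")
        mode = _marker_mode(X[:, j])
        out[X[:, j] != X[:, j], j] = mode  # NaN != NaN
    return GenotypeMatrix(g.samples, g.markers, out, sort=False)


def _marker_mode(col: np.ndarray) -> int:
    vals = col[~np.isnan(col)].astype(int)
    counts = np.bincount(vals, minlength=3)
    return int(np.argmax(counts))  # ties -> lower dosage


def _mean_abs_distance(row: np.ndarray, others: np.ndarray) -> np.ndarray:
    """Mean |dosage difference| over shared non-missing panel markers."""
    diff = np.abs(others - row[None, :])
    shared = np.isfinite(diff)
    cnt = shared.sum(axis=1)
    with np.errstate(invalid="ignore"):
        d = np.where(cnt > 0, np.nansum(diff, axis=1) / np.maximum(cnt, 1), np.nan)
    return d


def _pairwise_complete_corr(X: np.ndarray) -> np.ndarray:
    """Pearson correlation between columns using pairwise-complete samples.

    Computed by moment sums over the observation-indicator masks so it stays
    vectorised for a few thousand markers.
    """
    obs = np.isfinite(X)
    Xz = np.where(obs, X, 0.0)
    O = obs.astype(np.float64)
    n_ij = O.T @ O
    s_i = Xz.T @ O
    s_ii = (Xz**2).T @ O
    s_ij = Xz.T @ Xz
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = s_ij / n_ij - (s_i / n_ij) * (s_i.T / n_ij)
        var_i = s_ii / n_ij - (s_i / n_ij) ** 2
        denom = np.sqrt(var_i * var_i.T)
        r = cov / denom
    r[n_ij < 2] = np.nan
    return r
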