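"""Pairwise marker LD, haplotype-block pruning, and LD-decay profiling.

LD between two markers is the Pearson correlation ``r`` of their dosage
columns.  Pairs are only evaluated within a chromosome and inside a
positional/ordinal window; everything outside the window is treated as
``r = 0``.  Block pruning connects markers with ``|r| >= threshold`` and
keeps one representative per connected component (the lowest-position
marker, ties broken by marker id).  Decay profiling uses ``r**2`` binned by
physical distance, with the distance at which mean ``r**2`` crosses 0.25
obtained by linear interpolation between bin mid-points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .containers import GenotypeMatrix, MarkerSubset

DEFAULT_WINDOW_BP = 1_000_000
DEFAULT_WINDOW_MARKERS = 500


@dataclass
class LDMatrix:
    """Sparse within-window pairwise LD (upper-triangle pair list)."""

    n_markers: int
    i: np.ndarray  # first marker index of each pair (i < j)
    j: np.ndarray
    r: np.ndarray  # signed Pearson correlation
    distance_bp: np.ndarray
    window_bp: int
    window_markers: int
    marker_ids: list = field(default_factory=list)

    def pairs(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"i": self.i, "j": self.j, "r": self.r, "distance_bp": self.distance_bp}
        )


def pairwise_r(
    g: GenotypeMatrix,
    window_bp: int = DEFAULT_WINDOW_BP,
    window_markers: int = DEFAULT_WINDOW_MARKERS,
) -> LDMatrix:
    """Windowed within-chromosome dosage correlations.

    Requires a complete (imputed) matrix.  A constant marker yields ``r = 0``
    for its pairs, with a warning — QC should have removed it.
    """
    if window_bp <= 0 or window_markers <= 0:
        raise ValueError("windows must be positive")
    if g.missing_mask().any():
        raise ValueError("pairwise_r requires a fully imputed matrix")
    X = g.dosages.astype(np.float64)
    sd = X.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant marker(s); their LD recorded as 0",
            stacklevel=2,
        )
    Z = X - X.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(sd > 0, Z / sd, 0.0)
    n = g.n_samples
    pos = g.positions
    chroms = g.chromosomes

    ii: list[np.ndarray] = []
    jj: list[np.ndarray] = []
    rr: list[np.ndarray] = []
    dd: list[np.ndarray] = []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        p = pos[idx]
        for a in range(len(idx)):
            hi = min(len(idx), a + 1 + window_markers)
            b = np.arange(a + 1, hi)
            b = b[p[b] - p[a] <= window_bp]
            if b.size == 0:
                continue
            r = Z[:, idx[b]].T @ Z[:, idx[a]] / n
            ii.append(np.full(b.size, idx[a]))
            jj.append(idx[b])
            rr.append(np.clip(r, -1.0, 1.0))
            dd.append(p[b] - p[a])
    cat = lambda xs, dt: (
        np.concatenate(xs).astype(dt) if xs else np.empty(0, dtype=dt)
    )
    return LDMatrix(
        n_markers=g.n_markers,
        i=cat(ii, np.int64),
        j=cat(jj, np.int64),
        r=cat(rr, np.float64),
        distance_bp=cat(dd, np.int64),
        window_bp=window_bp,
        window_markers=window_markers,
        marker_ids=g.marker_ids,
    )


def prune_by_ld(
    g: GenotypeMatrix, ld: LDMatrix, threshold: float
) -> MarkerSubset:
    """Keep one marker per |r| >= threshold haplotype block.

    Blocks are connected components of the within-window LD graph; the
    retained representative is the lowest-position marker in the block
    (ties by marker id).  Singletons are always retained.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if ld.n_markers != g.n_markers or ld.marker_ids != g.marker_ids:
        raise ValueError("LD matrix was computed from a different marker panel")
    strong = np.abs(ld.r) >= threshold
    m = g.n_markers
    graph = coo_matrix(
        (np.ones(int(strong.sum())), (ld.i[strong], ld.j[strong])), shape=(m, m)
    )
    n_comp, labels = connected_components(graph, directed=False)
    pos = g.positions
    ids = np.asarray(g.marker_ids, dtype=object)
    order = np.lexsort((ids, pos, labels))  # by block, then position, then id
    first = np.ones(m, dtype=bool)
    first[1:] = labels[order][1:] != labels[order][:-1]
    keep = np.sort(order[first])
    return MarkerSubset(
        f"LD_{int(round(threshold * 100)):02d}",
        tuple(int(x) for x in keep),
        provenance=f"LD pruning |r|>={threshold} "
        f"(window {ld.window_bp} bp / {ld.window_markers} markers)",
    )


@dataclass
class DecayProfile:
    """Mean r² by physical-distance bin plus the r²=0.25 crossing."""

    table: pd.DataFrame  # columns: bin_lo, bin_hi, mid, mean_r2, n_pairs
    crossing_bp: float  # NaN if mean r² never falls below 0.25 in range
    below_first_bin: bool  # True when already < 0.25 in the first bin


def ld_decay_profile(
    g: GenotypeMatrix,
    max_distance: int = 500_000,
    n_bins: int = 50,
    window_markers: int = 2000,
) -> DecayProfile:
    """Profile the decay of r² with distance and locate the 0.25 crossing."""
    ld = pairwise_r(g, window_bp=max_distance, window_markers=window_markers)
    if ld.r.size == 0:
        raise ValueError("no within-window marker pair on any chromosome")
    edges = np.linspace(0, max_distance, n_bins + 1)
    which = np.clip(np.digitize(ld.distance_bp, edges[1:], right=True), 0, n_bins - 1)
    r2 = ld.r**2
    sums = np.bincount(which, weights=r2, minlength=n_bins)
    counts = np.bincount(which, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    table = pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "mid": 0.5 * (edges[:-1] + edges[1:]),
            "mean_r2": mean_r2,
            "n_pairs": counts,
        }
    )
    crossing, below = _crossing_at(table, level=0.25)
    return DecayProfile(table=table, crossing_bp=crossing, below_first_bin=below)


def _crossing_at(table: pd.DataFrame, level: float) -> tuple[float, bool]:
    filled = table.dropna(subset=["mean_r2"])
    if filled.empty:
        return float("nan"), False
    mids = filled["mid"].to_numpy()
    vals = filled["mean_r2"].to_numpy()
    if vals[0] < level:
        return float(mids[0]), True
    below = np.flatnonzero(vals < level)
    if below.size == 0:
        return float("nan"), False
    b = below[0]
    a = b - 1
    frac = (vals[a] - level) / (vals[a] - vals[b])
    return float(mids[a] + frac * (mids[b] - mids[a])), False


def write_subset_tsv(g: GenotypeMatrix, subset: MarkerSubset, path: str) -> None:
    rows = pd.DataFrame(
        {
            "id": [g.marker_ids[i] for i in subset.indices],
            "chromosome": [g.markers[i].chromosome for i in subset.indices],
            "position": [g.markers[i].position for i in subset.indices],
        }
    )
    rows.to_csv(path, sep="\t", index=False)
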