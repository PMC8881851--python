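"""Cross-validation harness, accuracy, variance F-test and grid reporting.

The validation design follows the benchmark convention: random
training:testing partitions at proportions 90:10, 70:30 and 50:50, ten
repeats, prediction accuracy as the Pearson correlation between predicted
GEBVs and observed phenotypes in the testing partition, and the arithmetic
mean over repeats as the reported cell value.  Splits are shared across
models and subsets for a fair comparison.

Marker subsets may be built once on the full data (replicating the common
practice of selecting markers before cross-validation) or rebuilt inside
each training fold (``leakage-safe`` mode, the statistically clean choice);
pass a ``subset_builder`` callable for the latter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, MarkerSubset, TraitVector, standardize
from .heritability import estimate_h2
from .models import ModelSpec, fit, predict_gebv

SubsetBuilder = Callable[[GenotypeMatrix, TraitVector], MarkerSubset]


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    n_samples: int
    proportion: float  # training fraction
    repeats: int
    seed: int
    splits: list  # [(train_idx, test_idx), ...] sorted integer arrays


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5))


def make_splits(
    n: int, proportion: float, repeats: int = 10, seed: int = 0
) -> SplitPlan:
    """Uniform random train/test partitions, reproducible from the seed."""
    if not 0 < proportion < 1:
        raise ValueError("proportion must be in (0, 1)")
    if n < 10:
        raise ValueError("need at least 10 samples")
    n_test = _round_half_away((1.0 - proportion) * n)
    if n_test == 0:
        raise ValueError("testing partition would be empty")
    if n_test >= n:
        raise ValueError("training partition would be empty")
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(repeats):
        perm = rng.permutation(n)
        test = np.sort(perm[:n_test])
        train = np.sort(perm[n_test:])
        splits.append((train, test))
    return SplitPlan(n, proportion, repeats, seed, splits)


# ---------------------------------------------------------------------------
# accuracy and the variance F-test
# ---------------------------------------------------------------------------

def accuracy(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Pearson correlation of predictions with observations.

    Returns NaN (flagged missing) when either side is constant; requires at
    least 3 aligned pairs.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must be aligned")
    if predicted.size < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.std(predicted) == 0 or np.std(observed) == 0:
        return float("nan")
    return float(stats.pearsonr(predicted, observed)[0])


def f_test_two_variances(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float]:
    """Two-sample F-test of equal variances; returns (F, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if vb == 0:
        raise ZeroDivisionError("zero variance in the denominator sample")
    F = va / vb
    dist = stats.f(a.size - 1, b.size - 1)
    p = 2.0 * min(dist.sf(F), dist.cdf(F))
    return float(F), float(min(p, 1.0))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVGridResult:
    """Long-format per-repeat records plus per-proportion pivot tables."""

    records: pd.DataFrame
    tables: dict = field(default_factory=dict)  # proportion -> pivot table

    def aggregate(self) -> pd.DataFrame:
        ok = self.records[~self.records["failed"]]
        return (
            ok.groupby(["model", "subset", "proportion"], as_index=False)
            .agg(accuracy=("accuracy", "mean"), h2_train=("h2_train", "mean"))
        )


def run_cv(
    g: GenotypeMatrix,
    y: TraitVector,
    spec: ModelSpec,
    subset: Optional[MarkerSubset],
    plan: SplitPlan,
    subset_builder: Optional[SubsetBuilder] = None,
    record_h2: bool = False,
) -> pd.DataFrame:
    """Cross-validate one (model, subset, proportion) cell.

    Per repeat: standardize the training phenotype, fit on the training
    partition, predict the testing partition, record the accuracy (and the
    training-partition h2 when asked).  With ``subset_builder`` the subset
    is recomputed inside each training fold (leakage-safe mode).
    """
    if subset is None and subset_builder is None:
        raise ValueError("provide a subset or a subset_builder")
    if plan.n_samples != g.n_samples:
        raise ValueError("split plan was made for a different sample count")
    if g.samples != y.sample_ids:
        raise ValueError("samples of genotypes and phenotype are not aligned")
    rows = []
    for rep, (train, test) in enumerate(plan.splits):
        g_tr, g_te = g.take_samples(train), g.take_samples(test)
        y_tr = TraitVector(
            y.trait_name, [y.sample_ids[i] for i in train], y.values[train]
        )
        y_te = y.values[test]
        row = {
            "model": spec.family,
            "subset": subset.name if subset is not None else "per-fold",
            "proportion": plan.proportion,
            "repeat": rep,
            "n_train": len(train),
            "n_test": len(test),
            "accuracy": float("nan"),
            "h2_train": float("nan"),
            "failed": False,
        }
        try:
            y_tr_std = standardize(y_tr)
            fold_subset = (
                subset_builder(g_tr, y_tr_std) if subset_builder else subset
            )
            row["subset"] = fold_subset.name if subset is None else row["subset"]
            rep_spec = ModelSpec(**{**spec.__dict__, "seed": spec.seed + rep})
            fitted = fit(rep_spec, g_tr, y_tr_std, fold_subset)
            pred = predict_gebv(fitted, g_te)
            row["accuracy"] = accuracy(pred, y_te)
            if record_h2:
                row["h2_train"] = estimate_h2(
                    g_tr, y_tr_std, fold_subset
                ).h2
        except Exception as exc:  # noqa: BLE001 - fold failures are recorded
            warnings.warn(f"fold {rep} failed: {exc}", stacklevel=2)
            row["failed"] = True
        rows.append(row)
    return pd.DataFrame(rows)


def benchmark_grid(
    g: GenotypeMatrix,
    y: TraitVector,
    models: Sequence[ModelSpec],
    subsets: Sequence[MarkerSubset],
    proportions: Sequence[float] = (0.9, 0.7, 0.5),
    repeats: int = 10,
    seed: int = 0,
    record_h2: bool = False,
) -> CVGridResult:
    """Full factorial models x subsets x proportions cross-validation.

    Splits are generated once per proportion and shared by every model and
    subset.  Returns long-format records and one model x subset pivot table
    of mean accuracy per proportion.
    """
    frames = []
    for k, prop in enumerate(proportions):
        plan = make_splits(g.n_samples, prop, repeats=repeats, seed=seed + k)
        for spec in models:
            for subset in subsets:
                frames.append(
                    run_cv(g, y, spec, subset, plan, record_h2=record_h2)
                )
    records = pd.concat(frames, ignore_index=True)
    result = CVGridResult(records=records)
    for prop in proportions:
        sub = records[(records["proportion"] == prop) & (~records["failed"])]
        result.tables[prop] = sub.pivot_table(
            index="model", columns="subset", values="accuracy", aggfunc="mean"
        )
    n_failed = int(records["failed"].sum())
    if n_failed:
        warnings.warn(f"{n_failed} fold(s) failed and were excluded", stacklevel=2)
    return result


def write_grid(result: CVGridResult, records_path: str, tables_prefix: str) -> None:
    result.records.to_csv(records_path, sep="\t", index=False)
    for prop, table in result.tables.items():
        table.to_csv(f"{tables_prefix}_p{int(round(prop * 100))}.tsv", sep="\t")
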