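"""Marker-based narrow-sense heritability from REML variance components.

The estimate comes from the kinship mixed model Y = X beta + Z u + e with
Var(u) = sigma2_a K (K built from the chosen marker subset, mean diagonal 1)
and Var(e) = sigma2_e I; h2 = sigma2_a / (sigma2_a + sigma2_e).  Fixed
effects are an intercept only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .containers import GenotypeMatrix, MarkerSubset, TraitVector, full_panel
from .models import kinship, reml_variance_components


@dataclass
class HeritabilityEstimate:
    sigma2_a: float
    sigma2_e: float
    h2: float
    n_samples: int
    n_markers: int
    boundary: bool = False  # REML ratio pinned at the search boundary
    context: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sigma2_a < 0 or self.sigma2_e < 0:
            raise ValueError("variance components must be non-negative")
        total = self.sigma2_a + self.sigma2_e
        if total > 0 and abs(self.h2 - self.sigma2_a / total) > 1e-10:
            raise ValueError("h2 inconsistent with its variance components")


def estimate_h2(
    g: GenotypeMatrix,
    y: TraitVector,
    subset: Optional[MarkerSubset] = None,
    sample_indices: Optional[Sequence[int]] = None,
) -> HeritabilityEstimate:
    """REML heritability on a marker subset and optional sample partition."""
    if subset is None:
        subset = full_panel(g)
    subset.validate_against(g)
    if sample_indices is not None:
        g = g.take_samples(sample_indices)
        y = TraitVector(
            y.trait_name,
            [y.sample_ids[i] for i in sample_indices],
            y.values[list(sample_indices)],
            standardized=y.standardized,
            broad_sense_H2=y.broad_sense_H2,
        )
    if g.samples != y.sample_ids:
        raise ValueError("samples of genotypes and phenotype are not aligned")
    if np.isnan(y.values).any():
        raise ValueError("phenotype contains missing values")
    if g.n_samples < 30:
        warnings.warn(
            f"only {g.n_samples} samples; heritability estimate will be noisy",
            stacklevel=2,
        )
    gs = g.take_markers(list(subset.indices))
    K = kinship(gs)
    res = reml_variance_components(K.values, y.values)
    total = res.sigma2_g + res.sigma2_e
    return HeritabilityEstimate(
        sigma2_a=res.sigma2_g,
        sigma2_e=res.sigma2_e,
        h2=res.sigma2_g / total if total > 0 else 0.0,
        n_samples=g.n_samples,
        n_markers=len(subset),
        boundary=res.boundary,
        context={"subset": subset.name, "trait": y.trait_name},
    )
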