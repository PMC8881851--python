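"""Core in-memory containers shared by every pipeline stage.

Genotypes are held as an ``n_samples x n_markers`` dosage matrix coding the
count of the alternate allele (0, 1, 2), with ``MISSING`` (-1) as the
missing-data sentinel.  Markers carry a physical map (chromosome label and
1-based base-pair position) and are kept sorted by (chromosome, position)
with chromosome labels compared naturally ("2" before "10").
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np

#: Sentinel for a missing dosage cell.
MISSING: int = -1


def natural_chrom_key(label: str) -> tuple:
    """Sort key treating digit runs in a chromosome label numerically."""
    parts = re.split(r"(\d+)", str(label))
    return tuple(int(p) if p.isdigit() else p for p in parts)


@dataclass(frozen=True)
class MarkerRecord:
    """A single biallelic marker: name, map position, optional alleles."""

    id: str
    chromosome: str
    position: int
    ref: Optional[str] = None
    alt: Optional[str] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"marker {self.id}: position must be >= 1")


class GenotypeMatrix:
    """Samples x markers dosage matrix with a marker map.

    Parameters
    ----------
    samples
        Ordered sample identifiers (non-empty, unique).
    markers
        One :class:`MarkerRecord` per column (non-empty, unique ids).
    dosages
        Integer array of shape ``(len(samples), len(markers))`` with values
        in {0, 1, 2} or :data:`MISSING`.
    sort
        Sort markers by (chromosome, position) on construction (default).
    """

    def __init__(
        self,
        samples: Sequence[str],
        markers: Sequence[MarkerRecord],
        dosages: np.ndarray,
        *,
        sort: bool = True,
    ) -> None:
        samples = list(samples)
        markers = list(markers)
        dosages = np.asarray(dosages)
        if len(samples) == 0:
            raise ValueError("GenotypeMatrix requires at least one sample")
        if len(markers) == 0:
            raise ValueError("GenotypeMatrix requires at least one marker")
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample identifiers")
        ids = [m.id for m in markers]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate marker id(s): {dup[:5]}")
        if dosages.shape != (len(samples), len(markers)):
            raise ValueError(
                f"dosage shape {dosages.shape} does not match "
                f"({len(samples)}, {len(markers)})"
            )
        dosages = dosages.astype(np.int8, copy=True)
        valid = np.isin(dosages, (0, 1, 2, MISSING))
        if not valid.all():
            bad = dosages[~valid].ravel()[:5]
            raise ValueError(f"dosages must be in {{0,1,2,{MISSING}}}; got {bad}")
        if sort:
            order = sorted(
                range(len(markers)),
                key=lambda j: (
                    natural_chrom_key(markers[j].chromosome),
                    markers[j].position,
                    markers[j].id,
                ),
            )
            markers = [markers[j] for j in order]
            dosages = dosages[:, order]
        self.samples: list[str] = samples
        self.markers: list[MarkerRecord] = markers
        self.dosages: np.ndarray = dosages

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_samples, self.n_markers)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_markers} markers)"

    # -- derived arrays -------------------------------------------------
    @property
    def marker_ids(self) -> list[str]:
        return [m.id for m in self.markers]

    @property
    def chromosomes(self) -> np.ndarray:
        return np.asarray([m.chromosome for m in self.markers], dtype=object)

    @property
    def positions(self) -> np.ndarray:
        return np.asarray([m.position for m in self.markers], dtype=np.int64)

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per marker over non-missing cells."""
        d = self.dosages.astype(float)
        d[d == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return self.missing_mask().mean(axis=0)

    def dosages_float(self) -> np.ndarray:
        """Float copy with missing cells as NaN."""
        d = self.dosages.astype(np.float64)
        d[self.dosages == MISSING] = np.nan
        return d

    # -- subsetting ------------------------------------------------------
    def take_markers(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            self.samples,
            [self.markers[j] for j in idx],
            self.dosages[:, idx],
            sort=False,
        )

    def take_samples(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            [self.samples[i] for i in idx],
            self.markers,
            self.dosages[idx, :],
            sort=False,
        )


@dataclass
class TraitVector:
    """Per-sample phenotype for one trait.

    ``values`` is aligned with ``sample_ids``; missing observations are NaN.
    ``broad_sense_H2`` is carried as metadata only (a literature value for
    the trait, never estimated here).
    """

    trait_name: str
    sample_ids: list[str]
    values: np.ndarray
    standardized: bool = False
    broad_sense_H2: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or len(self.values) != len(self.sample_ids):
            raise ValueError("values must be 1-D and aligned with sample_ids")
        if self.broad_sense_H2 is not None and not 0 <= self.broad_sense_H2 <= 1:
            raise ValueError("broad_sense_H2 must be in [0, 1]")
        if np.all(np.isnan(self.values)):
            raise ValueError(f"trait {self.trait_name!r}: all values missing")
        if self.standardized:
            v = self.values[~np.isnan(self.values)]
            if abs(v.mean()) > 1e-8 or abs(v.var() - 1.0) > 1e-8:
                raise ValueError("standardized flag set but values are not z-scores")

    def __len__(self) -> int:
        return len(self.values)

    def nonmissing(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def aligned_to(self, g: GenotypeMatrix) -> "TraitVector":
        """Reorder to a genotype matrix's sample order (inner alignment).

        Raises if any genotyped sample lacks a phenotype record.
        """
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in g.samples if s not in index]
        if missing:
            raise KeyError(f"samples without phenotype: {missing[:5]}")
        order = [index[s] for s in g.samples]
        return TraitVector(
            self.trait_name,
            list(g.samples),
            self.values[order],
            standardized=self.standardized,
            broad_sense_H2=self.broad_sense_H2,
        )


def standardize(t: TraitVector) -> TraitVector:
    """Zero-mean, unit-variance copy over non-missing entries (idempotent)."""
    v = t.values.copy()
    ok = ~np.isnan(v)
    mu = v[ok].mean()
    sd = v[ok].std()
    if sd == 0:
        raise ValueError(f"trait {t.trait_name!r} is constant; cannot standardize")
    v[ok] = (v[ok] - mu) / sd
    return TraitVector(
        t.trait_name,
        list(t.sample_ids),
        v,
        standardized=True,
        broad_sense_H2=t.broad_sense_H2,
    )


@dataclass
class QCReport:
    """Tally of the marker quality-control filters, in application order."""

    n_input: int
    n_missing_removed: int
    n_monomorphic_removed: int
    n_maf_removed: int
    n_retained: int
    maf: np.ndarray = field(repr=False, default=None)  # per input marker
    missing_rate: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        total = (
            self.n_missing_removed
            + self.n_monomorphic_removed
            + self.n_maf_removed
            + self.n_retained
        )
        if total != self.n_input:
            raise ValueError("QC tallies do not sum to the input marker count")


@dataclass(frozen=True)
class MarkerSubset:
    """A named, provenance-tagged selection of marker column indices."""

    name: str
    indices: tuple
    provenance: str = ""

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        if len(set(idx)) != len(idx):
            raise ValueError("marker subset indices must be unique")
        if any(i < 0 for i in idx):
            raise ValueError("marker subset indices must be non-negative")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self) -> Iterator[int]:
        return iter(self.indices)

    def validate_against(self, g: GenotypeMatrix) -> None:
        if self.indices and max(self.indices) >= g.n_markers:
            raise IndexError(
                f"subset {self.name!r} indexes marker "
                f"{max(self.indices)} but panel has {g.n_markers}"
            )


def full_panel(g: GenotypeMatrix, name: str = "Com") -> MarkerSubset:
    """The complete-panel subset (the paper-style 'Com' set)."""
    return MarkerSubset(name, tuple(range(g.n_markers)), provenance="complete panel")
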