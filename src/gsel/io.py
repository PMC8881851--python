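"""Reading and writing genotype/phenotype data, and marker quality control.

Supported genotype dialects:

``vcf``
    Plain or bgzipped VCF; only the GT field is used (via :mod:`cyvcf2`).
``hapmap``
    HapMap tab format: 11 metadata columns then one diploid call per sample
    (``AA``/``AG``/``NN`` or single-letter IUPAC-free calls).
``plink_raw``
    PLINK ``--recode A`` additive text (.raw): FID IID PAT MAT SEX PHENOTYPE
    then one 0/1/2/NA column per marker.  No physical map is present; markers
    are placed on chromosome "0" at their column order.
``dosage_csv``
    Rows = samples, header = marker ids, cells = 0/1/2 or empty/NA.  A
    sidecar ``<path>.map.tsv`` (id, chromosome, position) written by
    :func:`write_dosage_csv` is picked up automatically when present.
"""

from __future__ import annotations

import csv
import os
import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .containers import (
    MISSING,
    GenotypeMatrix,
    MarkerRecord,
    QCReport,
    TraitVector,
)

_FORMATS = ("vcf", "hapmap", "plink_raw", "dosage_csv")


class FormatError(ValueError):
    """Malformed input; carries the offending line number where known."""


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_genotypes(path: str, format: str) -> GenotypeMatrix:
    """Read a genotype file into a :class:`GenotypeMatrix`.

    Dosages code the count of the alternate (non-reference) allele; missing
    genotypes map to the missing sentinel; markers come back sorted by
    (chromosome, position).
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    reader = {
        "vcf": _read_vcf,
        "hapmap": _read_hapmap,
        "plink_raw": _read_plink_raw,
        "dosage_csv": _read_dosage_csv,
    }[format]
    return reader(path)


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)  # gt_types: 0/1/2 = dosage, 3 = missing
    samples = list(vcf.samples)
    if not samples:
        raise FormatError("VCF contains no samples")
    markers: list[MarkerRecord] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        mid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        alt = rec.ALT[0] if rec.ALT else None
        markers.append(
            MarkerRecord(mid, str(rec.CHROM), int(rec.POS), rec.REF, alt)
        )
        gt = np.asarray(rec.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        rows.append(gt)
    if not markers:
        raise FormatError("VCF contains no variant records")
    dosages = np.stack(rows, axis=1)
    return GenotypeMatrix(samples, markers, dosages)


_HAPMAP_META_COLS = 11


def _read_hapmap(path: str) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) <= _HAPMAP_META_COLS:
            raise FormatError("HapMap header has no sample columns")
        samples = header[_HAPMAP_META_COLS:]
        markers: list[MarkerRecord] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise FormatError(
                    f"line {lineno}: expected {len(header)} columns, got {len(fields)}"
                )
            mid, alleles, chrom, pos = fields[0], fields[1], fields[2], fields[3]
            try:
                position = int(pos)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: bad position {pos!r}") from exc
            pair = alleles.split("/")
            if len(pair) != 2:
                raise FormatError(f"line {lineno}: bad alleles field {alleles!r}")
            ref, alt = pair
            row = []
            for call in fields[_HAPMAP_META_COLS:]:
                row.append(_hapmap_call_to_dosage(call, ref, alt, lineno))
            markers.append(MarkerRecord(mid, chrom, position, ref, alt))
            rows.append(row)
    if not markers:
        raise FormatError("HapMap file contains no marker rows")
    dosages = np.asarray(rows, dtype=np.int8).T
    return GenotypeMatrix(samples, markers, dosages)


def _hapmap_call_to_dosage(call: str, ref: str, alt: str, lineno: int) -> int:
    if call in ("NN", "N", "--", "..", ""):
        return MISSING
    if len(call) == 1:  # haploid-style shorthand for a homozygote
        call = call * 2
    if len(call) != 2:
        raise FormatError(f"line {lineno}: bad genotype call {call!r}")
    dosage = 0
    for a in call:
        if a == alt:
            dosage += 1
        elif a != ref:
            raise FormatError(
                f"line {lineno}: allele {a!r} not in {{{ref},{alt}}}"
            )
    return dosage


def _read_plink_raw(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+")
    meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    if not set(meta).issubset(df.columns):
        raise FormatError(".raw file missing the FID..PHENOTYPE header columns")
    snp_cols = [c for c in df.columns if c not in meta]
    if not snp_cols:
        raise FormatError(".raw file has no SNP columns")
    samples = df["IID"].astype(str).tolist()
    markers = []
    for j, col in enumerate(snp_cols):
        # column names look like "<snp>_<countedallele>"
        name, _, counted = col.rpartition("_")
        markers.append(MarkerRecord(name or col, "0", j + 1, alt=counted or None))
    vals = df[snp_cols].to_numpy(dtype=float)
    dosages = np.where(np.isnan(vals), MISSING, vals).astype(np.int8)
    return GenotypeMatrix(samples, markers, dosages, sort=False)


def _read_dosage_csv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] == 0:
        raise FormatError("dosage CSV has no marker columns")
    samples = df.index.astype(str).tolist()
    ids = [str(c) for c in df.columns]
    map_path = path + ".map.tsv"
    if os.path.exists(map_path):
        mp = pd.read_csv(map_path, sep="\t", dtype={"chromosome": str})
        mp = mp.set_index("id")
        markers = [
            MarkerRecord(
                i, str(mp.loc[i, "chromosome"]), int(mp.loc[i, "position"])
            )
            for i in ids
        ]
    else:
        markers = [MarkerRecord(i, "0", j + 1) for j, i in enumerate(ids)]
    vals = df.to_numpy(dtype=float)
    bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"dosage CSV cell ({samples[i]}, {ids[j]}) = {vals[i, j]!r} "
            "is not 0/1/2/NA"
        )
    dosages = np.where(np.isnan(vals), MISSING, vals).astype(np.int8)
    return GenotypeMatrix(samples, markers, dosages)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_dosage_csv(g: GenotypeMatrix, path: str, write_map: bool = True) -> None:
    """Write samples x markers dosages as CSV (missing as empty cell).

    A sidecar ``<path>.map.tsv`` preserves the marker map so that
    ``read_genotypes(path, "dosage_csv")`` round-trips exactly.
    """
    df = pd.DataFrame(
        g.dosages.astype(object), index=g.samples, columns=g.marker_ids
    )
    df = df.mask(df == MISSING, other=pd.NA)
    df.to_csv(path, index_label="sample")
    if write_map:
        mp = pd.DataFrame(
            {
                "id": g.marker_ids,
                "chromosome": [m.chromosome for m in g.markers],
                "position": [m.position for m in g.markers],
            }
        )
        mp.to_csv(path + ".map.tsv", sep="\t", index=False)


def write_qc_report(report: QCReport, path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["metric", "value"])
        w.writerow(["n_input", report.n_input])
        w.writerow(["n_missing_removed", report.n_missing_removed])
        w.writerow(["n_monomorphic_removed", report.n_monomorphic_removed])
        w.writerow(["n_maf_removed", report.n_maf_removed])
        w.writerow(["n_retained", report.n_retained])


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def apply_qc(
    g: GenotypeMatrix,
    maf_threshold: float = 0.05,
    missing_threshold: float = 0.10,
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter markers by missing rate and minor allele frequency.

    Filters apply in order: first markers with missing rate strictly above
    ``missing_threshold`` are removed, then markers with MAF at or below
    ``maf_threshold``.  Monomorphic markers (MAF = 0, including all-missing
    columns) fall under the MAF filter but are tallied separately.  The
    sample set is unchanged.
    """
    if not 0 <= maf_threshold < 0.5:
        raise ValueError("maf_threshold must be in [0, 0.5)")
    if not 0 <= missing_threshold <= 1:
        raise ValueError("missing_threshold must be in [0, 1]")
    miss = g.missing_rate()
    maf = g.maf()  # NaN for all-missing columns
    maf_eff = np.where(np.isnan(maf), 0.0, maf)

    drop_missing = miss > missing_threshold
    remaining = ~drop_missing
    low_maf = remaining & (maf_eff <= maf_threshold)
    drop_mono = low_maf & (maf_eff == 0.0)
    drop_maf = low_maf & ~drop_mono
    keep = remaining & ~low_maf

    report = QCReport(
        n_input=g.n_markers,
        n_missing_removed=int(drop_missing.sum()),
        n_monomorphic_removed=int(drop_mono.sum()),
        n_maf_removed=int(drop_maf.sum()),
        n_retained=int(keep.sum()),
        maf=maf,
        missing_rate=miss,
    )
    if report.n_retained == 0:
        raise ValueError("quality control removed every marker (empty panel)")
    return g.take_markers(np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(
    path: str,
    trait: str,
    sample_col: Optional[str] = None,
    broad_sense_H2: Optional[float] = None,
) -> TraitVector:
    """Read one trait column from a CSV/TSV phenotype table.

    The sample-ID column is the first column unless ``sample_col`` names it.
    Values stay in their original units; missing cells become NaN.
    """
    sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if sample_col is None:
        sample_col = df.columns[0]
    if trait not in df.columns:
        raise KeyError(f"trait column {trait!r} not in {list(df.columns)}")
    values = pd.to_numeric(df[trait], errors="raise").to_numpy(dtype=float)
    if np.all(np.isnan(values)):
        raise ValueError(f"trait {trait!r}: every value is missing")
    return TraitVector(
        trait,
        df[sample_col].astype(str).tolist(),
        values,
        broad_sense_H2=broad_sense_H2,
    )


def write_phenotypes(traits: list[TraitVector], path: str) -> None:
    """Write traits (sharing one sample list) to CSV."""
    ids = traits[0].sample_ids
    for t in traits[1:]:
        if t.sample_ids != ids:
            raise ValueError("traits must share the same sample order")
    df = pd.DataFrame({"sample": ids})
    for t in traits:
        df[t.trait_name] = t.values
    df.to_csv(path, index=False)
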