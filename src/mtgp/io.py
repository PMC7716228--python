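"""Readers and writers for phenotype tables and genotype matrices.

Phenotypes travel as delimited text with columns env, line, block,
is_check, DTH and one column per trait.  Genotypes are either a
tab-delimited numeric matrix (header row of marker IDs, one row per line,
first column the line ID) or a VCF; the numeric coding ({0,1,2}, {-1,0,1},
or IUPAC nucleotide letters) is auto-detected and mapped to dosage, and
the decision is logged.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, TRAIT_UNITS, MarkerMatrix
from .phenomodel import REQUIRED_COLUMNS, validate_records

log = logging.getLogger("mtgp")

#: IUPAC ambiguity letters for heterozygous calls.
_IUPAC_HET = set("RYSWKM")
_MISSING_TOKENS = {"", "N", "NA", "NAN", ".", "-9", "-"}


def read_phenotypes(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a phenotype CSV, remap columns, and validate the dialect.

    ``column_map`` maps file column names to canonical names (env, line,
    block, is_check, DTH, GY, HI, SF, TGW).  Unknown trait columns raise;
    traits missing from the file are simply absent from the result.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file {path} lacks required columns: {missing}")
    traits = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    unknown = [t for t in traits if t not in TRAIT_UNITS]
    if unknown:
        raise ValueError(
            f"unknown trait columns {unknown}; expected a subset of {sorted(TRAIT_UNITS)} "
            "(use column_map to rename)"
        )
    df["is_check"] = df["is_check"].astype(bool)
    validate_records(df, traits)
    n_missing = int(df[traits].isna().sum().sum())
    log.info(
        "read %d phenotype records (%d envs, %d lines, %d missing trait values) from %s",
        len(df), df["env"].nunique(), df["line"].nunique(), n_missing, path,
    )
    return df


def write_phenotypes(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Genotypes


def _detect_coding(values: pd.DataFrame) -> str:
    sample = values.to_numpy().ravel()
    tokens = pd.unique(pd.Series(sample).astype(str).str.strip().str.upper())
    tokens = [t for t in tokens if t not in _MISSING_TOKENS]
    numeric = []
    for t in tokens:
        try:
            numeric.append(float(t))
        except ValueError:
            return "iupac"
    vals = set(numeric)
    if vals <= {0.0, 1.0, 2.0}:
        return "012"
    if vals <= {-1.0, 0.0, 1.0}:
        return "-101"
    raise ValueError(f"cannot infer genotype coding from values {sorted(vals)[:6]}")


def read_genotypes(path: str | Path) -> MarkerMatrix:
    """Read a genotype matrix from tab-delimited text or VCF."""
    path = Path(path)
    if path.suffix in (".vcf",) or str(path).endswith(".vcf.gz"):
        return _read_vcf(path)

    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] == 0:  # fall back to comma-separated
        df = pd.read_csv(path, sep=",", index_col=0, dtype=str)
    coding = _detect_coding(df)
    log.info("inferred genotype coding %r for %s", coding, path)

    if coding in ("012", "-101"):
        arr = df.apply(pd.to_numeric, errors="coerce").to_numpy(float)
        if coding == "-101":
            arr = arr + 1.0
        out = np.where(np.isnan(arr), MISSING, arr).astype(np.int8)
    else:
        out = _decode_iupac(df)
    return MarkerMatrix(out, [str(i) for i in df.index], [str(c) for c in df.columns])


def _decode_iupac(df: pd.DataFrame) -> np.ndarray:
    """Map nucleotide letters to minor-allele dosage per marker."""
    raw = df.to_numpy(dtype=str)
    n, p = raw.shape
    out = np.full((n, p), MISSING, dtype=np.int8)
    for j in range(p):
        col = np.char.upper(np.char.strip(raw[:, j].astype(str)))
        is_missing = np.isin(col, list(_MISSING_TOKENS))
        is_het = np.isin(col, list(_IUPAC_HET))
        hom = col[~is_missing & ~is_het]
        alleles, counts = np.unique(hom, return_counts=True)
        if len(alleles) > 2:
            top = alleles[np.argsort(counts)[::-1][:2]]
        else:
            top = alleles
        if len(top) == 0:
            continue
        minor = top[np.argmin([counts[list(alleles).index(a)] for a in top])] if len(top) == 2 else top[0]
        out[:, j] = np.where(
            is_missing, MISSING, np.where(is_het, 1, np.where(col == minor, 2, 0))
        )
    return out


def _read_vcf(path: Path) -> MarkerMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    ids = []
    skipped = 0
    for v in vcf:
        if len(v.ALT) != 1:
            skipped += 1
            continue
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = v.gt_types
        dosage = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        rows.append(dosage.astype(np.int8))
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}")
    if skipped:
        log.info("skipped %d non-biallelic VCF records", skipped)
    if not rows:
        raise ValueError(f"no biallelic records in {path}")
    values = np.stack(rows, axis=1)  # samples x markers
    return MarkerMatrix(values, samples, ids)


def write_genotypes(markers: MarkerMatrix, path: str | Path) -> None:
    """Tab-delimited matrix: header of marker IDs, one row per line.

    Missing calls are written as ``NA`` so that the {0,1,2} coding stays
    unambiguous on re-read.
    """
    vals = markers.values.astype(float)
    vals[markers.missing_mask()] = np.nan
    df = pd.DataFrame(vals, index=markers.line_ids, columns=markers.marker_ids)
    # keep integer formatting for clean round trips of integer dosages
    df = df.map(lambda v: "" if np.isnan(v) else (str(int(v)) if v == int(v) else repr(v)))
    df.index.name = "line"
    df.to_csv(path, sep="\t", na_rep="NA")
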