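"""SNP and genotype quality control, allelic testing, imputation, and GRM.

The filter chain mirrors a standard GBS panel cleanup for inbred lines:
drop lines with excessive missing data, then markers by missingness, minor
allele frequency, and heterozygous-call frequency (inbred wheat should be
nearly homozygous, so a high heterozygote rate flags paralogous or
error-prone sites).  A per-site Fisher exact test checks that the two
alleles segregate independently across lines, the expectation for a true
allelic SNP in an inbred panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MISSING, GenomicRelationship, MarkerMatrix


@dataclass
class QcReport:
    """Per-rule removal counts and per-marker statistics."""

    n_lines_in: int
    n_markers_in: int
    lines_removed_missing: int
    markers_removed_missing: int
    markers_removed_maf: int
    markers_removed_het: int
    n_lines_out: int
    n_markers_out: int
    marker_stats: pd.DataFrame = field(repr=False)  # maf, missingness, het per input marker
    thresholds: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("lines_in", self.n_lines_in),
            ("lines_removed_missing", self.lines_removed_missing),
            ("lines_out", self.n_lines_out),
            ("markers_in", self.n_markers_in),
            ("markers_removed_missing", self.markers_removed_missing),
            ("markers_removed_maf", self.markers_removed_maf),
            ("markers_removed_het", self.markers_removed_het),
            ("markers_out", self.n_markers_out),
        ]
        return pd.DataFrame(rows, columns=["rule", "count"])


def _marker_stats(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker (maf, missingness, het rate) over observed calls."""
    miss = values == MISSING
    obs = (~miss).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(miss, 0, values)
        alt = vals.sum(axis=0) / np.maximum(2 * obs, 1)  # alt-allele frequency
        maf = np.minimum(alt, 1.0 - alt)
        maf = np.where(obs > 0, maf, np.nan)
        missingness = miss.mean(axis=0)
        het = np.where(obs > 0, (values == 1).sum(axis=0) / np.maximum(obs, 1), np.nan)
    return maf, missingness, het


def filter_markers(
    m: MarkerMatrix,
    max_marker_missing: float = 0.5,
    min_maf: float = 0.05,
    max_het: float = 0.10,
    max_line_missing: float = 0.85,
) -> tuple[MarkerMatrix, QcReport]:
    """Apply the line/marker filter chain; thresholds are exclusive for removal.

    Order of application: line missingness (> ``max_line_missing``), marker
    missingness (> ``max_marker_missing``), MAF (< ``min_maf``),
    heterozygosity (> ``max_het``).  Boundary values are retained.
    """
    if m.n_lines == 0 or m.n_markers == 0:
        raise ValueError("empty marker matrix")
    values = m.values
    if np.issubdtype(values.dtype, np.floating):
        raise ValueError("filter_markers expects integer dosages (run before imputation)")

    line_missing = (values == MISSING).mean(axis=1)
    keep_lines = line_missing <= max_line_missing
    n_lines_removed = int((~keep_lines).sum())
    work = m.subset(lines=keep_lines)

    maf, missingness, het = _marker_stats(work.values)
    stats_df = pd.DataFrame(
        {"marker": work.marker_ids, "maf": maf, "missingness": missingness, "het": het}
    )

    keep = missingness <= max_marker_missing
    n_miss = int((~keep).sum())
    # MAF rule counts only markers surviving the previous rule, in order.
    fail_maf = keep & ((maf < min_maf) | np.isnan(maf))
    n_maf = int(fail_maf.sum())
    keep &= ~fail_maf
    fail_het = keep & (het > max_het)
    n_het = int(fail_het.sum())
    keep &= ~fail_het

    if not keep.any():
        raise ValueError("all markers removed by QC filters")

    out = work.subset(markers=keep)
    report = QcReport(
        n_lines_in=m.n_lines,
        n_markers_in=m.n_markers,
        lines_removed_missing=n_lines_removed,
        markers_removed_missing=n_miss,
        markers_removed_maf=n_maf,
        markers_removed_het=n_het,
        n_lines_out=out.n_lines,
        n_markers_out=out.n_markers,
        marker_stats=stats_df,
        thresholds={
            "max_marker_missing": max_marker_missing,
            "min_maf": min_maf,
            "max_het": max_het,
            "max_line_missing": max_line_missing,
        },
    )
    return out, report


def allelic_fisher_test(calls: np.ndarray, alpha: float = 0.001) -> tuple[float, bool]:
    """Fisher exact test that a SNP's two alleles segregate as one locus.

    Builds the 2x2 table of lines carrying / not carrying each allele
    (heterozygotes count toward both), computes the two-sided Fisher exact
    p-value, and keeps the SNP when independence is rejected at ``alpha``.

    Returns ``(p_value, keep)``.  Raises on a monomorphic marker, for which
    the test is undefined.
    """
    calls = np.asarray(calls)
    calls = calls[(calls != MISSING) & ~np.isnan(calls.astype(float))]
    n_het = int((calls == 1).sum())
    n_ref = int((calls == 0).sum())  # carries only the reference allele
    n_alt = int((calls == 2).sum())  # carries only the alternate allele
    if (n_ref + n_het == 0) or (n_alt + n_het == 0):
        raise ValueError("monomorphic marker: allelic test undefined")
    # Rows: carries ref allele yes/no; columns: carries alt allele yes/no.
    table = np.array([[n_het, n_ref], [n_alt, 0]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p), bool(p < alpha)


def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher exact p-value for an arbitrary 2x2 count table."""
    _, p = stats.fisher_exact(np.asarray(table), alternative="two-sided")
    return float(p)


def impute_missing(m: MarkerMatrix, method: str = "mean") -> MarkerMatrix:
    """Replace missing calls by the per-marker mean dosage.

    ``method='mean'`` keeps fractional dosages; ``method='mean_rounded'``
    rounds to the nearest integer dosage.  Observed calls are unchanged.
    """
    if method not in ("mean", "mean_rounded"):
        raise ValueError(f"unknown imputation method {method!r}")
    miss = m.missing_mask()
    if not miss.any():
        return m
    x = m.values.astype(float)
    x[miss] = np.nan
    col_mean = np.nanmean(x, axis=0)
    if np.isnan(col_mean).any():
        bad = [m.marker_ids[i] for i in np.where(np.isnan(col_mean))[0][:5]]
        raise ValueError(f"fully missing markers cannot be imputed: {bad}")
    idx = np.where(miss)
    x[idx] = col_mean[idx[1]]
    if method == "mean_rounded":
        x = np.rint(x).astype(m.values.dtype if m.values.dtype.kind == "i" else np.int8)
    return MarkerMatrix(x, m.line_ids, m.marker_ids)


def build_grm(m: MarkerMatrix) -> GenomicRelationship:
    """G = XX'/p from the centered, unit-variance (sample sd) marker matrix."""
    x = m.values.astype(float)
    if np.any(m.missing_mask()):
        raise ValueError("marker matrix contains missing calls; impute first")
    x = x - x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [m.marker_ids[i] for i in np.where(sd == 0)[0][:5]]
        raise ValueError(f"zero-variance (monomorphic) markers: {bad}")
    x /= sd
    g = x @ x.T / m.n_markers
    g = (g + g.T) / 2.0
    return GenomicRelationship(g, list(m.line_ids), m.n_markers)
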