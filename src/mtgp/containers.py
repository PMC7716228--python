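"""Core in-memory containers shared across the pipeline.

The pipeline moves three objects between stages: a dosage-coded marker
matrix (lines x SNPs), a table of adjusted line means per environment and
trait (BLUEs), and the genomic relationship matrix derived from the
markers.  All three are thin wrappers around NumPy arrays with explicit
identifier axes, so that every stage can align on line/marker/environment
labels instead of positional indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call in integer dosage matrices.
MISSING = -1

#: Trait registry: canonical trait names and their units.
TRAIT_UNITS = {
    "GY": "t/ha",
    "HI": "%",
    "SF": "grains/g chaff",
    "TGW": "g",
}


@dataclass
class MarkerMatrix:
    """Lines x biallelic SNPs coded as minor-allele dosage {0, 1, 2}.

    Missing calls carry the sentinel :data:`MISSING` (integer matrices) or
    ``nan`` (float matrices, e.g. after unrounded imputation).
    """

    values: np.ndarray
    line_ids: list[str]
    marker_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.line_ids = list(self.line_ids)
        self.marker_ids = list(self.marker_ids)
        n, p = self.values.shape
        if n != len(self.line_ids) or p != len(self.marker_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        if len(set(self.line_ids)) != n:
            raise ValueError("duplicate line IDs")
        if len(set(self.marker_ids)) != p:
            raise ValueError("duplicate marker IDs")

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> np.ndarray:
        """Boolean mask of missing calls, regardless of dtype."""
        if np.issubdtype(self.values.dtype, np.floating):
            return np.isnan(self.values)
        return self.values == MISSING

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.line_ids, columns=self.marker_ids)

    def subset(self, *, lines: np.ndarray | None = None, markers: np.ndarray | None = None) -> "MarkerMatrix":
        """Row/column subset by boolean mask or integer index array."""
        vals = self.values
        lids, mids = self.line_ids, self.marker_ids
        if lines is not None:
            idx = np.arange(len(lids))[lines] if np.asarray(lines).dtype == bool else np.asarray(lines)
            vals = vals[idx]
            lids = [lids[i] for i in idx]
        if markers is not None:
            idx = np.arange(len(mids))[markers] if np.asarray(markers).dtype == bool else np.asarray(markers)
            vals = vals[:, idx]
            mids = [mids[i] for i in idx]
        return MarkerMatrix(vals, lids, mids)


@dataclass
class GenomicRelationship:
    """VanRaden-style genomic relationship matrix G = XX'/p.

    ``p`` is the number of (centered, unit-variance) markers used.
    """

    matrix: np.ndarray
    line_ids: list[str]
    p: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n) or n != len(self.line_ids):
            raise ValueError("G must be square and match line_ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("G must be symmetric")

    @property
    def n_lines(self) -> int:
        return self.matrix.shape[0]

    def align(self, line_ids: list[str]) -> np.ndarray:
        """Return G restricted and reordered to the given line IDs."""
        pos = {l: i for i, l in enumerate(self.line_ids)}
        try:
            idx = np.array([pos[l] for l in line_ids])
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"line {e.args[0]!r} not present in GRM") from None
        return self.matrix[np.ix_(idx, idx)]


@dataclass
class BlueTable:
    """Adjusted line means (BLUEs) per line x environment x trait.

    ``values`` has shape (n_lines, n_envs, n_traits); missing / masked cells
    are ``nan``.  ``se`` (same shape) holds standard errors when available.
    """

    values: np.ndarray
    line_ids: list[str]
    env_ids: list[str]
    trait_ids: list[str]
    se: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.line_ids), len(self.env_ids), len(self.trait_ids))
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
            if self.se.shape != expected:
                raise ValueError("se shape mismatch")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def copy(self) -> "BlueTable":
        return BlueTable(
            self.values.copy(),
            list(self.line_ids),
            list(self.env_ids),
            list(self.trait_ids),
            None if self.se is None else self.se.copy(),
        )

    def trait(self, trait: str) -> np.ndarray:
        """(n_lines, n_envs) slice for one trait."""
        return self.values[:, :, self.trait_ids.index(trait)]

    def to_long(self) -> pd.DataFrame:
        n, i, l = self.values.shape
        lines = np.repeat(self.line_ids, i)
        envs = np.tile(self.env_ids, n)
        df = pd.DataFrame({"line": lines, "env": envs})
        for t, name in enumerate(self.trait_ids):
            df[name] = self.values[:, :, t].reshape(-1)
        return df

    @classmethod
    def from_long(cls, df: pd.DataFrame, trait_ids: list[str] | None = None) -> "BlueTable":
        traits = trait_ids or [c for c in df.columns if c not in ("line", "env")]
        lines = sorted(df["line"].unique())
        envs = sorted(df["env"].unique())
        arr = np.full((len(lines), len(envs), len(traits)), np.nan)
        li = {l: i for i, l in enumerate(lines)}
        ei = {e: i for i, e in enumerate(envs)}
        for _, row in df.iterrows():
            for t, name in enumerate(traits):
                arr[li[row["line"]], ei[row["env"]], t] = row[name]
        return cls(arr, lines, envs, traits)
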