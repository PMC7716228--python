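"""Synthetic genotype/phenotype generator for a structured inbred wheat panel.

Emulates the statistical structure of a Gulf-Atlantic-style soft wheat
genomic-selection panel: ~237 unreplicated entries plus repeated checks laid
out in an augmented block design over four environments, genotyped with
GBS-like biallelic SNPs in about ten subpopulations, and phenotyped for four
correlated yield-component traits (GY, HI, SF, TGW).

Genotypes follow a Balding-Nichols divergence model: each subpopulation's
allele frequencies are Beta-distributed around a common ancestral frequency
with an Fst-like divergence parameter.  Genetic values are infinitesimal
(Gaussian effects on every marker) with a trait covariance ``Sigma_t`` and
an environment covariance ``Sigma_E``; residual variances are solved
analytically per trait x environment cell so that realized broad-sense
heritability matches the requested target in expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, MarkerMatrix

# ---------------------------------------------------------------------------
# Study-scale default parameters.
#
# Environment order everywhere: Citra 2017, Citra 2018, Quincy 2017,
# Quincy 2018.  Trait order: GY, HI, SF, TGW.

DEFAULT_TRAITS = ["GY", "HI", "SF", "TGW"]
DEFAULT_ENVS = ["Citra_2017", "Citra_2018", "Quincy_2017", "Quincy_2018"]


def _corr(off: dict[tuple[int, int], float], dim: int) -> np.ndarray:
    m = np.eye(dim)
    for (i, j), v in off.items():
        m[i, j] = m[j, i] = v
    return m


#: Genetic correlations among GY, HI, SF, TGW (unit genetic variances).
DEFAULT_TRAIT_COV = _corr(
    {(0, 1): 0.67, (0, 2): 0.17, (0, 3): 0.18, (1, 2): 0.17, (1, 3): 0.10, (2, 3): -0.32},
    4,
)

#: Genetic correlations among the four environments.
DEFAULT_ENV_COV = _corr(
    {(0, 1): 0.17, (0, 2): 0.24, (0, 3): 0.19, (1, 2): 0.19, (1, 3): 0.16, (2, 3): 0.26},
    4,
)

#: Residual correlations among traits (phenotypic-correlation-like).
DEFAULT_RESIDUAL_COV = _corr(
    {(0, 1): 0.76, (0, 2): 0.36, (0, 3): 0.33, (1, 2): 0.30, (1, 3): 0.24, (2, 3): -0.23},
    4,
)

#: Broad-sense heritability per trait (rows: GY, HI, SF, TGW) x environment
#: (cols: Citra 2017, Citra 2018, Quincy 2017, Quincy 2018).
DEFAULT_H2 = np.array(
    [
        [0.71, 0.80, 0.36, 0.24],
        [0.78, 0.74, 0.43, 0.26],
        [0.38, 0.68, 0.22, 0.32],
        [0.48, 0.87, 0.58, 0.44],
    ]
)

#: Panel-level trait means (GY t/ha, HI %, SF grains/g chaff, TGW g).
DEFAULT_TRAIT_MEANS = np.array([3.6, 36.2, 85.0, 37.3])


@dataclass
class SimConfig:
    """Parameters of the synthetic panel.

    Defaults reproduce the study conditions: 237 entries + 3 checks in
    10 subpopulations, 27,957 GBS SNPs with low heterozygosity, 4 traits in
    4 environments with per-cell heritabilities spanning 0.22-0.87, trait
    and environment genetic correlations as estimated for this panel, and
    an augmented design with 12 blocks per environment.
    """

    n_lines: int = 237
    n_checks: int = 3
    n_markers: int = 27957
    n_subpops: int = 10
    n_traits: int = 4
    n_envs: int = 4
    n_blocks: int = 12
    trait_genetic_cov: np.ndarray = field(default_factory=lambda: DEFAULT_TRAIT_COV.copy())
    env_genetic_cov: np.ndarray = field(default_factory=lambda: DEFAULT_ENV_COV.copy())
    residual_cov: np.ndarray = field(default_factory=lambda: DEFAULT_RESIDUAL_COV.copy())
    ge_variance: float = 1.0  # weight of Sigma_E vs a common across-env main effect
    target_h2: np.ndarray = field(default_factory=lambda: DEFAULT_H2.copy())  # traits x envs
    maf_range: tuple[float, float] = (0.05, 0.5)
    het_rate: float = 0.02
    missing_rate: float = 0.10
    fst: float = 0.2  # Balding-Nichols divergence
    trait_means: np.ndarray = field(default_factory=lambda: DEFAULT_TRAIT_MEANS.copy())
    env_effect_sd: float = 0.5
    block_effect_sd: float = 0.3
    dth_effect: np.ndarray = field(default_factory=lambda: np.zeros(4))  # per-trait slope on DTH
    dth_mean: float = 100.0
    dth_sd: float = 5.0  # between-line spread in heading date
    dth_plot_sd: float = 2.0  # within-line plot-to-plot spread
    trait_ids: list[str] = field(default_factory=lambda: list(DEFAULT_TRAITS))
    env_ids: list[str] = field(default_factory=lambda: list(DEFAULT_ENVS))
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_lines", "n_checks", "n_markers", "n_subpops", "n_traits", "n_envs", "n_blocks"):
            if name != "n_checks" and getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_checks < 0:
            raise ValueError("n_checks must be >= 0")
        if self.n_subpops > self.n_lines:
            raise ValueError("n_subpops cannot exceed n_lines")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must be in (0, 1)")
        for m, dim, nm in (
            (self.trait_genetic_cov, self.n_traits, "trait_genetic_cov"),
            (self.env_genetic_cov, self.n_envs, "env_genetic_cov"),
            (self.residual_cov, self.n_traits, "residual_cov"),
        ):
            m = np.asarray(m, dtype=float)
            if m.shape != (dim, dim):
                raise ValueError(f"{nm} must be {dim}x{dim}")
            if not np.allclose(m, m.T):
                raise ValueError(f"{nm} must be symmetric")
            if np.linalg.eigvalsh(m).min() < -1e-8:
                raise ValueError(f"{nm} must be positive semidefinite")
        self.target_h2 = np.asarray(self.target_h2, dtype=float)
        if self.target_h2.shape != (self.n_traits, self.n_envs):
            raise ValueError("target_h2 must be n_traits x n_envs")
        if np.any(self.target_h2 < 0) or np.any(self.target_h2 > 1):
            raise ValueError("target_h2 entries must lie in [0, 1]")
        if not 0.0 <= self.ge_variance <= 1.0:
            raise ValueError("ge_variance must be in [0, 1]")
        self.dth_effect = np.asarray(self.dth_effect, dtype=float)
        if self.dth_effect.shape != (self.n_traits,):
            raise ValueError("dth_effect must have one slope per trait")

    @property
    def n_total_lines(self) -> int:
        return self.n_lines + self.n_checks

    def line_ids(self) -> list[str]:
        width = max(3, len(str(self.n_lines)))
        entries = [f"L{i + 1:0{width}d}" for i in range(self.n_lines)]
        checks = [f"CHK{i + 1}" for i in range(self.n_checks)]
        return entries + checks

    def check_ids(self) -> list[str]:
        return [f"CHK{i + 1}" for i in range(self.n_checks)]


@dataclass
class TruthRecord:
    """Ground truth behind one simulated panel (the parameter-recovery oracle)."""

    genetic_values: np.ndarray  # (n_total_lines, n_envs, n_traits)
    marker_effects: np.ndarray  # (n_markers, n_envs, n_traits)
    subpop_labels: np.ndarray  # (n_total_lines,)
    realized_h2: np.ndarray  # (n_traits, n_envs)
    residual_sd: np.ndarray  # (n_traits, n_envs)
    line_ids: list[str]
    env_ids: list[str]
    trait_ids: list[str]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.realized_h2)):
            raise ValueError("realized h2 must be finite")


def _psd_sqrt(m: np.ndarray) -> np.ndarray:
    """Symmetric matrix square root tolerating semidefinite input."""
    w, v = np.linalg.eigh(m)
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w) @ v.T


def simulate_marker_matrix(config: SimConfig) -> tuple[MarkerMatrix, np.ndarray]:
    """Draw a structured inbred dosage matrix plus subpopulation labels.

    Returns a (lines x markers) matrix coded {0, 1, 2} with the missing
    sentinel, and an integer label per line.  Subpopulation allele
    frequencies diverge from a common ancestral frequency under the
    Balding-Nichols Beta model with parameter ``config.fst``.
    """
    rng = np.random.default_rng(config.seed)
    n, p, k = config.n_total_lines, config.n_markers, config.n_subpops

    lo, hi = config.maf_range
    ancestral = rng.uniform(lo, hi, size=p)
    f = config.fst
    a = ancestral * (1.0 - f) / f
    b = (1.0 - ancestral) * (1.0 - f) / f
    subpop_freq = np.clip(rng.beta(a, b, size=(k, p)), 1e-4, 1.0 - 1e-4)

    # Every subpopulation is guaranteed nonempty; the rest is random.
    labels = np.concatenate([np.arange(k), rng.integers(0, k, size=n - k)])
    rng.shuffle(labels)

    freq = subpop_freq[labels]  # (n, p)
    dosage = (2 * (rng.random((n, p)) < freq)).astype(np.int8)
    if config.het_rate > 0:
        dosage[rng.random((n, p)) < config.het_rate] = 1
    if config.missing_rate > 0:
        dosage[rng.random((n, p)) < config.missing_rate] = MISSING

    marker_ids = [f"M{i + 1:06d}" for i in range(p)]
    return MarkerMatrix(dosage, config.line_ids(), marker_ids), labels


def _standardized(markers: MarkerMatrix) -> np.ndarray:
    """Mean-impute, center, and unit-scale dosages; zero out monomorphic columns."""
    x = markers.values.astype(float)
    miss = markers.missing_mask()
    x[miss] = np.nan
    col_mean = np.nanmean(x, axis=0)
    idx = np.where(miss)
    x[idx] = col_mean[idx[1]]
    x -= col_mean
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf  # monomorphic markers contribute nothing
    return x / sd


def simulate_phenotypes(
    markers: MarkerMatrix, config: SimConfig
) -> tuple[pd.DataFrame, TruthRecord]:
    """Generate augmented-design plot records and the matching truth.

    Genetic values are drawn from marker effects whose (environment, trait)
    covariance is ``w * Sigma_E + (1 - w) * J`` (Kronecker) ``Sigma_t``, with
    ``w = ge_variance``; at the default ``w = 1`` the environment margin of
    the genetic values equals ``Sigma_E`` exactly.  Per-cell residual
    variances are solved from the realized genetic variances so that
    broad-sense heritability hits ``target_h2`` in expectation.
    """
    if markers.n_lines != config.n_total_lines:
        raise ValueError(
            f"marker matrix has {markers.n_lines} lines, config expects {config.n_total_lines}"
        )
    rng = np.random.default_rng(config.seed + 1)
    n, p = markers.n_lines, markers.n_markers
    L, I = config.n_traits, config.n_envs

    xs = _standardized(markers)

    w = config.ge_variance
    env_cov = w * config.env_genetic_cov + (1.0 - w) * np.ones((I, I))
    full_cov = np.kron(env_cov, config.trait_genetic_cov)  # (I*L, I*L), env-major
    root = _psd_sqrt(full_cov / p)
    effects = rng.standard_normal((p, I * L)) @ root
    u = (xs @ effects).reshape(n, I, L)  # genetic values per line x env x trait

    # Residual calibration: sigma2_e = v_g (1 - h2) / h2 per trait x env cell.
    v_g = u.var(axis=0, ddof=1)  # (I, L)
    h2 = config.target_h2.T  # (I, L) to align with v_g
    with np.errstate(divide="ignore"):
        sigma2_e = np.where(h2 > 0, v_g * (1.0 - h2) / np.maximum(h2, 1e-12), v_g * 1e6)
    sigma_e = np.sqrt(sigma2_e)

    res_corr = _to_corr(config.residual_cov)
    res_root = np.linalg.cholesky(res_corr + 1e-10 * np.eye(L))

    env_eff = rng.normal(0.0, config.env_effect_sd, size=(I, L))
    block_eff = rng.normal(0.0, config.block_effect_sd, size=(I, config.n_blocks, L))
    dth = rng.normal(config.dth_mean, config.dth_sd, size=n)

    line_ids = config.line_ids()
    entry_idx = np.arange(config.n_lines)
    check_idx = np.arange(config.n_lines, n)

    rows: list[dict] = []
    for i in range(I):
        order = rng.permutation(entry_idx)
        blocks = np.array_split(order, config.n_blocks)
        for k, block_lines in enumerate(blocks):
            plot_lines = np.concatenate([block_lines, check_idx])
            z = rng.standard_normal((len(plot_lines), L)) @ res_root.T
            e = z * sigma_e[i]  # per-trait residual sd for this environment
            dth_plot = dth[plot_lines] + rng.normal(0, config.dth_plot_sd, len(plot_lines))
            y = (
                config.trait_means
                + env_eff[i]
                + block_eff[i, k]
                + np.outer(dth_plot - config.dth_mean, config.dth_effect)
                + u[plot_lines, i, :]
                + e
            )
            for r, j in enumerate(plot_lines):
                row = {
                    "env": config.env_ids[i],
                    "line": line_ids[j],
                    "block": f"B{k + 1:02d}",
                    "is_check": bool(j >= config.n_lines),
                    "DTH": float(dth_plot[r]),
                }
                row.update({t: float(y[r, t_i]) for t_i, t in enumerate(config.trait_ids)})
                rows.append(row)

    records = pd.DataFrame(rows)
    realized_h2 = (v_g / (v_g + sigma2_e)).T  # (L, I) -> traits x envs
    truth = TruthRecord(
        genetic_values=u,
        marker_effects=effects.reshape(p, I, L),
        subpop_labels=np.asarray(getattr(config, "_labels", np.full(n, -1))),
        realized_h2=realized_h2,
        residual_sd=sigma_e.T,
        line_ids=line_ids,
        env_ids=list(config.env_ids),
        trait_ids=list(config.trait_ids),
    )
    return records, truth


def simulate_panel(config: SimConfig) -> tuple[MarkerMatrix, pd.DataFrame, TruthRecord]:
    """Convenience wrapper: genotypes, phenotypes, and truth in one call."""
    markers, labels = simulate_marker_matrix(config)
    config._labels = labels  # type: ignore[attr-defined]
    records, truth = simulate_phenotypes(markers, config)
    truth.subpop_labels = labels
    return markers, records, truth


def _to_corr(cov: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)
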