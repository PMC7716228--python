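"""Phenotype-stage mixed models: BLUEs, heritability, trait correlations.

Two models drive this stage.  The joint model treats genotype as fixed and
environment, block-within-environment, and genotype x environment as
independent random effects; per-environment adjusted means (BLUEs) are the
genotype solutions plus the environment and G x E predictions.  The
per-environment model treats genotype and block as random and yields the
variance components behind broad-sense heritability
``H2 = sigma2_G / (sigma2_G + sigma2_e)``.

Variance components are estimated by REML: the residual variance is
profiled out and the remaining variance ratios are optimized on the log
scale with a quasi-Newton method.  Replicated checks in the augmented
design carry the information that separates genotypic from residual
variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .containers import BlueTable

log = logging.getLogger("mtgp")

REQUIRED_COLUMNS = ("env", "line", "block", "is_check", "DTH")


def validate_records(records: pd.DataFrame, traits: list[str]) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"phenotype records missing required columns: {missing}")
    absent = [t for t in traits if t not in records.columns]
    if absent:
        raise ValueError(f"unknown trait columns requested: {absent}")
    dup = records.duplicated(subset=["env", "line", "block"])
    if dup.any():
        raise ValueError(f"{int(dup.sum())} duplicate (env, line, block) keys")


# ---------------------------------------------------------------------------
# REML machinery


def _one_hot(labels: pd.Series) -> tuple[np.ndarray, list]:
    cats = pd.Categorical(labels)
    z = np.zeros((len(labels), len(cats.categories)))
    z[np.arange(len(labels)), cats.codes] = 1.0
    return z, list(cats.categories)


def _reml(y: np.ndarray, x: np.ndarray, z_list: list[np.ndarray]) -> dict:
    """REML fit of y = X b + sum_r Z_r u_r + e with iid components.

    Returns variance components, GLS fixed effects with covariance, and
    BLUPs of each random component.
    """
    n, q = x.shape
    kernels = [z @ z.T for z in z_list]

    def neg_restricted_ll(log_gamma: np.ndarray) -> float:
        h = np.eye(n)
        for g, k in zip(np.exp(log_gamma), kernels):
            h += g * k
        try:
            c = np.linalg.cholesky(h)
        except np.linalg.LinAlgError:
            return 1e10
        logdet_h = 2.0 * np.log(np.diag(c)).sum()
        hi_y = np.linalg.solve(h, y)
        hi_x = np.linalg.solve(h, x)
        xtx = x.T @ hi_x
        sign, logdet_xtx = np.linalg.slogdet(xtx)
        if sign <= 0:
            return 1e10
        beta = np.linalg.solve(xtx, x.T @ hi_y)
        r = y - x @ beta
        quad = float(r @ np.linalg.solve(h, r))
        if quad <= 0:
            return 1e10
        df = n - q
        return 0.5 * (df * np.log(quad / df) + logdet_h + logdet_xtx)

    x0 = np.zeros(len(z_list))
    res = optimize.minimize(
        neg_restricted_ll,
        x0,
        method="L-BFGS-B",
        bounds=[(-12.0, 12.0)] * len(z_list),
        options={"maxiter": 200},
    )
    gamma = np.exp(res.x)

    h = np.eye(n)
    for g, k in zip(gamma, kernels):
        h += g * k
    hi_x = np.linalg.solve(h, x)
    hi_y = np.linalg.solve(h, y)
    xtx = x.T @ hi_x
    if np.linalg.cond(xtx) > 1e12:
        raise ValueError("design is singular: fixed effects are not estimable")
    beta = np.linalg.solve(xtx, x.T @ hi_y)
    r = y - x @ beta
    hi_r = np.linalg.solve(h, r)
    sigma2_e = float(r @ hi_r) / (n - q)
    blups = [g * z.T @ hi_r for g, z in zip(gamma, z_list)]
    beta_cov = sigma2_e * np.linalg.inv(xtx)
    return {
        "gamma": gamma,
        "sigma2_e": sigma2_e,
        "sigma2": gamma * sigma2_e,
        "beta": beta,
        "beta_cov": beta_cov,
        "blups": blups,
        "converged": bool(res.success),
    }


# ---------------------------------------------------------------------------
# BLUEs (joint model)


def fit_blues(
    records: pd.DataFrame,
    traits: list[str] | None = None,
    adjust_dth: bool = False,
    scope: str = "per_env",
) -> BlueTable:
    """Adjusted line means from the joint mixed model.

    Genotype is fixed; environment, block-within-environment, and G x E are
    independent random effects.  With ``adjust_dth`` the days-to-heading
    covariate (centered) enters as an additional fixed effect.  With
    ``scope='per_env'`` the cell value is genotype effect + environment +
    G x E predictions; ``scope='overall'`` returns one across-environment
    adjusted mean per line.
    """
    traits = traits or [c for c in records.columns if c not in REQUIRED_COLUMNS]
    validate_records(records, traits)
    if records["line"].nunique() < 2:
        raise ValueError("need at least two genotypes")
    if scope not in ("per_env", "overall"):
        raise ValueError("scope must be 'per_env' or 'overall'")

    lines = sorted(records["line"].unique())
    envs = sorted(records["env"].unique())
    n_lines, n_envs = len(lines), len(envs)

    zg_full, _ = _one_hot(pd.Categorical(records["line"], categories=lines))
    ze, _ = _one_hot(pd.Categorical(records["env"], categories=envs))
    zb, _ = _one_hot(records["env"].astype(str) + "/" + records["block"].astype(str))
    ge_labels = pd.Categorical(
        records["line"].astype(str) + "/" + records["env"].astype(str),
        categories=[f"{l}/{e}" for l in lines for e in envs],
    )
    zge = np.zeros((len(records), n_lines * n_envs))
    zge[np.arange(len(records)), ge_labels.codes] = 1.0

    x = zg_full  # genotype means absorb the intercept
    if adjust_dth:
        dth = records["DTH"].to_numpy(float)
        x = np.column_stack([x, dth - dth.mean()])

    z_list = [ze, zb] if n_envs > 1 else [zb]
    if n_envs > 1:
        z_list.append(zge)

    values = np.full((n_lines, n_envs, len(traits)), np.nan)
    ses = np.full_like(values, np.nan)
    for t_i, trait in enumerate(traits):
        y = records[trait].to_numpy(float)
        ok = np.isfinite(y)
        fit = _reml(y[ok], x[ok], [z[ok] for z in z_list])
        g_eff = fit["beta"][:n_lines]
        g_se = np.sqrt(np.diag(fit["beta_cov"])[:n_lines])
        if n_envs > 1:
            env_eff = fit["blups"][0]
            ge_eff = fit["blups"][-1].reshape(n_lines, n_envs)
        else:
            env_eff = np.zeros(1)
            ge_eff = np.zeros((n_lines, 1))
        if scope == "per_env":
            values[:, :, t_i] = g_eff[:, None] + env_eff[None, :] + ge_eff
        else:
            values[:, :, t_i] = g_eff[:, None]
        ses[:, :, t_i] = g_se[:, None]

    if scope == "overall":
        return BlueTable(values[:, :1, :], lines, ["overall"], traits, ses[:, :1, :])
    return BlueTable(values, lines, envs, traits, ses)


# ---------------------------------------------------------------------------
# Heritability (per-environment model)


@dataclass
class VarianceComponents:
    env: str
    trait: str
    sigma2_g: float
    sigma2_b: float
    sigma2_e: float
    h2: float
    cv: float  # 100 * sigma_e / trait mean

    def __post_init__(self) -> None:
        if min(self.sigma2_g, self.sigma2_b, self.sigma2_e) < 0:
            raise ValueError("variance components must be nonnegative")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("H2 must lie in [0, 1]")


def estimate_heritability(
    records: pd.DataFrame, env: str, trait: str, adjust_dth: bool = False
) -> VarianceComponents:
    """Broad-sense heritability within one environment.

    Fits genotype and block as random effects by REML on the single
    environment's records and returns ``H2 = s2_G / (s2_G + s2_e)``.
    """
    validate_records(records, [trait])
    sub = records.loc[records["env"] == env].reset_index(drop=True)
    if sub.empty:
        raise ValueError(f"no records for environment {env!r}")
    counts = sub.groupby("line")[trait].count()
    if counts.max() < 2:
        raise ValueError(
            "no genotype is replicated in this environment; "
            "genotypic variance is unidentifiable"
        )

    y = sub[trait].to_numpy(float)
    ok = np.isfinite(y)
    sub, y = sub.loc[ok].reset_index(drop=True), y[ok]
    zg, _ = _one_hot(sub["line"])
    zb, _ = _one_hot(sub["block"])
    x = np.ones((len(sub), 1))
    if adjust_dth:
        dth = sub["DTH"].to_numpy(float)
        x = np.column_stack([x, dth - dth.mean()])

    fit = _reml(y, x, [zg, zb])
    s2_g, s2_b = fit["sigma2"]
    s2_e = fit["sigma2_e"]
    h2 = s2_g / (s2_g + s2_e) if (s2_g + s2_e) > 0 else 0.0
    mean = float(np.mean(y))
    cv = 100.0 * np.sqrt(s2_e) / mean if mean != 0 else np.nan
    return VarianceComponents(env, trait, float(s2_g), float(s2_b), float(s2_e), float(h2), cv)


def heritability_table(
    records: pd.DataFrame, traits: list[str] | None = None, adjust_dth: bool = False
) -> pd.DataFrame:
    """H2 and variance components for every environment x trait cell."""
    traits = traits or [c for c in records.columns if c not in REQUIRED_COLUMNS]
    rows = []
    for env in sorted(records["env"].unique()):
        for trait in traits:
            vc = estimate_heritability(records, env, trait, adjust_dth=adjust_dth)
            rows.append(vars(vc))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Trait correlations


def trait_pearson(blues: BlueTable) -> pd.DataFrame:
    """Pairwise Pearson correlations of traits on line x environment values."""
    if blues.shape[0] < 3:
        raise ValueError("need at least 3 lines for correlations")
    long = blues.to_long()
    mat = long[blues.trait_ids]
    constant = mat.std(ddof=1) == 0
    if constant.any():
        log.warning("constant traits have undefined correlations: %s",
                    list(mat.columns[constant]))
    corr = mat.corr(method="pearson")
    for t in mat.columns[constant]:
        corr.loc[t, :] = np.nan
        corr.loc[:, t] = np.nan
        corr.loc[t, t] = 1.0
    return corr
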