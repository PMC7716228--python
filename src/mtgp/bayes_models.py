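"""Bayesian prediction models: MGBLUP, BMTME, and BMORS.

MGBLUP is a single-trait multi-environment genomic BLUP with a main
genetic effect (kernel ``Zg G Zg'``) and a reaction-norm G x E effect whose
kernel is the Hadamard product of the genetic kernel with the
environment-incidence kernel ``ZE ZE'``.  With cells laid out line-within-
environment these kernels are ``J_I (x) G`` and ``I_I (x) G``, so a single
eigendecomposition of G turns every Gibbs update into independent scalar
draws.

BMTME is the matrix-variate multi-trait multi-environment model

    Y = X beta + Z1 b1 + Z2 b2 + E,

with ``b1 ~ MN(0, G, Sigma_t)`` (genotype x trait), ``b2 ~ MN(0,
Sigma_E (x) G, Sigma_t)`` (genotype x environment x trait) and residual
rows iid ``N(0, R_e)``.  All full conditionals are conjugate: matrix-normal
for the effects (block-diagonal after rotating by the eigenvectors of G and
Sigma_E), inverse-Wishart for Sigma_t, Sigma_E and R_e, flat-prior normal
for beta.  Masked response cells are handled by data augmentation, which
gives cross-validation and leave-one-environment-out prediction a single
code path.

BMORS stacks single-trait MGBLUP predictions: stage one fits MGBLUP per
trait, stage two regresses the target trait on the standardized stage-one
predictions of all traits (scaling constants estimated on training cells
only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import BlueTable, GenomicRelationship

log = logging.getLogger("mtgp")


@dataclass
class McmcConfig:
    """Gibbs-sampler settings (defaults follow the study: 15,000/10,000)."""

    iterations: int = 15000
    burn_in: int = 10000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


def _scaled_inv_chi2(rng: np.random.Generator, df: float, scale: float, ss: float, n: int) -> float:
    """Draw from the scaled-inverse-chi^2 full conditional."""
    return (df * scale + ss) / rng.chisquare(df + n)


def _eigh_psd(g: np.ndarray, floor: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    lam, vec = np.linalg.eigh((g + g.T) / 2.0)
    if lam.min() < -1e-6:
        raise ValueError("relationship matrix is not positive semidefinite")
    return np.maximum(lam, floor), vec


# ---------------------------------------------------------------------------
# MGBLUP


@dataclass
class MgblupFit:
    env_effects: np.ndarray  # (I,)
    genetic_values: np.ndarray  # (J,) posterior-mean main genetic effect
    ge_effects: np.ndarray  # (J, I)
    var_g: float
    var_ge: float
    var_e: float
    fitted: np.ndarray  # (J, I) posterior-mean fitted cells
    mask: np.ndarray  # (J, I) True where the input cell was missing/masked
    line_ids: list[str]
    env_ids: list[str]

    def predictions(self) -> np.ndarray:
        """Posterior-mean predictions for every cell (observed and masked)."""
        return self.fitted


def fit_mgblup(
    blues: BlueTable | np.ndarray,
    grm: GenomicRelationship,
    mcmc: McmcConfig,
    trait: str | None = None,
    include_ge: bool = True,
    prior_df: float = 5.0,
) -> MgblupFit:
    """Single-trait multi-environment GBLUP fitted by Gibbs sampling.

    ``blues`` is a (lines x environments) table for one trait; ``nan`` cells
    are treated as unobserved and predicted by data augmentation.  Variance
    priors are scaled-inverse-chi^2 with ``prior_df`` degrees of freedom and
    scale 0.5 x phenotypic variance.
    """
    if isinstance(blues, BlueTable):
        if trait is None and len(blues.trait_ids) != 1:
            raise ValueError("specify trait= for a multi-trait BlueTable")
        y = blues.trait(trait or blues.trait_ids[0]).copy()
        line_ids, env_ids = list(blues.line_ids), list(blues.env_ids)
    else:
        y = np.asarray(blues, dtype=float).copy()
        line_ids = [f"L{i}" for i in range(y.shape[0])]
        env_ids = [f"E{i}" for i in range(y.shape[1])]

    J, I = y.shape
    g = grm.align(line_ids)
    lam, vec = _eigh_psd(g)
    w = vec * np.sqrt(lam)  # u = W a with a ~ N(0, s2 I)

    if I < 2 and include_ge:
        log.warning("single environment: dropping the G x E term")
        include_ge = False

    mask = ~np.isfinite(y)
    if mask.all():
        raise ValueError("no observed cells")
    y_obs_var = float(np.nanvar(y, ddof=1))
    s0 = 0.5 * y_obs_var if y_obs_var > 0 else 0.5
    rng = np.random.default_rng(mcmc.seed)

    # State.
    y_full = y.copy()
    col_means = np.nanmean(np.where(mask, np.nan, y), axis=0)
    col_means = np.where(np.isfinite(col_means), col_means, np.nanmean(y))
    y_full[mask] = np.broadcast_to(col_means, y.shape)[mask]
    beta = col_means.copy()
    a = np.zeros(J)
    b = np.zeros((J, I))
    var_g = var_ge = var_e = s0

    acc = {k: 0.0 for k in ("beta", "u1", "u2", "fitted", "var_g", "var_ge", "var_e")}
    n_kept = 0

    for it in range(mcmc.iterations):
        u1 = w @ a
        u2 = w @ b if include_ge else b
        fitted = beta[None, :] + u1[:, None] + u2

        # Data augmentation for masked cells.
        if mask.any():
            y_full[mask] = fitted[mask] + np.sqrt(var_e) * rng.standard_normal(int(mask.sum()))

        # Environment means (flat prior).
        resid = y_full - u1[:, None] - u2
        beta = resid.mean(axis=0) + np.sqrt(var_e / J) * rng.standard_normal(I)

        # Main genetic effect in the eigenbasis: precision diagonal.
        r1 = y_full - beta[None, :] - u2
        s = vec.T @ r1.sum(axis=1)  # (J,)
        d = I * lam / var_e + 1.0 / var_g
        mean = (np.sqrt(lam) * s / var_e) / d
        a = mean + rng.standard_normal(J) / np.sqrt(d)
        u1 = w @ a

        # G x E deviations, independently per environment.
        if include_ge:
            r2 = y_full - beta[None, :] - u1[:, None]
            s2 = vec.T @ r2  # (J, I)
            d2 = lam[:, None] / var_e + 1.0 / var_ge
            mean2 = (np.sqrt(lam)[:, None] * s2 / var_e) / d2
            b = mean2 + rng.standard_normal((J, I)) / np.sqrt(d2)
            u2 = w @ b

        # Variances.
        var_g = _scaled_inv_chi2(rng, prior_df, s0, float(a @ a), J)
        if include_ge:
            var_ge = _scaled_inv_chi2(rng, prior_df, s0, float((b * b).sum()), J * I)
        e = y_full - beta[None, :] - u1[:, None] - u2
        var_e = _scaled_inv_chi2(rng, prior_df, s0, float((e * e).sum()), J * I)

        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            n_kept += 1
            acc["beta"] = acc["beta"] + beta
            acc["u1"] = acc["u1"] + u1
            acc["u2"] = acc["u2"] + u2
            acc["fitted"] = acc["fitted"] + (beta[None, :] + u1[:, None] + u2)
            acc["var_g"] += var_g
            acc["var_ge"] += var_ge
            acc["var_e"] += var_e

    return MgblupFit(
        env_effects=acc["beta"] / n_kept,
        genetic_values=acc["u1"] / n_kept,
        ge_effects=acc["u2"] / n_kept,
        var_g=acc["var_g"] / n_kept,
        var_ge=acc["var_ge"] / n_kept,
        var_e=acc["var_e"] / n_kept,
        fitted=acc["fitted"] / n_kept,
        mask=mask,
        line_ids=line_ids,
        env_ids=env_ids,
    )


# ---------------------------------------------------------------------------
# BMTME


@dataclass
class PosteriorSummary:
    beta_mean: np.ndarray  # (I, L)
    b1_mean: np.ndarray  # (J, L)
    b2_mean: np.ndarray  # (I, J, L)
    sigma_t: np.ndarray  # (L, L) posterior mean trait genetic covariance
    sigma_env: np.ndarray  # (I, I) posterior mean environment covariance
    r_e: np.ndarray  # (L, L) posterior mean residual covariance
    rg_traits: np.ndarray  # (L, L) posterior-mean genetic correlations
    rg_envs: np.ndarray  # (I, I)
    sigma_t_sd: np.ndarray
    r_e_sd: np.ndarray
    fitted: np.ndarray  # (J, I, L) posterior-mean fitted cells
    mask: np.ndarray  # (J, I, L)
    n_jitter: int
    line_ids: list[str]
    env_ids: list[str]
    trait_ids: list[str]

    def predictions(self) -> np.ndarray:
        return self.fitted


def _sample_mvn_rows(
    rng: np.random.Generator,
    lin: np.ndarray,  # (m, L) likelihood linear terms Re^-1 r
    re_inv: np.ndarray,  # (L, L)
    prior_scales: np.ndarray,  # (m,) prior variance multipliers
    sigma_inv: np.ndarray,  # (L, L) prior column precision (Sigma_t^-1)
    n_rep: float = 1.0,
) -> np.ndarray:
    """Sample independent rows with precision ``n_rep Re^-1 + (1/s_m) St^-1``."""
    m, L = lin.shape
    prec = n_rep * re_inv[None] + sigma_inv[None] / prior_scales[:, None, None]
    chol = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, lin[:, :, None])[:, :, 0]
    z = rng.standard_normal((m, L, 1))
    noise = np.linalg.solve(np.transpose(chol, (0, 2, 1)), z)[:, :, 0]
    return mean + noise


def _invwishart_jittered(
    rng: np.random.Generator, df: float, scale: np.ndarray, counter: list[int]
) -> np.ndarray:
    scale = (scale + scale.T) / 2.0
    for attempt in range(5):
        try:
            draw = np.atleast_2d(stats.invwishart.rvs(df=df, scale=scale, random_state=rng))
            np.linalg.cholesky(draw)  # reject numerically non-PD draws
            return draw
        except np.linalg.LinAlgError:
            counter[0] += 1
            scale = scale + 10.0 ** (attempt - 6) * np.eye(scale.shape[0])
    raise np.linalg.LinAlgError("inverse-Wishart scale could not be stabilized")


def fit_bmtme(
    blues: BlueTable,
    grm: GenomicRelationship,
    mcmc: McmcConfig,
) -> PosteriorSummary:
    """Matrix-variate multi-trait multi-environment Gibbs sampler.

    Priors: flat on beta; inverse-Wishart(dim + 2, I) on Sigma_t, Sigma_E
    and R_e.  The eigendecomposition of G is precomputed once; Sigma_E is
    re-diagonalized each sweep (it is only I x I).  Masked cells are imputed
    by data augmentation each sweep and their posterior-mean fitted values
    serve as predictions.
    """
    y3 = blues.values  # (J, I, L)
    J, I, L = y3.shape
    g = grm.align(list(blues.line_ids))
    lam, vec = _eigh_psd(g)

    mask3 = ~np.isfinite(y3)
    if mask3.all():
        raise ValueError("no observed cells")
    rng = np.random.default_rng(mcmc.seed)
    jitter_count = [0]

    # Work in (I, J, L) layout: environment-major cells.
    y = np.transpose(y3, (1, 0, 2)).copy()
    mask = np.transpose(mask3, (1, 0, 2))
    cell_mask = mask.any(axis=2)

    col_means = np.nanmean(np.where(mask, np.nan, y), axis=(0, 1))
    col_means = np.where(np.isfinite(col_means), col_means, 0.0)
    y[mask] = np.broadcast_to(col_means, y.shape)[mask]

    beta = y.mean(axis=1)  # (I, L)
    b1 = np.zeros((J, L))
    b2 = np.zeros((I, J, L))
    sigma_t = np.eye(L)
    sigma_env = np.eye(I)
    r_e = np.eye(L) * max(float(np.nanvar(y3, ddof=1)), 1e-3)

    nu_t, s0_t = L + 2.0, np.eye(L)
    nu_e, s0_e = I + 2.0, np.eye(I)
    nu_r, s0_r = L + 2.0, np.eye(L)

    n_kept = 0
    acc_beta = np.zeros((I, L))
    acc_b1 = np.zeros((J, L))
    acc_b2 = np.zeros((I, J, L))
    acc_st = np.zeros((L, L))
    acc_se = np.zeros((I, I))
    acc_re = np.zeros((L, L))
    acc_st2 = np.zeros((L, L))
    acc_re2 = np.zeros((L, L))
    acc_rg_t = np.zeros((L, L))
    acc_rg_e = np.zeros((I, I))
    acc_fit = np.zeros((I, J, L))

    lam_inv = 1.0 / lam

    for it in range(mcmc.iterations):
        re_inv = np.linalg.inv(r_e)
        st_inv = np.linalg.inv(sigma_t)

        fitted = beta[:, None, :] + b1[None, :, :] + b2

        # --- data augmentation -------------------------------------------
        if cell_mask.any():
            chol_re_aug = np.linalg.cholesky(r_e)
            full_rows = mask.all(axis=2)
            if full_rows.any():
                ii, jj = np.where(full_rows)
                z = rng.standard_normal((len(ii), L))
                y[ii, jj] = fitted[ii, jj] + z @ chol_re_aug.T
            partial = cell_mask & ~full_rows
            for i, j in zip(*np.where(partial)):
                # Conditional normal of masked traits given observed ones.
                m = mask[i, j]
                mu = fitted[i, j]
                mm, oo = m, ~m
                s_oo = r_e[np.ix_(oo, oo)]
                s_mo = r_e[np.ix_(mm, oo)]
                s_mm = r_e[np.ix_(mm, mm)]
                k = s_mo @ np.linalg.inv(s_oo)
                cond_mu = mu[mm] + k @ (y[i, j, oo] - mu[oo])
                cond_cov = s_mm - k @ s_mo.T
                cl = np.linalg.cholesky(cond_cov + 1e-12 * np.eye(int(mm.sum())))
                y[i, j, mm] = cond_mu + cl @ rng.standard_normal(int(mm.sum()))

        # --- beta (flat prior) -------------------------------------------
        resid = y - b1[None, :, :] - b2
        beta = resid.mean(axis=1)
        chol_re = np.linalg.cholesky(r_e)
        beta = beta + (rng.standard_normal((I, L)) @ chol_re.T) / np.sqrt(J)

        # --- b1: genotype x trait ----------------------------------------
        r1 = (y - beta[:, None, :] - b2).sum(axis=0)  # (J, L)
        s_t = vec.T @ r1  # rotated sums
        lin = s_t @ re_inv.T  # (J, L) = Re^-1 r per row
        b1_t = _sample_mvn_rows(rng, lin, re_inv, lam, st_inv, n_rep=float(I))
        b1 = vec @ b1_t

        # --- b2: genotype x environment x trait --------------------------
        theta, u_env = np.linalg.eigh((sigma_env + sigma_env.T) / 2.0)
        theta = np.maximum(theta, 1e-8)
        r2 = y - beta[:, None, :] - b1[None, :, :]  # (I, J, L)
        r2_t = np.einsum("ie,ijl->ejl", u_env, r2)  # U' on the env axis
        r2_t = np.einsum("jk,ejl->ekl", vec, r2_t)  # V' on the line axis
        scales = (theta[:, None] * lam[None, :]).reshape(-1)
        lin2 = (r2_t.reshape(I * J, L)) @ re_inv.T
        b2_t = _sample_mvn_rows(rng, lin2, re_inv, scales, st_inv, n_rep=1.0)
        b2_t = b2_t.reshape(I, J, L)
        b2 = np.einsum("ei,ejl->ijl", u_env.T, b2_t)
        b2 = np.einsum("jk,ikl->ijl", vec, b2)

        # --- Sigma_t ------------------------------------------------------
        b1_t = vec.T @ b1
        quad1 = b1_t.T @ (b1_t * lam_inv[:, None])
        b2_rot = np.einsum("ie,ijl->ejl", u_env, b2)  # U' on env axis
        b2_rot = np.einsum("jk,ejl->ekl", vec, b2_rot)  # V' on line axis
        weights = 1.0 / (theta[:, None] * lam[None, :])
        quad2 = np.einsum("ejl,ej,ejm->lm", b2_rot, weights, b2_rot)
        sigma_t = _invwishart_jittered(rng, nu_t + J + I * J, s0_t + quad1 + quad2, jitter_count)

        # --- Sigma_E ------------------------------------------------------
        st_inv = np.linalg.inv(sigma_t)
        ginv_b2 = np.einsum("jk,ikl->ijl", vec * lam_inv, np.einsum("jk,ijl->ikl", vec, b2))
        w2 = np.einsum("ijl,lm->ijm", ginv_b2, st_inv)
        m_e = np.einsum("ijl,kjl->ik", b2, w2)
        sigma_env = _invwishart_jittered(rng, nu_e + J * L, s0_e + m_e, jitter_count)

        # --- R_e ----------------------------------------------------------
        e = y - beta[:, None, :] - b1[None, :, :] - b2
        e2 = e.reshape(I * J, L)
        r_e = _invwishart_jittered(rng, nu_r + I * J, s0_r + e2.T @ e2, jitter_count)

        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            n_kept += 1
            acc_beta += beta
            acc_b1 += b1
            acc_b2 += b2
            acc_st += sigma_t
            acc_se += sigma_env
            acc_re += r_e
            acc_st2 += sigma_t**2
            acc_re2 += r_e**2
            acc_rg_t += _cov_to_corr(sigma_t)
            acc_rg_e += _cov_to_corr(sigma_env)
            acc_fit += beta[:, None, :] + b1[None, :, :] + b2

    st_mean = acc_st / n_kept
    re_mean = acc_re / n_kept
    return PosteriorSummary(
        beta_mean=acc_beta / n_kept,
        b1_mean=acc_b1 / n_kept,
        b2_mean=acc_b2 / n_kept,
        sigma_t=st_mean,
        sigma_env=acc_se / n_kept,
        r_e=re_mean,
        rg_traits=acc_rg_t / n_kept,
        rg_envs=acc_rg_e / n_kept,
        sigma_t_sd=np.sqrt(np.maximum(acc_st2 / n_kept - st_mean**2, 0.0)),
        r_e_sd=np.sqrt(np.maximum(acc_re2 / n_kept - re_mean**2, 0.0)),
        fitted=np.transpose(acc_fit / n_kept, (1, 0, 2)),
        mask=mask3,
        n_jitter=jitter_count[0],
        line_ids=list(blues.line_ids),
        env_ids=list(blues.env_ids),
        trait_ids=list(blues.trait_ids),
    )


def _cov_to_corr(cov: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.clip(np.diag(cov), 1e-12, None))
    return cov / np.outer(d, d)


def genetic_correlations(ps: PosteriorSummary | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Trait and environment genetic correlation matrices.

    From a :class:`PosteriorSummary` returns the posterior means of the
    per-draw correlations; from a raw covariance matrix returns its
    correlation matrix (and an empty environment matrix).
    """
    if isinstance(ps, PosteriorSummary):
        var_t = np.diag(ps.sigma_t)
        if np.any(var_t <= 1e-10):
            log.warning("near-zero genetic variance: correlation undefined for some traits")
        return ps.rg_traits, ps.rg_envs
    cov = np.asarray(ps, dtype=float)
    return _cov_to_corr(cov), np.empty((0, 0))


# ---------------------------------------------------------------------------
# BMORS


@dataclass
class BmorsFit:
    stage1_fitted: np.ndarray  # (J, I, L)
    scale_mu: np.ndarray  # (L,)
    scale_sd: np.ndarray  # (L,)
    beta_mean: np.ndarray  # (L + 1,) intercept first
    beta_sd: np.ndarray
    predictions: np.ndarray  # (J, I) for the target trait
    mask: np.ndarray  # (J, I)
    target_trait: str
    dropped_traits: list[str] = field(default_factory=list)


def _bayes_ridge(
    rng: np.random.Generator,
    x: np.ndarray,
    y: np.ndarray,
    iterations: int = 2000,
    burn_in: int = 500,
    tau2: float = 1e4,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Small conjugate Gibbs sampler for y = X b + e (nearly flat prior)."""
    n, q = x.shape
    xtx = x.T @ x
    xty = x.T @ y
    var_e = max(float(np.var(y, ddof=1)), 1e-8)
    beta = np.zeros(q)
    acc = np.zeros(q)
    acc2 = np.zeros(q)
    acc_ve = 0.0
    kept = 0
    eye = np.eye(q)
    for it in range(iterations):
        prec = xtx / var_e + eye / tau2
        chol = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, xty / var_e)
        beta = mean + np.linalg.solve(chol.T, rng.standard_normal(q))
        r = y - x @ beta
        var_e = _scaled_inv_chi2(rng, 4.0, 0.5 * float(np.var(y, ddof=1)), float(r @ r), n)
        if it >= burn_in:
            kept += 1
            acc += beta
            acc2 += beta**2
            acc_ve += var_e
    mean = acc / kept
    sd = np.sqrt(np.maximum(acc2 / kept - mean**2, 0.0))
    return mean, sd, acc_ve / kept


def fit_bmors(
    blues: BlueTable,
    grm: GenomicRelationship,
    mcmc: McmcConfig,
    target_trait: str,
    stage1_fits: dict[str, MgblupFit] | None = None,
) -> BmorsFit:
    """Two-stage multi-output regressor stacking for one target trait.

    Stage one fits single-trait MGBLUP for every trait (masked cells
    predicted by augmentation); stage two regresses the target trait on the
    standardized stage-one predictions, with scaling constants estimated on
    training (unmasked) cells only and reused on validation predictions.
    """
    if target_trait not in blues.trait_ids:
        raise ValueError(f"unknown target trait {target_trait!r}")
    L = len(blues.trait_ids)
    J, I, _ = blues.shape
    if stage1_fits is None:
        stage1_fits = {
            t: fit_mgblup(blues, grm, mcmc, trait=t) for t in blues.trait_ids
        }

    fitted = np.stack([stage1_fits[t].fitted for t in blues.trait_ids], axis=2)  # (J, I, L)
    t_idx = blues.trait_ids.index(target_trait)
    target_obs = blues.values[:, :, t_idx]
    train = np.isfinite(target_obs)
    if not train.any():
        raise ValueError("no training cells for the target trait")

    mu = np.zeros(L)
    sd = np.ones(L)
    keep_cols = []
    dropped = []
    for l, t in enumerate(blues.trait_ids):
        vals = fitted[:, :, l][train]
        mu[l] = vals.mean()
        sd[l] = vals.std(ddof=0)
        if sd[l] <= 1e-10:
            dropped.append(t)
            log.warning("stage-1 predictions for %s are constant; dropped from stage 2", t)
        else:
            keep_cols.append(l)
    z = (fitted - mu[None, None, :]) / np.where(sd <= 1e-10, 1.0, sd)[None, None, :]

    x_train = np.column_stack(
        [np.ones(int(train.sum()))] + [z[:, :, l][train] for l in keep_cols]
    )
    y_train = target_obs[train]
    rng = np.random.default_rng(mcmc.seed + 7919)
    beta_mean_k, beta_sd_k, _ = _bayes_ridge(rng, x_train, y_train)

    beta_mean = np.zeros(L + 1)
    beta_sd = np.zeros(L + 1)
    beta_mean[0], beta_sd[0] = beta_mean_k[0], beta_sd_k[0]
    for pos, l in enumerate(keep_cols, start=1):
        beta_mean[l + 1] = beta_mean_k[pos]
        beta_sd[l + 1] = beta_sd_k[pos]

    design_all = np.concatenate(
        [np.ones((J, I, 1)), z[:, :, keep_cols]], axis=2
    )
    preds = design_all @ beta_mean_k

    return BmorsFit(
        stage1_fitted=fitted,
        scale_mu=mu,
        scale_sd=sd,
        beta_mean=beta_mean,
        beta_sd=beta_sd,
        predictions=preds,
        mask=~train,
        target_trait=target_trait,
        dropped_traits=dropped,
    )


def bmors_predict_all(
    blues: BlueTable,
    grm: GenomicRelationship,
    mcmc: McmcConfig,
) -> np.ndarray:
    """BMORS predictions for every trait, sharing the stage-one fits."""
    stage1 = {t: fit_mgblup(blues, grm, mcmc, trait=t) for t in blues.trait_ids}
    out = np.empty_like(blues.values)
    for t_i, t in enumerate(blues.trait_ids):
        fit = fit_bmors(blues, grm, mcmc, target_trait=t, stage1_fits=stage1)
        out[:, :, t_i] = fit.predictions
    return out


def leave_one_env_out_bmors(
    blues: BlueTable,
    grm: GenomicRelationship,
    mcmc: McmcConfig,
) -> dict[str, np.ndarray]:
    """Predict each environment from the remaining ones with BMORS.

    For every environment, all its trait cells are masked, the model is
    trained on the other environments, and the (lines x traits) predictions
    for the held-out environment are returned.
    """
    I = len(blues.env_ids)
    if I < 2:
        raise ValueError("leave-one-environment-out requires at least 2 environments")
    out: dict[str, np.ndarray] = {}
    for i, env in enumerate(blues.env_ids):
        masked = blues.copy()
        masked.values[:, i, :] = np.nan
        preds = bmors_predict_all(masked, grm, mcmc)
        out[env] = preds[:, i, :]
    return out
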