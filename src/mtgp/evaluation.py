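"""Model evaluation: population structure, cross-validation, accuracy, RTS.

Population structure is summarized DAPC-style: principal components of the
standardized marker matrix (retaining a configurable variance fraction),
k-means to propose k groups, then linear discriminant functions that yield
posterior membership probabilities.  Cross-validation masks whole lines
(by default in every environment simultaneously) and scores each model by
the Pearson correlation of observed and predicted values per environment
and trait.  Predictive ability ``rp`` converts to accuracy through the
square root of broad-sense heritability, and response to selection follows
the breeder's equation ``R = H^2 S`` with the selection differential ``S``
taken over the top fraction of lines ranked by GEBV.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .containers import BlueTable, GenomicRelationship, MarkerMatrix

log = logging.getLogger("mtgp")


# ---------------------------------------------------------------------------
# DAPC-style clustering


@dataclass
class ClusterModel:
    assignments: np.ndarray  # (n,) cluster index per line
    posteriors: np.ndarray  # (n, k) membership probabilities
    n_components: int
    explained_variance: float
    line_ids: list[str]

    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.posteriors.shape[1])


def cluster_panel(
    markers: MarkerMatrix,
    k: int = 10,
    var_fraction: float = 0.9,
    seed: int = 0,
) -> ClusterModel:
    """Discriminant analysis of principal components on the marker matrix.

    PCA on the standardized dosages retains the smallest number of
    components explaining ``var_fraction`` of the variance; k-means proposes
    ``k`` groups on the retained scores; linear discriminant functions then
    give posterior membership probabilities, and each line is assigned to
    its maximum-posterior group.
    """
    if k > markers.n_lines:
        raise ValueError("k cannot exceed the number of lines")
    x = markers.values.astype(float)
    miss = markers.missing_mask()
    if miss.any():
        x[miss] = np.nan
        mu = np.nanmean(x, axis=0)
        idx = np.where(miss)
        x[idx] = mu[idx[1]]
    x -= x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    x /= sd

    max_pc = min(markers.n_lines - 1, markers.n_markers)
    pca = PCA(n_components=max_pc, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(x)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_pc = int(np.searchsorted(cum, var_fraction) + 1)
    n_pc = min(max(n_pc, 2), max_pc)
    scores = scores[:, :n_pc]

    if n_pc < k - 1:
        log.warning(
            "only %d informative components for %d clusters; discriminants truncated",
            n_pc,
            k,
        )

    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(scores)

    lda = LinearDiscriminantAnalysis()
    lda.fit(scores, labels)
    posteriors = lda.predict_proba(scores)
    assignments = np.argmax(posteriors, axis=1)
    return ClusterModel(
        assignments=assignments,
        posteriors=posteriors,
        n_components=n_pc,
        explained_variance=float(cum[n_pc - 1]),
        line_ids=list(markers.line_ids),
    )


# ---------------------------------------------------------------------------
# Fold construction


@dataclass
class FoldAssignment:
    folds: np.ndarray  # (n,) fold index in 0..f-1
    n_folds: int
    scheme: str
    seed: int
    line_ids: list[str]

    def validation_lines(self, fold: int) -> list[str]:
        return [l for l, f in zip(self.line_ids, self.folds) if f == fold]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"line": self.line_ids, "fold": self.folds + 1, "scheme": self.scheme})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FoldAssignment":
        return cls(
            folds=df["fold"].to_numpy(int) - 1,
            n_folds=int(df["fold"].max()),
            scheme=str(df["scheme"].iloc[0]) if "scheme" in df else "imported",
            seed=-1,
            line_ids=list(df["line"]),
        )


def make_folds(
    line_ids: list[str],
    f: int = 5,
    scheme: str = "random",
    clusters: np.ndarray | None = None,
    seed: int = 0,
) -> FoldAssignment:
    """Partition lines into f folds, optionally stratified by cluster.

    Both schemes assign shuffled lines round-robin to folds, which
    guarantees overall fold sizes differing by at most one; the stratified
    scheme walks cluster by cluster with a single continuing round-robin
    pointer, so within-cluster fold counts also differ by at most one.
    """
    n = len(line_ids)
    if f > n:
        raise ValueError("more folds than lines")
    if scheme not in ("random", "stratified"):
        raise ValueError("scheme must be 'random' or 'stratified'")
    if scheme == "stratified" and clusters is None:
        raise ValueError("stratified folds require cluster labels")

    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    if scheme == "random":
        order = rng.permutation(n)
        folds[order] = np.arange(n) % f
    else:
        clusters = np.asarray(clusters)
        if len(clusters) != n:
            raise ValueError("cluster labels must match lines")
        pointer = int(rng.integers(0, f))
        for c in np.unique(clusters):
            members = np.where(clusters == c)[0]
            members = rng.permutation(members)
            for m in members:
                folds[m] = pointer % f
                pointer += 1
    return FoldAssignment(folds, f, scheme, seed, list(line_ids))


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class CvResult:
    rp: np.ndarray  # (f, n_envs, n_traits) per-fold predictive correlations
    env_ids: list[str]
    trait_ids: list[str]
    predictions: np.ndarray  # (n_lines, n_envs, n_traits) out-of-fold predictions
    flags: list[str] = field(default_factory=list)

    def mean_rp(self) -> np.ndarray:
        return np.nanmean(self.rp, axis=0)


def cross_validate(
    predict_fn,
    blues: BlueTable,
    grm: GenomicRelationship,
    folds: FoldAssignment,
    mask_all_envs: bool = True,
) -> CvResult:
    """Masked-line cross-validation of a cell-predicting model.

    ``predict_fn(masked_blues, grm) -> (n_lines, n_envs, n_traits)`` must
    return predictions for every cell without reading masked values.  With
    ``mask_all_envs`` each validation line is hidden in every environment at
    once; otherwise environments are masked (and predicted) one at a time.
    """
    J, I, L = blues.shape
    rp = np.full((folds.n_folds, I, L), np.nan)
    preds_all = np.full((J, I, L), np.nan)
    flags: list[str] = []
    line_pos = {l: i for i, l in enumerate(blues.line_ids)}

    for fold in range(folds.n_folds):
        val_lines = folds.validation_lines(fold)
        val_idx = np.array([line_pos[l] for l in val_lines])
        if mask_all_envs:
            masked = blues.copy()
            masked.values[val_idx, :, :] = np.nan
            preds = predict_fn(masked, grm)
            preds_all[val_idx] = preds[val_idx]
            rp[fold] = _fold_correlations(blues.values, preds, val_idx, flags, fold)
        else:
            for i in range(I):
                masked = blues.copy()
                masked.values[val_idx, i, :] = np.nan
                preds = predict_fn(masked, grm)
                preds_all[val_idx, i, :] = preds[val_idx, i, :]
                rp[fold, i, :] = _fold_correlations(
                    blues.values[:, [i], :], preds[:, [i], :], val_idx, flags, fold
                )[0]
    return CvResult(rp, list(blues.env_ids), list(blues.trait_ids), preds_all, flags)


def _fold_correlations(obs3, pred3, val_idx, flags, fold) -> np.ndarray:
    _, I, L = obs3.shape
    out = np.full((I, L), np.nan)
    for i in range(I):
        for l in range(L):
            obs = obs3[val_idx, i, l]
            pred = pred3[val_idx, i, l]
            ok = np.isfinite(obs) & np.isfinite(pred)
            if ok.sum() < 3:
                flags.append(f"fold {fold}: <3 validation lines in env {i}, trait {l}")
                continue
            if np.std(obs[ok]) == 0 or np.std(pred[ok]) == 0:
                flags.append(f"fold {fold}: constant values in env {i}, trait {l}")
                continue
            out[i, l] = np.corrcoef(obs[ok], pred[ok])[0, 1]
    return out


# ---------------------------------------------------------------------------
# Accuracy and response to selection


def prediction_accuracy(rp_folds: np.ndarray, h2: float) -> tuple[float, float]:
    """Accuracy = mean(rp)/sqrt(H2); SE = sd(rp)/(sqrt(f) sqrt(H2)).

    Values can exceed 1 and are reported as computed.
    """
    rp_folds = np.asarray(rp_folds, dtype=float)
    rp_folds = rp_folds[np.isfinite(rp_folds)]
    if h2 <= 0:
        raise ValueError("accuracy is undefined for H2 <= 0")
    if len(rp_folds) < 2:
        raise ValueError("need at least two folds")
    f = len(rp_folds)
    acc = float(np.mean(rp_folds) / math.sqrt(h2))
    se = float(np.std(rp_folds, ddof=1) / (math.sqrt(f) * math.sqrt(h2)))
    return acc, se


@dataclass
class SelectionResult:
    response: float  # R = H2 * S
    differential: float  # S
    selected: list[str]
    intensity: float


def response_to_selection(
    gebv: np.ndarray,
    phenotype: np.ndarray,
    h2: float,
    intensity: float = 0.10,
    line_ids: list[str] | None = None,
) -> SelectionResult:
    """Breeder's-equation response from truncation selection on GEBV.

    Lines are ranked by GEBV (descending; ties broken by line ID for
    reproducibility), the top ``ceil(intensity * n)`` are selected, the
    selection differential is the phenotype mean of the selected minus the
    population mean, and ``R = H2 * S``.
    """
    gebv = np.asarray(gebv, dtype=float)
    phenotype = np.asarray(phenotype, dtype=float)
    if gebv.shape != phenotype.shape:
        raise ValueError("gebv and phenotype must align")
    if not 0.0 < intensity < 1.0:
        raise ValueError("intensity must lie in (0, 1)")
    n = len(gebv)
    ids = line_ids if line_ids is not None else [f"L{i:04d}" for i in range(n)]
    ok = np.isfinite(gebv) & np.isfinite(phenotype)
    gebv, phenotype = gebv[ok], phenotype[ok]
    ids = [i for i, o in zip(ids, ok) if o]
    n = len(gebv)
    n_sel = max(1, math.ceil(intensity * n))
    order = sorted(range(n), key=lambda i: (-gebv[i], ids[i]))
    sel = order[:n_sel]
    s = float(phenotype[sel].mean() - phenotype.mean())
    return SelectionResult(
        response=h2 * s, differential=s, selected=[ids[i] for i in sel], intensity=intensity
    )


def rts_standard_error(r_folds: np.ndarray) -> float:
    """SE of response to selection across folds: sd(R)/sqrt(f)."""
    r_folds = np.asarray(r_folds, dtype=float)
    r_folds = r_folds[np.isfinite(r_folds)]
    return float(np.std(r_folds, ddof=1) / math.sqrt(len(r_folds)))


def build_report(
    entries: list[dict],
) -> pd.DataFrame:
    """Tidy evaluation report: model, env, trait, scheme, rp, accuracy, ..."""
    cols = ["model", "env", "trait", "scheme", "rp", "accuracy", "se", "s", "r", "se_r"]
    df = pd.DataFrame(entries)
    return df.reindex(columns=[c for c in cols if c in df.columns] +
                      [c for c in df.columns if c not in cols])
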