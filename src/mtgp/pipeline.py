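"""End-to-end workflow: QC -> BLUEs/H2 -> folds -> model fits -> report.

The pipeline consumes a :class:`RunConfig`, executes the stages in order,
persists each stage's outputs under the configured directory, and writes a
manifest (config hash, stage seeds, package versions) sufficient to
re-execute the run bit-identically on one thread.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, bayes_models, evaluation, genoqc, io, neural_models, phenomodel
from .containers import BlueTable
from .simdata import SimConfig, simulate_panel

log = logging.getLogger("mtgp")

KNOWN_MODELS = ("MGBLUP", "BMTME", "BMORS", "SMDL", "MMDL")


@dataclass
class RunConfig:
    """Full configuration of one pipeline run."""

    output_dir: str = "mtgp_run"
    phenotype_path: str | None = None
    genotype_path: str | None = None
    simulate: dict = field(default_factory=dict)  # SimConfig overrides; used when no paths
    # QC thresholds
    max_marker_missing: float = 0.5
    min_maf: float = 0.05
    max_het: float = 0.10
    max_line_missing: float = 0.85
    # models and MCMC
    models: list[str] = field(default_factory=lambda: ["MGBLUP", "BMTME", "BMORS"])
    mcmc_iterations: int = 15000
    mcmc_burn_in: int = 10000
    mcmc_thin: int = 1
    # cross-validation
    cv_folds: int = 5
    cv_scheme: str = "random"  # or "stratified"
    n_clusters: int = 10
    mask_all_envs: bool = True
    # neural settings
    net_neurons: int = 35
    net_epochs: int = 40
    # evaluation
    selection_intensity: float = 0.10
    adjust_dth: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = [m for m in self.models if m not in KNOWN_MODELS]
        if unknown:
            raise ValueError(f"unknown models {unknown}; choose from {KNOWN_MODELS}")
        if self.cv_scheme not in ("random", "stratified"):
            raise ValueError("cv_scheme must be 'random' or 'stratified'")
        for name in ("max_marker_missing", "min_maf", "max_het", "max_line_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.selection_intensity < 1.0:
            raise ValueError("selection_intensity must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_seed(root: int, stage: str) -> int:
    """Derive a deterministic 31-bit stage seed from the root seed."""
    h = hashlib.sha256(f"{root}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _make_predictor(model: str, cfg: RunConfig, markers_std: np.ndarray, seed: int):
    """Wrap a model as predict_fn(masked_blues, grm) -> (J, I, L) array."""
    mcmc = bayes_models.McmcConfig(cfg.mcmc_iterations, cfg.mcmc_burn_in, cfg.mcmc_thin, seed)

    if model == "MGBLUP":
        def predict(masked: BlueTable, grm):
            out = np.empty_like(masked.values)
            for t_i, t in enumerate(masked.trait_ids):
                out[:, :, t_i] = bayes_models.fit_mgblup(masked, grm, mcmc, trait=t).fitted
            return out
        return predict

    if model == "BMTME":
        def predict(masked: BlueTable, grm):
            return bayes_models.fit_bmtme(masked, grm, mcmc).fitted
        return predict

    if model == "BMORS":
        def predict(masked: BlueTable, grm):
            return bayes_models.bmors_predict_all(masked, grm, mcmc)
        return predict

    # Neural models: markers + one-hot environment indicators as input.
    multi = model == "MMDL"

    def predict(masked: BlueTable, grm):
        J, I, L = masked.shape
        env_onehot = np.eye(I)
        x_cells = np.concatenate(
            [np.repeat(markers_std, I, axis=0), np.tile(env_onehot, (J, 1))], axis=1
        )
        y_cells = masked.values.reshape(J * I, L)
        out = np.full((J * I, L), np.nan)
        spec = neural_models.NetSpec(
            neurons_per_layer=cfg.net_neurons, epochs=cfg.net_epochs, seed=seed
        )
        if multi:
            train = np.isfinite(y_cells).all(axis=1)
            preds = neural_models.train_network(
                x_cells[train], y_cells[train], x_cells, spec
            )
            out[:] = preds
        else:
            for l in range(L):
                train = np.isfinite(y_cells[:, l])
                preds = neural_models.train_network(
                    x_cells[train], y_cells[train, l], x_cells, spec
                )
                out[:, l] = preds[:, 0]
        return out.reshape(J, I, L)

    return predict


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages and return the artifact directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stage_seeds": {},
        "stages": [],
    }
    t_start = time.time()

    def stage(name: str):
        seed = _stage_seed(config.seed, name)
        manifest["stage_seeds"][name] = seed
        manifest["stages"].append(name)
        log.info("stage %s (seed %d)", name, seed)
        return seed

    try:
        # ------------------------------------------------------------ data
        seed = stage("data")
        if config.phenotype_path and config.genotype_path:
            records = io.read_phenotypes(config.phenotype_path)
            markers = io.read_genotypes(config.genotype_path)
            truth = None
        else:
            sim = SimConfig(**{**config.simulate, "seed": seed})
            markers, records, truth = simulate_panel(sim)
            io.write_genotypes(markers, out / "genotypes.tsv")
            io.write_phenotypes(records, out / "phenotypes.csv")

        # -------------------------------------------------------------- qc
        stage("qc")
        markers_f, report = genoqc.filter_markers(
            markers,
            max_marker_missing=config.max_marker_missing,
            min_maf=config.min_maf,
            max_het=config.max_het,
            max_line_missing=config.max_line_missing,
        )
        report.to_frame().to_csv(out / "qc_report.csv", index=False)
        imputed = genoqc.impute_missing(markers_f)
        grm = genoqc.build_grm(imputed)

        # ---------------------------------------------------- blues and h2
        stage("blues")
        traits = [c for c in records.columns if c not in phenomodel.REQUIRED_COLUMNS]
        blues = phenomodel.fit_blues(records, traits=traits, adjust_dth=config.adjust_dth)
        blues.to_long().to_csv(out / "blues.csv", index=False)
        h2_table = phenomodel.heritability_table(records, traits, adjust_dth=config.adjust_dth)
        h2_table.to_csv(out / "heritability.csv", index=False)

        # keep only genotyped lines (QC may have dropped some)
        keep = [l for l in blues.line_ids if l in set(grm.line_ids)]
        idx = [blues.line_ids.index(l) for l in keep]
        blues = BlueTable(
            blues.values[idx], keep, blues.env_ids, blues.trait_ids,
            None if blues.se is None else blues.se[idx],
        )

        # ------------------------------------------------------------ folds
        seed = stage("folds")
        clusters = None
        if config.cv_scheme == "stratified":
            model = evaluation.cluster_panel(imputed, k=config.n_clusters, seed=seed)
            order = {l: i for i, l in enumerate(model.line_ids)}
            clusters = np.array([model.assignments[order[l]] for l in blues.line_ids])
        folds = evaluation.make_folds(
            blues.line_ids, f=config.cv_folds, scheme=config.cv_scheme,
            clusters=clusters, seed=seed,
        )
        folds.to_frame().to_csv(out / "folds.csv", index=False)

        # ------------------------------------------------- model fits + CV
        markers_std = _standardized_for_nets(imputed, blues.line_ids)
        h2_lookup = {
            (r["env"], r["trait"]): r["h2"] for _, r in h2_table.iterrows()
        }
        entries = []
        for model_name in config.models:
            seed = stage(f"cv_{model_name}")
            predict_fn = _make_predictor(model_name, config, markers_std, seed)
            cv = evaluation.cross_validate(
                predict_fn, blues, grm, folds, mask_all_envs=config.mask_all_envs
            )
            for i, env in enumerate(blues.env_ids):
                for l, trait in enumerate(blues.trait_ids):
                    rp = cv.rp[:, i, l]
                    h2 = h2_lookup.get((env, trait), np.nan)
                    acc = se = np.nan
                    if np.isfinite(h2) and h2 > 0 and np.isfinite(rp).sum() >= 2:
                        acc, se = evaluation.prediction_accuracy(rp, h2)
                    r_folds, s_folds = [], []
                    for fold in range(folds.n_folds):
                        val = folds.validation_lines(fold)
                        vi = [blues.line_ids.index(x) for x in val]
                        sel = evaluation.response_to_selection(
                            cv.predictions[vi, i, l],
                            blues.values[vi, i, l],
                            h2 if np.isfinite(h2) else 0.0,
                            intensity=config.selection_intensity,
                            line_ids=val,
                        )
                        r_folds.append(sel.response)
                        s_folds.append(sel.differential)
                    entries.append({
                        "model": model_name, "env": env, "trait": trait,
                        "scheme": config.cv_scheme,
                        "rp": float(np.nanmean(rp)), "accuracy": acc, "se": se,
                        "s": float(np.nanmean(s_folds)), "r": float(np.nanmean(r_folds)),
                        "se_r": evaluation.rts_standard_error(np.array(r_folds)),
                    })

        stage("report")
        report_df = evaluation.build_report(entries)
        report_df.to_csv(out / "evaluation_report.csv", index=False)
        manifest["runtime_seconds"] = round(time.time() - t_start, 2)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return out
    except Exception as exc:
        failed = manifest["stages"][-1] if manifest["stages"] else "init"
        manifest["failed_stage"] = failed
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {exc}") from exc


def _standardized_for_nets(markers, line_ids: list[str]) -> np.ndarray:
    pos = {l: i for i, l in enumerate(markers.line_ids)}
    x = markers.values.astype(float)[[pos[l] for l in line_ids]]
    x -= x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return x / sd
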