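"""Shared fixtures: small structured panels generated at test time."""

import numpy as np
import pytest

from mtgp import genoqc
from mtgp.containers import BlueTable
from mtgp.simdata import SimConfig, simulate_marker_matrix, simulate_panel


@pytest.fixture(scope="session")
def structured_panel():
    """200-line, 10-subpopulation marker panel with a strong GRM."""
    cfg = SimConfig(
        n_lines=200, n_checks=0, n_markers=1100, n_subpops=10, fst=0.3,
        het_rate=0.0, missing_rate=0.0, seed=7,
    )
    markers, labels = simulate_marker_matrix(cfg)
    filtered, _ = genoqc.filter_markers(markers)
    grm = genoqc.build_grm(filtered)
    return {"markers": filtered, "labels": labels, "grm": grm, "config": cfg}


@pytest.fixture(scope="session")
def small_panel():
    """Complete small panel with phenotypes and truth (augmented design)."""
    cfg = SimConfig(
        n_lines=80, n_checks=3, n_markers=500, n_subpops=5, n_blocks=4, seed=2,
    )
    markers, records, truth = simulate_panel(cfg)
    return {"markers": markers, "records": records, "truth": truth, "config": cfg}


def planted_gblup_data(grm, n_traits=1, h2=0.5, seed=0, trait_corr=None):
    """Genetic values drawn from the GRM plus calibrated residual noise."""
    rng = np.random.default_rng(seed)
    n = grm.n_lines
    chol = np.linalg.cholesky(grm.matrix + 1e-8 * np.eye(n))
    if trait_corr is None:
        trait_corr = np.eye(n_traits)
    g = chol @ rng.standard_normal((n, n_traits)) @ np.linalg.cholesky(trait_corr).T
    v_g = g.var(axis=0, ddof=1)
    e_sd = np.sqrt(v_g * (1 - h2) / h2)
    y = g + rng.standard_normal((n, n_traits)) * e_sd
    return g, y


def as_blue_table(y, line_ids, env_ids=None, trait_ids=None):
    """Wrap a (lines x envs [x traits]) array as a BlueTable."""
    y = np.asarray(y, dtype=float)
    if y.ndim == 2:
        y = y[:, :, None]
    env_ids = env_ids or [f"E{i + 1}" for i in range(y.shape[1])]
    trait_ids = trait_ids or [f"T{i + 1}" for i in range(y.shape[2])]
    return BlueTable(y, list(line_ids), env_ids, trait_ids)
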