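"""Feed-forward network models (SMDL/MMDL) and the response-surface search.

The networks are densely connected with three hidden layers of equal width,
rectified-linear activations, inverted dropout (rate 0.25) after each hidden
layer, and linear outputs: one output neuron for the single-trait model
(SMDL), one per trait for the multi-trait model (MMDL).  Training minimizes
mean squared error (summed over outputs for MMDL) with the Adam optimizer
on mini-batches; responses are standardized per trait before training and
predictions are mapped back to the original scale.  All randomness flows
from the NetSpec seed, so training is reproducible on a single thread.

Hyperparameters (number of neurons and number of epochs) are tuned by a
full-factorial response-surface search: every (neurons, epochs) grid cell is
scored by cross-validated predictive correlation, and a quadratic-plateau
curve in the number of neurons is fitted at each epoch level to locate the
optimum, the standard agronomic join-point model
``y = a + b x + c x^2`` for ``x <= x0`` and constant beyond ``x0 = -b/2c``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

log = logging.getLogger("mtgp")


@dataclass
class NetSpec:
    """Architecture and training settings for the dense network."""

    neurons_per_layer: int = 35
    epochs: int = 40
    n_hidden_layers: int = 3
    dropout_rate: float = 0.25
    n_outputs: int = 1
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.neurons_per_layer <= 0 or self.epochs <= 0:
            raise ValueError("neurons and epochs must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.n_outputs < 1 or self.n_hidden_layers < 1:
            raise ValueError("need at least one output and one hidden layer")


class DenseNetwork:
    """Minimal dense ReLU network with inverted dropout and Adam."""

    def __init__(self, n_inputs: int, spec: NetSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        sizes = [n_inputs] + [spec.neurons_per_layer] * spec.n_hidden_layers + [spec.n_outputs]
        self.weights = [
            rng.standard_normal((a, b)) * np.sqrt(2.0 / a) for a, b in zip(sizes[:-1], sizes[1:])
        ]
        self.biases = [np.zeros(b) for b in sizes[1:]]
        self._rng = rng
        self._adam_m = [np.zeros_like(w) for w in self.weights + self.biases]
        self._adam_v = [np.zeros_like(w) for w in self.weights + self.biases]
        self._adam_t = 0

    def _forward(self, x: np.ndarray, train: bool) -> tuple[np.ndarray, list, list]:
        acts, masks = [x], []
        h = x
        n_layers = len(self.weights)
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if i < n_layers - 1:
                h = np.maximum(h, 0.0)
                if train and self.spec.dropout_rate > 0:
                    keep = 1.0 - self.spec.dropout_rate
                    m = (self._rng.random(h.shape) < keep) / keep
                    h = h * m
                    masks.append(m)
                else:
                    masks.append(None)
            acts.append(h)
        return h, acts, masks

    def _adam_step(self, grads: list[np.ndarray]) -> None:
        self._adam_t += 1
        lr, b1, b2, eps = self.spec.learning_rate, 0.9, 0.999, 1e-8
        params = self.weights + self.biases
        for p, g, m, v in zip(params, grads, self._adam_m, self._adam_v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self._adam_t)
            vhat = v / (1 - b2**self._adam_t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    def fit(self, x: np.ndarray, y: np.ndarray) -> None:
        y = y.reshape(len(y), -1)
        n = len(x)
        bs = min(self.spec.batch_size, n)
        for _ in range(self.spec.epochs):
            order = self._rng.permutation(n)
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                self._train_batch(x[idx], y[idx])

    def _train_batch(self, xb: np.ndarray, yb: np.ndarray) -> None:
        out, acts, masks = self._forward(xb, train=True)
        if not np.all(np.isfinite(out)):
            raise FloatingPointError(
                "training diverged (non-finite activations); "
                "reduce the learning rate or standardize the inputs"
            )
        m = len(xb)
        delta = 2.0 * (out - yb) / m  # d(MSE)/d(out), summed over outputs
        grads_w = [np.zeros_like(w) for w in self.weights]
        grads_b = [np.zeros_like(b) for b in self.biases]
        for i in range(len(self.weights) - 1, -1, -1):
            a_prev = acts[i]
            grads_w[i] = a_prev.T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.weights[i].T
                hidden = acts[i]
                delta = delta * (hidden > 0)
                if masks[i - 1] is not None:
                    delta = delta * masks[i - 1]
        self._adam_step(grads_w + grads_b)

    def predict(self, x: np.ndarray) -> np.ndarray:
        out, _, _ = self._forward(x, train=False)
        return out


def train_network(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    spec: NetSpec,
) -> np.ndarray:
    """Train the dense network and predict the held-out rows.

    Inputs (markers plus any environment indicators) are standardized on
    the training set; responses are standardized per trait and predictions
    de-standardized, so the procedure is invariant to affine changes of the
    response scale.
    """
    x_train = np.asarray(x_train, dtype=float)
    x_test = np.asarray(x_test, dtype=float)
    y_train = np.asarray(y_train, dtype=float).reshape(len(x_train), -1)
    if not (np.all(np.isfinite(x_train)) and np.all(np.isfinite(y_train))):
        raise ValueError("inputs and responses must be complete (no NaN)")

    mu_x = x_train.mean(axis=0)
    sd_x = x_train.std(axis=0)
    sd_x[sd_x == 0] = 1.0
    xs_train = (x_train - mu_x) / sd_x
    xs_test = (x_test - mu_x) / sd_x

    mu_y = y_train.mean(axis=0)
    sd_y = y_train.std(axis=0)
    sd_y[sd_y == 0] = 1.0
    ys = (y_train - mu_y) / sd_y

    spec = NetSpec(**{**vars(spec), "n_outputs": y_train.shape[1]})
    net = DenseNetwork(xs_train.shape[1], spec)
    net.fit(xs_train, ys)
    preds = net.predict(xs_test)
    return preds * sd_y + mu_y


# ---------------------------------------------------------------------------
# Quadratic-plateau fit


@dataclass
class PlateauFit:
    intercept: float
    slope: float
    curvature: float
    join: float
    plateau_value: float
    rss: float
    flag: str = ""  # "", "no_plateau", "join_at_boundary", "flat"


def _plateau_curve(x: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    x0 = -b / (2.0 * c)
    return np.where(x <= x0, a + b * x + c * x**2, a + b * x0 + c * x0**2)


def fit_quadratic_plateau(x: np.ndarray, y: np.ndarray) -> PlateauFit:
    """Least-squares quadratic-plateau fit with continuity and smoothness.

    The curve rises as ``a + b x + c x^2`` (c < 0) and is constant past the
    join point ``x0 = -b/(2c)``.  Optimization restarts from a grid of
    candidate join points; degenerate fits (non-negative curvature, or a
    join outside the searched range) are flagged and fall back to the
    argmax of the observed values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4 or len(np.unique(x)) < 3:
        raise ValueError("need at least 4 points with 3 distinct x values")

    if np.ptp(y) == 0.0:
        return PlateauFit(float(y[0]), 0.0, 0.0, float(x.min()), float(y[0]), 0.0, flag="flat")

    def residuals(params: np.ndarray) -> np.ndarray:
        a, b, c = params
        if c >= -1e-12:
            return y - (a + b * x + c * x**2)
        return y - _plateau_curve(x, a, b, c)

    # Starts: plain quadratic OLS plus a sweep of candidate join points.
    starts = []
    coef = np.polyfit(x, y, 2)
    starts.append(np.array([coef[2], coef[1], min(coef[0], -1e-6)]))
    for x0 in np.linspace(x.min() + 1e-3, x.max() * 1.5, 8):
        ymax = y.max()
        c0 = -(ymax - y.min()) / max(x0**2, 1e-6)
        starts.append(np.array([y.min(), -2.0 * c0 * x0, c0]))

    best = None
    for s in starts:
        try:
            res = optimize.least_squares(residuals, s, method="lm", max_nfev=2000)
        except Exception:  # pragma: no cover - defensive
            continue
        if best is None or res.cost < best.cost:
            best = res
    a, b, c = best.x
    rss = float(2.0 * best.cost)

    if c >= -1e-10 or b <= 0:
        j = int(np.argmax(y))
        return PlateauFit(a, float(b), float(c), float(x[j]), float(y[j]), rss, flag="no_plateau")
    x0 = -b / (2.0 * c)
    plateau = a + b * x0 + c * x0**2
    flag = ""
    if x0 > x.max() or x0 < x.min():
        flag = "join_at_boundary"
        x0 = float(np.clip(x0, x.min(), x.max()))
        plateau = a + b * x0 + c * x0**2
    return PlateauFit(float(a), float(b), float(c), float(x0), float(plateau), rss, flag=flag)


# ---------------------------------------------------------------------------
# Response-surface search


@dataclass
class SurfaceSearchResult:
    grid: np.ndarray  # (n_cells, 3): neurons, epochs, mean CV correlation
    plateau_fits: dict[int, PlateauFit]  # per epoch level
    best_neurons: int
    best_epochs: int
    best_score: float
    fallback: bool = False

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.grid, columns=["neurons", "epochs", "cv_correlation"])


def surface_search(
    x: np.ndarray,
    y: np.ndarray,
    spec: NetSpec | None = None,
    neuron_grid: tuple[int, ...] = tuple(range(5, 75, 5)),
    epoch_grid: tuple[int, ...] = tuple(range(10, 90, 10)),
    n_folds: int = 5,
    seed: int = 0,
) -> SurfaceSearchResult:
    """Full-factorial (neurons x epochs) search scored by CV correlation.

    Every combination is evaluated by ``n_folds``-fold cross-validated
    Pearson correlation (averaged over folds and outputs); a quadratic-
    plateau curve in neurons is fitted at each epoch level, and the optimum
    is the epoch level with the highest plateau together with its join
    point rounded to the nearest searched neuron count.
    """
    if len(neuron_grid) == 0 or len(epoch_grid) == 0:
        raise ValueError("grids must be nonempty")
    base = spec or NetSpec()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).reshape(len(x), -1)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(x))
    folds = np.array_split(order, n_folds)

    rows = []
    for epochs in epoch_grid:
        for neurons in neuron_grid:
            cors = []
            for f, val_idx in enumerate(folds):
                train_idx = np.setdiff1d(order, val_idx, assume_unique=False)
                s = NetSpec(
                    **{
                        **vars(base),
                        "neurons_per_layer": int(neurons),
                        "epochs": int(epochs),
                        "seed": base.seed + f,
                    }
                )
                preds = train_network(x[train_idx], y[train_idx], x[val_idx], s)
                for out in range(y.shape[1]):
                    obs = y[val_idx, out]
                    if np.std(preds[:, out]) > 0 and np.std(obs) > 0:
                        cors.append(np.corrcoef(obs, preds[:, out])[0, 1])
                    else:
                        cors.append(0.0)
            rows.append((neurons, epochs, float(np.mean(cors))))
    grid = np.array(rows, dtype=float)

    can_fit = len(np.unique(neuron_grid)) >= 3 and len(neuron_grid) >= 4
    plateau_fits: dict[int, PlateauFit] = {}
    fallback = not can_fit
    if can_fit:
        for epochs in epoch_grid:
            sel = grid[:, 1] == epochs
            plateau_fits[int(epochs)] = fit_quadratic_plateau(grid[sel, 0], grid[sel, 2])
        best_epochs = max(plateau_fits, key=lambda e: plateau_fits[e].plateau_value)
        fit = plateau_fits[best_epochs]
        best_neurons = int(min(neuron_grid, key=lambda n: abs(n - fit.join)))
        best_score = fit.plateau_value
    else:
        log.warning("fewer than 3 neuron levels: falling back to grid argmax")
        k = int(np.argmax(grid[:, 2]))
        best_neurons, best_epochs, best_score = int(grid[k, 0]), int(grid[k, 1]), grid[k, 2]

    return SurfaceSearchResult(
        grid=grid,
        plateau_fits=plateau_fits,
        best_neurons=best_neurons,
        best_epochs=int(best_epochs),
        best_score=float(best_score),
        fallback=fallback,
    )
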