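"""From-scratch multilayer perceptron for expression regression.

The network family the search explores: logistic (sigmoid) hidden layers,
a single linear output unit, trained to minimize mean squared error. Two
trainers are provided — mini-batch RMSprop (used during the evolutionary
search) and full-batch Rprop+ (resilient backpropagation with weight
backtracking, used for the final predictive model). Regularization is
early stopping on a validation split plus dropout applied only between the
last hidden layer and the output (inverted scaling at train time).

Everything is plain NumPy; gradients are exact backpropagation and are
checked against finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

WORST_FITNESS = 1e9  # sentinel for infeasible phenotypes


def sigmoid(t: np.ndarray) -> np.ndarray:
    """Standard logistic 1/(1+e^{-t}), computed stably for large |t|."""
    out = np.empty_like(t, dtype=float)
    pos = t >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
    e = np.exp(t[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def logistic(x, L: float = 1.0, k: float = 1.0, x0: float = 0.0):
    """General logistic L/(1+e^{-k(x-x0)})."""
    return L * sigmoid(k * (np.asarray(x, float) - x0))


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MLPModel:
    """Feed-forward net: ``layer_sizes = [n_inputs, hidden..., n_outputs]``.

    ``weights[l]`` has shape (layer_sizes[l], layer_sizes[l+1]);
    ``biases[l]`` has shape (layer_sizes[l+1],). Hidden layers are logistic,
    the output is affine.
    """

    layer_sizes: tuple
    weights: tuple
    biases: tuple
    init_seed: int = 0

    def __post_init__(self):
        sizes = tuple(int(s) for s in self.layer_sizes)
        object.__setattr__(self, "layer_sizes", sizes)
        W = tuple(np.asarray(w, float) for w in self.weights)
        b = tuple(np.asarray(v, float) for v in self.biases)
        object.__setattr__(self, "weights", W)
        object.__setattr__(self, "biases", b)
        if len(W) != len(sizes) - 1 or len(b) != len(sizes) - 1:
            raise ValueError("weights/biases must have one entry per layer transition")
        for l, (w, v) in enumerate(zip(W, b)):
            if w.shape != (sizes[l], sizes[l + 1]) or v.shape != (sizes[l + 1],):
                raise ValueError(f"layer {l}: shape mismatch {w.shape} for sizes {sizes}")
            if not (np.isfinite(w).all() and np.isfinite(v).all()):
                raise ValueError(f"layer {l}: non-finite parameters")

    @property
    def n_inputs(self) -> int:
        return self.layer_sizes[0]

    @property
    def n_hidden_layers(self) -> int:
        return len(self.layer_sizes) - 2

    def copy_with(self, weights, biases) -> "MLPModel":
        return replace(self, weights=tuple(weights), biases=tuple(biases))

    # -- serialization -------------------------------------------------------
    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "layer_sizes": list(self.layer_sizes),
            "weights": [w.ravel().tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "init_seed": self.init_seed}))

    @classmethod
    def from_json(cls, path) -> "MLPModel":
        d = json.loads(Path(path).read_text())
        sizes = d["layer_sizes"]
        W = [np.asarray(w, float).reshape(sizes[l], sizes[l + 1])
             for l, w in enumerate(d["weights"])]
        b = [np.asarray(v, float) for v in d["biases"]]
        return cls(tuple(sizes), tuple(W), tuple(b), d.get("init_seed", 0))


def init_model(layer_sizes, seed: int = 0) -> MLPModel:
    """Glorot-uniform weights (limit sqrt(6/(fan_in+fan_out))), zero biases."""
    sizes = tuple(int(s) for s in layer_sizes)
    if any(s < 1 for s in sizes) or len(sizes) < 2:
        raise ValueError(f"invalid layer sizes {sizes}")
    rng = np.random.default_rng(seed)
    W, b = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        W.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        b.append(np.zeros(fan_out))
    return MLPModel(sizes, tuple(W), tuple(b), init_seed=seed)


def forward(m: MLPModel, X: np.ndarray) -> np.ndarray:
    """Predictions, shape (n_samples,). No dropout at inference."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != m.n_inputs:
        raise ValueError(f"expected {m.n_inputs} input columns, got {X.shape[1]}")
    a = X
    for l in range(len(m.weights) - 1):
        a = sigmoid(a @ m.weights[l] + m.biases[l])
    out = a @ m.weights[-1] + m.biases[-1]
    return out[:, 0]


def loss_and_gradients(m: MLPModel, X: np.ndarray, y: np.ndarray,
                       dropout_mask: np.ndarray | None = None,
                       dropout_rate: float = 0.0):
    """MSE and exact backprop gradients.

    ``dropout_mask`` (boolean, length = last hidden width) zeroes dropped
    units of the last hidden layer; surviving activations are scaled by
    1/(1-rate) so inference needs no rescaling. Returns
    ``(mse, grads_W, grads_b)`` with gradients of the *mean* squared error.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite inputs")
    n = X.shape[0]
    activations = [X]
    a = X
    for l in range(len(m.weights) - 1):
        a = sigmoid(a @ m.weights[l] + m.biases[l])
        activations.append(a)
    if dropout_mask is not None:
        keep = np.asarray(dropout_mask, bool).astype(float)
        scale = 1.0 / (1.0 - dropout_rate) if dropout_rate > 0 else 1.0
        a = a * keep * scale
        activations[-1] = a
    yhat = (a @ m.weights[-1] + m.biases[-1])[:, 0]
    resid = yhat - y
    mse = float(np.mean(resid ** 2))

    grads_W = [None] * len(m.weights)
    grads_b = [None] * len(m.weights)
    # delta at output: d(mse)/d(yhat) = 2*resid/n
    delta = (2.0 * resid / n)[:, None]
    grads_W[-1] = activations[-1].T @ delta
    grads_b[-1] = delta.sum(axis=0)
    back = delta @ m.weights[-1].T
    if dropout_mask is not None:
        back = back * keep * (scale if dropout_rate > 0 else 1.0)
    for l in range(len(m.weights) - 2, -1, -1):
        a_l = activations[l + 1]
        # derivative through the (pre-dropout) logistic activation
        if dropout_mask is not None and l == len(m.weights) - 2:
            raw = sigmoid(activations[l] @ m.weights[l] + m.biases[l])
            delta = back * raw * (1.0 - raw)
        else:
            delta = back * a_l * (1.0 - a_l)
        grads_W[l] = activations[l].T @ delta
        grads_b[l] = delta.sum(axis=0)
        if l > 0:
            back = delta @ m.weights[l].T
    return mse, grads_W, grads_b


def evaluate(m: MLPModel, X: np.ndarray, y: np.ndarray):
    """Held-out (MSE, R^2); R^2 = 1 - SS_res/SS_tot about mean(y).

    A zero-variance ``y`` makes R^2 undefined: returned as ``nan``.
    """
    y = np.asarray(y, float).ravel()
    if y.size == 0:
        raise ValueError("empty evaluation set")
    yhat = forward(m, X)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    mse = ss_res / y.size
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return mse, r2


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (defaults follow the search's protocol:
    RMSprop, batch 50, learning rate 0.01, up to 5000 epochs, patience of
    10 validation evaluations, 50% dropout before the output)."""

    optimizer: str = "rmsprop"
    learning_rate: float = 0.01
    batch_size: int = 50
    max_epochs: int = 5000
    patience: int = 10
    dropout_rate: float = 0.5
    rmsprop_decay: float = 0.9
    rmsprop_eps: float = 1e-8
    eta_plus: float = 1.2
    eta_minus: float = 0.5
    delta0: float = 0.1
    delta_min: float = 1e-6
    delta_max: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.patience < 1 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("patience, batch_size and max_epochs must be >= 1")


@dataclass
class TrainHistory:
    epochs: list = field(default_factory=list)
    train_mse: list = field(default_factory=list)
    val_mse: list = field(default_factory=list)
    stopped_early: bool = False

    def to_csv(self, path) -> None:
        lines = ["epoch,train_mse,val_mse"]
        lines += [f"{e},{t},{v}" for e, t, v in
                  zip(self.epochs, self.train_mse, self.val_mse)]
        Path(path).write_text("\n".join(lines) + "\n")


def _snapshot(m: MLPModel):
    return ([w.copy() for w in m.weights], [b.copy() for b in m.biases])


def train_rmsprop(m: MLPModel, train, val, cfg: TrainConfig):
    """Mini-batch RMSprop with early stopping on validation MSE.

    ``train``/``val`` are (X, y) pairs with disjoint samples. Validation is
    evaluated once per epoch; after ``cfg.patience`` consecutive evaluations
    without improvement training stops and the best-validation snapshot is
    returned. Returns ``(model, TrainHistory)``.
    """
    (Xtr, ytr), (Xva, yva) = train, val
    Xtr = np.atleast_2d(np.asarray(Xtr, float))
    ytr = np.asarray(ytr, float).ravel()
    if Xtr.shape[0] == 0 or np.asarray(yva).size == 0:
        raise ValueError("empty training or validation split")
    rng = np.random.default_rng(cfg.seed)
    W = [w.copy() for w in m.weights]
    b = [v.copy() for v in m.biases]
    sq_W = [np.zeros_like(w) for w in W]
    sq_b = [np.zeros_like(v) for v in b]
    last_hidden = m.layer_sizes[-2]
    n = Xtr.shape[0]
    history = TrainHistory()
    best_val = np.inf
    best = _snapshot(m)
    stall = 0
    cur = m
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            cur = m.copy_with(W, b)
            if cfg.dropout_rate > 0:
                mask = rng.random(last_hidden) >= cfg.dropout_rate
                if not mask.any():  # keep at least one unit alive
                    mask[rng.integers(last_hidden)] = True
            else:
                mask = None
            _, gW, gb = loss_and_gradients(cur, Xtr[idx], ytr[idx],
                                           dropout_mask=mask,
                                           dropout_rate=cfg.dropout_rate)
            for l in range(len(W)):
                sq_W[l] = cfg.rmsprop_decay * sq_W[l] + (1 - cfg.rmsprop_decay) * gW[l] ** 2
                sq_b[l] = cfg.rmsprop_decay * sq_b[l] + (1 - cfg.rmsprop_decay) * gb[l] ** 2
                W[l] -= cfg.learning_rate * gW[l] / (np.sqrt(sq_W[l]) + cfg.rmsprop_eps)
                b[l] -= cfg.learning_rate * gb[l] / (np.sqrt(sq_b[l]) + cfg.rmsprop_eps)
        cur = m.copy_with(W, b)
        tr_mse, _ = evaluate(cur, Xtr, ytr)
        va_mse, _ = evaluate(cur, Xva, yva)
        history.epochs.append(epoch)
        history.train_mse.append(tr_mse)
        history.val_mse.append(va_mse)
        if va_mse < best_val:
            best_val = va_mse
            best = _snapshot(cur)
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                history.stopped_early = True
                break
    return m.copy_with(*best), history


class RpropPlusState:
    """Per-parameter Rprop+ state (step sizes, previous gradients/updates).

    Implements resilient backpropagation with weight backtracking: step
    sizes grow by ``eta_plus`` while the gradient keeps its sign, shrink by
    ``eta_minus`` on a sign change — and on a sign change the previous
    update is reverted and the stored gradient zeroed so the next step is
    treated as fresh.
    """

    def __init__(self, shapes, cfg: TrainConfig):
        self.cfg = cfg
        self.step = [np.full(s, cfg.delta0) for s in shapes]
        self.prev_grad = [np.zeros(s) for s in shapes]
        self.prev_update = [np.zeros(s) for s in shapes]

    def update(self, params, grads):
        """Mutates ``params`` in place given current ``grads``."""
        cfg = self.cfg
        for i, (p, g) in enumerate(zip(params, grads)):
            sign = self.prev_grad[i] * g
            grow = sign > 0
            shrink = sign < 0
            self.step[i][grow] = np.minimum(self.step[i][grow] * cfg.eta_plus,
                                            cfg.delta_max)
            self.step[i][shrink] = np.maximum(self.step[i][shrink] * cfg.eta_minus,
                                              cfg.delta_min)
            upd = -np.sign(g) * self.step[i]
            upd[shrink] = -self.prev_update[i][shrink]  # backtrack
            p += upd
            g = g.copy()
            g[shrink] = 0.0  # no adaptation on the step after a reversal
            self.prev_grad[i] = g
            self.prev_update[i] = upd


def train_rprop_plus(m: MLPModel, train, val=None, cfg: TrainConfig | None = None):
    """Full-batch Rprop+ training; early stopping if ``val`` is given.

    Returns ``(model, TrainHistory)``; without a validation split the final
    weights are returned after ``cfg.max_epochs`` full-batch steps.
    """
    if cfg is None:
        cfg = TrainConfig(optimizer="rprop_plus")
    (Xtr, ytr) = train
    Xtr = np.atleast_2d(np.asarray(Xtr, float))
    ytr = np.asarray(ytr, float).ravel()
    W = [w.copy() for w in m.weights]
    b = [v.copy() for v in m.biases]
    state = RpropPlusState([w.shape for w in W] + [v.shape for v in b], cfg)
    history = TrainHistory()
    best_val = np.inf
    best = _snapshot(m)
    stall = 0
    for epoch in range(cfg.max_epochs):
        cur = m.copy_with(W, b)
        tr_mse, gW, gb = loss_and_gradients(cur, Xtr, ytr)
        state.update(W + b, gW + gb)
        cur = m.copy_with(W, b)
        history.epochs.append(epoch)
        history.train_mse.append(tr_mse)
        if val is not None:
            va_mse, _ = evaluate(cur, val[0], val[1])
            history.val_mse.append(va_mse)
            if va_mse < best_val:
                best_val = va_mse
                best = _snapshot(cur)
                stall = 0
            else:
                stall += 1
                if stall >= cfg.patience:
                    history.stopped_early = True
                    break
        else:
            history.val_mse.append(float("nan"))
            best = _snapshot(cur)
    return m.copy_with(*best), history


def rprop_minimize(grad_fn, w0: np.ndarray, n_iter: int = 100,
                   cfg: TrainConfig | None = None) -> np.ndarray:
    """Generic Rprop+ descent on an arbitrary gradient field (used for
    sanity checks of the optimizer outside the network context)."""
    if cfg is None:
        cfg = TrainConfig(optimizer="rprop_plus")
    w = np.asarray(w0, float).copy()
    state = RpropPlusState([w.shape], cfg)
    for _ in range(n_iter):
        g = np.asarray(grad_fn(w), float)
        state.update([w], [g])
    return w


# ---------------------------------------------------------------------------
# Phenotype fitness
# ---------------------------------------------------------------------------

@dataclass
class FitnessRecord:
    """MSE/R^2 summaries across validation repetitions for one phenotype.

    The evolutionary search minimizes ``mean_mse`` (the adaptation value).
    """

    phenotype_summary: str
    validation: str
    mses: list
    r2s: list
    n_repetitions: int
    feasible: bool = True

    @property
    def mean_mse(self) -> float:
        return float(np.mean(self.mses)) if self.mses else WORST_FITNESS

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.r2s)) if self.r2s else float("nan")

    @classmethod
    def infeasible(cls, summary: str) -> "FitnessRecord":
        return cls(phenotype_summary=summary, validation="none",
                   mses=[WORST_FITNESS], r2s=[float("nan")],
                   n_repetitions=0, feasible=False)


def _phenotype_data(phenotype, ds):
    mask = np.asarray(phenotype.feature_mask, bool)
    return ds.values[:, mask], ds.target


def fitness_holdout(phenotype, ds, cfg: TrainConfig, n_repetitions: int = 20,
                    seed: int | None = None) -> FitnessRecord:
    """Repeated random 50/25/25 (train/validation/test) hold-out fitness.

    Each repetition re-splits, re-initializes and retrains; the adaptation
    value is the mean test MSE over repetitions.
    """
    if not phenotype.feasible:
        return FitnessRecord.infeasible(phenotype.architecture_label())
    X, y = _phenotype_data(phenotype, ds)
    n = X.shape[0]
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    mses, r2s = [], []
    for _ in range(n_repetitions):
        perm = rng.permutation(n)
        n_tr, n_va = int(round(0.5 * n)), int(round(0.25 * n))
        tr, va, te = perm[:n_tr], perm[n_tr:n_tr + n_va], perm[n_tr + n_va:]
        model = init_model([X.shape[1], *phenotype.hidden_layers, 1],
                           seed=int(rng.integers(2 ** 31)))
        rep_cfg = replace(cfg, seed=int(rng.integers(2 ** 31)))
        model, _ = train_rmsprop(model, (X[tr], y[tr]), (X[va], y[va]), rep_cfg)
        mse, r2 = evaluate(model, X[te], y[te])
        mses.append(mse)
        r2s.append(r2)
    return FitnessRecord(phenotype_summary=phenotype.architecture_label(),
                         validation="holdout", mses=mses, r2s=r2s,
                         n_repetitions=n_repetitions)


def fitness_kfold(phenotype, ds, cfg: TrainConfig, k: int = 10,
                  seed: int | None = None) -> FitnessRecord:
    """k-fold fitness: k disjoint test folds partitioning the samples; 25%
    of each training portion is held out for early stopping."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if not phenotype.feasible:
        return FitnessRecord.infeasible(phenotype.architecture_label())
    X, y = _phenotype_data(phenotype, ds)
    n = X.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} samples, have {n}")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    mses, r2s = [], []
    for i in range(k):
        te = folds[i]
        rest = np.concatenate([folds[j] for j in range(k) if j != i])
        n_va = max(1, int(round(0.25 * rest.size)))
        va, tr = rest[:n_va], rest[n_va:]
        model = init_model([X.shape[1], *phenotype.hidden_layers, 1],
                           seed=int(rng.integers(2 ** 31)))
        rep_cfg = replace(cfg, seed=int(rng.integers(2 ** 31)))
        model, _ = train_rmsprop(model, (X[tr], y[tr]), (X[va], y[va]), rep_cfg)
        mse, r2 = evaluate(model, X[te], y[te])
        mses.append(mse)
        r2s.append(r2)
    return FitnessRecord(phenotype_summary=phenotype.architecture_label(),
                         validation="kfold", mses=mses, r2s=r2s,
                         n_repetitions=k)
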