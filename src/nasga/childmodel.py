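"""Materialize, train and score recurrent child classifiers.

The per-timestep cell computes

* node 1: ``h1 = f1(x_t @ W_in + h_prev @ W_rec)``
* node k>1: ``hk = f_k(h_parent(k) @ W_edge(parent(k), k))``

the cell output ``h_t`` is the mean over terminal-node outputs and is fed
back as the previous state; a linear head over the last timestep's ``h_t``
yields two-class logits.  Learned weights are written back to a shared
store so subsequent children reusing a connection start from them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .cellspace import (
    Chromosome,
    INPUT_KEY,
    RECUR_KEY,
    build_dag,
    edge_key,
    init_weight,
    to_adjacency,
)

HEAD_WEIGHT_KEY = "head:weight"
HEAD_BIAS_KEY = "head:bias"


@dataclass
class TrainConfig:
    hidden: int = 16
    batch_size: int = 64
    learning_rate: float = 0.01
    patience: int = 10
    max_epochs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.hidden < 1 or self.batch_size < 1:
            raise ValueError("hidden and batch_size must be >= 1")


@dataclass
class FitnessRecord:
    chromosome_id: int
    accuracy: float
    epochs_run: int
    best_val_loss: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")


class SharedWeightStore:
    """Mapping from weight-gene key to learned matrix, with a version counter."""

    def __init__(self) -> None:
        self._store: dict[str, np.ndarray] = {}
        self.version = 0

    def __contains__(self, key: str) -> bool:
        return key in self._store

    def get(self, key: str) -> np.ndarray:
        return self._store[key]

    def keys(self) -> list[str]:
        return sorted(self._store)

    def commit(self, updates: dict[str, np.ndarray]) -> None:
        for key, value in updates.items():
            self._store[key] = np.array(value, dtype=np.float64)
        self.version += 1

    def save(self, archive: str | Path, manifest: str | Path | None = None) -> None:
        archive = Path(archive)
        np.savez(archive, **self._store)
        if manifest is not None:
            Path(manifest).write_text(
                json.dumps({"version": self.version, "keys": self.keys()}, indent=2)
            )

    @classmethod
    def load(cls, archive: str | Path, manifest: str | Path | None = None) -> "SharedWeightStore":
        store = cls()
        with np.load(Path(archive)) as data:
            store._store = {k: np.array(data[k]) for k in data.files}
        if manifest is not None:
            store.version = int(json.loads(Path(manifest).read_text())["version"])
        return store


@dataclass
class CellModel:
    """A materialized chromosome: parameter tensors plus forward logic."""

    chromosome: Chromosome
    hidden: int
    n_features: int
    params: dict[str, nn.Tensor] = field(default_factory=dict)

    def parameters(self) -> list[nn.Tensor]:
        return [self.params[k] for k in sorted(self.params)]

    def forward(self, x: np.ndarray) -> nn.Tensor:
        """Logits for a batch ``x`` of shape (batch, time, features)."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 3 or x.shape[2] != self.n_features:
            raise ValueError(
                f"expected input (batch, time, {self.n_features}), got {x.shape}"
            )
        dag = build_dag(to_adjacency(self.chromosome))
        batch, steps, _ = x.shape
        h_prev = nn.Tensor(np.zeros((batch, self.hidden)))
        for t in range(steps):
            xt = nn.Tensor(x[:, t, :])
            node_out: dict[int, nn.Tensor] = {}
            pre = nn.add(
                nn.matmul(xt, self.params[INPUT_KEY]),
                nn.matmul(h_prev, self.params[RECUR_KEY]),
            )
            node_out[1] = nn.ACTIVATION_FNS[dag.activations[0]](pre)
            for k in range(2, dag.n + 1):
                j = dag.parent_of[k - 2]
                pre = nn.matmul(node_out[j], self.params[edge_key(j, k)])
                node_out[k] = nn.ACTIVATION_FNS[dag.activations[k - 1]](pre)
            h_prev = nn.mean_tensors([node_out[k] for k in dag.terminals])
        logits = nn.add(
            nn.matmul(h_prev, self.params[HEAD_WEIGHT_KEY]),
            self.params[HEAD_BIAS_KEY],
        )
        return logits

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Positive-class probability per episode."""
        return nn.softmax(self.forward(x).data)[:, 1]

    def weight_arrays(self) -> dict[str, np.ndarray]:
        return {k: t.data.copy() for k, t in self.params.items()}


def materialize_model(
    chromosome: Chromosome,
    store: SharedWeightStore,
    config: TrainConfig,
    n_features: int = 40,
) -> CellModel:
    """Build a trainable classifier; store weights win over chromosome genes,
    chromosome genes win over fresh random initialization."""
    rng = np.random.default_rng(config.seed)
    params: dict[str, nn.Tensor] = {}
    for key in chromosome.selected_weight_keys():
        if key in store:
            value = store.get(key)
        elif key in chromosome.weights:
            value = chromosome.weights[key]
        else:
            value = init_weight(key, n_features, config.hidden, rng)
        expected = (n_features, config.hidden) if key == INPUT_KEY else (config.hidden, config.hidden)
        if value.shape != expected:
            raise ValueError(f"weight gene {key}: shape {value.shape} != {expected}")
        params[key] = nn.Tensor(np.array(value), requires_grad=True)
    if HEAD_WEIGHT_KEY in store:
        head_w = store.get(HEAD_WEIGHT_KEY)
        head_b = store.get(HEAD_BIAS_KEY)
        if head_w.shape != (config.hidden, 2):
            raise ValueError(f"classification head shape {head_w.shape} != {(config.hidden, 2)}")
    else:
        head_w = rng.normal(0.0, np.sqrt(2.0 / (config.hidden + 2)), size=(config.hidden, 2))
        head_b = np.zeros(2)
    params[HEAD_WEIGHT_KEY] = nn.Tensor(np.array(head_w), requires_grad=True)
    params[HEAD_BIAS_KEY] = nn.Tensor(np.array(head_b), requires_grad=True)
    return CellModel(
        chromosome=chromosome, hidden=config.hidden, n_features=n_features, params=params
    )


def _evaluate(model: CellModel, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(mean cross-entropy, accuracy) without building a graph."""
    logits = model.forward(x)
    probs = nn.softmax(logits.data)
    n = len(y)
    loss = float(np.mean(-np.log(np.clip(probs[np.arange(n), y.astype(int)], 1e-12, None))))
    acc = float(np.mean(probs.argmax(axis=1) == y))
    return loss, acc


def train_child(
    model: CellModel,
    train_x: np.ndarray,
    train_y: np.ndarray,
    val_x: np.ndarray,
    val_y: np.ndarray,
    config: TrainConfig,
) -> FitnessRecord:
    """Adam + cross-entropy with early stopping on validation loss.

    Stops when the best validation loss has not improved for ``patience``
    consecutive epochs, or at ``max_epochs``.
    """
    if len(train_x) == 0 or len(val_x) == 0:
        raise ValueError("train and validation splits must be non-empty")
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    train_y = np.asarray(train_y, dtype=np.intp)
    val_y = np.asarray(val_y, dtype=np.intp)
    best_loss = np.inf
    best_acc = 0.0
    best_params: dict[str, np.ndarray] | None = None
    stall = 0
    epochs_run = 0
    for _epoch in range(config.max_epochs):
        order = rng.permutation(len(train_x))
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            opt.zero_grad()
            loss = nn.softmax_cross_entropy(model.forward(train_x[idx]), train_y[idx])
            loss.backward()
            opt.step()
        epochs_run += 1
        val_loss, val_acc = _evaluate(model, val_x, val_y)
        if val_loss < best_loss - 1e-12:
            best_loss = val_loss
            best_acc = val_acc
            best_params = {k: t.data.copy() for k, t in model.params.items()}
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    if best_params is not None:  # restore the best-validation-loss epoch
        for k, t in model.params.items():
            t.data = best_params[k]
    chromosome = getattr(model, "chromosome", None)
    return FitnessRecord(
        chromosome_id=chromosome.id if chromosome is not None else -1,
        accuracy=best_acc,
        epochs_run=epochs_run,
        best_val_loss=float(best_loss),
    )


def epochs_to_accuracy(
    chromosomes,
    train_x: np.ndarray,
    train_y: np.ndarray,
    val_x: np.ndarray,
    val_y: np.ndarray,
    config: TrainConfig,
    target_accuracy: float,
    share_weights: bool,
    epoch_cap: int = 30,
) -> int:
    """Cumulative epochs needed for each chromosome in sequence to reach
    ``target_accuracy`` on validation (or hit ``epoch_cap``).

    With ``share_weights`` the sequence trains against one persistent store
    (committing after each chromosome); without it every chromosome starts
    from scratch.  Used to quantify the weight-sharing speedup.
    """
    from . import nn as _nn

    store = SharedWeightStore()
    train_y = np.asarray(train_y, dtype=np.intp)
    total_epochs = 0
    for i, chromosome in enumerate(chromosomes):
        cfg = TrainConfig(
            hidden=config.hidden,
            batch_size=config.batch_size,
            learning_rate=config.learning_rate,
            seed=config.seed + i,
        )
        model = materialize_model(
            chromosome, store if share_weights else SharedWeightStore(), cfg, train_x.shape[2]
        )
        rng = np.random.default_rng(cfg.seed)
        opt = _nn.Adam(model.parameters(), lr=cfg.learning_rate)
        for _epoch in range(epoch_cap):
            _loss, acc = _evaluate(model, val_x, val_y)
            if acc >= target_accuracy:
                break
            order = rng.permutation(len(train_x))
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                opt.zero_grad()
                loss = _nn.softmax_cross_entropy(model.forward(train_x[idx]), train_y[idx])
                loss.backward()
                opt.step()
            total_epochs += 1
        if share_weights:
            commit_weights(model, chromosome, store)
    return total_epochs


def commit_weights(
    model: CellModel, chromosome: Chromosome, store: SharedWeightStore
) -> SharedWeightStore:
    """Write learned matrices for the selected genes (plus the head) back to
    the store and into the chromosome's weight genes."""
    updates: dict[str, np.ndarray] = {}
    for key in chromosome.selected_weight_keys():
        learned = model.params[key].data.copy()
        updates[key] = learned
        chromosome.weights[key] = learned.copy()
    updates[HEAD_WEIGHT_KEY] = model.params[HEAD_WEIGHT_KEY].data.copy()
    updates[HEAD_BIAS_KEY] = model.params[HEAD_BIAS_KEY].data.copy()
    store.commit(updates)
    return store
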