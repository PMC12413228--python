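"""Training harnesses: end-to-end, branched-frozen, and k-fold CV.

Both strategies optimise binary cross-entropy with Adam (learning rate
1e-4). End-to-end training updates every weight, including the token
embedding table, from the final loss. Branched training first fits each
branch separately under a temporary sigmoid head, then freezes the
branch weights and trains only the combined head; the temporary heads
are discarded.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from ._nn import Adam, Dense, Sigmoid, bce_loss, run_backward, run_forward
from .metrics import MetricsReport, compute_metrics
from .nets import HybridNet, NetConfig
from .plm_store import EmbeddingTable, target_embeddings
from .seqdata import SiteRecord, encode_windows, labels_of

DEFAULT_EPOCHS = 100
DEFAULT_BATCH = 256
DEFAULT_LR = 1e-4
DEFAULT_PATIENCE = 10


@dataclass
class TrainRun:
    model: HybridNet
    history: list[dict] = field(default_factory=list)
    seed: int = 0
    strategy: str = "end_to_end"
    #: for branched runs: branch weights captured when the branches were
    #: frozen, so callers can verify stage 2 left them bitwise intact
    branch_weights_at_freeze: list[np.ndarray] | None = None

    def write_history(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for row in self.history:
                fh.write(json.dumps(row) + "\n")


def records_to_arrays(
    records: Sequence[SiteRecord], plm_table: EmbeddingTable
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(tokens, target-site PLM vectors, labels) for a batch of records."""
    return (
        encode_windows(records),
        target_embeddings(plm_table, records).astype(np.float64),
        labels_of(records),
    )


def predict_records(net: HybridNet, records, plm_table: EmbeddingTable) -> np.ndarray:
    tokens, plm, _ = records_to_arrays(records, plm_table)
    return net.predict(tokens, plm)


class _Trainable:
    """Anything with forward(inputs, train), backward(dprobs), all_layers()."""


class _BranchWithHead:
    """A branch plus a temporary Dense(1)+sigmoid head for stage-1 training."""

    def __init__(self, branch, feat_dim: int, rng: np.random.Generator):
        self.branch = branch
        self.head = [Dense(feat_dim, 1, rng), Sigmoid()]

    def all_layers(self):
        return self.branch.layers + self.head

    def forward(self, x, train=False):
        feats = self.branch.forward(x, train=train)
        return run_forward(self.head, feats, train=train)[:, 0]

    def backward(self, dprobs):
        d = run_backward(self.head, dprobs[:, None])
        self.branch.backward(d)


def _fit(
    model,
    train_inputs: tuple,
    train_labels: np.ndarray,
    val_inputs: tuple | None,
    val_labels: np.ndarray | None,
    *,
    epochs: int,
    batch_size: int,
    lr: float,
    patience: int,
    rng: np.random.Generator,
    log=None,
    keep_best: bool = True,
) -> list[dict]:
    """Minibatch Adam/BCE loop; retains best-validation-loss weights."""
    optimizer = Adam(model.all_layers(), lr=lr)
    n = len(train_labels)
    history: list[dict] = []
    best_loss = np.inf
    best_weights = None
    since_best = 0
    has_val = val_inputs is not None and val_labels is not None and len(val_labels) > 0
    get_weights = getattr(model, "get_weights", None)

    def forward_all(inputs, train):
        return model.forward(*inputs, train=train) if len(inputs) > 1 else model.forward(
            inputs[0], train=train
        )

    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            batch = tuple(a[idx] for a in train_inputs)
            probs = forward_all(batch, True)
            loss, dp = bce_loss(probs, train_labels[idx])
            model.backward(dp)
            optimizer.step()
            epoch_loss += loss * len(idx)
        row = {"epoch": epoch, "train_loss": epoch_loss / n}
        if has_val:
            val_probs = forward_all(val_inputs, False)
            val_loss, _ = bce_loss(val_probs, val_labels)
            row["val_loss"] = val_loss
            monitored = val_loss
        else:
            monitored = row["train_loss"]
        history.append(row)
        if log is not None:
            print(json.dumps(row), file=log)
        if monitored < best_loss - 1e-12:
            best_loss = monitored
            since_best = 0
            if keep_best and get_weights is not None:
                best_weights = model.get_weights()
        else:
            since_best += 1
            if has_val and since_best >= patience:
                break
    if keep_best and best_weights is not None:
        model.set_weights(best_weights)
    return history


def _check_plm(records, plm_table) -> None:
    missing = sorted({r.protein_id for r in records if r.protein_id not in plm_table.entries})
    if missing:
        raise KeyError(f"missing PLM embeddings for: {', '.join(missing)}")


def train_end_to_end(
    config: NetConfig,
    train_records: Sequence[SiteRecord],
    plm_table: EmbeddingTable,
    val_records: Sequence[SiteRecord] | None = None,
    seed: int = 0,
    epochs: int = DEFAULT_EPOCHS,
    batch_size: int = DEFAULT_BATCH,
    lr: float = DEFAULT_LR,
    patience: int = DEFAULT_PATIENCE,
    log=None,
) -> TrainRun:
    """Train the full hybrid model end-to-end; deterministic given seed."""
    _check_plm(train_records, plm_table)
    net = HybridNet(config, seed=seed)
    rng = np.random.default_rng(seed + 1)
    tokens, plm, labels = records_to_arrays(train_records, plm_table)
    val_inputs = val_labels = None
    if val_records:
        _check_plm(val_records, plm_table)
        vt, vp, val_labels = records_to_arrays(val_records, plm_table)
        val_inputs = (vt, vp)
    history = _fit(
        net, (tokens, plm), labels, val_inputs, val_labels,
        epochs=epochs, batch_size=batch_size, lr=lr, patience=patience,
        rng=rng, log=log,
    )
    return TrainRun(model=net, history=history, seed=seed, strategy="end_to_end")


def train_branched(
    config: NetConfig,
    train_records: Sequence[SiteRecord],
    plm_table: EmbeddingTable,
    val_records: Sequence[SiteRecord] | None = None,
    seed: int = 0,
    epochs: int = DEFAULT_EPOCHS,
    batch_size: int = DEFAULT_BATCH,
    lr: float = DEFAULT_LR,
    patience: int = DEFAULT_PATIENCE,
    log=None,
) -> TrainRun:
    """Two-stage training: fit each branch separately, then freeze both
    branches and train only the combined head."""
    _check_plm(train_records, plm_table)
    net = HybridNet(config, seed=seed)
    rng = np.random.default_rng(seed + 1)
    head_rng = np.random.default_rng(seed + 2)
    tokens, plm, labels = records_to_arrays(train_records, plm_table)
    val_inputs = val_labels = None
    vt = vp = None
    if val_records:
        _check_plm(val_records, plm_table)
        vt, vp, val_labels = records_to_arrays(val_records, plm_table)

    fit_kw = dict(epochs=epochs, batch_size=batch_size, lr=lr,
                  patience=patience, rng=rng, log=log, keep_best=False)

    word_tmp = _BranchWithHead(net.word, config.branch_dense, head_rng)
    h1 = _fit(word_tmp, (tokens,), labels,
              (vt,) if vt is not None else None, val_labels, **fit_kw)
    mlp_tmp = _BranchWithHead(net.mlp, config.branch_dense, head_rng)
    h2 = _fit(mlp_tmp, (plm,), labels,
              (vp,) if vp is not None else None, val_labels, **fit_kw)

    # stage 2: freeze branches, train the head on the final loss
    net.set_branches_trainable(False)
    frozen = [
        layer.params[name].copy()
        for layer in net.word.layers + net.mlp.layers
        for name in layer.params
    ]
    if vt is not None:
        val_inputs = (vt, vp)
    h3 = _fit(net, (tokens, plm), labels, val_inputs, val_labels,
              epochs=epochs, batch_size=batch_size, lr=lr,
              patience=patience, rng=rng, log=log, keep_best=True)

    history = (
        [{**r, "stage": "word"} for r in h1]
        + [{**r, "stage": "mlp"} for r in h2]
        + [{**r, "stage": "head"} for r in h3]
    )
    return TrainRun(model=net, history=history, seed=seed, strategy="branched",
                    branch_weights_at_freeze=frozen)


def kfold_cv(
    config: NetConfig,
    records: Sequence[SiteRecord],
    plm_table: EmbeddingTable,
    k: int = 10,
    seed: int = 0,
    epochs: int = DEFAULT_EPOCHS,
    batch_size: int = DEFAULT_BATCH,
    lr: float = DEFAULT_LR,
    log=None,
) -> tuple[list[MetricsReport], dict[str, float], dict[str, float]]:
    """Stratified k-fold cross-validation; per-fold reports plus mean/sd.

    Each record appears in exactly one validation fold. Folds train for
    a fixed epoch budget (no early stopping) so no held-out information
    leaks into model selection.
    """
    labels = labels_of(records)
    n_min = min(int(np.sum(labels == 1)), int(np.sum(labels == 0)))
    if k > n_min:
        raise ValueError(f"k={k} exceeds the minority class count {n_min}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    records = list(records)
    reports: list[MetricsReport] = []
    for fold, (tr_idx, va_idx) in enumerate(skf.split(np.zeros(len(records)), labels)):
        run = train_end_to_end(
            config,
            [records[i] for i in tr_idx],
            plm_table,
            val_records=None,
            seed=seed + fold,
            epochs=epochs,
            batch_size=batch_size,
            lr=lr,
            log=log,
        )
        va = [records[i] for i in va_idx]
        probs = predict_records(run.model, va, plm_table)
        reports.append(compute_metrics(labels_of(va), probs))
        if log is not None:
            print(f"fold {fold}: auroc={reports[-1].auroc}", file=log or sys.stderr)
    keys = ["accuracy", "precision", "recall", "specificity", "f1", "mcc", "auroc", "auprc"]
    mean = {}
    sd = {}
    for key in keys:
        vals = [getattr(r, key) for r in reports if getattr(r, key) is not None]
        mean[key] = float(np.mean(vals)) if vals else float("nan")
        sd[key] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return reports, mean, sd
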