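"""Hybrid classifier architectures for succinylation-site prediction.

Every model has two branches whose 32-unit feature vectors are
concatenated and passed through a small sigmoid head:

* a *word-embedding branch* over the 33-token window — one of three
  variants: plain two-layer Conv1D, an inception module (parallel
  kernels 1,3,5,7,9,11 plus a pooled 1x1-conv branch), or a residual
  network of two concatenation-skip blocks;
* an *MLP branch* over the per-residue protein-language-model embedding
  of the target lysine (width 1024 for ProtT5).

With the default configuration the residual hybrid has exactly 93,082
trainable parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._nn import (
    Adam,
    Conv1D,
    Dense,
    Dropout,
    Embedding,
    Flatten,
    Layer,
    MaxPool1D,
    MaxPool1DSame,
    ReLU,
    Sigmoid,
    run_backward,
    run_forward,
)

BRANCH_KINDS = ("conv", "inception", "resnet")


@dataclass
class NetConfig:
    window_length: int = 33
    vocab: int = 21
    embed_dim: int = 21
    branch_kind: str = "resnet"
    conv_filters: tuple[int, int] = (32, 64)
    conv_kernel: int = 3
    inception_kernels: tuple[int, ...] = (1, 3, 5, 7, 9, 11)
    inception_filters: int = 32
    plm_width: int = 1024
    branch_dense: int = 32
    head_dense: int = 32
    dropout: float = 0.30
    pool_size: int = 2

    def __post_init__(self) -> None:
        if self.window_length % 2 != 1:
            raise ValueError("window_length must be odd")
        if self.embed_dim < 1 or any(f < 1 for f in self.conv_filters):
            raise ValueError("embed_dim and filter counts must be >= 1")
        if self.branch_kind not in BRANCH_KINDS:
            raise ValueError(
                f"unknown branch_kind {self.branch_kind!r}; expected one of {BRANCH_KINDS}"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conv_filters"] = list(self.conv_filters)
        d["inception_kernels"] = list(self.inception_kernels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetConfig":
        d = dict(d)
        if "conv_filters" in d:
            d["conv_filters"] = tuple(d["conv_filters"])
        if "inception_kernels" in d:
            d["inception_kernels"] = tuple(d["inception_kernels"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Composite blocks

class ResidualBlock:
    """Two same-padded Conv1D layers with a concatenation skip connection.

    Output channels = filters + input channels; ReLU after each conv,
    no post-concatenation activation.
    """

    def __init__(self, c_in: int, filters: int, kernel: int, rng: np.random.Generator):
        self.filters = filters
        self.conv1 = Conv1D(c_in, filters, kernel, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv1D(filters, filters, kernel, rng)
        self.relu2 = ReLU()
        self.layers = [self.conv1, self.relu1, self.conv2, self.relu2]

    def forward(self, x, train=False):
        y = run_forward(self.layers, x, train=train)
        return np.concatenate([y, x], axis=2)

    def backward(self, dout):
        f = self.filters
        dy, dskip = dout[:, :, :f], dout[:, :, f:]
        return run_backward(self.layers, dy) + dskip


class InceptionModule:
    """Parallel same-padded convolutions of several kernel sizes plus a
    stride-1 max-pool branch ending in a 1x1 convolution; outputs are
    concatenated along the channel axis (len(kernels)+1 branches)."""

    def __init__(self, c_in: int, kernels, filters: int, rng: np.random.Generator):
        self.filters = filters
        self.branches: list[list[Layer]] = [
            [Conv1D(c_in, filters, k, rng), ReLU()] for k in kernels
        ]
        self.branches.append([MaxPool1DSame(3), Conv1D(c_in, filters, 1, rng), ReLU()])
        self.layers = [layer for branch in self.branches for layer in branch]

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    def forward(self, x, train=False):
        return np.concatenate(
            [run_forward(b, x, train=train) for b in self.branches], axis=2
        )

    def backward(self, dout):
        f = self.filters
        dx = None
        for i, branch in enumerate(self.branches):
            d = run_backward(branch, dout[:, :, i * f : (i + 1) * f])
            dx = d if dx is None else dx + d
        return dx


# ---------------------------------------------------------------------------
# Branches

class WordBranch:
    """Word-embedding branch: (N, 33) tokens -> (N, branch_dense) features."""

    def __init__(self, config: NetConfig, rng: np.random.Generator):
        self.config = config
        c = config
        self.embedding = Embedding(c.vocab, c.embed_dim, rng)
        self.blocks: list = []  # alternating feature blocks and pools
        channels = c.embed_dim
        length = c.window_length
        if c.branch_kind == "conv":
            for f in c.conv_filters:
                self.blocks.append([Conv1D(channels, f, c.conv_kernel, rng), ReLU()])
                self.blocks.append([MaxPool1D(c.pool_size)])
                channels = f
                length //= c.pool_size
        elif c.branch_kind == "resnet":
            for f in c.conv_filters:
                block = ResidualBlock(channels, f, c.conv_kernel, rng)
                self.blocks.append(block)
                self.blocks.append([MaxPool1D(c.pool_size)])
                channels = f + channels
                length //= c.pool_size
        else:  # inception
            module = InceptionModule(c.embed_dim, c.inception_kernels, c.inception_filters, rng)
            self.blocks.append(module)
            self.blocks.append([MaxPool1D(c.pool_size)])
            channels = module.n_branches * c.inception_filters
            length //= c.pool_size
        self.flat_dim = length * channels
        self.tail = [
            Flatten(),
            Dense(self.flat_dim, c.branch_dense, rng),
            ReLU(),
            Dropout(c.dropout, rng),
        ]

    @property
    def layers(self) -> list[Layer]:
        out = [self.embedding]
        for blk in self.blocks:
            out.extend(blk.layers if hasattr(blk, "layers") else blk)
        out.extend(self.tail)
        return out

    def forward(self, tokens: np.ndarray, train: bool = False) -> np.ndarray:
        x = self.embedding.forward(tokens, train=train)
        for blk in self.blocks:
            if hasattr(blk, "forward"):
                x = blk.forward(x, train=train)
            else:
                x = run_forward(blk, x, train=train)
        return run_forward(self.tail, x, train=train)

    def backward(self, dout: np.ndarray) -> None:
        d = run_backward(self.tail, dout)
        for blk in reversed(self.blocks):
            if hasattr(blk, "backward"):
                d = blk.backward(d)
            else:
                d = run_backward(blk, d)
        self.embedding.backward(d)


class MLPBranch:
    """Dense(32) + ReLU + dropout over the target-site PLM embedding."""

    def __init__(self, config: NetConfig, rng: np.random.Generator):
        self.config = config
        self.layers = [
            Dense(config.plm_width, config.branch_dense, rng),
            ReLU(),
            Dropout(config.dropout, rng),
        ]

    def forward(self, plm: np.ndarray, train: bool = False) -> np.ndarray:
        if plm.shape[1] != self.config.plm_width:
            raise ValueError(
                f"PLM width mismatch: got {plm.shape[1]}, expected {self.config.plm_width}"
            )
        return run_forward(self.layers, plm, train=train)

    def backward(self, dout: np.ndarray) -> None:
        run_backward(self.layers, dout)


class HybridNet:
    """Two-branch classifier: concat(word 32, MLP 32) -> dense -> sigmoid."""

    def __init__(self, config: NetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.word = WordBranch(config, rng)
        self.mlp = MLPBranch(config, rng)
        self.head = [
            Dense(2 * config.branch_dense, config.head_dense, rng),
            ReLU(),
            Dropout(config.dropout, rng),
            Dense(config.head_dense, 1, rng),
            Sigmoid(),
        ]

    def all_layers(self) -> list[Layer]:
        return self.word.layers + self.mlp.layers + self.head

    def forward(self, tokens: np.ndarray, plm: np.ndarray, train: bool = False) -> np.ndarray:
        w = self.word.forward(tokens, train=train)
        m = self.mlp.forward(plm, train=train)
        h = np.concatenate([w, m], axis=1)
        return run_forward(self.head, h, train=train)[:, 0]

    def backward(self, dprobs: np.ndarray) -> None:
        d = run_backward(self.head, dprobs[:, None])
        k = self.config.branch_dense
        self.word.backward(d[:, :k])
        self.mlp.backward(d[:, k:])

    def predict(self, tokens: np.ndarray, plm: np.ndarray) -> np.ndarray:
        """Deterministic evaluation-mode probabilities in (0, 1)."""
        return self.forward(tokens, plm, train=False)

    # -- freezing (branched training support) --------------------------------

    def set_branches_trainable(self, trainable: bool) -> None:
        for layer in self.word.layers + self.mlp.layers:
            if layer.params:
                layer.trainable = trainable

    # -- checkpointing --------------------------------------------------------

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.all_layers() for p in layer.params.values()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        i = 0
        for layer in self.all_layers():
            for name in layer.params:
                layer.params[name] = weights[i].copy()
                i += 1
        if i != len(weights):
            raise ValueError("weight list does not match architecture")

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"w{i}": w for i, w in enumerate(self.get_weights())}
        np.savez(path, **arrays)
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(self.config.to_dict())
        )

    @classmethod
    def load(cls, path: str | Path) -> "HybridNet":
        path = Path(path)
        config = NetConfig.from_dict(
            json.loads(path.with_suffix(path.suffix + ".json").read_text())
        )
        net = cls(config, seed=0)
        with np.load(path) as npz:
            weights = [npz[f"w{i}"] for i in range(len(npz.files))]
        net.set_weights(weights)
        return net


# ---------------------------------------------------------------------------
# Public builders

def build_word_branch(config: NetConfig, seed: int = 0) -> WordBranch:
    return WordBranch(config, np.random.default_rng(seed))


def build_mlp_branch(config: NetConfig, seed: int = 0) -> MLPBranch:
    return MLPBranch(config, np.random.default_rng(seed))


def build_hybrid(config: NetConfig | None = None, seed: int = 0) -> HybridNet:
    return HybridNet(config or NetConfig(), seed=seed)


def count_parameters(net) -> int:
    """Total trainable scalars, including the embedding table and biases."""
    layers = net.all_layers() if hasattr(net, "all_layers") else net.layers
    return int(sum(l.n_params() for l in layers if l.trainable))


def make_optimizer(net, lr: float = 1e-4) -> Adam:
    layers = net.all_layers() if hasattr(net, "all_layers") else net.layers
    return Adam(layers, lr=lr)
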