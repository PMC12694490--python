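"""The interaction classifier: CNN feature extraction, Bi-GRU, attention, sigmoid.

Each organism embedding x_i (a length-d_h vector, treated as a 1-channel 1-D
signal) passes through a tower of (conv -> ReLU -> max-pool) stages

    x^C_t = ReLU(W^C * x_i + b^C),

then a bidirectional GRU concatenating forward and backward states per step,
then additive attention pooling h^A = sum_t alpha_t h^G_t with the weights
summing to 1.  The pooled phage and bacterium vectors are concatenated and
mapped through a fully connected layer with a sigmoid:

    y_hat = sigmoid(W_f (h^A_p (+) h^A_b) + b_f).

Training minimizes mean binary cross-entropy with the AMSGrad optimizer.
Default hyperparameters: four conv stages with filters [32, 64, 128, 256],
kernel 3, pool 2, dropout 0.5 after the CNN tower and on the Bi-GRU output,
GRU hidden size 64, 32 attention units, learning rate 3e-4, batch size 16,
200 epochs.

Ablation variants: ``PBIP3`` drops the Bi-GRU (attention pools the CNN
features directly), ``PBIP4`` drops attention (mean-pools the Bi-GRU states),
``PBIP5`` disables the SMOTE augmentation stage (handled by the pipeline).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from ._layers import (
    AMSGrad,
    Attention,
    BiGRU,
    Conv1D,
    Dense,
    Dropout,
    Layer,
    MaxPool1D,
    MeanPool,
    ReLU,
    attention_weights,
    gru_step,
    sigmoid,
)
from .embedder import PairEmbedding

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "PBIPModel",
    "train_model",
    "bce_loss",
    "ablation_variant",
    "AblationVariant",
    "gru_step",
    "attention_weights",
    "max_pool",
    "save_model",
    "load_model",
]


class NetworkError(ValueError):
    pass


@dataclass
class ModelConfig:
    filters: tuple[int, ...] = (32, 64, 128, 256)
    kernel_size: int = 3
    pool_size: int = 2
    cnn_dropout: float = 0.5
    gru_hidden: int = 64
    gru_dropout: float = 0.5
    attention_units: int = 32
    tower_sharing: Literal["shared", "separate"] = "separate"
    classification_threshold: float = 0.5
    use_bigru: bool = True
    use_attention: bool = True
    seed: int = 0

    @property
    def conv_layers(self) -> int:
        return len(self.filters)

    def __post_init__(self) -> None:
        if any(f < 1 for f in self.filters) or not self.filters:
            raise NetworkError("filter counts must be positive")
        for rate in (self.cnn_dropout, self.gru_dropout):
            if not 0.0 <= rate < 1.0:
                raise NetworkError("dropout must lie in [0, 1)")

    @classmethod
    def reduced(cls, seed: int = 0) -> "ModelConfig":
        """Desk-scale configuration for small embeddings (d_h ~ 16)."""
        return cls(
            filters=(8, 16),
            gru_hidden=8,
            attention_units=16,
            cnn_dropout=0.25,
            gru_dropout=0.25,
            seed=seed,
        )


@dataclass
class TrainConfig:
    learning_rate: float = 3e-4
    batch_size: int = 16
    epochs: int = 200
    optimizer: str = "amsgrad"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise NetworkError("invalid training hyperparameters")
        if self.optimizer != "amsgrad":
            raise NetworkError(f"unsupported optimizer {self.optimizer!r}")

    @classmethod
    def reduced(cls) -> "TrainConfig":
        """Desk-scale training schedule for the reduced architecture.

        30 epochs at learning rate 3e-3: the full-size rate of 3e-4 is tuned
        for 200-epoch runs and underfits badly in a 30-epoch small-model
        regime (the training loss barely moves).
        """
        return cls(learning_rate=3e-3, epochs=30)


def max_pool(feature_map: np.ndarray, pool_size: int = 2) -> np.ndarray:
    """Non-overlapping max pooling of a (T,) or (T, C) map; remainder dropped."""
    x = np.asarray(feature_map, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    T = x.shape[0]
    if T < pool_size:
        raise NetworkError(f"map length {T} shorter than pool size {pool_size}")
    out = MaxPool1D(pool_size).forward(x[None])[0]
    return out[:, 0] if squeeze else out


def bce_loss(predictions: Sequence[float], labels: Sequence[float], eps: float = 1e-7) -> float:
    """Mean binary cross-entropy with predictions clipped to [eps, 1-eps]."""
    p = np.clip(np.asarray(predictions, dtype=float), eps, 1.0 - eps)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise NetworkError(f"length mismatch: {p.shape} vs {y.shape}")
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


class _Tower:
    """Per-organism feature extractor: CNN stages (+ Bi-GRU) (+ attention)."""

    def __init__(self, rng: np.random.Generator, in_length: int, cfg: ModelConfig):
        self.cfg = cfg
        self.conv: list[Layer] = []
        c_in, length = 1, in_length
        for f in cfg.filters:
            self.conv += [Conv1D(rng, c_in, f, cfg.kernel_size), ReLU(), MaxPool1D(cfg.pool_size)]
            c_in = f
            length //= cfg.pool_size
        if length < 1:
            raise NetworkError(
                f"input length {in_length} too short for {cfg.conv_layers} "
                f"pool-{cfg.pool_size} stages; need >= {cfg.pool_size ** cfg.conv_layers}"
            )
        self.n_steps = length
        self.cnn_dropout = Dropout(cfg.cnn_dropout)
        if cfg.use_bigru:
            self.bigru: BiGRU | None = BiGRU(rng, c_in, cfg.gru_hidden)
            self.gru_dropout = Dropout(cfg.gru_dropout)
            feat_dim = 2 * cfg.gru_hidden
        else:
            self.bigru = None
            feat_dim = c_in
        if cfg.use_attention:
            self.pool: Layer = Attention(rng, feat_dim, cfg.attention_units)
        else:
            self.pool = MeanPool()
        self.out_dim = feat_dim

    def layers(self) -> list[Layer]:
        out = [*self.conv, self.cnn_dropout]
        if self.bigru is not None:
            out += [self.bigru, self.gru_dropout]
        return out + [self.pool]

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        h = x[:, :, None]
        for layer in self.conv:
            h = layer.forward(h, train)
        h = self.cnn_dropout.forward(h, train, rng)
        if self.bigru is not None:
            h = self.bigru.forward(h, train)
            h = self.gru_dropout.forward(h, train, rng)
        return self.pool.forward(h, train)

    def backward(self, dpooled: np.ndarray) -> None:
        dh = self.pool.backward(dpooled)
        if self.bigru is not None:
            dh = self.gru_dropout.backward(dh)
            dh = self.bigru.backward(dh)
        dh = self.cnn_dropout.backward(dh)
        for layer in reversed(self.conv):
            dh = layer.backward(dh)


class PBIPModel:
    """Two-tower CNN/Bi-GRU/attention classifier over pair embeddings."""

    def __init__(self, config: ModelConfig, input_dim: int):
        self.config = config
        self.input_dim = input_dim
        rng = np.random.default_rng(config.seed)
        self.tower_p = _Tower(rng, input_dim, config)
        self.tower_b = self.tower_p if config.tower_sharing == "shared" else _Tower(rng, input_dim, config)
        self.final = Dense(rng, self.tower_p.out_dim + self.tower_b.out_dim, 1)

    def layers(self) -> list[Layer]:
        seen: set[int] = set()
        out: list[Layer] = []
        for layer in [*self.tower_p.layers(), *self.tower_b.layers(), self.final]:
            if id(layer) not in seen:
                seen.add(id(layer))
                out.append(layer)
        return out

    @property
    def n_params(self) -> int:
        return sum(l.n_params for l in self.layers())

    def zero_grad(self) -> None:
        for layer in self.layers():
            layer.zero_grad()

    def forward(
        self,
        x_p: np.ndarray,
        x_b: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Interaction probabilities for batched pair halves (B, d_h) each."""
        hp = self.tower_p.forward(np.asarray(x_p, dtype=float), train, rng)
        hb = self.tower_b.forward(np.asarray(x_b, dtype=float), train, rng)
        logits = self.final.forward(np.concatenate([hp, hb], axis=1), train)[:, 0]
        self._last_split = hp.shape[1]
        return sigmoid(logits)

    def backward(self, dlogits: np.ndarray) -> None:
        """Backprop from d(loss)/d(logit); call immediately after forward."""
        dcat = self.final.backward(dlogits[:, None])
        split = self._last_split
        # towers backward in reverse forward order (matters when shared)
        self.tower_b.backward(dcat[:, split:])
        self.tower_p.backward(dcat[:, :split])

    def predict(self, pairs: Sequence[PairEmbedding], batch_size: int = 256) -> np.ndarray:
        xp = np.stack([p.x_p for p in pairs])
        xb = np.stack([p.x_b for p in pairs])
        out = np.empty(len(pairs))
        for i in range(0, len(pairs), batch_size):
            out[i : i + batch_size] = self.forward(xp[i : i + batch_size], xb[i : i + batch_size])
        return out

    def classify(self, pairs: Sequence[PairEmbedding]) -> np.ndarray:
        return (self.predict(pairs) >= self.config.classification_threshold).astype(int)


def train_model(
    pairs: Sequence[PairEmbedding],
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    seed: int | None = None,
) -> tuple[PBIPModel, list[float]]:
    """Train a model on labeled pair embeddings; returns (model, loss history).

    Mini-batches are reshuffled every epoch from a seeded generator (the last
    incomplete batch is kept); dropout is active during training only.  The
    per-epoch mean training loss is recorded.  Raises on divergence.
    """
    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    if not pairs:
        raise NetworkError("no training pairs")
    if any(p.label is None for p in pairs):
        raise NetworkError("all training pairs must be labeled")
    xp = np.stack([p.x_p for p in pairs])
    xb = np.stack([p.x_b for p in pairs])
    y = np.array([p.label for p in pairs], dtype=float)

    model = PBIPModel(model_config, input_dim=xp.shape[1])
    opt = AMSGrad(model.layers(), lr=train_config.learning_rate)
    rng = np.random.default_rng(model_config.seed if seed is None else seed)
    n = len(pairs)
    history: list[float] = []
    for epoch in range(train_config.epochs):
        perm = rng.permutation(n)
        total = 0.0
        for start in range(0, n, train_config.batch_size):
            idx = perm[start : start + train_config.batch_size]
            model.zero_grad()
            p = model.forward(xp[idx], xb[idx], train=True, rng=rng)
            batch_loss = bce_loss(p, y[idx])
            if not np.isfinite(batch_loss):
                raise NetworkError(f"training diverged (non-finite loss) at epoch {epoch}")
            eps = 1e-7
            pc = np.clip(p, eps, 1.0 - eps)
            model.backward((pc - y[idx]) / len(idx))
            opt.step()
            total += batch_loss * len(idx)
        history.append(total / n)
    return model, history


@dataclass(frozen=True)
class AblationVariant:
    """A named pipeline configuration switch."""

    name: str
    use_bigru: bool = True
    use_attention: bool = True
    use_smote: bool = True

    def apply(self, config: ModelConfig) -> ModelConfig:
        return replace(config, use_bigru=self.use_bigru, use_attention=self.use_attention)


_VARIANTS = {
    "full": AblationVariant("full"),
    "PBIP3": AblationVariant("PBIP3", use_bigru=False),
    "PBIP4": AblationVariant("PBIP4", use_attention=False),
    "PBIP5": AblationVariant("PBIP5", use_smote=False),
}


def ablation_variant(name: str) -> AblationVariant:
    """Look up an ablation switch: PBIP3 = no Bi-GRU, PBIP4 = no attention,
    PBIP5 = no SMOTE augmentation; "full" = the complete model."""
    try:
        return _VARIANTS[name]
    except KeyError:
        raise NetworkError(
            f"unknown variant {name!r}; choose from {sorted(_VARIANTS)}"
        ) from None


# ---------------------------------------------------------------------------
# Persistence


def save_model(model: PBIPModel, path: str) -> None:
    """Persist parameters plus config to a single .npz archive."""
    arrays: dict[str, np.ndarray] = {}
    for i, layer in enumerate(model.layers()):
        for name, arr in layer.params.items():
            arrays[f"layer{i}_{name}"] = arr
    meta = {"config": asdict(model.config), "input_dim": model.input_dim}
    arrays["_meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path: str) -> PBIPModel:
    data = np.load(path)
    meta = json.loads(bytes(data["_meta"]).decode())
    cfg_dict = meta["config"]
    cfg_dict["filters"] = tuple(cfg_dict["filters"])
    model = PBIPModel(ModelConfig(**cfg_dict), input_dim=meta["input_dim"])
    for i, layer in enumerate(model.layers()):
        for name in layer.params:
            layer.params[name][...] = data[f"layer{i}_{name}"]
    return model
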