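import numpy as np
import pytest

from pbip.embedder import PairEmbedding
from pbip.network import ModelConfig, TrainConfig


def make_pairs(n_pos, n_neg, d_h=8, seed=0, separation=2.0):
    """Labeled pair embeddings with a linear class offset (separable for tests)."""
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n_pos + n_neg):
        label = int(i < n_pos)
        shift = separation * label
        pairs.append(
            PairEmbedding(
                phage_id=f"p{i}",
                bacterium_id=f"b{i}",
                x_p=rng.standard_normal(d_h) + shift,
                x_b=rng.standard_normal(d_h) + shift,
                label=label,
            )
        )
    return pairs


@pytest.fixture
def toy_pairs():
    return make_pairs(20, 20, d_h=8, seed=1)


def tiny_model_config(seed=0, **kw):
    """Smallest architecture the conv/pool stack allows; dropout off for determinism."""
    defaults = dict(
        filters=(2, 3),
        gru_hidden=2,
        attention_units=3,
        cnn_dropout=0.0,
        gru_dropout=0.0,
        seed=seed,
    )
    defaults.update(kw)
    return ModelConfig(**defaults)


def tiny_train_config(epochs=3, **kw):
    return TrainConfig(learning_rate=1e-2, epochs=epochs, **kw)
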