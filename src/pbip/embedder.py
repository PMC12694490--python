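"""Deep protein-sequence embeddings via a multiplicative LSTM.

A protein S = (a_1 .. a_T) is one-hot encoded over the 20-letter alphabet
(X_one, T x 20), projected through a learned token embedding W_emb (20 x d_e)
to X_emb = X_one W_emb, and run through an mLSTM with hidden size d_h.  The
protein embedding is the time-average of the hidden states,
x = (1/T) sum_t h_t, the organism embedding is the mean over its proteins,
and a phage-bacterium pair is represented by the concatenation [x_p, x_b].

The mLSTM follows the multiplicative-LSTM recurrence used by UniRep-style
protein language models: an intermediate multiplicative state

    m_t = (W_mx x_t) * (W_mh h_{t-1})

replaces h_{t-1} in the input, forget and output gates and the candidate:

    i_t = sigmoid(W_ix x_t + W_im m_t + b_i)
    f_t = sigmoid(W_fx x_t + W_fm m_t + b_f)
    o_t = sigmoid(W_ox x_t + W_om m_t + b_o)
    c~_t = tanh(W_cx x_t + W_cm m_t + b_c)
    c_t = f_t * c_{t-1} + i_t * c~_t
    h_t = o_t * tanh(c_t)

with zero initial hidden and cell states.  The canonical pretrained model uses
d_e = 10 and d_h = 1900; tests and desk-scale runs use seeded random weights
with small d_h, which the same code paths support.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .sequence_io import (
    AA_INDEX,
    AMINO_ACIDS,
    InteractionTable,
    OrganismProteome,
    ProteinSequence,
    SequenceError,
)

# Gate block order inside the stacked weight matrices.
GATES = ("i", "f", "o", "c")


class EmbedderError(ValueError):
    pass


@dataclass
class EmbedderParams:
    """Token-embedding and mLSTM weights.

    ``wx``: (d_e, 4*d_h) input-to-gates, ``wm``: (d_h, 4*d_h) m-to-gates
    (gate block order i, f, o, candidate), ``wmx``: (d_e, d_h) and
    ``wmh``: (d_h, d_h) multiplicative projections, ``b``: (4*d_h,) biases.
    """

    w_emb: np.ndarray
    wx: np.ndarray
    wm: np.ndarray
    wmx: np.ndarray
    wmh: np.ndarray
    b: np.ndarray

    @property
    def d_e(self) -> int:
        return self.w_emb.shape[1]

    @property
    def d_h(self) -> int:
        return self.wmh.shape[0]

    def __post_init__(self) -> None:
        d_e, d_h = self.d_e, self.d_h
        expected = {
            "w_emb": (20, d_e),
            "wx": (d_e, 4 * d_h),
            "wm": (d_h, 4 * d_h),
            "wmx": (d_e, d_h),
            "wmh": (d_h, d_h),
            "b": (4 * d_h,),
        }
        for name, shape in expected.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise EmbedderError(
                    f"weight {name} has shape {arr.shape}, expected {shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise EmbedderError(f"weight {name} contains non-finite entries")


def random_params(d_e: int = 10, d_h: int = 1900, seed: int = 0) -> EmbedderParams:
    """Seeded random mLSTM parameters (Gaussian, 1/sqrt(fan_in) scale).

    Used when the pretrained weight arrays are not supplied; reproducible for a
    fixed seed.
    """
    rng = np.random.default_rng(seed)

    def g(fan_in: int, *shape: int) -> np.ndarray:
        return rng.standard_normal(shape) / np.sqrt(fan_in)

    return EmbedderParams(
        w_emb=g(1, 20, d_e),
        wx=g(d_e, d_e, 4 * d_h),
        wm=g(d_h, d_h, 4 * d_h),
        wmx=g(d_e, d_e, d_h),
        wmh=g(d_h, d_h, d_h),
        b=np.zeros(4 * d_h),
    )


_WEIGHT_FILES = {
    "w_emb": "embed_matrix.npy",
    "wx": "wx.npy",
    "wm": "wh.npy",
    "wmx": "wmx.npy",
    "wmh": "wmh.npy",
    "b": "b.npy",
}


def load_pretrained_weights(
    directory: str | os.PathLike, d_e: int = 10, d_h: int = 1900
) -> EmbedderParams:
    """Load released pretrained weight arrays for the canonical 1900-unit model.

    Expects numpy array files ``embed_matrix.npy`` (20 x d_e after restriction
    to the 20 canonical residues), ``wx.npy``, ``wh.npy``, ``wmx.npy``,
    ``wmh.npy`` and ``b.npy`` in ``directory``.  Missing or mis-shaped arrays
    raise an error listing the expected shapes.
    """
    directory = Path(directory)
    arrays = {}
    expected = {
        "w_emb": (20, d_e),
        "wx": (d_e, 4 * d_h),
        "wm": (d_h, 4 * d_h),
        "wmx": (d_e, d_h),
        "wmh": (d_h, d_h),
        "b": (4 * d_h,),
    }
    for key, fname in _WEIGHT_FILES.items():
        fpath = directory / fname
        if not fpath.exists():
            raise EmbedderError(
                f"missing weight file {fname} in {directory}; expected arrays "
                f"and shapes: { {f: expected[k] for k, f in _WEIGHT_FILES.items()} }"
            )
        arr = np.load(fpath)
        if arr.shape != expected[key]:
            raise EmbedderError(
                f"weight file {fname} has shape {arr.shape}, expected {expected[key]}"
            )
        arrays[key] = arr
    return EmbedderParams(**arrays)


# ---------------------------------------------------------------------------
# Forward operations


def one_hot(sequence: ProteinSequence) -> np.ndarray:
    """One-hot encode a protein: T x 20 with row t indicating residue a_t."""
    idx = np.array([AA_INDEX[a] for a in sequence.residues], dtype=np.intp)
    out = np.zeros((len(idx), len(AMINO_ACIDS)))
    out[np.arange(len(idx)), idx] = 1.0
    return out


def decode_one_hot(x_one: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[j] for j in np.argmax(x_one, axis=1))


def project_tokens(x_one: np.ndarray, w_emb: np.ndarray) -> np.ndarray:
    """X_emb = X_one W_emb: each one-hot row selects its residue's embedding."""
    if x_one.ndim != 2 or w_emb.ndim != 2 or x_one.shape[1] != w_emb.shape[0]:
        raise EmbedderError(
            f"shape mismatch: X_one {x_one.shape} vs W_emb {w_emb.shape}"
        )
    return x_one @ w_emb


def mlstm_forward(x_emb: np.ndarray, params: EmbedderParams) -> np.ndarray:
    """Run the mLSTM over a T x d_e input; returns the T x d_h hidden states."""
    T = x_emb.shape[0]
    if T < 1:
        raise EmbedderError("empty input to mlstm_forward")
    d_h = params.d_h
    h = np.zeros(d_h)
    c = np.zeros(d_h)
    states = np.empty((T, d_h))
    for t in range(T):
        x_t = x_emb[t]
        m = (x_t @ params.wmx) * (h @ params.wmh)
        z = x_t @ params.wx + m @ params.wm + params.b
        i = _sigmoid(z[:d_h])
        f = _sigmoid(z[d_h : 2 * d_h])
        o = _sigmoid(z[2 * d_h : 3 * d_h])
        cand = np.tanh(z[3 * d_h :])
        c = f * c + i * cand
        h = o * np.tanh(c)
        if not np.all(np.isfinite(h)):
            raise EmbedderError(f"non-finite hidden state at time step {t}")
        states[t] = h
    return states


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


@dataclass(frozen=True)
class ProteinEmbedding:
    source_id: str
    vector: np.ndarray


def protein_embedding(
    sequence: ProteinSequence, params: EmbedderParams
) -> ProteinEmbedding:
    """x = (1/T) sum_t h_t: time-averaged mLSTM hidden states."""
    states = mlstm_forward(project_tokens(one_hot(sequence), params.w_emb), params)
    return ProteinEmbedding(source_id=sequence.id, vector=states.mean(axis=0))


def organism_embedding(
    embeddings: Sequence[ProteinEmbedding | np.ndarray],
) -> np.ndarray:
    """Componentwise mean of a non-empty set of protein embeddings."""
    if len(embeddings) == 0:
        raise EmbedderError("organism_embedding requires at least one protein")
    vectors = [
        e.vector if isinstance(e, ProteinEmbedding) else np.asarray(e)
        for e in embeddings
    ]
    lengths = {v.shape for v in vectors}
    if len(lengths) != 1:
        raise EmbedderError(f"mixed embedding shapes: {sorted(lengths)}")
    return np.mean(vectors, axis=0)


def embed_organism(proteome: OrganismProteome, params: EmbedderParams) -> np.ndarray:
    return organism_embedding([protein_embedding(p, params) for p in proteome.proteins])


@dataclass
class PairEmbedding:
    """Concatenated embedding [x_p, x_b] for one phage-bacterium pair.

    SMOTE-generated samples carry ``synthetic=True`` plus provenance (indices
    of the two parent positives and the interpolation coefficient alpha).
    """

    phage_id: str
    bacterium_id: str
    x_p: np.ndarray
    x_b: np.ndarray
    label: int | None = None
    synthetic: bool = False
    parent_a: int | None = None
    parent_b: int | None = None
    alpha: float | None = None

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.x_p, self.x_b])

    @property
    def d_h(self) -> int:
        return self.x_p.shape[0]


def embed_pair(
    phage: OrganismProteome, bacterium: OrganismProteome, params: EmbedderParams
) -> PairEmbedding:
    return PairEmbedding(
        phage_id=phage.id,
        bacterium_id=bacterium.id,
        x_p=embed_organism(phage, params),
        x_b=embed_organism(bacterium, params),
    )


def embed_dataset(
    phages: Iterable[OrganismProteome],
    bacteria: Iterable[OrganismProteome],
    table: InteractionTable,
    params: EmbedderParams,
) -> list[PairEmbedding]:
    """Embed every organism once and assemble labeled pair embeddings."""
    phage_vecs: Mapping[str, np.ndarray] = {
        p.id: embed_organism(p, params) for p in phages
    }
    bact_vecs: Mapping[str, np.ndarray] = {
        b.id: embed_organism(b, params) for b in bacteria
    }
    labels = table.labels()
    pairs = []
    for rec in table.records:
        if rec.phage_id not in phage_vecs:
            raise EmbedderError(f"no proteome for phage {rec.phage_id!r}")
        if rec.bacterium_id not in bact_vecs:
            raise EmbedderError(f"no proteome for bacterium {rec.bacterium_id!r}")
        pairs.append(
            PairEmbedding(
                phage_id=rec.phage_id,
                bacterium_id=rec.bacterium_id,
                x_p=phage_vecs[rec.phage_id],
                x_b=bact_vecs[rec.bacterium_id],
                label=labels[(rec.phage_id, rec.bacterium_id)],
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# Tabular persistence of pair embeddings

import pandas as pd  # noqa: E402


def pairs_to_frame(pairs: Sequence[PairEmbedding]) -> pd.DataFrame:
    if not pairs:
        raise EmbedderError("no pairs to serialize")
    d2 = 2 * pairs[0].d_h
    rows = []
    for p in pairs:
        row = {
            "phage_id": p.phage_id,
            "bacterium_id": p.bacterium_id,
            "label": p.label,
            "synthetic": int(p.synthetic),
            "parent_a": p.parent_a if p.parent_a is not None else -1,
            "parent_b": p.parent_b if p.parent_b is not None else -1,
            "alpha": p.alpha if p.alpha is not None else np.nan,
        }
        vec = p.vector
        if vec.shape[0] != d2:
            raise EmbedderError("pair vectors have inconsistent lengths")
        row.update({f"v{i}": vec[i] for i in range(d2)})
        rows.append(row)
    return pd.DataFrame(rows)


def save_pairs(pairs: Sequence[PairEmbedding], path: str | os.PathLike) -> None:
    pairs_to_frame(pairs).to_csv(path, index=False)


def load_pairs(path: str | os.PathLike) -> list[PairEmbedding]:
    df = pd.read_csv(path)
    vcols = sorted(
        (c for c in df.columns if c.startswith("v") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    d_h = len(vcols) // 2
    out = []
    for _, row in df.iterrows():
        vec = row[vcols].to_numpy(dtype=float)
        out.append(
            PairEmbedding(
                phage_id=str(row["phage_id"]),
                bacterium_id=str(row["bacterium_id"]),
                x_p=vec[:d_h],
                x_b=vec[d_h:],
                label=None if pd.isna(row["label"]) else int(row["label"]),
                synthetic=bool(row.get("synthetic", 0)),
                parent_a=None if row.get("parent_a", -1) < 0 else int(row["parent_a"]),
                parent_b=None if row.get("parent_b", -1) < 0 else int(row["parent_b"]),
                alpha=None if pd.isna(row.get("alpha", np.nan)) else float(row["alpha"]),
            )
        )
    return out
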