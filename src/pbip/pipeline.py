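"""End-to-end orchestration: simulate/load -> embed -> augment -> train -> evaluate.

A run is fully determined by a :class:`RunConfig`: one global seed fans out to
deterministic per-stage sub-seeds (a CRC of the stage name mixed with the
seed), so any stage can be re-run in isolation and a repeated run reproduces
its metrics exactly on the same machine.  Every run directory receives the
resolved config snapshot, the pair-embedding table, the trained model, the
loss history, a metrics report and a log with per-stage row counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import embedder as emb
from .augmentation import SmoteConfig, balance_with_smote, passthrough
from .evaluation import evaluate_predictions
from .network import (
    ModelConfig,
    TrainConfig,
    ablation_variant,
    save_model,
    train_model,
)
from .sequence_io import InteractionTable, load_interaction_table, load_proteomes
from .synthetic_data import downscale_profile, generate_dataset

logger = logging.getLogger("pbip")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed derived from the global seed."""
    return (zlib.crc32(stage.encode()) ^ (global_seed * 2654435761)) % (2**31)


@dataclass
class RunConfig:
    # input: either a simulation profile or directories of FASTA + interaction CSV
    simulate_profile: str | None = "desk"
    phages_fasta: str | None = None
    bacteria_fasta: str | None = None
    interactions: str | None = None
    # embedding
    embedder_weights: str | None = None  # directory of pretrained arrays, else random
    d_h: int = 16
    d_e: int = 10
    # stages
    smote: SmoteConfig = field(default_factory=SmoteConfig)
    model: ModelConfig = field(default_factory=ModelConfig.reduced)
    train: TrainConfig = field(default_factory=TrainConfig.reduced)
    test_fraction: float = 0.25
    variant: str = "full"
    seed: int = 0

    def resolved(self) -> dict:
        out = dataclasses.asdict(self)
        return out


def _stratified_split(labels: np.ndarray, test_fraction: float, rng: np.random.Generator):
    test_idx: list[int] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        n_test = max(1, int(round(test_fraction * len(idx))))
        test_idx.extend(rng.permutation(idx)[:n_test].tolist())
    mask = np.zeros(len(labels), dtype=bool)
    mask[test_idx] = True
    return np.flatnonzero(~mask), np.flatnonzero(mask)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline; returns the metrics dict and writes artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path) -> dict:
    variant = ablation_variant(config.variant)
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(config.resolved(), fh, default_flow_style=None)

    # --- stage: data
    if config.simulate_profile is not None:
        sim_cfg = downscale_profile(
            config.simulate_profile, seed=stage_seed(config.seed, "simulate")
        )
        data = generate_dataset(sim_cfg, out_dir=out / "data")
        phages, bacteria, table = data.phages, data.bacteria, data.table
        logger.info("simulate: %d phages, %d bacteria, %d records",
                    len(phages), len(bacteria), len(table))
    else:
        if not (config.phages_fasta and config.bacteria_fasta and config.interactions):
            raise ValueError("either simulate_profile or input paths must be set")
        phages = load_proteomes(config.phages_fasta, "phage")
        bacteria = load_proteomes(config.bacteria_fasta, "bacterium")
        table = load_interaction_table(config.interactions)
        logger.info("load: %d phages, %d bacteria, %d records",
                    len(phages), len(bacteria), len(table))

    # --- stage: embed
    if config.embedder_weights:
        params = emb.load_pretrained_weights(config.embedder_weights)
    else:
        params = emb.random_params(
            d_e=config.d_e, d_h=config.d_h, seed=stage_seed(config.seed, "embed")
        )
    pairs = emb.embed_dataset(phages, bacteria, table, params)
    emb.save_pairs(pairs, out / "pairs.csv")
    logger.info("embed: %d pairs, d_h=%d", len(pairs), params.d_h)

    # --- stage: split
    labels = np.array([p.label for p in pairs], dtype=int)
    rng = np.random.default_rng(stage_seed(config.seed, "split"))
    train_idx, test_idx = _stratified_split(labels, config.test_fraction, rng)
    train_pairs = [pairs[i] for i in train_idx]
    test_pairs = [pairs[i] for i in test_idx]
    logger.info("split: %d train / %d test pairs", len(train_pairs), len(test_pairs))

    # --- stage: augment
    if variant.use_smote:
        smote_cfg = dataclasses.replace(
            config.smote, seed=stage_seed(config.seed, "augment")
        )
        augmented = balance_with_smote(train_pairs, smote_cfg)
        logger.info("augment: %d -> %d training pairs (SMOTE)",
                    len(train_pairs), len(augmented))
    else:
        augmented = passthrough(train_pairs)
        logger.info("augment: skipped (variant %s)", variant.name)
    emb.save_pairs(augmented, out / "train_pairs.csv")

    # --- stage: train
    model_cfg = variant.apply(
        dataclasses.replace(config.model, seed=stage_seed(config.seed, "train"))
    )
    model, history = train_model(
        augmented, model_cfg, config.train, seed=stage_seed(config.seed, "train")
    )
    save_model(model, str(out / "model.npz"))
    with open(out / "loss_history.csv", "w") as fh:
        fh.write("epoch,loss\n")
        fh.writelines(f"{i},{loss}\n" for i, loss in enumerate(history))
    logger.info("train: %d epochs, final loss %.4f", len(history),
                history[-1] if history else float("nan"))

    # --- stage: evaluate
    scores = model.predict(test_pairs)
    report = evaluate_predictions(scores, [p.label for p in test_pairs])
    metrics = report.to_dict()
    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2)
    with open(out / "scores.csv", "w") as fh:
        fh.write("phage_id,bacterium_id,score,label_at_threshold\n")
        thr = model.config.classification_threshold
        for p, s in zip(test_pairs, scores):
            fh.write(f"{p.phage_id},{p.bacterium_id},{s},{int(s >= thr)}\n")
    logger.info("evaluate: %s", {k: round(v, 4) for k, v in metrics.items()})
    return metrics
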