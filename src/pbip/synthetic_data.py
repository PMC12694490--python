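"""Desk-scale synthetic phage/bacterium proteomes with a planted interaction signal.

Each organism receives a hidden motif class; a fixed class-specific motif
string (default length 8) is spliced into one of its proteins at a random
position, over an otherwise i.i.d. background of the 20 amino acids.  The
interaction label of a (phage, bacterium) pair is a lookup in a binary
compatibility matrix over the two classes, optionally flipped with a small
noise probability, and the emitted matrix is complete.

The default profiles use a *nested* host-range compatibility rule (positive
iff phage class index + bacterium class index reaches a threshold; in the
2-class case, "infective phage AND susceptible bacterium").  Real phage-
bacteria infection matrices are famously nested - generalist phages infect
many strains and sensitive strains are infected by many phages - and a nested
rule also keeps the planted signal expressible by a classifier that combines
the two organisms additively, which is how the final fully connected layer
combines the phage and bacterium towers.  An arbitrary compatibility matrix
(e.g. identity, which is NOT additively expressible) can still be configured
explicitly for generator-level tests.

Profiles:

- ``unit``: 6 x 6 organisms, 2 proteins each, lengths 30-60 (fast unit tests)
- ``desk``: 40 x 40 organisms, 3-6 proteins, lengths 80-200, ~25% positives
- ``paper-shape``: 104 phages x 120 bacteria (12 480 records) with class
  probabilities set so the expected positive rate is ~7.2%, mimicking the
  sparsity of the strain-level interaction matrix.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sequence_io import (
    AMINO_ACIDS,
    InteractionRecord,
    InteractionTable,
    OrganismProteome,
    ProteinSequence,
    save_interaction_table,
    write_proteomes,
)


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    n_phages: int = 40
    n_bacteria: int = 40
    proteins_per_organism: tuple[int, int] = (3, 6)
    protein_length: tuple[int, int] = (80, 200)
    n_motif_classes: int = 2
    motif_length: int = 8
    compatibility: np.ndarray | None = None
    phage_class_probs: np.ndarray | None = None
    bacterium_class_probs: np.ndarray | None = None
    background_frequencies: np.ndarray | None = None
    positive_rate_target: float | None = None
    noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        c = self.n_motif_classes
        if self.compatibility is None:
            # nested host-range rule: top class pair(s) interact
            i = np.arange(c)
            self.compatibility = (i[:, None] + i[None, :] >= 2 * (c - 1)).astype(int)
        self.compatibility = np.asarray(self.compatibility, dtype=int)
        if self.compatibility.shape != (c, c):
            raise SimulationError(
                f"compatibility must be {c}x{c}, got {self.compatibility.shape}"
            )
        for attr in ("phage_class_probs", "bacterium_class_probs"):
            p = getattr(self, attr)
            p = np.full(c, 1.0 / c) if p is None else np.asarray(p, dtype=float)
            if p.shape != (c,) or abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
                raise SimulationError(f"{attr} must be {c} probabilities summing to 1")
            setattr(self, attr, p)
        bg = self.background_frequencies
        bg = np.full(20, 0.05) if bg is None else np.asarray(bg, dtype=float)
        if bg.shape != (20,) or abs(bg.sum() - 1.0) > 1e-9 or np.any(bg < 0):
            raise SimulationError("background_frequencies must be 20 values summing to 1")
        self.background_frequencies = bg
        if not 0.0 <= self.noise_rate <= 1.0:
            raise SimulationError("noise_rate must lie in [0, 1]")
        if self.motif_length >= self.protein_length[0]:
            raise SimulationError(
                f"motif length {self.motif_length} must be shorter than the "
                f"minimum protein length {self.protein_length[0]}"
            )

    @property
    def expected_positive_rate(self) -> float:
        """Pre-noise expected positive fraction under the class priors."""
        base = float(
            self.phage_class_probs @ self.compatibility @ self.bacterium_class_probs
        )
        return base * (1 - self.noise_rate) + (1 - base) * self.noise_rate


@dataclass
class SyntheticDataset:
    phages: list[OrganismProteome]
    bacteria: list[OrganismProteome]
    table: InteractionTable
    ground_truth: pd.DataFrame  # organism_id, role, motif_class, protein_index, insert_position
    motifs: dict[str, list[str]]  # role -> per-class motif strings
    config: SimulationConfig


def _random_sequence(rng: np.random.Generator, length: int, freqs: np.ndarray) -> str:
    idx = rng.choice(20, size=length, p=freqs)
    return "".join(AMINO_ACIDS[i] for i in idx)


def _make_organism(
    rng: np.random.Generator,
    org_id: str,
    role: str,
    motif: str,
    config: SimulationConfig,
) -> tuple[OrganismProteome, int, int]:
    n_prot = int(rng.integers(config.proteins_per_organism[0], config.proteins_per_organism[1] + 1))
    carrier = int(rng.integers(0, n_prot))
    proteins = []
    insert_pos = -1
    for j in range(n_prot):
        length = int(rng.integers(config.protein_length[0], config.protein_length[1] + 1))
        if j == carrier:
            back = _random_sequence(rng, length - config.motif_length, config.background_frequencies)
            insert_pos = int(rng.integers(0, len(back) + 1))
            residues = back[:insert_pos] + motif + back[insert_pos:]
        else:
            residues = _random_sequence(rng, length, config.background_frequencies)
        proteins.append(ProteinSequence(id=f"prot{j}", residues=residues))
    return (
        OrganismProteome(id=org_id, role=role, proteins=tuple(proteins)),
        carrier,
        insert_pos,
    )


def generate_dataset(
    config: SimulationConfig, out_dir: str | os.PathLike | None = None
) -> SyntheticDataset:
    """Generate proteomes, a complete labeled interaction matrix and ground truth.

    All randomness flows from ``config.seed``; two calls with the same config
    produce byte-identical outputs.  When ``out_dir`` is given, writes
    ``phages.fasta``, ``bacteria.fasta``, ``interactions.csv`` and
    ``ground_truth.csv``.
    """
    rng = np.random.default_rng(config.seed)
    c = config.n_motif_classes
    motifs = {
        role: [
            _random_sequence(rng, config.motif_length, np.full(20, 0.05))
            for _ in range(c)
        ]
        for role in ("phage", "bacterium")
    }
    truth_rows = []
    organisms: dict[str, list[OrganismProteome]] = {"phage": [], "bacterium": []}
    classes: dict[str, list[int]] = {"phage": [], "bacterium": []}
    for role, n, probs in (
        ("phage", config.n_phages, config.phage_class_probs),
        ("bacterium", config.n_bacteria, config.bacterium_class_probs),
    ):
        for i in range(n):
            cls = int(rng.choice(c, p=probs))
            org, carrier, pos = _make_organism(
                rng, f"{role}{i:03d}", role, motifs[role][cls], config
            )
            organisms[role].append(org)
            classes[role].append(cls)
            truth_rows.append(
                {
                    "organism_id": org.id,
                    "role": role,
                    "motif_class": cls,
                    "protein_index": carrier,
                    "insert_position": pos,
                }
            )
    records = []
    for i, phage in enumerate(organisms["phage"]):
        for j, bact in enumerate(organisms["bacterium"]):
            y = int(config.compatibility[classes["phage"][i], classes["bacterium"][j]])
            if config.noise_rate > 0 and rng.random() < config.noise_rate:
                y = 1 - y
            records.append(
                InteractionRecord(phage_id=phage.id, bacterium_id=bact.id, label=y)
            )
    table = InteractionTable(
        records=records,
        phage_ids=[p.id for p in organisms["phage"]],
        bacterium_ids=[b.id for b in organisms["bacterium"]],
    )
    dataset = SyntheticDataset(
        phages=organisms["phage"],
        bacteria=organisms["bacterium"],
        table=table,
        ground_truth=pd.DataFrame(truth_rows),
        motifs=motifs,
        config=config,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_proteomes(out / "phages.fasta", dataset.phages)
        write_proteomes(out / "bacteria.fasta", dataset.bacteria)
        save_interaction_table(table, out / "interactions.csv")
        dataset.ground_truth.to_csv(out / "ground_truth.csv", index=False)
    return dataset


_P_AND = 0.269  # P(top class) per role for the AND rule -> ~7.23% positives


def downscale_profile(name: str, seed: int = 0) -> SimulationConfig:
    """Named study-scale configurations: ``unit``, ``desk``, ``paper-shape``."""
    if name == "unit":
        return SimulationConfig(
            n_phages=6,
            n_bacteria=6,
            proteins_per_organism=(2, 2),
            protein_length=(30, 60),
            seed=seed,
        )
    if name == "desk":
        return SimulationConfig(seed=seed)
    if name == "paper-shape":
        return SimulationConfig(
            n_phages=104,
            n_bacteria=120,
            phage_class_probs=np.array([1 - _P_AND, _P_AND]),
            bacterium_class_probs=np.array([1 - _P_AND, _P_AND]),
            positive_rate_target=0.072,
            seed=seed,
        )
    raise SimulationError(f"unknown profile {name!r}; choose unit, desk or paper-shape")


def strain_matrix_like(
    n_phages: int = 104,
    n_bacteria: int = 125,
    n_positive: int = 938,
    n_fully_resistant: int = 5,
) -> InteractionTable:
    """Synthetic label-only matrix matching published strain-level summary counts.

    Builds a complete phage x bacterium interaction table with exactly
    ``n_positive`` positives, the last ``n_fully_resistant`` bacteria fully
    resistant (no positives) and every other bacterium susceptible to at least
    one phage.  Positives are spread deterministically (round-robin) across
    the susceptible strains; this is a stand-in reconstruction for dataset
    arithmetic, not real interaction data.
    """
    n_susceptible = n_bacteria - n_fully_resistant
    if n_positive > n_phages * n_susceptible or n_positive < n_susceptible:
        raise SimulationError("cannot place positives under the given constraints")
    base, extra = divmod(n_positive, n_susceptible)
    positives: set[tuple[int, int]] = set()
    for j in range(n_susceptible):
        count = base + (1 if j < extra else 0)
        start = (j * base) % n_phages
        for k in range(count):
            positives.add(((start + k) % n_phages, j))
    assert len(positives) == n_positive
    records = [
        InteractionRecord(
            phage_id=f"phage{i:03d}",
            bacterium_id=f"bact{j:03d}",
            label=int((i, j) in positives and j < n_susceptible),
        )
        for i in range(n_phages)
        for j in range(n_bacteria)
    ]
    return InteractionTable(
        records=records,
        phage_ids=[f"phage{i:03d}" for i in range(n_phages)],
        bacterium_ids=[f"bact{j:03d}" for j in range(n_bacteria)],
    )


def concatenated_proteome(organism: OrganismProteome) -> str:
    """All proteins joined into one string, for sketch-similarity auditing."""
    return "".join(p.residues for p in organism.proteins)
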