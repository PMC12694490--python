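"""Reading, validating and organizing protein sequences and interaction records.

A phage-bacterium interaction dataset consists of per-organism protein sets
(proteomes) and a labeled interaction matrix.  Labels either come in directly
as 0/1 or are derived from replicate plaque assay scores via a consensus rule:
an interaction is positive when at least ``min_positive_replicates`` replicate
scores strictly exceed ``score_threshold``.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino acids, in the fixed ordering used throughout the
#: package (one-hot index 0 is A, index 19 is V).
AMINO_ACIDS = "ARNDCEQGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Residue codes that are legal in FASTA but outside the canonical alphabet.
NONSTANDARD = set("XBZUJO*")

CanonPolicy = Literal["drop_nonstandard", "reject"]


class SequenceError(ValueError):
    """Malformed or non-canonical sequence input."""


class InteractionTableError(ValueError):
    """Invalid interaction table (duplicates, missing labels, incomplete matrix)."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein as an identifier plus a residue string S = (a_1 .. a_T)."""

    id: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"protein {self.id!r} has an empty residue string")
        bad = set(self.residues) - set(AMINO_ACIDS)
        if bad:
            raise SequenceError(
                f"protein {self.id!r} contains non-canonical residues {sorted(bad)}"
            )


@dataclass(frozen=True)
class OrganismProteome:
    """A phage or bacterium together with its ordered protein set."""

    id: str
    role: Literal["phage", "bacterium"]
    proteins: tuple[ProteinSequence, ...]

    @property
    def count(self) -> int:
        return len(self.proteins)

    def __post_init__(self) -> None:
        if self.role not in ("phage", "bacterium"):
            raise ValueError(f"unknown role {self.role!r}")
        if not self.proteins:
            raise SequenceError(f"organism {self.id!r} has no proteins")


def canonicalize(residues: str, policy: CanonPolicy = "drop_nonstandard") -> str:
    """Uppercase a residue string and apply the non-standard-residue policy.

    ``drop_nonstandard`` removes positions with codes outside the 20-letter
    alphabet; ``reject`` raises on the first such code.
    """
    up = residues.upper().replace(" ", "").replace("\n", "")
    keep = []
    for ch in up:
        if ch in AA_INDEX:
            keep.append(ch)
        elif policy == "reject":
            raise SequenceError(f"non-standard residue {ch!r} under policy 'reject'")
        elif ch not in NONSTANDARD:
            raise SequenceError(f"unrecognized residue code {ch!r}")
    return "".join(keep)


def parse_protein_fasta(
    path: str | os.PathLike, policy: CanonPolicy = "drop_nonstandard"
) -> list[ProteinSequence]:
    """Parse a protein FASTA file into canonicalized :class:`ProteinSequence`.

    Record order is preserved.  An empty file is an error, as is a record whose
    residues are all non-canonical under the drop policy.
    """
    seqs: list[ProteinSequence] = []
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            residues = canonicalize(str(rec.seq), policy)
            if not residues:
                raise SequenceError(
                    f"record {rec.id!r} in {path} has no canonical residues"
                )
            seqs.append(ProteinSequence(id=rec.id, residues=residues))
    if not seqs:
        raise SequenceError(f"no FASTA records found in {path}")
    return seqs


def write_protein_fasta(path: str | os.PathLike, seqs: Iterable[ProteinSequence]) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta-2line")


def load_proteomes(
    path: str | os.PathLike,
    role: Literal["phage", "bacterium"],
    policy: CanonPolicy = "drop_nonstandard",
) -> list[OrganismProteome]:
    """Load one FASTA holding a whole role's proteomes.

    Record ids follow ``<organism_id>|<protein_id>``; consecutive records with
    the same organism id form one proteome.
    """
    by_org: dict[str, list[ProteinSequence]] = {}
    for seq in parse_protein_fasta(path, policy):
        org_id, _, prot_id = seq.id.partition("|")
        by_org.setdefault(org_id, []).append(
            ProteinSequence(id=prot_id or seq.id, residues=seq.residues)
        )
    return [
        OrganismProteome(id=org, role=role, proteins=tuple(prots))
        for org, prots in by_org.items()
    ]


def write_proteomes(path: str | os.PathLike, organisms: Iterable[OrganismProteome]) -> None:
    flat = [
        ProteinSequence(id=f"{org.id}|{p.id}", residues=p.residues)
        for org in organisms
        for p in org.proteins
    ]
    write_protein_fasta(path, flat)


# ---------------------------------------------------------------------------
# Interaction records


def consensus_label(
    replicate_scores: Sequence[float],
    score_threshold: float = 1.5,
    min_positive_replicates: int = 2,
) -> int:
    """Consensus label from replicate plaque scores.

    Returns 1 iff at least ``min_positive_replicates`` scores are *strictly*
    greater than ``score_threshold`` (a score exactly at the threshold counts
    as negative), else 0.
    """
    if len(replicate_scores) == 0:
        raise ValueError("consensus_label requires at least one replicate score")
    n_pos = sum(1 for s in replicate_scores if s > score_threshold)
    return int(n_pos >= min_positive_replicates)


@dataclass(frozen=True)
class InteractionRecord:
    phage_id: str
    bacterium_id: str
    label: int | None = None
    replicate_scores: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.label is None and self.replicate_scores is None:
            raise InteractionTableError(
                f"record ({self.phage_id},{self.bacterium_id}) has neither a "
                "label nor replicate scores"
            )
        if self.label is not None and self.label not in (0, 1):
            raise InteractionTableError(
                f"label for ({self.phage_id},{self.bacterium_id}) must be 0 or 1"
            )


@dataclass
class InteractionTable:
    """Labeled phage x bacterium records with ordered unique id lists."""

    records: list[InteractionRecord]
    phage_ids: list[str] = field(default_factory=list)
    bacterium_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for r in self.records:
            key = (r.phage_id, r.bacterium_id)
            if key in seen:
                raise InteractionTableError(f"duplicate pair {key}")
            seen.add(key)
        if not self.phage_ids:
            self.phage_ids = list(dict.fromkeys(r.phage_id for r in self.records))
        if not self.bacterium_ids:
            self.bacterium_ids = list(
                dict.fromkeys(r.bacterium_id for r in self.records)
            )
        known_p, known_b = set(self.phage_ids), set(self.bacterium_ids)
        for r in self.records:
            if r.phage_id not in known_p or r.bacterium_id not in known_b:
                raise InteractionTableError(
                    f"record ({r.phage_id},{r.bacterium_id}) uses an id missing "
                    "from the id lists"
                )

    def __len__(self) -> int:
        return len(self.records)

    def labels(self) -> dict[tuple[str, str], int]:
        out: dict[tuple[str, str], int] = {}
        for r in self.records:
            y = r.label
            if y is None:
                y = consensus_label(r.replicate_scores)
            out[(r.phage_id, r.bacterium_id)] = y
        return out

    def is_complete(self) -> bool:
        return len(self.records) == len(self.phage_ids) * len(self.bacterium_ids)

    def to_frame(self) -> pd.DataFrame:
        labels = self.labels()
        return pd.DataFrame(
            {
                "phage_id": [r.phage_id for r in self.records],
                "bacterium_id": [r.bacterium_id for r in self.records],
                "label": [labels[(r.phage_id, r.bacterium_id)] for r in self.records],
            }
        )


def load_interaction_table(path: str | os.PathLike) -> InteractionTable:
    """Load an interaction table from CSV/TSV.

    Requires header columns ``phage_id`` and ``bacterium_id`` plus either a
    ``label`` column or one or more ``score_*`` replicate columns (labels are
    then resolved with :func:`consensus_label`).
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    required = {"phage_id", "bacterium_id"}
    if not required.issubset(df.columns):
        raise InteractionTableError(
            f"{path}: missing required columns {sorted(required - set(df.columns))}"
        )
    score_cols = [c for c in df.columns if c.startswith("score")]
    records: list[InteractionRecord] = []
    for _, row in df.iterrows():
        if "label" in df.columns and not pd.isna(row["label"]):
            records.append(
                InteractionRecord(
                    phage_id=str(row["phage_id"]),
                    bacterium_id=str(row["bacterium_id"]),
                    label=int(row["label"]),
                )
            )
        elif score_cols:
            scores = tuple(float(row[c]) for c in score_cols)
            records.append(
                InteractionRecord(
                    phage_id=str(row["phage_id"]),
                    bacterium_id=str(row["bacterium_id"]),
                    label=consensus_label(scores),
                    replicate_scores=scores,
                )
            )
        else:
            raise InteractionTableError(
                f"{path}: row ({row['phage_id']},{row['bacterium_id']}) has no "
                "label and no score columns"
            )
    return InteractionTable(records=records)


def save_interaction_table(table: InteractionTable, path: str | os.PathLike) -> None:
    table.to_frame().to_csv(path, index=False)


def matrix_statistics(table: InteractionTable) -> dict[str, float]:
    """Summary statistics of a complete interaction matrix.

    Returns total pair count, positive count, positive fraction in percent, and
    mean positives per phage / per bacterium, fractions rounded to 2 decimals.
    """
    n_p, n_b = len(table.phage_ids), len(table.bacterium_ids)
    if not table.is_complete():
        missing = _missing_pairs(table)
        raise InteractionTableError(
            f"incomplete matrix: {len(missing)} missing pairs, e.g. {missing[:3]}"
        )
    labels = table.labels()
    positives = sum(labels.values())
    total = n_p * n_b
    return {
        "n_phages": n_p,
        "n_bacteria": n_b,
        "total": total,
        "positives": positives,
        "positive_fraction_pct": round(100.0 * positives / total, 2),
        "mean_positives_per_phage": round(positives / n_p, 2),
        "mean_positives_per_bacterium": round(positives / n_b, 2),
    }


def _missing_pairs(table: InteractionTable) -> list[tuple[str, str]]:
    have = {(r.phage_id, r.bacterium_id) for r in table.records}
    return [
        (p, b)
        for p in table.phage_ids
        for b in table.bacterium_ids
        if (p, b) not in have
    ]


def drop_fully_resistant_strains(table: InteractionTable) -> InteractionTable:
    """Remove bacteria with zero positive interactions (fully resistant strains).

    Requires a complete matrix; returns a new complete table over the remaining
    bacteria.  Idempotent.
    """
    if not table.is_complete():
        raise InteractionTableError("drop_fully_resistant_strains needs a complete matrix")
    labels = table.labels()
    pos_by_bact: dict[str, int] = {b: 0 for b in table.bacterium_ids}
    for (p, b), y in labels.items():
        pos_by_bact[b] += y
    keep = [b for b in table.bacterium_ids if pos_by_bact[b] > 0]
    keep_set = set(keep)
    records = [r for r in table.records if r.bacterium_id in keep_set]
    return InteractionTable(
        records=records,
        phage_ids=list(table.phage_ids),
        bacterium_ids=keep,
    )
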