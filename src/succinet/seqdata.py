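"""Sequence and site-label handling.

Candidate succinylation sites are lysine (K) residues. Each site is
represented by a fixed 33-residue window centred on the target lysine
(16 residues upstream, 16 downstream); windows that run past a sequence
end are padded with ``'X'``, which doubles as the "missing amino acid"
token of the 21-letter model alphabet.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

#: Canonical amino acids, alphabetical. Index 20 is the pad / unknown token.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
PAD_CHAR = "X"
PAD_TOKEN = 20
VOCAB_SIZE = 21

#: Window geometry: 16-K-16.
HALF_WIDTH = 16
WINDOW_LENGTH = 2 * HALF_WIDTH + 1

_TOKEN_OF = {aa: i for i, aa in enumerate(ALPHABET)}


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")


@dataclass(frozen=True)
class SiteRecord:
    """One labelled candidate site (1-based position within the protein)."""

    protein_id: str
    position: int
    label: int
    window: str

    def __post_init__(self) -> None:
        if len(self.window) != WINDOW_LENGTH:
            raise ValueError(
                f"window must have length {WINDOW_LENGTH}, got {len(self.window)}"
            )
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


@dataclass
class DatasetSplit:
    train: list[SiteRecord]
    validation: list[SiteRecord]
    fold_assignments: dict[tuple[str, int], int] | None = field(default=None)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into ProteinRecords.

    Sequences are uppercased with whitespace stripped. Duplicate ids and
    empty files are errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id!r}")
        seen.add(rec.id)
        seq = "".join(str(rec.seq).split()).upper()
        records.append(ProteinRecord(rec.id, seq))
    if not records:
        raise ValueError(f"no records in FASTA file {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def extract_window(
    sequence: str, position: int, half_width: int = HALF_WIDTH, pad: str = PAD_CHAR
) -> str:
    """Fixed window of length 2*half_width+1 centred on a 1-based position.

    Out-of-range flanks are filled with the pad character; the centre
    character always equals ``sequence[position-1]``.
    """
    if not 1 <= position <= len(sequence):
        raise ValueError(
            f"position {position} out of range for sequence of length {len(sequence)}"
        )
    i = position - 1
    left = sequence[max(0, i - half_width) : i]
    right = sequence[i + 1 : i + 1 + half_width]
    return (
        pad * (half_width - len(left))
        + left
        + sequence[i]
        + right
        + pad * (half_width - len(right))
    )


def encode_window(window: str) -> np.ndarray:
    """Map a window string to integer tokens in [0, 20].

    Canonical residues map to their alphabetical index; 'X' and any
    non-canonical letter (B, J, O, U, Z, ...) map to the shared token 20.
    """
    if len(window) != WINDOW_LENGTH:
        raise ValueError(f"window must have length {WINDOW_LENGTH}")
    return np.array([_TOKEN_OF.get(c, PAD_TOKEN) for c in window], dtype=np.int64)


def decode_tokens(tokens: Sequence[int]) -> str:
    """Inverse of :func:`encode_window` over the 21-letter alphabet."""
    return "".join(
        PAD_CHAR if t == PAD_TOKEN else ALPHABET[int(t)] for t in tokens
    )


def encode_windows(records: Sequence[SiteRecord]) -> np.ndarray:
    """Stack encoded windows for a batch of records, shape (n, 33)."""
    return np.stack([encode_window(r.window) for r in records])


def labels_of(records: Sequence[SiteRecord]) -> np.ndarray:
    return np.array([r.label for r in records], dtype=np.int64)


def build_site_dataset(
    proteins: Sequence[ProteinRecord],
    positive_sites: Iterable[tuple[str, int]],
) -> list[SiteRecord]:
    """Enumerate every lysine as a candidate site.

    A site is positive iff listed in ``positive_sites``; all other lysines
    are negatives. A positive that does not address a lysine is an error.
    """
    positives = set(positive_sites)
    by_id = {p.id: p for p in proteins}
    for pid, pos in positives:
        prot = by_id.get(pid)
        if prot is None or not 1 <= pos <= len(prot.sequence) or prot.sequence[pos - 1] != "K":
            raise ValueError(f"positive site ({pid!r}, {pos}) is not a lysine residue")
    records: list[SiteRecord] = []
    for prot in proteins:
        for i, aa in enumerate(prot.sequence):
            if aa == "K":
                pos = i + 1
                records.append(
                    SiteRecord(
                        protein_id=prot.id,
                        position=pos,
                        label=int((prot.id, pos) in positives),
                        window=extract_window(prot.sequence, pos),
                    )
                )
    return records


def balance_undersample(records: Sequence[SiteRecord], seed: int) -> list[SiteRecord]:
    """Balance classes by randomly undersampling negatives (without replacement).

    All positives are kept. If positives already outnumber negatives, the
    input is returned with a warning.
    """
    pos = [r for r in records if r.label == 1]
    neg = [r for r in records if r.label == 0]
    if not pos:
        raise ValueError("no positive records to balance against")
    if len(pos) > len(neg):
        warnings.warn("more positives than negatives; keeping all negatives")
        return list(records)
    rng = np.random.default_rng(seed)
    keep = rng.choice(len(neg), size=len(pos), replace=False)
    out = pos + [neg[i] for i in sorted(keep)]
    return out


def split_stratified(
    records: Sequence[SiteRecord], validation_fraction: float = 0.1, seed: int = 0
) -> DatasetSplit:
    """Stratified train/validation split preserving the class ratio.

    Class proportions in both parts match the input within one record
    per class.
    """
    if not 0 < validation_fraction < 1:
        raise ValueError("validation_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list[SiteRecord] = []
    val: list[SiteRecord] = []
    for cls in (0, 1):
        members = [r for r in records if r.label == cls]
        n_val = int(round(validation_fraction * len(members)))
        order = rng.permutation(len(members))
        val.extend(members[i] for i in sorted(order[:n_val]))
        train.extend(members[i] for i in sorted(order[n_val:]))
    return DatasetSplit(train=train, validation=val)


def make_imbalanced_validation_sets(
    validation: Sequence[SiteRecord],
    n_sets: int = 10,
    positive_removal: float = 0.9,
    seed: int = 0,
) -> list[list[SiteRecord]]:
    """Build class-imbalanced evaluation sets from a balanced validation set.

    Each output set keeps every negative and an independent random
    ceil((1 - positive_removal) * P) subset of positives.
    """
    if not 0 <= positive_removal < 1:
        raise ValueError("positive_removal must be in [0, 1)")
    pos = [r for r in validation if r.label == 1]
    neg = [r for r in validation if r.label == 0]
    n_keep = int(np.ceil((1.0 - positive_removal) * len(pos)))
    rng = np.random.default_rng(seed)
    sets: list[list[SiteRecord]] = []
    for _ in range(n_sets):
        keep = rng.choice(len(pos), size=n_keep, replace=False)
        sets.append([pos[i] for i in sorted(keep)] + list(neg))
    return sets


# ---------------------------------------------------------------------------
# TSV interchange: protein_id <tab> position <tab> label [<tab> window]

def read_site_labels(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a site-label TSV (header: protein_id, position, label)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    for col in ("protein_id", "position", "label"):
        if col not in df.columns:
            raise ValueError(f"site TSV missing column {col!r}")
    return [
        (str(r.protein_id), int(r.position), int(r.label))
        for r in df.itertuples(index=False)
    ]


def write_site_records(records: Sequence[SiteRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in records],
            "position": [r.position for r in records],
            "label": [r.label for r in records],
            "window": [r.window for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_site_records(path: str | Path) -> list[SiteRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    if "window" not in df.columns:
        raise ValueError("record TSV missing 'window' column")
    return [
        SiteRecord(str(r.protein_id), int(r.position), int(r.label), str(r.window))
        for r in df.itertuples(index=False)
    ]
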