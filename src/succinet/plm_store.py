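"""Storage of per-protein, per-residue language-model embeddings.

Embeddings are stored for whole proteins (an L x D float32 matrix per
protein id) so one archive serves every candidate site of a protein. The
on-disk format is a keyed ``.npz`` archive plus a JSON sidecar recording
the embedding width and the producing model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class EmbeddingTable:
    entries: dict[str, np.ndarray] = field(default_factory=dict)
    width: int | None = None
    model: str = "unknown"

    def __post_init__(self) -> None:
        for pid, mat in self.entries.items():
            mat = np.asarray(mat, dtype=np.float32)
            if mat.ndim != 2:
                raise ValueError(f"embedding for {pid!r} must be 2-D (L x D)")
            if self.width is None:
                self.width = mat.shape[1]
            elif mat.shape[1] != self.width:
                raise ValueError(
                    f"embedding width mismatch for {pid!r}: "
                    f"{mat.shape[1]} != {self.width}"
                )
            self.entries[pid] = mat

    def __len__(self) -> int:
        return len(self.entries)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_embeddings(table: EmbeddingTable, path: str | Path) -> None:
    """Write an EmbeddingTable to a keyed .npz archive with a JSON sidecar."""
    if not table.entries:
        raise ValueError("no entries in embedding table")
    path = Path(path)
    np.savez(path, **{pid: m.astype(np.float32) for pid, m in table.entries.items()})
    meta = {"width": int(table.width), "model": table.model}
    _sidecar_path(path).write_text(json.dumps(meta))


def read_embeddings(path: str | Path) -> EmbeddingTable:
    """Lossless (float32) read-back of :func:`write_embeddings` output."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with np.load(path) as npz:
        entries = {pid: npz[pid] for pid in npz.files}
    model = "unknown"
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        model = json.loads(sidecar.read_text()).get("model", "unknown")
    return EmbeddingTable(entries=entries, model=model)


def target_embedding(table: EmbeddingTable, protein_id: str, position: int) -> np.ndarray:
    """Per-residue embedding row of the target site (1-based position)."""
    if protein_id not in table.entries:
        raise KeyError(f"no embeddings for protein {protein_id!r}")
    mat = table.entries[protein_id]
    if not 1 <= position <= mat.shape[0]:
        raise IndexError(
            f"position {position} out of range for {protein_id!r} (L={mat.shape[0]})"
        )
    return mat[position - 1]


def target_embeddings(table: EmbeddingTable, records) -> np.ndarray:
    """Stack target-site embedding vectors for a batch of site records.

    Raises KeyError listing every protein id that has no stored matrix.
    """
    missing = sorted({r.protein_id for r in records if r.protein_id not in table.entries})
    if missing:
        raise KeyError(f"missing embeddings for proteins: {', '.join(missing)}")
    return np.stack([target_embedding(table, r.protein_id, r.position) for r in records])
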