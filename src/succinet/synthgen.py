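"""Synthetic fixture generator.

Produces the three inputs the pipeline consumes — protein sequences
(FASTA), labelled lysine sites (TSV) and surrogate per-residue
embeddings (keyed archive) — with a controllable, fully seeded signal:

* *sequence signal*: positive sites carry a local compositional motif —
  at each motif offset around the target lysine, the residue is drawn
  from a small motif alphabet with probability ``motif_p`` instead of
  the uniform background;
* *embedding signal*: target-site embedding rows of positives are
  shifted by ``delta`` along a fixed random unit direction, negatives
  (and all non-site rows) are isotropic Gaussian noise.

The generator emulates class-separable windows and embeddings only; it
makes no attempt to mimic real succinylation sequence statistics or the
geometry of actual protein-language-model embeddings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .plm_store import EmbeddingTable, write_embeddings
from .seqdata import ALPHABET, ProteinRecord, write_fasta


@dataclass
class SynthConfig:
    #: defaults sized so the balanced dataset lands near 2,000 sites at a
    #: realistic positive rate (~9% of lysines carry the modification in
    #: curated succinylation data; balancing is done downstream by
    #: undersampling, mirroring the real pipeline)
    n_proteins: int = 1050
    length_range: tuple[int, int] = (150, 250)
    positive_fraction: float = 0.09
    motif_offsets: tuple[int, ...] = (-3, -2, -1, 1, 2, 3)
    motif_alphabet: str = "EDGA"
    motif_p: float = 0.5
    plm_width: int = 64
    delta: float = 1.0
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.motif_p <= 1.0:
            raise ValueError("motif_p must be in [0, 1]")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if 0 in self.motif_offsets:
            raise ValueError("motif offsets must not include the target position")


@dataclass
class SynthData:
    proteins: list[ProteinRecord]
    site_labels: list[tuple[str, int, int]]  # (protein_id, position, label)
    embeddings: EmbeddingTable
    truth: dict = field(default_factory=dict)


def generate(config: SynthConfig) -> SynthData:
    """Generate a deterministic synthetic dataset from the config seed."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    aa = np.array(list(ALPHABET))
    motif = np.array(list(config.motif_alphabet))

    proteins: list[ProteinRecord] = []
    positives: list[tuple[str, int]] = []
    negatives: list[tuple[str, int]] = []
    pos_positions: dict[str, list[int]] = {}

    for i in range(config.n_proteins):
        pid = f"synth{i:04d}"
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(aa, size=length)
        if not np.any(seq == "K"):
            seq[int(rng.integers(0, length))] = "K"
        # choose positive lysines, then plant the motif around them
        k_pos = np.flatnonzero(seq == "K") + 1  # 1-based
        n_pos = int(round(config.positive_fraction * len(k_pos)))
        chosen = rng.choice(len(k_pos), size=n_pos, replace=False) if n_pos else []
        chosen_positions = sorted(int(k_pos[j]) for j in chosen)
        for p in chosen_positions:
            for off in config.motif_offsets:
                idx = p - 1 + off
                if 0 <= idx < length and rng.random() < config.motif_p:
                    seq[idx] = motif[int(rng.integers(0, len(motif)))]
        # motif writes never touch the chosen lysines themselves, but may
        # erase *other* lysines; re-enumerate candidates afterwards
        sequence = "".join(seq)
        proteins.append(ProteinRecord(pid, sequence))
        final_k = [j + 1 for j, c in enumerate(sequence) if c == "K"]
        pos_set = set(chosen_positions)
        pos_positions[pid] = chosen_positions
        for p in final_k:
            (positives if p in pos_set else negatives).append((pid, p))

    # class-separable surrogate embeddings
    u = rng.normal(size=config.plm_width)
    u /= np.linalg.norm(u)
    entries: dict[str, np.ndarray] = {}
    for prot in proteins:
        mat = rng.normal(0.0, config.sigma, size=(len(prot.sequence), config.plm_width))
        for p in pos_positions[prot.id]:
            mat[p - 1] += config.delta * u
        entries[prot.id] = mat.astype(np.float32)
    table = EmbeddingTable(entries=entries, model="synthetic-surrogate")

    site_labels = [(pid, p, 1) for pid, p in positives] + [
        (pid, p, 0) for pid, p in negatives
    ]
    site_labels.sort()
    truth = {
        "config": {**asdict(config), "length_range": list(config.length_range),
                   "motif_offsets": list(config.motif_offsets)},
        "u": u.tolist(),
        "delta": config.delta,
        "motif_p": config.motif_p,
        "n_positive": len(positives),
        "n_negative": len(negatives),
    }
    return SynthData(proteins=proteins, site_labels=site_labels,
                     embeddings=table, truth=truth)


def generate_to_dir(config: SynthConfig, outdir: str | Path) -> SynthData:
    """Generate and write fixture files (FASTA, TSV, archive, truth JSON)."""
    data = generate(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(data.proteins, outdir / "proteins.fasta")
    with open(outdir / "sites.tsv", "w") as fh:
        fh.write("protein_id\tposition\tlabel\n")
        for pid, pos, label in data.site_labels:
            fh.write(f"{pid}\t{pos}\t{label}\n")
    write_embeddings(data.embeddings, outdir / "embeddings.npz")
    (outdir / "truth.json").write_text(json.dumps(data.truth))
    return data
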