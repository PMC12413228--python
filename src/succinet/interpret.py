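"""Shapley attribution of window positions, with structural aggregation.

Attribution is over the 33 token positions of the sequence window (the
PLM vector of the instance is held fixed inside ``predict_fn``). Masked
(excluded) positions take their values from background windows, and the
value of a coalition is the mean model output over the background set —
the Kernel SHAP masking convention. Two estimators are provided:

* :func:`exact_shapley` — classical enumeration over all subsets of the
  attributed positions (limited to 14 positions); the efficiency axiom
  holds exactly.
* :func:`kernel_shapley` — the Shapley-kernel weighted least-squares
  estimator with the efficiency constraint enforced; it enumerates all
  coalitions when feasible within the sample budget, otherwise samples
  coalitions from the kernel distribution.

For interpretation, attribution profiles are aggregated by window
offset (mean |value| per position) and by Cα–Cα distance from the
target residue in a 3-D structure (mean |value| per distance bin).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from Bio.PDB import PDBParser

from .seqdata import HALF_WIDTH, WINDOW_LENGTH

PredictFn = Callable[[Sequence[str]], np.ndarray]

MAX_EXACT_POSITIONS = 14


@dataclass
class AttributionProfile:
    """Per-window-position Shapley values for one prediction.

    ``values`` has one entry per window offset 0..32; offsets outside
    the attributed set are zero. Efficiency: sum(values) + base_value
    equals the model output on the instance.
    """

    values: np.ndarray
    base_value: float
    instance_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (WINDOW_LENGTH,):
            raise ValueError(f"values must have shape ({WINDOW_LENGTH},)")


@dataclass
class DistanceProfile:
    """Cα distance (Å) of each window residue to the target; NaN = missing."""

    distances: np.ndarray

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if self.distances.shape != (WINDOW_LENGTH,):
            raise ValueError(f"distances must have shape ({WINDOW_LENGTH},)")


def _composites(
    instance: str, backgrounds: Sequence[str], positions: Sequence[int], mask: int
) -> list[str]:
    """Composite windows: positions whose bit is set come from the instance,
    the remaining attributed positions from each background window."""
    out = []
    for bg in backgrounds:
        chars = list(instance)
        for bit, pos in enumerate(positions):
            if not mask >> bit & 1:
                chars[pos] = bg[pos]
        out.append("".join(chars))
    return out


def _coalition_values(
    predict_fn: PredictFn,
    instance: str,
    backgrounds: Sequence[str],
    positions: Sequence[int],
    masks: Sequence[int],
) -> np.ndarray:
    """v(S) for each coalition mask: mean prediction over the background set."""
    windows: list[str] = []
    for mask in masks:
        windows.extend(_composites(instance, backgrounds, positions, mask))
    preds = np.asarray(predict_fn(windows), dtype=float)
    return preds.reshape(len(masks), len(backgrounds)).mean(axis=1)


def _check_inputs(instance, backgrounds, positions):
    if len(instance) != WINDOW_LENGTH:
        raise ValueError(f"instance window must have length {WINDOW_LENGTH}")
    if not backgrounds:
        raise ValueError("need at least one background window")
    if positions is None:
        positions = list(range(WINDOW_LENGTH))
    positions = list(positions)
    if len(set(positions)) != len(positions):
        raise ValueError("duplicate attributed positions")
    return positions


def exact_shapley(
    predict_fn: PredictFn,
    instance_window: str,
    background_windows: Sequence[str],
    positions: Sequence[int] | None = None,
    instance_id: str | None = None,
) -> AttributionProfile:
    """Classical Shapley values by full subset enumeration.

    Limited to at most 14 attributed positions (2^m coalitions); use
    :func:`kernel_shapley` beyond that.
    """
    positions = _check_inputs(instance_window, background_windows, positions)
    m = len(positions)
    if m > MAX_EXACT_POSITIONS:
        raise ValueError(
            f"{m} positions exceed the enumeration limit of {MAX_EXACT_POSITIONS}; "
            "use kernel_shapley"
        )
    masks = list(range(1 << m))
    v = _coalition_values(
        predict_fn, instance_window, background_windows, positions, masks
    )
    fact = [math.factorial(i) for i in range(m + 1)]
    weights = [fact[s] * fact[m - 1 - s] / fact[m] for s in range(m)]
    phi = np.zeros(WINDOW_LENGTH)
    for bit, pos in enumerate(positions):
        total = 0.0
        for mask in masks:
            if mask >> bit & 1:
                continue
            s = bin(mask).count("1")
            total += weights[s] * (v[mask | 1 << bit] - v[mask])
        phi[pos] = total
    return AttributionProfile(
        values=phi, base_value=float(v[0]), instance_id=instance_id
    )


def kernel_shapley(
    predict_fn: PredictFn,
    instance_window: str,
    background_windows: Sequence[str],
    n_samples: int = 4096,
    seed: int = 0,
    positions: Sequence[int] | None = None,
    instance_id: str | None = None,
) -> AttributionProfile:
    """Kernel SHAP: coalition sampling + Shapley-kernel weighted least squares.

    The Shapley kernel weight of a coalition z is
    (M-1) / (C(M,|z|) * |z| * (M-|z|)); the efficiency constraint
    (attributions sum to f(x) - base) is enforced by substitution. When
    every non-trivial coalition fits in ``n_samples`` the solve is exact.
    """
    positions = _check_inputs(instance_window, background_windows, positions)
    m = len(positions)
    if m < 2:
        raise ValueError("need at least two attributed positions")
    if n_samples < m + 2:
        raise ValueError(f"n_samples must be at least M+2 = {m + 2}")

    base = float(
        _coalition_values(predict_fn, instance_window, background_windows, positions, [0])[0]
    )
    fx = float(np.mean(np.asarray(predict_fn([instance_window]), dtype=float)))

    n_all = (1 << m) - 2  # non-empty proper coalitions
    if n_all <= n_samples:
        masks = list(range(1, (1 << m) - 1))
        sizes = np.array([bin(mask).count("1") for mask in masks])
        weights = (m - 1) / (
            np.array([math.comb(m, s) for s in sizes]) * sizes * (m - sizes)
        )
    else:
        rng = np.random.default_rng(seed)
        size_w = np.array([(m - 1) / (s * (m - s)) for s in range(1, m)])
        size_w /= size_w.sum()
        masks = []
        for _ in range(n_samples):
            s = int(rng.choice(np.arange(1, m), p=size_w))
            bits = rng.choice(m, size=s, replace=False)
            masks.append(int(np.sum(1 << bits)))
        weights = np.ones(len(masks))  # sampling frequency carries the kernel

    v = _coalition_values(
        predict_fn, instance_window, background_windows, positions, masks
    )
    z = np.zeros((len(masks), m))
    for j, mask in enumerate(masks):
        for bit in range(m):
            z[j, bit] = mask >> bit & 1

    # enforce efficiency by eliminating the last coefficient
    e = fx - base
    y = v - base - z[:, -1] * e
    a = z[:, :-1] - z[:, -1:]
    sw = np.sqrt(weights)
    coef, *_ = np.linalg.lstsq(a * sw[:, None], y * sw, rcond=None)
    phi_local = np.append(coef, e - coef.sum())
    phi = np.zeros(WINDOW_LENGTH)
    phi[positions] = phi_local
    return AttributionProfile(values=phi, base_value=base, instance_id=instance_id)


# ---------------------------------------------------------------------------
# Structure handling

def read_structure_ca(pdb_path: str | Path, chain: str = "A") -> dict[int, np.ndarray]:
    """Cα coordinates per residue number from the ATOM records of a PDB file.

    HETATM residues are skipped; for altLoc duplicates the first
    conformer encountered is kept.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(pdb_path))
    model = next(structure.get_models())
    if chain not in model:
        raise KeyError(f"chain {chain!r} not found in {pdb_path}")
    coords: dict[int, np.ndarray] = {}
    for residue in model[chain]:
        if residue.id[0] != " ":  # skip HETATM / water
            continue
        if "CA" not in residue:
            continue
        atom = residue["CA"]
        if atom.is_disordered():
            atom = atom.disordered_get_list()[0]
        coords[residue.id[1]] = np.asarray(atom.get_coord(), dtype=float)
    if not coords:
        raise ValueError(f"no Cα atoms in {pdb_path} chain {chain!r}")
    return coords


def window_distances(
    coords: dict[int, np.ndarray], protein_length: int, position: int
) -> DistanceProfile:
    """Cα–Cα distances from each window residue to the target residue.

    Offsets outside the sequence, or residues without a Cα coordinate,
    are marked missing (NaN). The target offset (16) is exactly 0.
    """
    if position not in coords:
        raise KeyError(f"target residue {position} has no Cα coordinate")
    target = coords[position]
    d = np.full(WINDOW_LENGTH, np.nan)
    for off in range(WINDOW_LENGTH):
        resnum = position + (off - HALF_WIDTH)
        if not 1 <= resnum <= protein_length or resnum not in coords:
            continue
        d[off] = float(np.linalg.norm(coords[resnum] - target))
    d[HALF_WIDTH] = 0.0
    return DistanceProfile(distances=d)


# ---------------------------------------------------------------------------
# Aggregation

def aggregate_by_position(profiles: Sequence[AttributionProfile]) -> np.ndarray:
    """Mean absolute attribution per window offset, over many profiles."""
    if not profiles:
        raise ValueError("no profiles to aggregate")
    return np.mean([np.abs(p.values) for p in profiles], axis=0)


def aggregate_by_distance(
    profiles: Sequence[AttributionProfile],
    distance_profiles: Sequence[DistanceProfile],
    bin_width: float = 4.0,
) -> dict[int, tuple[float, int]]:
    """Mean |attribution| per Cα-distance bin [i*w, (i+1)*w).

    The target offset is excluded (its distance is 0 by construction and
    its attribution is structurally zero); missing distances are
    skipped. Empty bins are absent from the result, not zero.
    """
    if len(profiles) != len(distance_profiles):
        raise ValueError("profiles and distance profiles must align")
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for prof, dist in zip(profiles, distance_profiles):
        for off in range(WINDOW_LENGTH):
            if off == HALF_WIDTH:
                continue
            d = dist.distances[off]
            if not np.isfinite(d):
                continue
            b = int(d // bin_width)
            sums[b] = sums.get(b, 0.0) + abs(prof.values[off])
            counts[b] = counts.get(b, 0) + 1
    return {b: (sums[b] / counts[b], counts[b]) for b in sorted(sums)}


def write_position_profile_tsv(mean_abs: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("offset\tmean_abs_shap\n")
        for off, val in enumerate(mean_abs):
            fh.write(f"{off}\t{val:.10g}\n")


def write_distance_profile_tsv(
    bins: dict[int, tuple[float, int]], path: str | Path, bin_width: float = 4.0
) -> None:
    with open(path, "w") as fh:
        fh.write("bin_lo\tbin_hi\tmean_abs_shap\tn\n")
        for b, (mean, n) in bins.items():
            fh.write(f"{b * bin_width:.6g}\t{(b + 1) * bin_width:.6g}\t{mean:.10g}\t{n}\n")
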