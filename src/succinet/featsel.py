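"""Feature-group comparison: PCA reduction, mRMR selection, tree importance.

Feature groups of uneven width (word-embedding features, several PLM
embeddings, PSSM profiles, ...) are first reduced to a common width by
per-group PCA, then compared in two ways: greedy minimum-redundancy
maximum-relevance (mRMR) selection over the pooled matrix, and summed
split-gain importance from a gradient-boosted tree ensemble.

The mRMR variant is MID (mutual-information difference): after picking
the feature with maximal relevance I(f; y), each subsequent pick
maximises I(f; y) - mean_{s in S} I(f; s). Mutual information is the
plug-in estimate after equal-width discretisation into 10 bins; ties
break by pooled column order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA
from xgboost import XGBClassifier

N_BINS = 10


@dataclass
class FeatureGroupSet:
    groups: dict[str, np.ndarray]  # ordered: name -> (n_samples, width)
    labels: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        for name, mat in self.groups.items():
            if mat.shape[0] != n:
                raise ValueError(f"group {name!r} has {mat.shape[0]} rows, expected {n}")

    def pooled(self) -> tuple[np.ndarray, list[tuple[str, int]]]:
        """Column-stack all groups; returns matrix and (group, index) key list."""
        mats = []
        keys: list[tuple[str, int]] = []
        for name, mat in self.groups.items():
            mats.append(mat)
            keys.extend((name, j) for j in range(mat.shape[1]))
        return np.column_stack(mats), keys


@dataclass
class SelectionReport:
    selected: list[tuple[str, int]] = field(default_factory=list)
    per_group_counts: dict[str, int] = field(default_factory=dict)
    per_group_importance: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(
            {
                "selected": [list(t) for t in self.selected],
                "per_group_counts": self.per_group_counts,
                "per_group_importance": self.per_group_importance,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(s)
        return s

    def write_counts_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("group\tcount\timportance\n")
            names = set(self.per_group_counts) | set(self.per_group_importance)
            for name in sorted(names):
                fh.write(
                    f"{name}\t{self.per_group_counts.get(name, 0)}"
                    f"\t{self.per_group_importance.get(name, float('nan')):.6g}\n"
                )


def pca_reduce(fgs: FeatureGroupSet, n_components: int = 10) -> FeatureGroupSet:
    """Reduce every group to ``n_components`` columns by per-group PCA.

    Groups are centred (not scaled); components are orthonormal. A group
    narrower than ``n_components`` is an error.
    """
    n = len(fgs.labels)
    if n <= n_components:
        raise ValueError("need more samples than components")
    reduced: dict[str, np.ndarray] = {}
    for name, mat in fgs.groups.items():
        if mat.shape[1] < n_components:
            raise ValueError(
                f"group {name!r} has width {mat.shape[1]} < {n_components}"
            )
        reduced[name] = PCA(n_components=n_components, svd_solver="full").fit_transform(mat)
    return FeatureGroupSet(groups=reduced, labels=fgs.labels)


def discretize(x: np.ndarray, n_bins: int = N_BINS) -> np.ndarray:
    """Equal-width binning of one column into integer bins [0, n_bins)."""
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return np.zeros(len(x), dtype=np.int64)
    bins = np.minimum(((x - lo) / (hi - lo) * n_bins).astype(np.int64), n_bins - 1)
    return bins


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in MI (nats) between two integer-coded discrete vectors."""
    n = len(a)
    joint = np.zeros((int(a.max()) + 1, int(b.max()) + 1))
    np.add.at(joint, (a, b), 1.0)
    joint /= n
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    outer = np.outer(pa, pb)
    return float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))


def mrmr_select(fgs: FeatureGroupSet, k: int = 40) -> SelectionReport:
    """Greedy MID-scheme mRMR over the pooled feature matrix."""
    pooled, keys = fgs.pooled()
    m = pooled.shape[1]
    if k > m:
        raise ValueError(f"k={k} exceeds pooled feature count {m}")
    y = fgs.labels.astype(np.int64)
    cols = [discretize(pooled[:, j]) for j in range(m)]
    relevance = np.array([mutual_information(c, y) for c in cols])

    selected: list[int] = []
    redundancy_sum = np.zeros(m)
    available = np.ones(m, dtype=bool)
    for step in range(k):
        if step == 0:
            score = relevance.copy()
        else:
            score = relevance - redundancy_sum / step
        score[~available] = -np.inf
        # argmax breaks ties by lowest pooled column index
        pick = int(np.argmax(score))
        selected.append(pick)
        available[pick] = False
        for j in range(m):
            if available[j]:
                redundancy_sum[j] += mutual_information(cols[j], cols[pick])

    counts: dict[str, int] = {name: 0 for name in fgs.groups}
    sel_keys = [keys[i] for i in selected]
    for name, _ in sel_keys:
        counts[name] += 1
    return SelectionReport(selected=sel_keys, per_group_counts=counts)


def group_importance(fgs: FeatureGroupSet, seed: int = 0) -> SelectionReport:
    """Summed, normalised split-gain importance per feature group.

    Fits a gradient-boosted tree ensemble (300 trees, depth 6, learning
    rate 0.1) on the pooled matrix; per-feature gains are normalised to
    sum to 1 over the pool and summed within each group.
    """
    pooled, keys = fgs.pooled()
    y = fgs.labels
    if len(np.unique(y)) < 2:
        raise ValueError("labels are single-class; importance is undefined")
    clf = XGBClassifier(
        n_estimators=300,
        max_depth=6,
        learning_rate=0.1,
        random_state=seed,
        n_jobs=1,
        importance_type="gain",
        verbosity=0,
    )
    clf.fit(pooled, y)
    gains = clf.feature_importances_.astype(float)  # gain, normalised to sum 1
    total = gains.sum()
    if total > 0:
        gains = gains / total
    importance: dict[str, float] = {name: 0.0 for name in fgs.groups}
    for (name, _), g in zip(keys, gains):
        importance[name] += float(g)
    return SelectionReport(per_group_importance=importance)
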