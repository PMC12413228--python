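import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import average_precision_score, roc_auc_score

from succinet.metrics import (
    auprc,
    auroc,
    compute_metrics,
    confusion_counts,
    mcc_from_counts,
    pr_points,
    roc_points,
)


# --- independent brute-force oracles -------------------------------------

def oracle_auroc(labels, scores):
    """Pairwise enumeration of the probability of correct ranking."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


def oracle_metrics(labels, scores, threshold=0.5):
    tp = sum(1 for l, s in zip(labels, scores) if l == 1 and s >= threshold)
    fn = sum(1 for l, s in zip(labels, scores) if l == 1 and s < threshold)
    fp = sum(1 for l, s in zip(labels, scores) if l == 0 and s >= threshold)
    tn = sum(1 for l, s in zip(labels, scores) if l == 0 and s < threshold)
    n = tp + tn + fp + fn
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return dict(accuracy=(tp + tn) / n, precision=prec, recall=rec,
                specificity=spec, f1=f1, mcc=mcc)


def oracle_auprc(labels, scores):
    """Average precision via an explicit sweep over unique thresholds."""
    n_pos = sum(labels)
    thresholds = sorted(set(scores), reverse=True)
    ap, prev_rec = 0.0, 0.0
    for t in thresholds:
        tp = sum(1 for l, s in zip(labels, scores) if l == 1 and s >= t)
        npred = sum(1 for s in scores if s >= t)
        rec = tp / n_pos
        ap += (rec - prev_rec) * (tp / npred)
        prev_rec = rec
    return ap


# --- worked examples -------------------------------------------------------

def test_confusion_counts_example():
    labels = [1, 1, 1, 0, 0, 0, 0, 0]
    scores = [0.9, 0.8, 0.1, 0.7, 0.2, 0.3, 0.1, 0.4]
    c = confusion_counts(labels, scores)
    assert (c.tp, c.fn, c.fp, c.tn) == (2, 1, 1, 4)
    assert c.total == 8


def test_confusion_counts_boundary_inclusive():
    c = confusion_counts([1, 0], [0.5, 0.5])
    assert (c.tp, c.fp) == (1, 1)


def test_confusion_counts_errors():
    with pytest.raises(ValueError):
        confusion_counts([1], [0.1, 0.2])
    with pytest.raises(ValueError):
        confusion_counts([], [])


def test_metrics_hand_example():
    # counts (TP=2, TN=4, FP=1, FN=1)
    labels = [1, 1, 1, 0, 0, 0, 0, 0]
    scores = [0.9, 0.8, 0.1, 0.7, 0.2, 0.3, 0.1, 0.4]
    rep = compute_metrics(labels, scores)
    assert rep.accuracy == pytest.approx(0.75)
    assert rep.precision == pytest.approx(2 / 3)
    assert rep.recall == pytest.approx(2 / 3)
    assert rep.specificity == pytest.approx(0.8)
    assert rep.f1 == pytest.approx(2 / 3)
    assert rep.mcc == pytest.approx(7 / 15)


def test_perfect_and_degenerate_cases():
    labels = [1, 1, 0, 0]
    rep = compute_metrics(labels, [0.9, 0.8, 0.1, 0.2])
    for key in ("accuracy", "f1", "mcc", "auroc", "auprc"):
        assert getattr(rep, key) == pytest.approx(1.0)
    # constant scores: MCC defined as 0 by the zero-denominator rule
    rep0 = compute_metrics(labels, [0.7, 0.7, 0.7, 0.7])
    assert rep0.mcc == 0.0
    # precision 0 when no positive predictions
    repn = compute_metrics(labels, [0.1, 0.2, 0.1, 0.3])
    assert repn.precision == 0.0 and repn.recall == 0.0
    # single-class labels: curve areas flagged as undefined
    rep1 = compute_metrics([1, 1, 1], [0.2, 0.3, 0.4])
    assert rep1.auroc is None and rep1.auprc is None
    with pytest.raises(ValueError):
        auroc([1, 1], [0.1, 0.2])


def test_auroc_extremes():
    assert auroc([1, 0, 1, 0], [1, 0, 1, 0]) == 1.0
    assert auroc([1, 0], [0.4, 0.6]) == 0.0


def test_curve_areas_match_brute_force_on_mixed_example():
    labels = [1, 0, 1, 1, 0, 0]
    scores = [0.8, 0.8, 0.6, 0.3, 0.2, 0.2]
    assert auroc(labels, scores) == pytest.approx(oracle_auroc(labels, scores), abs=1e-12)
    assert auprc(labels, scores) == pytest.approx(oracle_auprc(labels, scores), abs=1e-12)


def test_metrics_agree_with_oracle_on_random_instances(rng):
    for _ in range(300):
        n = int(rng.integers(3, 25))
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        # mix continuous and tie-heavy discrete scores
        scores = np.round(rng.random(n), int(rng.integers(1, 3)))
        rep = compute_metrics(labels, scores)
        want = oracle_metrics(list(labels), list(scores))
        for key, val in want.items():
            assert getattr(rep, key) == pytest.approx(val, abs=1e-12), key
        assert rep.auroc == pytest.approx(oracle_auroc(labels, scores), abs=1e-12)
        assert rep.auprc == pytest.approx(oracle_auprc(labels, scores), abs=1e-12)
        # cross-check against the reference library implementations
        assert rep.auroc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)
        assert rep.auprc == pytest.approx(average_precision_score(labels, scores), abs=1e-12)


@settings(deadline=None, max_examples=60)
@given(st.data())
def test_auroc_monotone_invariance_and_symmetry(data):
    n = data.draw(st.integers(4, 20))
    labels = np.array(data.draw(
        st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
            lambda xs: 0 < sum(xs) < len(xs)
        )
    ))
    # scores on a coarse grid so monotone transforms cannot merge
    # distinct values through floating-point rounding
    scores = np.array(data.draw(
        st.lists(st.integers(-500, 500), min_size=n, max_size=n)
    )) / 100.0
    a = auroc(labels, scores)
    # strictly monotone transform leaves AUROC unchanged
    assert auroc(labels, np.exp(scores)) == pytest.approx(a, abs=1e-12)
    assert auroc(labels, 3 * scores - 7) == pytest.approx(a, abs=1e-12)
    # score negation flips ranking; exact complement when tie-free
    if len(np.unique(scores)) == n:
        assert auroc(labels, -scores) == pytest.approx(1 - a, abs=1e-12)


def test_curve_point_lists():
    labels = [1, 0, 1, 0]
    scores = [0.9, 0.7, 0.6, 0.2]
    roc = roc_points(labels, scores)
    assert roc[0] == (0.0, 0.0) and roc[-1] == (1.0, 1.0)
    pr = pr_points(labels, scores)
    assert pr[0] == (0.5, 1.0)  # highest threshold: 1 of 2 positives, precision 1
    assert pr[-1][0] == 1.0
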