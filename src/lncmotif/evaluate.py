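"""Binary classification metrics and the cross-species evaluation harness.

The six metrics are computed exactly as printed for the positive (lncRNA)
class:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    F1        = TP / (TP + (FP + FN) / 2)
    MCC       = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)

AUROC is the Mann-Whitney estimator (probability a random positive outscores
a random negative, ties counted half), equivalent to the trapezoidal area
under the ROC curve with tie-averaged ranks.  A "weighted" averaging mode
over both classes is available because published per-species tables often
show precision = recall = accuracy, the signature of support-weighted
averaging; the as-printed equations remain the default.
"""
from __future__ import annotations

import math
import warnings
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.stats import rankdata

from .model import TrainedClassifier, predict_batch
from .types import (
    ConfusionCounts,
    CrossSpeciesResult,
    KmerDocument,
    LNCRNA,
    MetricsReport,
)

Label = Union[str, int]


def _as_binary(labels: Sequence[Label]) -> np.ndarray:
    out = np.empty(len(labels), dtype=np.int64)
    for i, lbl in enumerate(labels):
        if isinstance(lbl, str):
            out[i] = 1 if lbl == LNCRNA else 0
        else:
            out[i] = 1 if lbl else 0
    return out


def confusion_counts(truth: Sequence[Label], predicted: Sequence[Label]) -> ConfusionCounts:
    """Count TP/FP/TN/FN with lncRNA as the positive class."""
    if len(truth) != len(predicted):
        raise ValueError("truth and prediction lengths differ")
    if len(truth) == 0:
        raise ValueError("cannot build a confusion matrix from no items")
    t = _as_binary(truth)
    p = _as_binary(predicted)
    return ConfusionCounts(
        TP=int(np.sum((t == 1) & (p == 1))),
        FP=int(np.sum((t == 0) & (p == 1))),
        TN=int(np.sum((t == 0) & (p == 0))),
        FN=int(np.sum((t == 1) & (p == 0))),
    )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"degenerate denominator in {name}; reporting 0", stacklevel=3)
        return 0.0
    return num / den


def compute_metrics(
    counts: ConfusionCounts,
    scores: Optional[Sequence[Tuple[float, Label]]] = None,
    average: str = "binary",
) -> MetricsReport:
    """Six-metric report from confusion counts (AUROC only when scores given).

    ``average='binary'`` applies the printed positive-class equations;
    ``average='weighted'`` support-weights precision/recall/F1 over both
    classes.
    """
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    n = counts.n
    if n == 0:
        raise ValueError("empty confusion table")
    accuracy = (tp + tn) / n
    if average == "binary":
        precision = _safe_div(tp, tp + fp, "precision")
        recall = _safe_div(tp, tp + fn, "recall")
        f1 = _safe_div(tp, tp + 0.5 * (fp + fn), "F1")
    elif average == "weighted":
        # positive class as above; negative class with TN in the TP role
        p_pos = _safe_div(tp, tp + fp, "precision+")
        r_pos = _safe_div(tp, tp + fn, "recall+")
        f_pos = _safe_div(tp, tp + 0.5 * (fp + fn), "F1+")
        p_neg = _safe_div(tn, tn + fn, "precision-")
        r_neg = _safe_div(tn, tn + fp, "recall-")
        f_neg = _safe_div(tn, tn + 0.5 * (fn + fp), "F1-")
        w_pos = (tp + fn) / n
        w_neg = (tn + fp) / n
        precision = w_pos * p_pos + w_neg * p_neg
        recall = w_pos * r_pos + w_neg * r_neg
        f1 = w_pos * f_pos + w_neg * f_neg
    else:
        raise ValueError(f"unknown averaging mode {average!r}")
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _safe_div(tp * tn - fp * fn, mcc_den, "MCC")
    roc = auroc(scores) if scores is not None else None
    return MetricsReport(
        accuracy=accuracy,
        auroc=roc,
        f1=f1,
        mcc=mcc,
        precision=precision,
        recall=recall,
        counts=counts,
        n=n,
    )


def auroc(scores: Sequence[Tuple[float, Label]]) -> float:
    """Mann-Whitney AUROC with tie-averaged ranks."""
    if len(scores) == 0:
        raise ValueError("no scores supplied")
    vals = np.array([s for s, _ in scores], dtype=np.float64)
    truth = _as_binary([t for _, t in scores])
    n_pos = int(truth.sum())
    n_neg = len(truth) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes to be present")
    ranks = rankdata(vals)  # average ranks on ties
    u = ranks[truth == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def evaluate_model(
    model: TrainedClassifier,
    dataset: Sequence[Tuple[KmerDocument, Label]],
    average: str = "binary",
) -> MetricsReport:
    """Predict a labelled dataset and compute the full metric report."""
    docs = [doc for doc, _ in dataset]
    truth = [lbl for _, lbl in dataset]
    scores = predict_batch(model, docs)
    predicted = [s.predicted_label for s in scores]
    counts = confusion_counts(truth, predicted)
    paired = [(s.p_lncRNA, t) for s, t in zip(scores, truth)]
    return compute_metrics(counts, scores=paired, average=average)


def cross_species_evaluate(
    model: TrainedClassifier,
    trained_species: str,
    test_sets: Dict[str, Sequence[Tuple[KmerDocument, Label]]],
    group_map: Dict[str, str],
    average: str = "binary",
) -> Tuple[List[CrossSpeciesResult], Dict[str, float]]:
    """Evaluate one trained model on every other species' test set.

    Returns per-pair metric reports plus the mean accuracy per group pair
    (monocot-monocot, dicot-dicot, monocot-dicot, dicot-monocot).
    """
    if trained_species not in group_map:
        raise KeyError(f"no group assignment for trained species {trained_species!r}")
    results: List[CrossSpeciesResult] = []
    for species, dataset in sorted(test_sets.items()):
        if species not in group_map:
            raise KeyError(f"no group assignment for test species {species!r}")
        report = evaluate_model(model, dataset, average=average)
        pair = f"{group_map[trained_species]}-{group_map[species]}"
        results.append(
            CrossSpeciesResult(
                trained_species=trained_species,
                test_species=species,
                group_pair=pair,
                metrics=report,
            )
        )
    group_acc: Dict[str, List[float]] = {}
    for res in results:
        group_acc.setdefault(res.group_pair, []).append(res.metrics.accuracy)
    group_means = {pair: float(np.mean(accs)) for pair, accs in sorted(group_acc.items())}
    return results, group_means
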