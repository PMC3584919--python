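"""Performance measures: accuracy, sensitivity, F-measure, prediction
similarity, and accuracy-vs-sensitivity sweeps over confidence.

Conventions follow the annotation-transfer literature: a prediction is a true
positive when it agrees with a known EC number at all four fields, a false
positive otherwise, and a query with no prediction is a false negative.
Accuracy = TP/(TP+FP); sensitivity = TP/(TP+FN) exactly as printed (false
positives are *not* part of the sensitivity denominator); ``coverage`` =
(TP+FP)/N is reported separately to surface that ambiguity.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .pipeline import Prediction

TAGS = ("correct", "incorrect", "none")


@dataclass(eq=False)
class EvalReport:
    tp: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    coverage: float
    f_measure: float
    n: int


def f_measure(accuracy: float, sensitivity: float, beta: float = 0.5) -> float:
    """Weighted harmonic mean; beta = 0.5 puts more emphasis on accuracy."""
    if accuracy == 0.0 and sensitivity == 0.0:
        return 0.0
    b2 = beta * beta
    return (1.0 + b2) * accuracy * sensitivity / (b2 * accuracy + sensitivity)


def _truth_of(truth: Mapping[str, Iterable[str]], query: str) -> frozenset[str]:
    if query not in truth:
        raise ValueError(f"no truth annotation for query {query!r}")
    return frozenset(truth[query])


def score_predictions(
    predictions: Mapping[str, Prediction] | Iterable[Prediction],
    truth: Mapping[str, Iterable[str]],
    beta: float = 0.5,
) -> EvalReport:
    preds = (
        list(predictions.values())
        if isinstance(predictions, Mapping)
        else list(predictions)
    )
    tp = fp = fn = 0
    for p in preds:
        known = _truth_of(truth, p.query)
        if p.label is None:
            fn += 1
        elif p.label in known:
            tp += 1
        else:
            fp += 1
    if tp + fp == 0:
        warnings.warn("no predictions made; accuracy undefined, reported as 0")
        accuracy = 0.0
    else:
        accuracy = tp / (tp + fp)
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    n = len(preds)
    return EvalReport(
        tp=tp,
        fp=fp,
        fn=fn,
        accuracy=accuracy,
        sensitivity=sensitivity,
        coverage=(tp + fp) / n if n else 0.0,
        f_measure=f_measure(accuracy, sensitivity, beta),
        n=n,
    )


def prediction_tags(
    predictions: Mapping[str, Prediction],
    truth: Mapping[str, Iterable[str]],
    queries: Sequence[str] | None = None,
) -> list[str]:
    """Per-query tag vector in {correct, incorrect, none} (fixed query order)."""
    queries = sorted(predictions) if queries is None else list(queries)
    tags = []
    for q in queries:
        p = predictions[q]
        known = _truth_of(truth, q)
        if p.label is None:
            tags.append("none")
        elif p.label in known:
            tags.append("correct")
        else:
            tags.append("incorrect")
    return tags


def prediction_similarity(tags1: Sequence[str], tags2: Sequence[str]) -> float:
    """Fraction of queries on which two annotation schemes agree in tag.

    The scalar product S(1,2) = sum_i [tag_i^1 == tag_i^2] / N over the
    three-tag alphabet; symmetric, reflexive (S(v,v)=1) and bounded in [0,1].
    """
    if len(tags1) != len(tags2):
        raise ValueError("tag vectors differ in length")
    if not tags1:
        raise ValueError("empty tag vectors")
    for t in list(tags1) + list(tags2):
        if t not in TAGS:
            raise ValueError(f"unknown tag {t!r}; expected one of {TAGS}")
    return sum(a == b for a, b in zip(tags1, tags2)) / len(tags1)


def roc_sweep(
    predictions: Sequence[tuple[str, str, float]],
    truth: Mapping[str, Iterable[str]],
) -> tuple[list[tuple[float, float]], float]:
    """Accuracy-vs-sensitivity curve over descending confidence thresholds.

    At each distinct z threshold, predictions below it count as abstentions
    (false negatives). The curve is anchored at sensitivity 0 with the
    accuracy of the single most confident prediction, and the area under it
    is the trapezoid over sensitivity.
    """
    entries = list(predictions)
    if not entries:
        raise ValueError("no predictions to sweep")
    n = len(entries)
    zs = sorted({z for _, _, z in entries}, reverse=True)
    points: list[tuple[float, float]] = []
    for thr in zs:
        kept = [(q, lab) for q, lab, z in entries if z >= thr]
        tp = sum(lab in _truth_of(truth, q) for q, lab in kept)
        fp = len(kept) - tp
        fn = n - len(kept)
        sens = tp / (tp + fn) if tp + fn else 0.0
        acc = tp / (tp + fp) if tp + fp else 0.0
        points.append((sens, acc))
    anchor = (0.0, points[0][1])
    curve = [anchor] + points
    sens_arr = np.array([p[0] for p in curve])
    acc_arr = np.array([p[1] for p in curve])
    order = np.argsort(sens_arr, kind="stable")
    auc = float(np.trapezoid(acc_arr[order], sens_arr[order]))
    return points, auc
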