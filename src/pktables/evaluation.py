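"""Stratified splitting, per-class precision/recall/F1 with macro and micro
aggregation, and Cohen's kappa for inter-annotator agreement.
"""
from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np

from .labels import CLASS_ORDER, Label, normalize_label
from .table_io import Corpus

__all__ = [
    "MetricsReport",
    "KappaResult",
    "largest_remainder",
    "stratified_split",
    "score",
    "cohens_kappa",
]


def largest_remainder(total: int, fractions: Sequence[float]) -> list[int]:
    """Allocate ``total`` seats to fractions by largest-remainder rounding.

    Ties in the fractional remainder go to the earlier (lower-index) bucket.
    """
    quotas = [total * f for f in fractions]
    counts = [int(q) for q in quotas]
    remainders = [q - c for q, c in zip(quotas, counts)]
    missing = total - sum(counts)
    for i in sorted(range(len(fractions)), key=lambda i: (-remainders[i], i))[:missing]:
        counts[i] += 1
    return counts


def stratified_split(
    corpus: Corpus,
    fractions: Sequence[float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[Corpus, ...]:
    """Split a labeled corpus preserving class proportions.

    Within each class, counts are allocated by largest-remainder rounding of
    the fractions; the assignment of individual tables is random given
    ``seed``. Splits are disjoint and exhaustive.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {tuple(fractions)}")
    if not corpus.is_labeled:
        raise ValueError("stratified_split requires a fully labeled corpus")
    n_splits = len(fractions)
    by_class: dict[Label, list[int]] = {}
    for i, table in enumerate(corpus):
        by_class.setdefault(table.label, []).append(i)  # type: ignore[arg-type]
    for label, members in by_class.items():
        if len(members) < n_splits:
            raise ValueError(
                f"class {label.value} has only {len(members)} members; "
                f"cannot stratify into {n_splits} splits"
            )
    rng = random.Random(seed)
    assignments: list[list[int]] = [[] for _ in range(n_splits)]
    for label in sorted(by_class, key=lambda l: l.value):
        members = list(by_class[label])
        rng.shuffle(members)
        counts = largest_remainder(len(members), fractions)
        start = 0
        for split_idx, count in enumerate(counts):
            assignments[split_idx].extend(members[start : start + count])
            start += count
    return tuple(
        Corpus(records=[corpus.records[i] for i in sorted(indices)])
        for indices in assignments
    )


@dataclass
class MetricsReport:
    """Per-class P/R/F1 plus macro and micro aggregates and the confusion
    matrix (rows = true class, columns = predicted, in canonical class order).
    """

    per_class: dict[Label, dict[str, float]]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    micro_precision: float
    micro_recall: float
    micro_f1: float
    support: dict[Label, int]
    confusion: np.ndarray

    def to_dict(self) -> dict:
        return {
            "per_class": {
                label.value: dict(metrics) for label, metrics in self.per_class.items()
            },
            "macro": {
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
            },
            "micro": {
                "precision": self.micro_precision,
                "recall": self.micro_recall,
                "f1": self.micro_f1,
            },
            "support": {label.value: n for label, n in self.support.items()},
            "confusion": self.confusion.tolist(),
        }


def _f1(precision: float, recall: float) -> float:
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def score(y_true: Sequence, y_pred: Sequence) -> MetricsReport:
    """Compute per-class precision/recall/F1, macro (unweighted mean over
    classes with non-zero support) and micro (global counts) aggregates.

    Zero-division convention: an empty denominator yields 0.
    """
    if len(y_true) != len(y_pred):
        raise ValueError(
            f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted labels"
        )
    true = [normalize_label(l) for l in y_true]
    pred = [normalize_label(l) for l in y_pred]
    idx = {label: i for i, label in enumerate(CLASS_ORDER)}
    confusion = np.zeros((len(CLASS_ORDER), len(CLASS_ORDER)), dtype=np.int64)
    for t, p in zip(true, pred):
        confusion[idx[t], idx[p]] += 1

    per_class: dict[Label, dict[str, float]] = {}
    support: dict[Label, int] = {}
    for label, i in idx.items():
        tp = int(confusion[i, i])
        fp = int(confusion[:, i].sum()) - tp
        fn = int(confusion[i, :].sum()) - tp
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        per_class[label] = {
            "precision": precision,
            "recall": recall,
            "f1": _f1(precision, recall),
        }
        support[label] = tp + fn

    supported = [label for label in CLASS_ORDER if support[label] > 0]
    macro_p = float(np.mean([per_class[l]["precision"] for l in supported]))
    macro_r = float(np.mean([per_class[l]["recall"] for l in supported]))
    macro_f = float(np.mean([per_class[l]["f1"] for l in supported]))

    tp_total = int(np.trace(confusion))
    n = len(true)
    micro = tp_total / n if n else 0.0

    return MetricsReport(
        per_class=per_class,
        macro_precision=macro_p,
        macro_recall=macro_r,
        macro_f1=macro_f,
        micro_precision=micro,
        micro_recall=micro,
        micro_f1=micro,
        support=support,
        confusion=confusion,
    )


@dataclass
class KappaResult:
    """Chance-corrected agreement: K = (p_o - p_e) / (1 - p_e)."""

    p_o: float
    p_e: float
    kappa: float


def cohens_kappa(labels_a: Sequence[Hashable], labels_b: Sequence[Hashable]) -> KappaResult:
    """Cohen's kappa between two annotators' label vectors.

    ``p_o`` is the observed agreement fraction; ``p_e`` the chance agreement
    from the two annotators' marginal distributions. The degenerate case of a
    single shared category (p_e = 1, p_o = 1) is defined as K = 1.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError(
            f"length mismatch: {len(labels_a)} vs {len(labels_b)} labels"
        )
    n = len(labels_a)
    if n == 0:
        raise ValueError("cohens_kappa requires at least one label pair")
    p_o = sum(a == b for a, b in zip(labels_a, labels_b)) / n
    categories = set(labels_a) | set(labels_b)
    counts_a = {c: 0 for c in categories}
    counts_b = {c: 0 for c in categories}
    for a in labels_a:
        counts_a[a] += 1
    for b in labels_b:
        counts_b[b] += 1
    p_e = sum((counts_a[c] / n) * (counts_b[c] / n) for c in categories)
    if p_e >= 1.0:
        kappa = 1.0 if p_o == 1.0 else 0.0
    else:
        kappa = (p_o - p_e) / (1 - p_e)
    return KappaResult(p_o=p_o, p_e=p_e, kappa=kappa)
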