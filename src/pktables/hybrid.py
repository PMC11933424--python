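"""Confidence-gated routing between the supervised classifier and the
zero-shot fallback, plus validation-set threshold selection.

A prediction is routed to the fallback iff its confidence is strictly below
the threshold; when the fallback output is unparseable the supervised label
stands (the router otherwise trusts the fallback unconditionally).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .classifier import Prediction, TableClassifier
from .labels import Label
from .llm_fallback import (
    UNPARSEABLE,
    FallbackLabel,
    LLMBackend,
    PromptTemplate,
    classify_zero_shot,
)
from .table_io import ExtractedTable

logger = logging.getLogger(__name__)

__all__ = [
    "RoutingDecision",
    "DEFAULT_THRESHOLD_CANDIDATES",
    "route",
    "select_threshold",
    "hybrid_classify",
]

#: Candidate confidence thresholds evaluated in the source analysis.
DEFAULT_THRESHOLD_CANDIDATES: tuple[float, ...] = (0.85, 0.9, 0.95)


@dataclass
class RoutingDecision:
    """One table's path through the hybrid pipeline."""

    table_id: str
    supervised: Prediction
    routed: bool
    fallback_label: FallbackLabel | None
    final_label: Label
    threshold: float

    def to_dict(self) -> dict:
        return {
            "table_id": self.table_id,
            "supervised": self.supervised.to_dict(),
            "routed": self.routed,
            "fallback_label": (
                None
                if self.fallback_label is None
                else (
                    "UNPARSEABLE"
                    if self.fallback_label is UNPARSEABLE
                    else self.fallback_label.value
                )
            ),
            "final_label": self.final_label.value,
            "threshold": self.threshold,
        }


def _check_threshold(threshold: float) -> float:
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    return float(threshold)


def route(prediction: Prediction, threshold: float) -> bool:
    """True iff the prediction goes to the fallback: confidence strictly
    below the threshold (confidence exactly at the threshold stays
    supervised)."""
    threshold = _check_threshold(threshold)
    return prediction.confidence < threshold


def select_threshold(
    val_predictions: Sequence[tuple[Prediction, Label]],
    candidates: Sequence[float] = DEFAULT_THRESHOLD_CANDIDATES,
    max_routed_frac: float = 0.10,
) -> tuple[float, list[dict]]:
    """Pick the routing threshold from labeled validation predictions.

    For each candidate T the trade-off table records the routed fraction and
    the number of supervised errors with confidence below T (errors the
    fallback could still fix). Chosen T maximizes captured errors subject to
    the routed-fraction cap; if no candidate satisfies the cap, the one with
    the smallest routed fraction wins. Ties prefer the smaller threshold when
    errors are captured (margin against over-routing) and the larger
    threshold when none are.
    """
    if not val_predictions:
        raise ValueError("select_threshold requires a non-empty validation set")
    if not candidates:
        raise ValueError("select_threshold requires at least one candidate threshold")
    n = len(val_predictions)
    rows: list[dict] = []
    for candidate in candidates:
        threshold = _check_threshold(candidate)
        routed = [p for p, _ in val_predictions if p.confidence < threshold]
        captured = sum(
            1
            for p, gold in val_predictions
            if p.confidence < threshold and p.label != Label(gold)
        )
        rows.append(
            {
                "threshold": threshold,
                "routed_fraction": len(routed) / n,
                "captured_errors": captured,
            }
        )

    qualifying = [r for r in rows if r["routed_fraction"] <= max_routed_frac]
    if qualifying:
        chosen = max(
            qualifying,
            key=lambda r: (
                r["captured_errors"],
                -r["routed_fraction"],
                -r["threshold"] if r["captured_errors"] > 0 else r["threshold"],
            ),
        )
    else:
        chosen = min(rows, key=lambda r: (r["routed_fraction"], -r["threshold"]))
    return chosen["threshold"], rows


def hybrid_classify(
    classifier: TableClassifier,
    backend: LLMBackend,
    template: PromptTemplate,
    tables: Sequence[ExtractedTable],
    threshold: float,
) -> list[RoutingDecision]:
    """Classify tables supervised-first, escalating low-confidence cases to
    the zero-shot fallback. Backend failures degrade to the supervised label.
    """
    threshold = _check_threshold(threshold)
    decisions: list[RoutingDecision] = []
    n_routed = 0
    for table in tables:
        prediction = classifier.predict_table(table)
        routed = route(prediction, threshold)
        fallback: FallbackLabel | None = None
        final = prediction.label
        if routed:
            n_routed += 1
            fallback = classify_zero_shot(backend, template, table)
            if fallback is not UNPARSEABLE:
                final = fallback  # type: ignore[assignment]
        decisions.append(
            RoutingDecision(
                table_id=table.table_id,
                supervised=prediction,
                routed=routed,
                fallback_label=fallback,
                final_label=final,
                threshold=threshold,
            )
        )
    if tables:
        logger.info(
            "hybrid routing: %d/%d tables (%.1f%%) below T=%.2f",
            n_routed,
            len(tables),
            100.0 * n_routed / len(tables),
            threshold,
        )
    return decisions
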