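"""Weighted majority-vote consensus of calibrated predictors.

Each non-missing tool contributes sign(P_i) * C_i, where P_i is +1 for a
deleterious call and -1 for a neutral call, and C_i is the tool's calibrated
confidence (observed accuracy).  The consensus score is the mean of these
signed terms over the N tools that returned a prediction:

    score = (sum_i C_i * P_i) / N        in [-1, +1]

A score in [-1, 0] is called neutral; (0, +1] deleterious.  |score| is the
consensus' own confidence and is itself calibrated to observed accuracy.
Missing tools are simply dropped and N renormalised, which is what lets the
consensus cover every mutation even when constituents do not.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

from .calibration import transform
from .errors import NoPredictionError, ValidationError
from .records import (
    CONSENSUS_TOOL,
    DELETERIOUS,
    NEUTRAL,
    CalibrationModel,
    ConsensusResult,
    Contribution,
    MutationKey,
    ToolPrediction,
)


def prediction_sign(predicted_class: str) -> int:
    """+1 for deleterious, -1 for neutral."""
    if predicted_class == DELETERIOUS:
        return 1
    if predicted_class == NEUTRAL:
        return -1
    raise ValidationError(
        f"cannot sign predicted_class {predicted_class!r}; "
        "missing predictions must be filtered first"
    )


def consensus_score(contributions: Sequence[Contribution]) -> float:
    """Mean signed calibrated confidence over non-missing tools."""
    if not contributions:
        raise NoPredictionError("no non-missing tool contributions")
    total = 0.0
    for c in contributions:
        if not 0.0 <= c.confidence <= 1.0:
            raise ValidationError(
                f"calibrated confidence outside [0, 1]: {c.confidence} "
                f"({c.tool})"
            )
        total += c.sign * c.confidence
    return total / len(contributions)


def classify(score: float) -> str:
    """Neutral on [-1, 0], deleterious on (0, +1]."""
    if not -1.0 <= score <= 1.0 or math.isnan(score):
        raise ValidationError(f"score outside [-1, +1]: {score}")
    return DELETERIOUS if score > 0.0 else NEUTRAL


def predict(
    key: MutationKey,
    predictions: Iterable[ToolPrediction],
    model: CalibrationModel,
    consensus_model: CalibrationModel | None = None,
) -> ConsensusResult:
    """Consensus result for one mutation from its tool predictions.

    ``consensus_model`` holds the pseudo-tool entries mapping |score| to
    observed accuracy; when omitted, ``consensus_confidence`` is None.
    """
    contributions = []
    for p in sorted(predictions, key=lambda p: p.tool):
        if p.is_missing:
            continue
        if p.key != key:
            raise ValidationError(
                f"prediction for {p.key} passed to predict() for {key}"
            )
        confidence = transform(
            model, p.tool, p.predicted_class, p.raw_confidence
        )
        contributions.append(
            Contribution(
                tool=p.tool,
                sign=prediction_sign(p.predicted_class),
                confidence=confidence,
            )
        )
    if not contributions:
        raise NoPredictionError(f"all tools missing for mutation {key}")
    score = consensus_score(contributions)
    predicted = classify(score)
    confidence = None
    if consensus_model is not None:
        confidence = transform(
            consensus_model, CONSENSUS_TOOL, predicted, abs(score)
        )
    return ConsensusResult(
        key=key,
        score=score,
        predicted_class=predicted,
        consensus_confidence=confidence,
        n_tools_used=len(contributions),
        contributions=tuple(contributions),
    )


def predict_dataset(
    predictions: Sequence[ToolPrediction],
    model: CalibrationModel,
    consensus_model: CalibrationModel | None = None,
) -> list[ConsensusResult]:
    """Consensus results for every mutation key present in ``predictions``.

    Mutations for which every tool is missing are skipped (the full default
    ensemble always has at least one covering tool, so in practice the
    consensus evaluates everything).
    """
    by_key: dict[MutationKey, list[ToolPrediction]] = {}
    for p in predictions:
        by_key.setdefault(p.key, []).append(p)
    results = []
    for key in sorted(by_key):
        if all(p.is_missing for p in by_key[key]):
            continue
        results.append(predict(key, by_key[key], model, consensus_model))
    return results


def select_top_confident(
    results: Sequence[ConsensusResult], fraction: float
) -> list[ConsensusResult]:
    """The ceil(fraction * n) results with largest |score|.

    Restricting predictions to the most confident consensus calls trades
    coverage for accuracy.  Ties on |score| are broken by mutation key so
    the selection is deterministic.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if not results:
        return []
    k = math.ceil(fraction * len(results))
    ranked = sorted(results, key=lambda r: (-abs(r.score), r.key))
    return ranked[:k]
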